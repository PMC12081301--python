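"""Allelic enrichment, local signal contrast and motif-gain scanning."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopscape.cnv import CnvProfile
from loopscape.genome import GenomicInterval
from loopscape.regmut import (
    Pwm,
    allele_frequencies,
    allelic_enrichment_test,
    local_signal_contrast,
    motif_gain,
    nominate,
    reverse_complement,
    scan_sequence,
    score_distribution,
    score_pvalue,
)
from statsmodels.stats.multitest import multipletests


def variant_row(wgs_ref, wgs_alt, hic_ref, hic_alt, pos=5000):
    return {
        "chrom": "chr1", "pos": pos, "ref": "C", "alt": "T",
        "wgs_ref": wgs_ref, "wgs_alt": wgs_alt,
        "hichip_ref": hic_ref, "hichip_alt": hic_alt,
    }


class TestAlleleFrequencies:
    def test_af_arithmetic(self):
        df = allele_frequencies(pd.DataFrame([variant_row(20, 20, 3, 17)]))
        assert df.at[0, "af_hichip"] == pytest.approx(0.85)
        assert df.at[0, "af_wgs"] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "wgs_depth,hic_depth,passes",
        [(30, 100, False), (31, 31, True), (100, 30, False), (31, 100, True)],
    )
    def test_coverage_filter_is_strict(self, wgs_depth, hic_depth, passes):
        df = allele_frequencies(
            pd.DataFrame([variant_row(wgs_depth - 5, 5, hic_depth - 5, 5)])
        )
        assert bool(df.at[0, "passes_coverage"]) is passes

    def test_zero_depth_gives_missing_af(self):
        df = allele_frequencies(pd.DataFrame([variant_row(0, 0, 10, 10)]))
        assert np.isnan(df.at[0, "af_wgs"])
        assert not df.at[0, "passes_coverage"]


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    n, r, k = a + b + c + d, a + b, a + c
    xs = np.arange(max(0, r + k - n), min(r, k) + 1)
    pmf = stats.hypergeom.pmf(xs, n, r, k)
    return float(pmf[pmf <= stats.hypergeom.pmf(a, n, r, k) * (1 + 1e-7)].sum())


class TestAllelicEnrichment:
    def test_balanced_table_gives_p_one(self):
        df = allelic_enrichment_test(
            allele_frequencies(pd.DataFrame([variant_row(10, 10, 10, 10)]),
                               min_depth=10)
        )
        assert df.at[0, "fisher_p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        df = allelic_enrichment_test(
            allele_frequencies(pd.DataFrame([variant_row(16, 4, 4, 16)]),
                               min_depth=10)
        )
        assert df.at[0, "fisher_p"] == pytest.approx(
            fisher_oracle(16, 4, 4, 16), abs=1e-12
        )
        assert bool(df.at[0, "enriched"])

    def test_bh_step_up_by_hand(self):
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_in_p_rank(self, rng):
        p = np.sort(rng.uniform(0, 1, 50))
        q = multipletests(p, method="fdr_bh")[1]
        assert np.all(np.diff(q) >= -1e-15)

    def test_untested_variants_keep_missing_p(self):
        df = pd.DataFrame([variant_row(20, 20, 3, 17), variant_row(5, 5, 5, 5)])
        out = allelic_enrichment_test(allele_frequencies(df))
        assert np.isnan(out.at[1, "fisher_p"])


def flat_profiles(samples, chrom_len=100_000):
    return {
        s: CnvProfile(s, [(GenomicInterval("chr1", 0, chrom_len), 2.0)])
        for s in samples
    }


class TestLocalSignalContrast:
    samples = [f"s{i}" for i in range(6)]

    def tracks(self, n_bins=200, base=10.0):
        return pd.DataFrame(
            np.full((n_bins, len(self.samples)), base), columns=self.samples
        )

    def sf(self):
        return pd.Series(1.0, index=self.samples)

    def test_window_geometry(self):
        tracks = self.tracks()
        tracks.iloc[90, 0] = 99.0  # bin [9000, 9100): first bin of the window
        res = local_signal_contrast(
            "v", "chr1", 10_000, tracks, self.sf(), flat_profiles(self.samples),
            carriers=["s0"],
        )
        assert res.bins.at[0, "s0"] == 99.0
        assert res.bins.shape == (20, 6)

    def test_identical_signal_gives_zero_t(self):
        res = local_signal_contrast(
            "v", "chr1", 10_000, self.tracks(), self.sf(),
            flat_profiles(self.samples), carriers=["s0"],
        )
        assert res.t_score == 0.0

    def test_boosted_carrier_gives_positive_t(self, rng):
        tracks = self.tracks() + rng.normal(0, 1, (200, 6))
        tracks.iloc[90:110, 0] *= 3.0
        res = local_signal_contrast(
            "v", "chr1", 10_000, tracks, self.sf(),
            flat_profiles(self.samples), carriers=["s0"],
        )
        assert res.t_score > 0
        assert res.p_value < 0.01

    def test_carrier_cn_correction_applies(self):
        tracks = self.tracks()
        tracks["s0"] *= 4.0  # carrier signal inflated fourfold...
        profiles = flat_profiles(self.samples)
        profiles["s0"] = CnvProfile(  # ...by a fourfold amplification
            "s0",
            [(GenomicInterval("chr1", 0, 50_000), 8.0),
             (GenomicInterval("chr1", 50_000, 150_000), 2.0)],
        )
        profiles["s0"].ploidy = 2.0
        res = local_signal_contrast(
            "v", "chr1", 10_000, tracks, self.sf(), profiles, carriers=["s0"],
        )
        assert abs(res.t_score) < 1e-9  # correction removes the CN artifact

    def test_window_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            local_signal_contrast(
                "v", "chr1", 500, self.tracks(), self.sf(),
                flat_profiles(self.samples), carriers=["s0"],
            )

    def test_nomination_requires_all_conditions(self):
        df = pd.DataFrame(
            {
                "passes_coverage": [True, True, True, False],
                "fisher_q": [0.01, 0.2, 0.01, 0.01],
                "enriched": [True, True, True, True],
                "t_score": [2.0, 2.0, -1.0, 2.0],
            }
        )
        np.testing.assert_array_equal(
            nominate(df), [True, False, False, False]
        )


def consensus_pwm(seq, p=0.97):
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(seq), 4), (1 - p) / 3)
    for i, b in enumerate(seq):
        m[i, base_idx[b]] = p
    return Pwm(f"cons_{seq}", m)


class TestMotifScanning:
    def test_dp_distribution_matches_enumeration(self):
        pwm = consensus_pwm("ACGTC", p=0.9)
        scores, probs = score_distribution(pwm)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        lo = pwm.log_odds
        enum: dict[float, float] = {}
        for seq in product(range(4), repeat=5):
            s = round(float(sum(lo[i, b] for i, b in enumerate(seq))), 9)
            enum[s] = enum.get(s, 0.0) + 0.25 ** 5
        for s in enum:
            assert score_pvalue(pwm, s, (scores, probs)) == pytest.approx(
                sum(p for t, p in enum.items() if t >= s - 1e-7), abs=1e-12
            )

    def test_consensus_gain_on_alt_allele(self):
        #            0123456789A  (variant at index 10)
        context = "AAAAAAAAGGTCAGAAAAAAA"  # ref T at center
        pwm = consensus_pwm("GGCCA")  # matches only with alt C at center
        changes = motif_gain(context, "C", [pwm], p_cutoff=0.01)
        assert [c.status for c in changes] == ["gained"]
        assert changes[0].best_alt.score > 0

    def test_locality_no_change_away_from_variant(self):
        context = "ACGTACGTACTTACGTACGTA"
        pwm = consensus_pwm("ACGTA")  # hits both ref and alt away from center
        changes = motif_gain(context, "G", [pwm], p_cutoff=0.01)
        assert changes == []

    def test_reverse_complement_scan_is_involution(self):
        pwm = consensus_pwm("GGATC", p=0.9)
        seq = "ACGGATCTTTACGATCCAAGT"
        fwd = scan_sequence(seq, pwm, p_cutoff=0.05)
        rev = scan_sequence(reverse_complement(seq), pwm, p_cutoff=0.05)
        assert sorted(h.score for h in fwd) == pytest.approx(
            sorted(h.score for h in rev)
        )

    def test_non_acgt_context_skipped(self):
        context = "AAAAAAAAAANAAAAAAAAAA"
        assert motif_gain(context, "C", [consensus_pwm("ACGT")]) is None

    def test_pwm_columns_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Pwm("bad", np.full((4, 4), 0.3))


class TestRegulatoryRecovery:
    def test_planted_variants_recovered(self, cohort):
        from loopscape.cnv import size_factors

        df = allelic_enrichment_test(allele_frequencies(cohort.variants))
        from loopscape.regmut import signal_contrast_table

        df = signal_contrast_table(
            df, cohort.tracks, size_factors(cohort.peak_signal),
            cohort.cnv_profiles, cohort.variant_carriers,
        )
        nom = nominate(df)
        truth = cohort.truth.variant_regulatory
        tp = int((nom & truth).sum())
        assert tp / truth.sum() >= 0.8
        fdr = int((nom & ~truth).sum()) / max(int(nom.sum()), 1)
        assert fdr <= 0.1
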
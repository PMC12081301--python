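"""Synthetic-cohort generator: determinism, planted structure and formats."""

import numpy as np
import pandas as pd
import pytest

from loopscape import io
from loopscape.simulate import (
    CohortConfig,
    simulate_allele_counts,
    simulate_cohort,
    simulate_contact_map,
)

SMALL = dict(
    n_samples=20, n_enhancer_genes=6, n_copy_genes=6, n_null_genes=6,
    n_peaks=80, n_background_loops=60, n_variants=40,
    n_amplicons_per_class=2,
)


class TestDeterminism:
    def test_same_seed_reproduces_every_table(self):
        c1 = simulate_cohort(CohortConfig(seed=42, **SMALL))
        c2 = simulate_cohort(CohortConfig(seed=42, **SMALL))
        pd.testing.assert_frame_equal(c1.peak_signal, c2.peak_signal)
        pd.testing.assert_frame_equal(c1.expression, c2.expression)
        pd.testing.assert_frame_equal(c1.variants, c2.variants)
        pd.testing.assert_frame_equal(c1.tracks, c2.tracks)
        assert c1.loops == c2.loops
        assert c1.truth.gene_class == c2.truth.gene_class
        np.testing.assert_array_equal(
            c1.contact_maps["CT0"].matrix, c2.contact_maps["CT0"].matrix
        )

    def test_different_seed_differs(self):
        c1 = simulate_cohort(CohortConfig(seed=1, **SMALL))
        c2 = simulate_cohort(CohortConfig(seed=2, **SMALL))
        assert not c1.expression.equals(c2.expression)

    def test_written_cohort_round_trips(self, tmp_path):
        c = simulate_cohort(CohortConfig(seed=7, **SMALL))
        c.write(tmp_path)
        assert io.read_loop_table(tmp_path / "union_loops.tsv",
                                  resolution=10_000) == c.loops
        assert io.read_bed(tmp_path / "peaks.bed") == c.peaks
        assert io.read_genes(tmp_path / "genes.tsv") == c.genes
        segs = io.read_seg(tmp_path / "cnv.seg")
        assert segs == c.cnv_segments
        assert (tmp_path / "manifest.json").exists()


class TestContactMap:
    def test_decay_profile_monotone_without_loops(self):
        cm = simulate_contact_map(
            100, [], np.ones(100), decay_exponent=1.0, seed=0,
            base_intensity=200.0,
        )
        means = [np.mean(np.diagonal(cm.matrix, offset=d)) for d in range(40)]
        # strong counts: empirical decay follows the (1 + d)^-1 law closely
        assert means[0] > means[10] > means[30]
        corr = np.corrcoef(
            np.log(np.array(means) + 1), -np.log(1 + np.arange(40))
        )[0, 1]
        assert corr > 0.95

    def test_planted_loop_exceeds_distance_matched_background(self):
        cm = simulate_contact_map(
            100, [(20, 50)], np.ones(100), decay_exponent=1.0, seed=1,
            base_intensity=100.0, loop_enrichment=5.0,
        )
        d = 30
        background = [cm.matrix[i, i + d] for i in range(70) if i != 20]
        assert cm.matrix[20, 50] > np.mean(background)

    def test_cn_doubling_doubles_expected_row_sum(self):
        track = np.ones(80)
        cm1 = simulate_contact_map(80, [], track, 0.5, seed=3,
                                   base_intensity=300.0)
        track2 = track.copy()
        track2[40] = 2.0
        cm2 = simulate_contact_map(80, [], track2, 0.5, seed=3,
                                   base_intensity=300.0)
        ratio = cm2.matrix[40].sum() / cm1.matrix[40].sum()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_loop_outside_matrix_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_contact_map(10, [(5, 20)], np.ones(10), 1.0, seed=0)


class TestAlleleCounts:
    def test_zero_shift_is_null(self):
        df = simulate_allele_counts(4000, (100, 200), regulatory_fraction=0.5,
                                    af_shift=0.0, seed=0)
        af_w = df["wgs_alt"] / (df["wgs_ref"] + df["wgs_alt"])
        af_h = df["hichip_alt"] / (df["hichip_ref"] + df["hichip_alt"])
        assert abs(af_w.mean() - af_h.mean()) < 0.01

    def test_shift_raises_hichip_af_for_regulatory(self):
        df = simulate_allele_counts(2000, (100, 200), regulatory_fraction=0.3,
                                    af_shift=0.3, seed=0)
        af_h = df["hichip_alt"] / (df["hichip_ref"] + df["hichip_alt"])
        af_w = df["wgs_alt"] / (df["wgs_ref"] + df["wgs_alt"])
        delta = (af_h - af_w).groupby(df["is_regulatory"]).mean()
        assert delta[True] == pytest.approx(0.3, abs=0.02)
        assert delta[False] == pytest.approx(0.0, abs=0.02)

    def test_coverage_boundary_all_pass_strict_filter(self):
        from loopscape.regmut import allele_frequencies

        df = simulate_allele_counts(50, (31, 31), 0.1, 0.2, seed=0)
        out = allele_frequencies(df, min_depth=30)
        assert out["passes_coverage"].all()

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            simulate_allele_counts(10, (50, 60), 0.1, 1.0, seed=0)


class TestPlantedStructure:
    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="bin pairs"):
            CohortConfig(n_background_loops=5_000_000)

    def test_enhancer_genes_track_enhancer_signal_not_cn(self):
        """RNA of enhancer-driven genes correlates more with planted enhancer
        signal than with CN in >= 90% of genes across replicate cohorts."""
        wins = total = 0
        for seed in range(8):
            c = simulate_cohort(CohortConfig(seed=seed, **{**SMALL, "n_samples": 60}))
            for g in c.genes:
                if c.truth.gene_class[g.gene_id] != "enhancer-driven":
                    continue
                rna = np.log2(c.expression.loc[g.gene_id] + 1)
                # planted enhancer signal: mean log2 signal of linked peaks
                linked = c.linked_peaks[g.gene_id]
                enh = np.log2(c.peak_signal.iloc[linked] + 1).mean(axis=0)
                seg_cn = [c.cnv_profiles[s].relative_cn(g.interval)
                          for s in c.samples]
                r_enh = abs(np.corrcoef(rna, enh)[0, 1])
                r_cn = abs(np.corrcoef(rna, seg_cn)[0, 1])
                wins += r_enh > r_cn
                total += 1
        assert wins / total >= 0.9

    def test_null_genes_have_no_cn_association(self):
        """Regressing null-gene RNA on CN recovers a zero slope (within two
        standard errors) in >= 93% of gene-replicates."""
        import statsmodels.api as sm

        ok = total = 0
        for seed in range(6):
            c = simulate_cohort(
                CohortConfig(seed=100 + seed, **{**SMALL, "n_samples": 60})
            )
            for g in c.genes:
                if c.truth.gene_class[g.gene_id] != "null":
                    continue
                y = np.log2(c.expression.loc[g.gene_id] + 1).to_numpy()
                x = np.array([c.cnv_profiles[s].relative_cn(g.interval)
                              for s in c.samples])
                fit = sm.OLS(y, sm.add_constant(x)).fit()
                ok += abs(fit.params[1]) <= 2 * fit.bse[1]
                total += 1
        assert ok / total >= 0.93

    def test_ground_truth_covers_every_entity(self, cohort):
        assert set(cohort.truth.gene_class) == {g.gene_id for g in cohort.genes}
        assert set(cohort.truth.loop_labels) == {
            lp.loop_id for lp in cohort.loops
        }
        assert len(cohort.truth.variant_regulatory) == len(cohort.variants)
        assert set(cohort.truth.amplicon_class) == {
            a.amplicon_id for a in cohort.amplicons
        }

    def test_generated_loops_satisfy_span_constraints(self, cohort):
        lo, hi = cohort.config.loop_distance_range
        for lp in cohort.loops:
            assert lo <= lp.anchor2.start - lp.anchor1.start <= hi
            lp.validate_resolution(cohort.config.resolution)
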
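"""Neoloop counting, amplicon-class comparisons and co-amplification."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from loopscape.cnv import CnvProfile
from loopscape.genome import GenomicInterval, LoopRecord
from loopscape.sv import (
    Amplicon,
    class_rate_comparison,
    coamplification_frequency,
    neoloop_quantify,
    rank_sum_test,
)


def gi(start, end, chrom="chrA"):
    return GenomicInterval(chrom, start, end)


def loop(b1, b2, res=10_000, chrom="chrA"):
    return LoopRecord(
        gi(b1 * res, (b1 + 1) * res, chrom),
        gi(b2 * res, (b2 + 1) * res, chrom),
        1.0,
    )


class TestNeoloopQuantify:
    def test_per_mb_arithmetic(self):
        amp = Amplicon("a", "cyclic", [gi(0, 2_000_000)], [("chrA", 1_000_000)])
        loops = [loop(90, 110), loop(95, 120), loop(80, 105), loop(99, 101),
                 loop(10, 20)]
        st = neoloop_quantify(loops, amp)
        assert st.n_loops == 5
        assert st.n_neoloops == 4
        assert st.neoloops_per_mb == pytest.approx(2.0)

    def test_loops_left_of_breakpoint_not_neoloops(self):
        amp = Amplicon("a", "linear", [gi(0, 3_000_000)], [("chrA", 2_500_000)])
        st = neoloop_quantify([loop(10, 50), loop(20, 80)], amp)
        assert st.n_loops == 2
        assert st.n_neoloops == 0

    def test_breakpoint_at_anchor_edges_is_boundary_inclusive_left(self):
        # anchor1.end <= b < anchor2.start
        amp = Amplicon("a", "BFB", [gi(0, 3_000_000)], [("chrA", 110_000)])
        assert neoloop_quantify([loop(10, 20)], amp).n_neoloops == 1  # b == end
        amp2 = Amplicon("a", "BFB", [gi(0, 3_000_000)], [("chrA", 200_000)])
        assert neoloop_quantify([loop(10, 20)], amp2).n_neoloops == 0  # b == start

    def test_matches_brute_force_on_random_loops(self, rng):
        bps = [("chrA", int(p)) for p in rng.integers(0, 3_000_000, 3)]
        amp = Amplicon("a", "complex", [gi(0, 3_000_000)], bps)
        loops = []
        for _ in range(100):
            b1 = int(rng.integers(0, 280))
            loops.append(loop(b1, b1 + int(rng.integers(4, 20))))
        st = neoloop_quantify(loops, amp)
        expected = sum(
            any(lp.anchor1.end <= p < lp.anchor2.start for _, p in bps)
            for lp in loops
        )
        assert st.n_neoloops == expected

    def test_invariant_to_order_and_duplicate_breakpoints(self, rng):
        bps = [("chrA", 500_000), ("chrA", 500_000), ("chrA", 1_500_000)]
        amp = Amplicon("a", "cyclic", [gi(0, 3_000_000)], bps)
        loops = [loop(int(b), int(b) + 10) for b in rng.integers(0, 280, 50)]
        st1 = neoloop_quantify(loops, amp)
        st2 = neoloop_quantify(loops[::-1], amp)
        assert (st1.n_loops, st1.n_neoloops) == (st2.n_loops, st2.n_neoloops)

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            Amplicon("a", "cyclic", [], [])

    def test_cohort_recovery_is_exact(self, cohort):
        for amp in cohort.amplicons:
            st = neoloop_quantify(cohort.amplicon_loops[amp.amplicon_id], amp)
            assert st.n_neoloops == cohort.truth.neoloop_counts[amp.amplicon_id]
            assert st.neoloops_per_mb == pytest.approx(
                st.n_neoloops / (amp.size / 1e6)
            )


class TestClassRateComparison:
    def test_identical_groups_give_p_one(self):
        out = class_rate_comparison({"cyclic": [1, 2, 3], "BFB": [1, 2, 3]})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_match_enumeration(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_extreme_shift_attains_minimum_p(self):
        base = [1.0, 2.0, 3.0, 4.0]
        shifted = [100.0, 101.0, 102.0, 103.0]
        p = rank_sum_test(base, shifted)
        assert p == pytest.approx(2 / 70)  # 2 / C(8,4): both extreme orderings

    def test_exact_enumeration_handles_ties_with_midranks(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        p = rank_sum_test(x, y)
        ranks = stats.rankdata(x + y)
        mu = 3 * 7 / 2
        obs = abs(ranks[:3].sum() - mu)
        count = sum(
            abs(ranks[list(s)].sum() - mu) >= obs - 1e-12
            for s in combinations(range(6), 3)
        )
        assert p == pytest.approx(count / 20)

    def test_large_groups_use_normal_approximation(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        p = rank_sum_test(list(x), list(y))
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))

    def test_small_class_skipped_and_bh_applied(self):
        out = class_rate_comparison(
            {"cyclic": [5, 6, 7], "BFB": [1, 2, 3], "linear": [1.0]}
        )
        assert set(zip(out["class_a"], out["class_b"])) == {("cyclic", "BFB")}
        assert "q" in out.columns

    def test_cohort_cyclic_rates_exceed_linear(self, cohort):
        rates = {}
        for amp in cohort.amplicons:
            from loopscape.sv import neoloop_quantify as nq

            st = nq(cohort.amplicon_loops[amp.amplicon_id], amp)
            rates.setdefault(amp.amp_class, []).append(st.neoloops_per_mb)
        assert np.median(rates["cyclic"]) > np.median(rates["linear"])
        out = class_rate_comparison(rates)
        assert len(out) == 6  # all class pairs compared


class TestCoamplification:
    def profile(self, cn_a, cn_b, sample="s"):
        return CnvProfile(sample, [
            (GenomicInterval("chr7", 0, 1_000_000), cn_a),
            (GenomicInterval("chr7", 1_000_000, 2_000_000), cn_b),
        ])

    A = GenomicInterval("chr7", 100_000, 200_000)
    B = GenomicInterval("chr7", 1_100_000, 1_200_000)

    def test_fraction_of_doubly_amplified_samples(self):
        profs = {f"s{i}": self.profile(8.0, 8.0, f"s{i}") for i in range(3)}
        profs.update(
            {f"t{i}": self.profile(2.0, 8.0, f"t{i}") for i in range(7)}
        )
        assert coamplification_frequency(profs, self.A, self.B) == pytest.approx(0.3)

    def test_threshold_above_all_cn_gives_zero(self):
        profs = {"s": self.profile(4.0, 4.0)}
        assert coamplification_frequency(profs, self.A, self.B,
                                         cn_threshold=10.0) == 0.0

    def test_matches_brute_force_recount(self, rng):
        profs = {}
        cns = rng.uniform(1, 10, (20, 2))
        for i, (ca, cb) in enumerate(cns):
            profs[f"s{i}"] = self.profile(float(ca), float(cb), f"s{i}")
        got = coamplification_frequency(profs, self.A, self.B)
        expected = np.mean((cns[:, 0] > 4.5) & (cns[:, 1] > 4.5))
        assert got == pytest.approx(expected)

    def test_missing_cn_excluded_from_denominator(self):
        profs = {"s0": self.profile(8.0, 8.0)}
        profs["s1"] = CnvProfile(
            "s1", [(GenomicInterval("chr7", 0, 1_000_000), 8.0)]
        )  # no call at interval B
        assert coamplification_frequency(profs, self.A, self.B) == 1.0

    def test_empty_denominator_is_nan(self):
        profs = {"s1": CnvProfile(
            "s1", [(GenomicInterval("chr9", 0, 1_000_000), 8.0)]
        )}
        assert np.isnan(coamplification_frequency(profs, self.A, self.B))
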
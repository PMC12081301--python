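"""Rearrangement-driven enhancer rewiring statistics.

A *neoloop* is a chromatin loop spanning a structural-variant junction --
absent from the unrearranged genome. Here neoloops are identified in
reference coordinates: a loop counted for an amplicon (both anchors inside
the amplicon's intervals) is a neoloop when at least one breakpoint falls
strictly between its anchors. This reference-space rule is exact for
junctions internal to the amplified region; inter-chromosomal junctions are
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnv import CnvProfile
from .genome import GenomicInterval, LoopRecord

logger = logging.getLogger(__name__)

AMPLICON_CLASSES = ("cyclic", "BFB", "complex", "linear")


@dataclass
class Amplicon:
    """A focal amplification: class, genomic footprint and SV breakpoints."""

    amplicon_id: str
    amp_class: str
    intervals: list[GenomicInterval]
    breakpoints: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if self.amp_class not in AMPLICON_CLASSES:
            raise ValueError(
                f"amplicon class must be one of {AMPLICON_CLASSES}, "
                f"got {self.amp_class!r}"
            )
        if not self.intervals:
            raise ValueError("amplicon needs at least one interval")

    @property
    def size(self) -> int:
        return sum(len(iv) for iv in self.intervals)


@dataclass
class NeoloopStats:
    amplicon_id: str
    amp_class: str
    n_loops: int
    n_neoloops: int
    neoloops_per_mb: float


def neoloop_quantify(
    loops: Sequence[LoopRecord], amplicon: Amplicon
) -> NeoloopStats:
    """Count amplicon loops and junction-spanning neoloops, per-Mb normalized.

    A loop belongs to the amplicon when both anchors overlap amplicon
    intervals; it is a neoloop when some breakpoint b on the loop's chromosome
    satisfies anchor1.end <= b < anchor2.start. Duplicate breakpoints and loop
    input order do not affect the counts.
    """
    if amplicon.size == 0:
        raise ValueError("amplicon of zero size")
    bps = sorted({(c, p) for c, p in amplicon.breakpoints})
    n_loops = 0
    n_neo = 0
    for lp in loops:
        in_amp1 = any(lp.anchor1.overlaps(iv) for iv in amplicon.intervals)
        in_amp2 = any(lp.anchor2.overlaps(iv) for iv in amplicon.intervals)
        if not (in_amp1 and in_amp2):
            continue
        n_loops += 1
        if any(
            c == lp.chrom and lp.anchor1.end <= p < lp.anchor2.start
            for c, p in bps
        ):
            n_neo += 1
    return NeoloopStats(
        amplicon_id=amplicon.amplicon_id,
        amp_class=amplicon.amp_class,
        n_loops=n_loops,
        n_neoloops=n_neo,
        neoloops_per_mb=n_neo / (amplicon.size / 1e6),
    )


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p via enumeration with midranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    m = len(x)
    n = len(pooled)
    obs = ranks[:m].sum()
    mu = m * (n + 1) / 2.0
    dev = abs(obs - mu)
    count = 0
    total = comb(n, m)
    for subset in combinations(range(n), m):
        w = ranks[list(subset)].sum()
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / total


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_max: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration for small groups
    (both sizes <= ``exact_max``), normal approximation with tie correction
    otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if len(x) <= exact_max and len(y) <= exact_max:
        return _exact_ranksum_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def class_rate_comparison(
    stats_by_class: dict[str, Sequence[float]], exact_max: int = 10
) -> pd.DataFrame:
    """Pairwise rank-sum tests of neoloops/Mb between amplicon classes, BH.

    Pairs where either class has fewer than 2 observations are skipped with a
    log message. Returns a table with class_a, class_b, p and q columns.
    """
    rows = []
    classes = list(stats_by_class)
    for a, b in combinations(classes, 2):
        xa = list(stats_by_class[a])
        xb = list(stats_by_class[b])
        if len(xa) < 2 or len(xb) < 2:
            logger.info("skipping pair (%s, %s): too few observations", a, b)
            continue
        rows.append({"class_a": a, "class_b": b,
                     "p": rank_sum_test(xa, xb, exact_max)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def coamplification_frequency(
    profiles: dict[str, CnvProfile],
    interval_a: GenomicInterval,
    interval_b: GenomicInterval,
    cn_threshold: float = 4.5,
) -> float:
    """Fraction of samples where both intervals exceed the CN seed threshold.

    A sample's CN at an interval is the length-weighted mean total CN over
    overlapping segments; samples with no CN call at either interval are
    excluded from the denominator. Returns NaN when no sample is evaluable.
    """
    n_eval = 0
    n_both = 0
    for prof in profiles.values():
        cn_a = _total_cn(prof, interval_a)
        cn_b = _total_cn(prof, interval_b)
        if np.isnan(cn_a) or np.isnan(cn_b):
            continue
        n_eval += 1
        if cn_a > cn_threshold and cn_b > cn_threshold:
            n_both += 1
    if n_eval == 0:
        logger.warning("co-amplification frequency undefined: no evaluable sample")
        return float("nan")
    return n_both / n_eval


def _total_cn(prof: CnvProfile, interval: GenomicInterval) -> float:
    weight = 0.0
    acc = 0.0
    for seg, cn in prof.segments:
        if not seg.overlaps(interval):
            continue
        ov = min(seg.end, interval.end) - max(seg.start, interval.start)
        weight += ov
        acc += ov * cn
    return acc / weight if weight else float("nan")
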
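"""Library-size normalization and copy-number correction of chromatin signal.

Copy-number handling follows the ratio convention: a sample's ploidy is the
length-weighted mean total copy number over all its segments, and a feature's
*relative* CN is its length-weighted mean ``total_cn / ploidy`` over the
overlapping segments, so the genome-wide average relative CN is 1. Signal is
corrected only where the relative CN exceeds 1 (amplifications); losses are
left untouched. Features overlapping a CN = 0 segment, or with no CNV call at
all, become missing (NaN) and stay missing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, LoopRecord


@dataclass
class CnvProfile:
    """Per-sample copy-number segments with derived ploidy."""

    sample_id: str
    segments: list[tuple[GenomicInterval, float]]
    hyperseg_threshold: int = 1000
    ploidy: float = field(init=False)
    hyper_segmented: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"{self.sample_id}: at least one segment required")
        lengths = np.array([len(iv) for iv, _ in self.segments], dtype=float)
        cns = np.array([cn for _, cn in self.segments], dtype=float)
        if np.any(cns < 0):
            raise ValueError(f"{self.sample_id}: negative copy number")
        total = lengths.sum()
        if total <= 0:
            raise ValueError(f"{self.sample_id}: zero total segment length")
        self.ploidy = float((lengths * cns).sum() / total)
        self.hyper_segmented = len(self.segments) > self.hyperseg_threshold

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def relative_cn(self, interval: GenomicInterval) -> float:
        """Length-weighted mean of total_cn / ploidy over overlapping segments.

        Returns NaN if no segment overlaps, or if any overlapping segment has
        total CN of exactly zero (homozygous deletion: signal undefined).
        """
        if self.ploidy <= 0:
            return float("nan")
        weight = 0.0
        acc = 0.0
        for seg, cn in self.segments:
            if not seg.overlaps(interval):
                continue
            if cn == 0:
                return float("nan")
            ov = min(seg.end, interval.end) - max(seg.start, interval.start)
            weight += ov
            acc += ov * (cn / self.ploidy)
        if weight == 0:
            return float("nan")
        return acc / weight


def ploidy_and_qc(
    sample_id: str,
    segments: Sequence[tuple[GenomicInterval, float]],
    hyperseg_threshold: int = 1000,
) -> CnvProfile:
    """Build a :class:`CnvProfile`, flagging hyper-segmented samples.

    Ploidy is the length-weighted mean total CN; samples with more than
    ``hyperseg_threshold`` segments are flagged as hyper-segmented (noisy
    CNV calls) and should normally be excluded from CN correction.
    """
    return CnvProfile(
        sample_id=sample_id,
        segments=list(segments),
        hyperseg_threshold=hyperseg_threshold,
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features x samples).

    The reference is the per-feature geometric mean over features positive in
    every sample; each sample's factor is the median ratio of its counts to
    the reference over those features.
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    all_pos = np.all(mat > 0, axis=1)
    if not np.any(all_pos):
        raise ValueError(
            "no feature is positive in all samples; median-of-ratios is "
            "undefined (consider a pseudo-reference fallback)"
        )
    sub = mat[all_pos]
    log_geo = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


def cn_correct(
    signal: pd.DataFrame,
    features: Sequence,
    profiles: dict[str, CnvProfile],
    mode: str = "peak",
) -> pd.DataFrame:
    """Divide size-factor-normalized signal by relative CN where amplified.

    ``features`` is a sequence aligned to the rows of ``signal``: intervals in
    ``mode='peak'``, :class:`~loopscape.genome.LoopRecord` (or (anchor1,
    anchor2) pairs) in ``mode='loop'``. Peaks are divided by ``max(r, 1)``;
    loops by ``max(r1, 1) * max(r2, 1)`` over the two anchors. Features with
    relative CN of NaN (CN = 0 or no call) become missing.
    """
    if mode not in ("peak", "loop"):
        raise ValueError(f"mode must be 'peak' or 'loop', got {mode!r}")
    if len(features) != signal.shape[0]:
        raise ValueError("features length must match signal rows")
    unknown = [s for s in signal.columns if s not in profiles]
    if unknown:
        raise KeyError(f"samples without CNV profile: {unknown}")

    out = signal.astype(float).copy()
    for j, sample in enumerate(signal.columns):
        prof = profiles[sample]
        divisors = np.empty(len(features))
        for i, feat in enumerate(features):
            if mode == "peak":
                r = prof.relative_cn(feat)
                divisors[i] = max(r, 1.0) if np.isfinite(r) else np.nan
            else:
                if isinstance(feat, LoopRecord):
                    a1, a2 = feat.anchor1, feat.anchor2
                else:
                    a1, a2 = feat
                r1 = prof.relative_cn(a1)
                r2 = prof.relative_cn(a2)
                if np.isfinite(r1) and np.isfinite(r2):
                    divisors[i] = max(r1, 1.0) * max(r2, 1.0)
                else:
                    divisors[i] = np.nan
        out.iloc[:, j] = signal.iloc[:, j].to_numpy(dtype=float) / divisors
    return out


def regression_peak_normalize(normalized_count, relative_cn):
    """Peak-count normalization used in the expression model:
    count / (relative CN * 2 + 1). The denominator is >= 1, so zero CN leaves
    the count unchanged rather than dividing by zero.
    """
    normalized_count = np.asarray(normalized_count, dtype=float)
    relative_cn = np.asarray(relative_cn, dtype=float)
    if np.any(normalized_count < 0):
        raise ValueError("normalized_count must be non-negative")
    if np.any(relative_cn < 0):
        raise ValueError("relative_cn must be non-negative")
    result = normalized_count / (relative_cn * 2.0 + 1.0)
    if result.ndim == 0:
        return float(result)
    return result
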
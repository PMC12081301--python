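"""Nomination of noncoding regulatory mutations.

Three lines of evidence are combined per somatic variant:

1. **Allelic enrichment** -- the alt allele is over-represented in H3K27ac
   HiChIP reads relative to WGS (Fisher's exact test on the two assays'
   ref/alt counts, BH-corrected), after requiring read depth > 30 in both.
2. **Local signal contrast** -- carriers show elevated CN-corrected H3K27ac
   signal in the 2-kb window centered on the variant (20 x 100-bp bins,
   Welch t-test vs non-carriers, positive t when carriers are higher).
3. **Motif gain** -- the alt allele creates a transcription-factor binding
   site absent from the reference 21-mer, scored against PWMs with exact
   score-distribution p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnv import CnvProfile
from .genome import GenomicInterval

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

WINDOW_BP = 2000
N_BINS = 20
BIN_BP = WINDOW_BP // N_BINS  # 100 bp


# ---------------------------------------------------------------------------
# Allele frequencies and allelic enrichment
# ---------------------------------------------------------------------------

def allele_frequencies(variants: pd.DataFrame, min_depth: int = 30) -> pd.DataFrame:
    """Add per-assay allele frequencies and the strict coverage filter.

    ``passes_coverage`` requires depth strictly greater than ``min_depth`` in
    both WGS and HiChIP; zero-depth assays get a missing AF and fail.
    """
    df = variants.copy()
    wgs_depth = df["wgs_ref"] + df["wgs_alt"]
    hic_depth = df["hichip_ref"] + df["hichip_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["af_wgs"] = np.where(wgs_depth > 0, df["wgs_alt"] / wgs_depth, np.nan)
        df["af_hichip"] = np.where(hic_depth > 0, df["hichip_alt"] / hic_depth, np.nan)
    df["passes_coverage"] = (wgs_depth > min_depth) & (hic_depth > min_depth)
    return df


def allelic_enrichment_test(variants: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher exact test of allele counts between assays, with BH.

    The 2x2 table is [[wgs_ref, wgs_alt], [hichip_ref, hichip_alt]]; only
    variants passing the coverage filter are tested, and BH runs across all
    tested variants. ``enriched`` flags AF_HiChIP > AF_WGS (the direction of
    regulatory interest).
    """
    df = variants.copy()
    if "passes_coverage" not in df.columns:
        df = allele_frequencies(df)
    tested = df.index[df["passes_coverage"]]
    pvals = []
    for i in tested:
        table = [
            [int(df.at[i, "wgs_ref"]), int(df.at[i, "wgs_alt"])],
            [int(df.at[i, "hichip_ref"]), int(df.at[i, "hichip_alt"])],
        ]
        pvals.append(stats.fisher_exact(table, alternative="two-sided")[1])
    df["fisher_p"] = np.nan
    df["fisher_q"] = np.nan
    if len(tested):
        df.loc[tested, "fisher_p"] = pvals
        df.loc[tested, "fisher_q"] = multipletests(pvals, method="fdr_bh")[1]
    df["enriched"] = df["af_hichip"] > df["af_wgs"]
    return df


# ---------------------------------------------------------------------------
# Local H3K27ac signal contrast
# ---------------------------------------------------------------------------

@dataclass
class SignalContrastResult:
    variant_id: str
    t_score: float
    p_value: float
    bins: pd.DataFrame  # 20 bins x samples, normalized + CN-corrected
    q_value: float = np.nan


def _window_bins(
    chrom: str,
    pos: int,
    tracks: pd.DataFrame,
    track_resolution: int,
) -> pd.DataFrame:
    """Extract the 20 x 100-bp window [pos - 1000, pos + 1000) per sample."""
    if track_resolution != BIN_BP:
        raise ValueError(f"tracks must be at {BIN_BP}-bp resolution")
    start = pos - WINDOW_BP // 2
    if start < 0:
        raise ValueError(f"window extends beyond chromosome start at pos {pos}")
    first = start // BIN_BP
    if first + N_BINS > tracks.shape[0]:
        raise ValueError(f"window extends beyond track end at pos {pos}")
    sub = tracks.iloc[first:first + N_BINS].copy()
    sub.index = range(N_BINS)
    return sub


def local_signal_contrast(
    variant_id: str,
    chrom: str,
    pos: int,
    tracks: pd.DataFrame,
    size_factors: pd.Series,
    cn_profiles: dict[str, CnvProfile],
    carriers: Sequence[str],
    track_resolution: int = BIN_BP,
    per_sample_means: bool = False,
) -> SignalContrastResult:
    """Welch t-test of carrier vs non-carrier H3K27ac signal around a variant.

    ``tracks`` holds per-sample binned signal (track bins x samples) at 100-bp
    resolution. Each sample's window is divided by its size factor and by
    max(relative CN, 1) over the window (NaN when the CN call is missing or
    zero). By default the test pools bin-level values across samples per
    group; ``per_sample_means`` switches to one mean value per sample.
    """
    carriers = list(carriers)
    noncarriers = [s for s in tracks.columns if s not in carriers]
    if len(carriers) < 1 or len(noncarriers) < 2:
        raise ValueError("need >= 1 carrier and >= 2 non-carrier samples")
    if pos - WINDOW_BP // 2 < 0:
        raise ValueError(f"window extends beyond chromosome start at pos {pos}")
    window = GenomicInterval(chrom, pos - WINDOW_BP // 2, pos + WINDOW_BP // 2)
    bins = _window_bins(chrom, pos, tracks, track_resolution)
    norm = bins.astype(float)
    for s in tracks.columns:
        v = norm[s] / size_factors[s]
        prof = cn_profiles.get(s)
        if prof is not None:
            r = prof.relative_cn(window)
            v = v / max(r, 1.0) if np.isfinite(r) else v * np.nan
        norm[s] = v

    if per_sample_means:
        car = norm[carriers].mean(axis=0).dropna().to_numpy()
        non = norm[noncarriers].mean(axis=0).dropna().to_numpy()
    else:
        car = norm[carriers].to_numpy().ravel()
        non = norm[noncarriers].to_numpy().ravel()
        car = car[np.isfinite(car)]
        non = non[np.isfinite(non)]
    if len(car) < 2 or len(non) < 2:
        raise ValueError("not enough finite signal values for the t-test")
    if np.std(car) == 0 and np.std(non) == 0:
        t, p = (0.0, 1.0)
    else:
        t, p = stats.ttest_ind(car, non, equal_var=False)
    return SignalContrastResult(
        variant_id=variant_id, t_score=float(t), p_value=float(p), bins=norm
    )


def signal_contrast_table(
    variants: pd.DataFrame,
    tracks: pd.DataFrame,
    size_factors: pd.Series,
    cn_profiles: dict[str, CnvProfile],
    carrier_map: dict[str, Sequence[str]],
    track_resolution: int = BIN_BP,
) -> pd.DataFrame:
    """Run :func:`local_signal_contrast` per variant and BH-adjust across them.

    ``carrier_map`` maps variant id (``chrom:pos``) to carrier sample names.
    Adds ``t_score``, ``t_p`` and ``t_q`` columns.
    """
    df = variants.copy()
    ids = [f"{c}:{p}" for c, p in zip(df["chrom"], df["pos"])]
    tvals, pvals = [], []
    for vid, chrom, pos in zip(ids, df["chrom"], df["pos"]):
        res = local_signal_contrast(
            vid, chrom, int(pos), tracks, size_factors, cn_profiles,
            carrier_map[vid], track_resolution,
        )
        tvals.append(res.t_score)
        pvals.append(res.p_value)
    df["t_score"] = tvals
    df["t_p"] = pvals
    df["t_q"] = multipletests(pvals, method="fdr_bh")[1]
    return df


def nominate(variants: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Boolean nomination: coverage pass, allelic enrichment at BH ``alpha``
    in the HiChIP direction, and a positive local-signal t score."""
    required = ["passes_coverage", "fisher_q", "enriched", "t_score"]
    missing = [c for c in required if c not in variants.columns]
    if missing:
        raise ValueError(f"variants table missing columns {missing}")
    return (
        variants["passes_coverage"]
        & (variants["fisher_q"] < alpha)
        & variants["enriched"]
        & (variants["t_score"] > 0)
    )


# ---------------------------------------------------------------------------
# PWM scanning with exact score-distribution p-values
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """Position weight matrix as per-position base probabilities (w x 4,
    column order ACGT), with background base frequencies."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be w x 4 (ACGT)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM position probabilities must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(self.matrix, 1e-12) / self.background)

    def score(self, seq: str) -> float:
        if len(seq) != self.width:
            raise ValueError("sequence length must equal PWM width")
        lo = self.log_odds
        return float(sum(lo[i, _BASE_INDEX[b]] for i, b in enumerate(seq)))


_DECIMALS = 9  # score keys merged at 1e-9 so DP and enumeration agree exactly


def score_distribution(pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the PWM log-odds score under the background.

    Dynamic program over positions: at each step every achievable partial
    score is extended by the four base contributions weighted by background
    probability. Returns (sorted unique scores, their probabilities).
    """
    lo = pwm.log_odds
    dist: dict[float, float] = {0.0: 1.0}
    for i in range(pwm.width):
        nxt: dict[float, float] = {}
        for s, prob in dist.items():
            for b in range(4):
                key = round(s + lo[i, b], _DECIMALS)
                nxt[key] = nxt.get(key, 0.0) + prob * pwm.background[b]
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    return scores, probs


def score_pvalue(pwm: Pwm, score: float,
                 dist: Optional[tuple[np.ndarray, np.ndarray]] = None) -> float:
    """P(background score >= ``score``), from the exact distribution."""
    if dist is None:
        dist = score_distribution(pwm)
    scores, probs = dist
    # small tolerance so a score computed by summation matches its DP key
    idx = np.searchsorted(scores, score - 10.0 ** (-_DECIMALS + 2))
    return float(probs[idx:].sum())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    motif_id: str
    offset: int
    strand: str
    score: float
    p_value: float


def scan_sequence(seq: str, pwm: Pwm, p_cutoff: float = 0.01) -> list[MotifHit]:
    """All placements (both strands) whose score p-value is <= ``p_cutoff``."""
    dist = score_distribution(pwm)
    hits = []
    w = pwm.width
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(len(s) - w + 1):
            window = s[off:off + w]
            score = pwm.score(window)
            p = score_pvalue(pwm, score, dist)
            if p <= p_cutoff:
                offset = off if strand == "+" else len(seq) - w - off
                hits.append(MotifHit(pwm.motif_id, offset, strand, score, p))
    return hits


@dataclass
class MotifChange:
    motif_id: str
    status: str  # gained | lost
    best_alt: Optional[MotifHit]
    best_ref: Optional[MotifHit]


def motif_gain(
    ref_context: str,
    alt_base: str,
    pwms: Sequence[Pwm],
    p_cutoff: float = 0.01,
) -> Optional[list[MotifChange]]:
    """Motifs gained or lost by a point mutation in its 21-bp context.

    ``ref_context`` is the reference 21-mer with the variant base at position
    11 (1-based). A motif is a hit in a sequence when any placement on either
    strand has score p-value <= ``p_cutoff``; gained = hit in alt only, lost =
    hit in ref only. Returns None (with a log message) when the context or
    alt base contains non-ACGT characters.
    """
    ref_context = ref_context.upper()
    alt_base = alt_base.upper()
    if len(ref_context) != 21:
        raise ValueError(f"context must be 21 bp, got {len(ref_context)}")
    if any(b not in _BASE_INDEX for b in ref_context) or alt_base not in _BASE_INDEX:
        logger.warning("non-ACGT context; variant skipped")
        return None
    alt_context = ref_context[:10] + alt_base + ref_context[11:]
    changes = []
    for pwm in pwms:
        ref_hits = scan_sequence(ref_context, pwm, p_cutoff)
        alt_hits = scan_sequence(alt_context, pwm, p_cutoff)
        best_ref = min(ref_hits, key=lambda h: h.p_value) if ref_hits else None
        best_alt = min(alt_hits, key=lambda h: h.p_value) if alt_hits else None
        if alt_hits and not ref_hits:
            changes.append(MotifChange(pwm.motif_id, "gained", best_alt, best_ref))
        elif ref_hits and not alt_hits:
            changes.append(MotifChange(pwm.motif_id, "lost", best_alt, best_ref))
    return changes
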
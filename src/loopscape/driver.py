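"""Variance partitioning of gene expression between copy number and linked
enhancer activity.

For each expressed gene, expression across samples is modeled by ordinary
least squares as

    RNA ~ H3K27ac + CN

where CN is the gene's ploidy-corrected relative copy number and H3K27ac is a
set of enhancer-activity terms: the individual (log2, standardized) signals of
the gene's loop-linked peaks when there are at most five, or the first five
principal components of the standardized peak matrix otherwise. Each term's
share of the model R^2 is computed with the Lindeman-Merenda-Gold (LMG)
decomposition -- the average over all predictor orderings of the term's
incremental R^2 -- in its non-relative form, so the shares sum to the full
model R^2. A gene is called copy-driven when the CN term carries the largest
share, enhancer-driven when any enhancer term does, and left unclassified when
the winning term's coefficient is not significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import factorial
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .cnv import CnvProfile
from .genome import GeneModel, GenomicInterval, LoopRecord, overlap_map, promoter_window

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gene filtering and peak linking
# ---------------------------------------------------------------------------

def select_and_link(
    genes: Sequence[GeneModel],
    tpm: pd.DataFrame,
    peaks: Sequence[GenomicInterval],
    loops: Sequence[LoopRecord],
    window: int = 1_000_000,
    flank: int = 1000,
    min_tpm: float = 10.0,
    min_samples: int = 3,
) -> tuple[list[GeneModel], dict[str, list[int]]]:
    """Filter to expressed genes and link each to loop-supported peaks.

    A gene is kept when its TPM exceeds ``min_tpm`` in more than
    ``min_samples`` samples (both strict). A peak is linked to a gene when it
    lies within ``window`` of the TSS and overlaps the non-promoter anchor of
    a loop whose other anchor overlaps the gene's promoter window.
    """
    expressed: list[GeneModel] = []
    for g in genes:
        if g.gene_id not in tpm.index:
            logger.info("gene %s absent from TPM matrix; skipped", g.gene_id)
            continue
        if int((tpm.loc[g.gene_id] > min_tpm).sum()) > min_samples:
            expressed.append(g)

    peak_list = list(peaks)
    anchor1 = [lp.anchor1 for lp in loops]
    anchor2 = [lp.anchor2 for lp in loops]
    p_on_a1 = overlap_map(anchor1, peak_list)
    p_on_a2 = overlap_map(anchor2, peak_list)

    linked: dict[str, list[int]] = {}
    for g in expressed:
        prom = promoter_window(g, flank)
        found: set[int] = set()
        for li, lp in enumerate(loops):
            if lp.chrom != g.chrom:
                continue
            if prom.overlaps(lp.anchor1):
                found.update(p_on_a2.get(li, ()))
            if prom.overlaps(lp.anchor2):
                found.update(p_on_a1.get(li, ()))
        kept = [
            pi for pi in sorted(found)
            if peak_list[pi].distance_to(g.tss) <= window
        ]
        linked[g.gene_id] = kept
    return expressed, linked


def peak_pca(peak_signal: pd.DataFrame, ncomp: int = 5) -> pd.DataFrame:
    """Reduce a gene's linked-peak signal (samples x peaks, already log2) to
    predictors: individual standardized peaks when there are <= ``ncomp``,
    otherwise the first ``ncomp`` principal-component scores of the
    standardized matrix.
    """
    complete = peak_signal.dropna()
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 complete samples for PCA")
    X = peak_signal.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if peak_signal.shape[1] <= ncomp:
        return pd.DataFrame(Z, index=peak_signal.index, columns=peak_signal.columns)
    mask = ~np.isnan(Z).any(axis=1)
    pca = PCA(n_components=ncomp)
    scores = np.full((Z.shape[0], ncomp), np.nan)
    scores[mask] = pca.fit_transform(Z[mask])
    return pd.DataFrame(
        scores,
        index=peak_signal.index,
        columns=[f"PC{i + 1}" for i in range(ncomp)],
    )


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

def _subset_r2(y: np.ndarray, X: np.ndarray) -> dict[frozenset, float]:
    """R^2 of the OLS fit (with intercept) for every predictor subset."""
    n, p = X.shape
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        raise ValueError("response has zero variance")
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    cols = list(range(p))
    for size in range(1, p + 1):
        for S in combinations(cols, size):
            Xs = np.column_stack([np.ones(n), X[:, S]])
            beta, _, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
            if rank < Xs.shape[1]:
                raise np.linalg.LinAlgError(
                    f"rank-deficient design for predictor subset {S}"
                )
            resid = y - Xs @ beta
            r2[frozenset(S)] = 1.0 - float(resid @ resid) / sst
    return r2


def lmg_importance(
    response: np.ndarray, predictors: np.ndarray
) -> tuple[np.ndarray, float]:
    """Subset-weighted LMG importances (non-relative) and full-model R^2.

    LMG_j = sum over subsets S not containing j of
    |S|! (p - |S| - 1)! / p! * [R^2(S + j) - R^2(S)], which equals the average
    over all p! predictor orderings of j's incremental R^2. The importances
    sum to the full-model R^2.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if p > 8:
        raise ValueError(f"LMG enumeration limited to 8 predictors, got {p}")
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} samples, got {n}")
    try:
        r2 = _subset_r2(y, X)
    except np.linalg.LinAlgError as exc:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 0.999
        ] if p > 1 else []
        raise ValueError(
            f"rank-deficient full design (near-collinear columns: {pairs})"
        ) from exc
    fp = factorial(p)
    importances = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [c for c in others if c != j]
        for size in range(p):
            w = factorial(size) * factorial(p - size - 1) / fp
            for S in combinations(rest, size):
                Sf = frozenset(S)
                importances[j] += w * (r2[Sf | {j}] - r2[Sf])
    return importances, r2[frozenset(others)]


def lmg_by_permutation(response: np.ndarray, predictors: np.ndarray) -> np.ndarray:
    """Brute-force LMG: average incremental R^2 over all p! orderings.

    Independent check of :func:`lmg_importance`; exponential in p.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    r2 = _subset_r2(y, X)
    importances = np.zeros(p)
    orderings = list(permutations(range(p)))
    for order in orderings:
        seen: frozenset = frozenset()
        for j in order:
            importances[j] += r2[seen | {j}] - r2[seen]
            seen = seen | {j}
    return importances / len(orderings)


def lmg_bootstrap_ci(
    response: np.ndarray,
    predictors: np.ndarray,
    cn_index: int,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded bootstrap CI on (max enhancer LMG - CN LMG).

    A CI excluding zero supports a confident enhancer-vs-copy call; an
    alternative to the winning-term coefficient test.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(response, dtype=float)
    X = np.asarray(predictors, dtype=float)
    n = len(y)
    diffs = np.empty(n_boot)
    enh = [j for j in range(X.shape[1]) if j != cn_index]
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            imp, _ = lmg_importance(y[idx], X[idx])
            diffs[b] = max(imp[j] for j in enh) - imp[cn_index]
        except ValueError:
            diffs[b] = np.nan
    lo, hi = np.nanquantile(diffs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class GeneImportance:
    """Per-gene variance-partition result."""

    gene_id: str
    importances: dict[str, float]
    r_squared: float
    winning_term: str
    winning_pvalue: float
    classification: str  # enhancer-driven | copy-driven | unclassified
    n_samples: int
    response_variance: float
    low_variance: bool


class DriverModelResults:
    """Results of :class:`OncogeneDriverModel.fit`."""

    def __init__(self, gene_results: list[GeneImportance], alpha: float,
                 variance_floor: float):
        self.gene_results = gene_results
        self.alpha = alpha
        self.variance_floor = variance_floor

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for gr in self.gene_results:
            enh_terms = {k: v for k, v in gr.importances.items() if k != "CN"}
            rows.append(
                {
                    "gene": gr.gene_id,
                    "class": gr.classification,
                    "r_squared": gr.r_squared,
                    "lmg_cn": gr.importances.get("CN", np.nan),
                    "lmg_enhancer_top": max(enh_terms.values()) if enh_terms else np.nan,
                    "winning_term": gr.winning_term,
                    "p_value": gr.winning_pvalue,
                    "n_samples": gr.n_samples,
                    "response_variance": gr.response_variance,
                    "low_variance": gr.low_variance,
                }
            )
        return pd.DataFrame(rows).set_index("gene")

    def summary(self) -> str:
        t = self.table
        lines = [
            "Oncogene expression variance partition (RNA ~ H3K27ac + CN)",
            f"  genes fitted:            {len(t)}",
            f"  enhancer-driven:         {(t['class'] == 'enhancer-driven').sum()}",
            f"  copy-driven:             {(t['class'] == 'copy-driven').sum()}",
            f"  unclassified (p >= {self.alpha:g}): "
            f"{(t['class'] == 'unclassified').sum()}",
            f"  below variance floor ({self.variance_floor:g}): "
            f"{int(t['low_variance'].sum())}",
            f"  median model R^2:        {t['r_squared'].median():.3f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DriverModelResults: {len(self.gene_results)} genes>"


class OncogeneDriverModel:
    """OLS variance-partition model of expression on enhancer signal and CN.

    Parameters
    ----------
    expression : DataFrame, genes x samples
        Library-size-normalized expression counts.
    tpm : DataFrame, genes x samples
        TPM used only for the expressed-gene filter.
    genes, peaks, loops
        Gene models, union H3K27ac peak intervals and significant loops.
    peak_signal : DataFrame, peaks x samples
        Size-factor-normalized peak counts (rows aligned to ``peaks``).
    cnv_profiles : mapping sample -> CnvProfile
    cancer_type : optional Series sample -> label
        When given, expression and all predictors are residualized on
        cancer-type indicators before fitting, so the partition is within
        cancer types.
    log_response : bool
        Model log2(normalized count + 1) instead of the raw normalized count.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        tpm: pd.DataFrame,
        genes: Sequence[GeneModel],
        peaks: Sequence[GenomicInterval],
        peak_signal: pd.DataFrame,
        loops: Sequence[LoopRecord],
        cnv_profiles: dict[str, CnvProfile],
        cancer_type: Optional[pd.Series] = None,
        window: int = 1_000_000,
        flank: int = 1000,
        ncomp: int = 5,
        log_response: bool = True,
        cn_normalize_peaks: bool = True,
    ):
        self.expression = expression
        self.tpm = tpm
        self.genes = list(genes)
        self.peaks = list(peaks)
        self.peak_signal = peak_signal
        self.loops = list(loops)
        self.cnv_profiles = cnv_profiles
        self.cancer_type = cancer_type
        self.window = window
        self.flank = flank
        self.ncomp = ncomp
        self.log_response = log_response
        self.cn_normalize_peaks = cn_normalize_peaks
        self.samples = [
            s for s in expression.columns
            if s in peak_signal.columns and s in cnv_profiles
        ]
        if len(self.samples) < 10:
            raise ValueError(
                f"only {len(self.samples)} samples shared across expression, "
                "peak signal and CNV profiles; need >= 10"
            )

    # -- predictor assembly -------------------------------------------------

    def _gene_cn(self, gene: GeneModel) -> pd.Series:
        vals = {
            s: self.cnv_profiles[s].relative_cn(gene.interval)
            for s in self.samples
        }
        return pd.Series(vals, name="CN")

    def _enhancer_predictors(self, gene: GeneModel, peak_idx: list[int]
                             ) -> Optional[pd.DataFrame]:
        if not peak_idx:
            return None
        sig = self.peak_signal.loc[
            self.peak_signal.index[peak_idx], self.samples
        ].T.astype(float)  # samples x peaks
        if self.cn_normalize_peaks:
            from .cnv import regression_peak_normalize

            for pi, col in zip(peak_idx, sig.columns):
                r = np.array([
                    self.cnv_profiles[s].relative_cn(self.peaks[pi])
                    for s in self.samples
                ])
                r = np.where(np.isfinite(r), r, 1.0)
                sig[col] = regression_peak_normalize(
                    np.clip(sig[col].to_numpy(), 0, None), r
                )
        logged = np.log2(sig + 1.0)
        return peak_pca(logged, ncomp=self.ncomp)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        alpha: float = 0.05,
        variance_floor: float = 1.0,
        min_complete: int = 10,
    ) -> DriverModelResults:
        expressed, linked = select_and_link(
            self.genes, self.tpm, self.peaks, self.loops,
            window=self.window, flank=self.flank,
        )
        results: list[GeneImportance] = []
        for gene in expressed:
            gr = self._fit_gene(
                gene, linked.get(gene.gene_id, []), alpha,
                variance_floor, min_complete,
            )
            if gr is not None:
                results.append(gr)
        return DriverModelResults(results, alpha, variance_floor)

    def _fit_gene(
        self,
        gene: GeneModel,
        peak_idx: list[int],
        alpha: float,
        variance_floor: float,
        min_complete: int,
    ) -> Optional[GeneImportance]:
        if gene.gene_id not in self.expression.index:
            logger.info("gene %s missing from expression matrix", gene.gene_id)
            return None
        y = self.expression.loc[gene.gene_id, self.samples].astype(float)
        if self.log_response:
            y = np.log2(y + 1.0)

        design = pd.DataFrame({"CN": self._gene_cn(gene)})
        enh = self._enhancer_predictors(gene, peak_idx)
        if enh is not None:
            design = design.join(enh)

        frame = design.copy()
        frame["__y"] = y
        frame = frame.dropna()
        keep = [c for c in design.columns if frame[c].std(ddof=0) > 0]
        dropped = [c for c in design.columns if c not in keep]
        if dropped:
            logger.info("gene %s: dropped constant predictors %s",
                        gene.gene_id, dropped)
        if not keep:
            return None
        p = len(keep)
        if len(frame) < max(p + 2, min_complete):
            logger.info("gene %s: only %d complete samples for %d predictors",
                        gene.gene_id, len(frame), p)
            return None

        yv = frame["__y"].to_numpy()
        X = frame[keep].to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

        if self.cancer_type is not None:
            ct = pd.get_dummies(
                self.cancer_type.loc[frame.index], drop_first=True
            ).to_numpy(dtype=float)
            if ct.shape[1] > 0:
                proj = np.column_stack([np.ones(len(yv)), ct])
                hat, *_ = np.linalg.lstsq(proj, yv, rcond=None)
                yv = yv - proj @ hat
                coefs, *_ = np.linalg.lstsq(proj, X, rcond=None)
                X = X - proj @ coefs

        try:
            importances, r2 = lmg_importance(yv, X)
        except ValueError as exc:
            logger.warning("gene %s: %s", gene.gene_id, exc)
            return None

        ols = sm.OLS(yv, sm.add_constant(X)).fit()
        pvalues = ols.pvalues[1:]

        win = int(np.argmax(importances))
        win_term = keep[win]
        win_p = float(pvalues[win])
        if win_p >= alpha or not np.isfinite(win_p):
            classification = "unclassified"
        elif win_term == "CN":
            classification = "copy-driven"
        else:
            classification = "enhancer-driven"

        var = float(np.var(frame["__y"].to_numpy(), ddof=1))
        return GeneImportance(
            gene_id=gene.gene_id,
            importances=dict(zip(keep, importances)),
            r_squared=float(r2),
            winning_term=win_term,
            winning_pvalue=win_p,
            classification=classification,
            n_samples=len(frame),
            response_variance=var,
            low_variance=var <= variance_floor,
        )
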
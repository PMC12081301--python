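"""Cell-type deconvolution of E-P loops with pseudobulk scATAC accessibility.

An E-P loop is called cell-type-specific in a sample when the promoter anchor
is supported by both an H3K27ac peak and a pseudobulk scATAC peak, while the
enhancer anchor carries H3K27ac and is accessible in exactly one cell type's
peak set. When both anchors are accessible across more than one cell type the
loop is shared; when neither anchor maps to any scATAC peak it is ambiguous.
Accessibility is binary (peak called per cell population or not). Samples
with too few noncancer cells lack power for pseudobulk peak calling and are
skipped entirely.

Cohort-level validation correlates a loop's interaction signal (EIS) with the
matching cell-type fraction across samples (Spearman, rho cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotatedLoop
from .genome import GenomicInterval, overlapping_indices

logger = logging.getLogger(__name__)


@dataclass
class CellTypePeaks:
    """Pseudobulk accessibility peaks of one cell population in one sample."""

    cell_type: str
    peaks: list[GenomicInterval]
    n_cells: int
    fraction: float
    malignant: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")


@dataclass
class LoopSpecificity:
    loop_id: str
    label: str  # "specific:<cell_type>" | "shared" | "ambiguous"
    promoter_celltypes: frozenset[str] = frozenset()
    enhancer_celltypes: frozenset[str] = frozenset()


def classify_loop_specificity(
    ep_loops: Sequence[AnnotatedLoop],
    h3k27ac_peaks: Sequence[GenomicInterval],
    celltype_peaks: Sequence[CellTypePeaks],
    min_noncancer_cells: int = 110,
) -> Optional[list[LoopSpecificity]]:
    """Classify E-P loops of one sample by cell-type-specific accessibility.

    Returns None (sample skipped) when the sample has fewer than
    ``min_noncancer_cells`` cells outside the malignant population. Raises if
    a loop is not annotated E-P. Classification does not depend on the order
    in which cell types are listed.
    """
    total_fraction = sum(ct.fraction for ct in celltype_peaks)
    if total_fraction > 1.0 + 1e-9:
        raise ValueError("cell-type fractions sum to more than 1")
    noncancer = sum(ct.n_cells for ct in celltype_peaks if not ct.malignant)
    if noncancer < min_noncancer_cells:
        logger.info(
            "sample skipped: %d noncancer cells < %d required",
            noncancer, min_noncancer_cells,
        )
        return None

    h3k = list(h3k27ac_peaks)
    cts = sorted(celltype_peaks, key=lambda ct: ct.cell_type)
    out = []
    for i, al in enumerate(ep_loops):
        if al.annotation != "E-P":
            raise ValueError(
                f"loop {al.loop.loop_id or i} is {al.annotation}, expected E-P"
            )
        prom = al.promoter_anchor
        enh = al.enhancer_anchor
        prom_h3k = bool(overlapping_indices(prom, h3k))
        enh_h3k = bool(overlapping_indices(enh, h3k))
        prom_ct = frozenset(
            ct.cell_type for ct in cts if overlapping_indices(prom, ct.peaks)
        )
        enh_ct = frozenset(
            ct.cell_type for ct in cts if overlapping_indices(enh, ct.peaks)
        )

        if prom_h3k and prom_ct and enh_h3k and len(enh_ct) == 1:
            label = f"specific:{next(iter(enh_ct))}"
        elif prom_h3k and enh_h3k and len(prom_ct) > 1 and len(enh_ct) > 1:
            label = "shared"
        else:
            # covers both "no scATAC peak at either anchor" and the edge
            # cases the three rules leave open (e.g. one supported anchor)
            label = "ambiguous"
        out.append(
            LoopSpecificity(
                loop_id=al.loop.loop_id or f"loop_{i}",
                label=label,
                promoter_celltypes=prom_ct,
                enhancer_celltypes=enh_ct,
            )
        )
    return out


@dataclass
class EisCorrelation:
    rho: float
    p_value: float
    n: int
    passes: bool
    reason: str = ""


def eis_fraction_correlation(
    eis_by_sample: pd.Series,
    fraction_by_sample: pd.Series,
    rho_cutoff: float = 0.30,
) -> EisCorrelation:
    """Spearman correlation of loop EIS with a cell-type fraction.

    Average ranks are used on ties. Passing requires rho >= ``rho_cutoff``;
    zero variance in either vector makes rho undefined and fails with a
    reason. Requires >= 5 paired samples.
    """
    paired = pd.concat(
        [eis_by_sample.rename("eis"), fraction_by_sample.rename("frac")], axis=1
    ).dropna()
    if len(paired) < 5:
        raise ValueError(f"need >= 5 paired samples, got {len(paired)}")
    x = paired["eis"].to_numpy()
    y = paired["frac"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return EisCorrelation(
            rho=float("nan"), p_value=float("nan"), n=len(paired),
            passes=False, reason="zero variance in one vector",
        )
    rho, p = stats.spearmanr(x, y)
    return EisCorrelation(
        rho=float(rho), p_value=float(p), n=len(paired),
        passes=bool(rho >= rho_cutoff),
    )
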
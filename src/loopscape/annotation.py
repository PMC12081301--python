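"""Loop classification by regulatory-element content and union loop/peak sets.

Each loop anchor is labeled ``promoter`` when it overlaps any promoter window
(TSS +/- flank), otherwise ``enhancer`` when it overlaps any H3K27ac peak,
otherwise ``neither``; the loop class follows from the unordered pair of
anchor labels (E-P, E-E, P-P, E-N, P-N, N-N). Promoter takes precedence over
enhancer at an anchor that overlaps both.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genome import (
    GeneModel,
    GenomicInterval,
    LoopRecord,
    overlap_map,
    promoter_window,
)

logger = logging.getLogger(__name__)

_PAIR_TO_CLASS = {
    frozenset(["P"]): "P-P",
    frozenset(["E", "P"]): "E-P",
    frozenset(["P", "N"]): "P-N",
    frozenset(["E"]): "E-E",
    frozenset(["E", "N"]): "E-N",
    frozenset(["N"]): "N-N",
}

_LABEL_TO_CODE = {"promoter": "P", "enhancer": "E", "neither": "N"}


@dataclass
class AnnotatedLoop:
    """A loop with per-anchor regulatory labels and derived class."""

    loop: LoopRecord
    anchor1_label: str  # promoter | enhancer | neither
    anchor2_label: str
    anchor1_genes: frozenset[str] = frozenset()
    anchor2_genes: frozenset[str] = frozenset()

    @property
    def annotation(self) -> str:
        return _PAIR_TO_CLASS[
            frozenset(
                [_LABEL_TO_CODE[self.anchor1_label], _LABEL_TO_CODE[self.anchor2_label]]
            )
        ]

    @property
    def promoter_anchor(self) -> Optional[GenomicInterval]:
        if self.anchor1_label == "promoter":
            return self.loop.anchor1
        if self.anchor2_label == "promoter":
            return self.loop.anchor2
        return None

    @property
    def enhancer_anchor(self) -> Optional[GenomicInterval]:
        if self.anchor1_label == "enhancer":
            return self.loop.anchor1
        if self.anchor2_label == "enhancer":
            return self.loop.anchor2
        return None


def classify_loops(
    loops: Sequence[LoopRecord],
    genes: Sequence[GeneModel],
    peaks: Sequence[GenomicInterval],
    flank: int = 1000,
) -> list[AnnotatedLoop]:
    """Classify loops by overlap of anchors with promoter windows and peaks.

    The classification is symmetric in anchor order; N-N loops (normally
    impossible under peak-anchored loop calling) are allowed with a warning
    so malformed inputs stay visible.
    """
    windows = [promoter_window(g, flank) for g in genes]
    anchors: list[GenomicInterval] = []
    for lp in loops:
        anchors.extend((lp.anchor1, lp.anchor2))
    prom_hits = overlap_map(anchors, windows)
    peak_hits = overlap_map(anchors, peaks)

    annotated: list[AnnotatedLoop] = []
    n_nn = 0
    for i, lp in enumerate(loops):
        labels = []
        gene_sets = []
        for j in (2 * i, 2 * i + 1):
            gset = frozenset(genes[k].gene_id for k in prom_hits.get(j, ()))
            if gset:
                labels.append("promoter")
            elif j in peak_hits:
                labels.append("enhancer")
            else:
                labels.append("neither")
            gene_sets.append(gset)
        al = AnnotatedLoop(
            loop=lp,
            anchor1_label=labels[0],
            anchor2_label=labels[1],
            anchor1_genes=gene_sets[0],
            anchor2_genes=gene_sets[1],
        )
        lp.annotation = al.annotation
        if al.annotation == "N-N":
            n_nn += 1
        annotated.append(al)
    if n_nn:
        logger.warning(
            "%d loops classified N-N (neither anchor overlaps a promoter or peak)",
            n_nn,
        )
    return annotated


def class_counts(annotated: Sequence[AnnotatedLoop]) -> pd.Series:
    """Loop-class tally (the stacked-bar summary of a cohort's loop calls)."""
    counts = Counter(al.annotation for al in annotated)
    return pd.Series(counts).sort_index()


def _resolution_of(loops: Sequence[LoopRecord]) -> int:
    widths = {len(lp.anchor1) for lp in loops} | {len(lp.anchor2) for lp in loops}
    if len(widths) != 1:
        raise ValueError(f"mixed anchor widths/resolutions: {sorted(widths)}")
    return widths.pop()


def merge_loop_sets(
    loop_sets: Sequence[Sequence[LoopRecord]],
    slack: Optional[int] = None,
) -> list[LoopRecord]:
    """Collapse nearby loops across samples into a union loop set.

    Two loops merge when both anchor start offsets lie within ``slack`` bases
    of each other (default: one bin, i.e. the anchor resolution); merging is
    transitive. Each merged record keeps the anchors of its highest-signal
    member, sums member signal and takes the minimum q-value.
    """
    all_loops = [lp for ls in loop_sets for lp in ls]
    if not all_loops:
        return []
    resolution = _resolution_of(all_loops)
    if slack is None:
        slack = resolution

    by_chrom: dict[str, list[int]] = {}
    for i, lp in enumerate(all_loops):
        by_chrom.setdefault(lp.chrom, []).append(i)

    parent = list(range(len(all_loops)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: all_loops[i].anchor1.start)
        for ii, i in enumerate(idxs):
            li = all_loops[i]
            for j in idxs[ii + 1:]:
                lj = all_loops[j]
                if lj.anchor1.start - li.anchor1.start > slack:
                    break
                if abs(lj.anchor2.start - li.anchor2.start) <= slack:
                    union(i, j)

    groups: dict[int, list[LoopRecord]] = {}
    for i in range(len(all_loops)):
        groups.setdefault(find(i), []).append(all_loops[i])

    merged = []
    for members in groups.values():
        rep = max(members, key=lambda lp: lp.signal)
        qvals = [lp.qvalue for lp in members if lp.qvalue is not None]
        merged.append(
            LoopRecord(
                anchor1=rep.anchor1,
                anchor2=rep.anchor2,
                signal=sum(lp.signal for lp in members),
                qvalue=min(qvals) if qvals else None,
            )
        )
    merged.sort(key=lambda lp: (lp.chrom, lp.anchor1.start, lp.anchor2.start))
    for k, lp in enumerate(merged):
        lp.loop_id = f"loop_{k}"
    return merged


def loop_signal_matrix(
    union_loops: Sequence[LoopRecord],
    sample_loop_sets: dict[str, Sequence[LoopRecord]],
) -> pd.DataFrame:
    """Per-sample loop signal on the union loop set.

    Entry (l, s) is the summed signal of sample s's loops whose anchor pairs
    both overlap union loop l's anchors (order-matched after canonical anchor
    sorting); zero when the sample has no overlapping loop.
    """
    index = [
        lp.loop_id if lp.loop_id is not None else f"loop_{i}"
        for i, lp in enumerate(union_loops)
    ]
    mat = pd.DataFrame(
        0.0, index=index, columns=list(sample_loop_sets.keys())
    )
    for sample, loops in sample_loop_sets.items():
        a1 = [lp.anchor1 for lp in loops]
        u1 = [ul.anchor1 for ul in union_loops]
        hits = overlap_map(u1, a1)
        for ui, cands in hits.items():
            ul = union_loops[ui]
            total = 0.0
            matched = False
            for ci in cands:
                lp = loops[ci]
                if lp.anchor2.overlaps(ul.anchor2):
                    total += lp.signal
                    matched = True
            if matched:
                mat.iloc[ui, mat.columns.get_loc(sample)] = total
    return mat
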
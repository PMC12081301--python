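"""Readers and writers for the tabular formats the pipeline touches.

Conventions:

* BED / BEDPE-like loop tables / matrix triplets are native 0-based half-open.
* SEG and GTF-lite gene tables are 1-based inclusive on disk and converted to
  the internal 0-based half-open convention exactly once, here.
* All tables are tab-delimited; loop, SEG, gene and variant tables carry a
  header row.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, LoopRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

LOOP_COLUMNS = ("chr1", "start1", "end1", "chr2", "start2", "end2", "signal")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3+ (no header); extra columns are ignored."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                intervals.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Loop tables (BEDPE-like, with header)
# ---------------------------------------------------------------------------

def read_loop_table(path: PathLike, resolution: Optional[int] = None) -> list[LoopRecord]:
    """Read a loop table: chr1 start1 end1 chr2 start2 end2 signal [qvalue].

    Anchors are reordered so anchor1 precedes anchor2. Inter-chromosomal rows
    are skipped (a count is logged). Malformed rows raise with the offending
    line number. If ``resolution`` is given, anchor widths are validated
    against it.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LOOP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing loop table columns {missing}")
    has_q = "qvalue" in df.columns
    records: list[LoopRecord] = []
    n_trans = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # header is line 1
        if row.chr1 != row.chr2:
            n_trans += 1
            continue
        try:
            rec = LoopRecord(
                anchor1=GenomicInterval(row.chr1, int(row.start1), int(row.end1)),
                anchor2=GenomicInterval(row.chr2, int(row.start2), int(row.end2)),
                signal=float(row.signal),
                qvalue=float(row.qvalue) if has_q and not pd.isna(row.qvalue) else None,
            )
            if resolution is not None:
                rec.validate_resolution(resolution)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    if n_trans:
        logger.warning("%s: skipped %d inter-chromosomal rows", path, n_trans)
    return records


def write_loop_table(loops: Sequence[LoopRecord], path: PathLike) -> None:
    rows = []
    for lp in loops:
        row = {
            "chr1": lp.anchor1.chrom,
            "start1": lp.anchor1.start,
            "end1": lp.anchor1.end,
            "chr2": lp.anchor2.chrom,
            "start2": lp.anchor2.start,
            "end2": lp.anchor2.end,
            "signal": lp.signal,
        }
        if lp.qvalue is not None:
            row["qvalue"] = lp.qvalue
        if lp.annotation is not None:
            row["annotation"] = lp.annotation
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG copy-number segments (1-based inclusive on disk)
# ---------------------------------------------------------------------------

def read_seg(path: PathLike) -> dict[str, list[tuple[GenomicInterval, float]]]:
    """Read SEG (sample chrom start end total_cn) into per-sample segments."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "chrom", "start", "end", "total_cn"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SEG columns {missing}")
    out: dict[str, list[tuple[GenomicInterval, float]]] = {}
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start) - 1, int(row.end))
        out.setdefault(str(row.sample), []).append((iv, float(row.total_cn)))
    return out


def write_seg(
    segments: dict[str, list[tuple[GenomicInterval, float]]], path: PathLike
) -> None:
    rows = [
        {
            "sample": sample,
            "chrom": iv.chrom,
            "start": iv.start + 1,
            "end": iv.end,
            "total_cn": cn,
        }
        for sample, segs in segments.items()
        for iv, cn in segs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (GTF-lite TSV, 1-based inclusive on disk)
# ---------------------------------------------------------------------------

def read_genes(path: PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gene table columns {missing}")
    return [
        GeneModel(
            gene_id=str(row.gene_id),
            interval=GenomicInterval(row.chrom, int(row.start) - 1, int(row.end)),
            strand=str(row.strand),
        )
        for row in df.itertuples(index=False)
    ]


def write_genes(genes: Sequence[GeneModel], path: PathLike) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.interval.start + 1 for g in genes],
            "end": [g.interval.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Contact matrix triplets with a sidecar JSON header
# ---------------------------------------------------------------------------

def read_contact_matrix(path: PathLike):
    """Read a triplet contact matrix plus its ``<path>.json`` sidecar."""
    from .contacts import ContactMatrix

    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar}")
    meta = json.loads(sidecar.read_text())
    n = int(meta["n_bins"])
    res = int(meta["resolution"])
    mat = np.zeros((n, n))
    df = pd.read_csv(path, sep="\t")
    b1 = (df["bin1_start"].to_numpy() // res).astype(int)
    b2 = (df["bin2_start"].to_numpy() // res).astype(int)
    mat[b1, b2] = df["count"].to_numpy()
    mat[b2, b1] = df["count"].to_numpy()
    return ContactMatrix(
        chrom=meta["chrom"],
        resolution=res,
        matrix=mat,
        total_valid_pairs=float(meta["total_valid_pairs"]),
        state=meta.get("state", "raw"),
    )


def write_contact_matrix(cm, path: PathLike) -> None:
    res = cm.resolution
    iu = np.triu_indices(cm.n_bins)
    counts = cm.matrix[iu]
    keep = counts != 0
    pd.DataFrame(
        {
            "bin1_start": iu[0][keep] * res,
            "bin2_start": iu[1][keep] * res,
            "count": counts[keep],
        }
    ).to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(
        json.dumps(
            {
                "chrom": cm.chrom,
                "resolution": res,
                "n_bins": cm.n_bins,
                "total_valid_pairs": cm.total_valid_pairs,
                "state": cm.state,
            }
        )
    )


# ---------------------------------------------------------------------------
# Signal matrices (feature x sample TSV; NaN for missing)
# ---------------------------------------------------------------------------

def read_signal_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_signal_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = (
    "chrom", "pos", "ref", "alt",
    "wgs_ref", "wgs_alt", "hichip_ref", "hichip_alt",
)


def read_variant_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing variant columns {missing}")
    return df


def write_variant_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWMs (JASPAR-style probability matrices, text)
# ---------------------------------------------------------------------------

def read_pwms(path: PathLike):
    """Read PWMs from JASPAR-style text:

        >MOTIF_ID
        A  [ 0.1 0.8 ... ]
        C  [ ... ]
        G  [ ... ]
        T  [ ... ]

    Values are per-position base probabilities.
    """
    from .regmut import Pwm

    pwms = []
    motif_id = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if motif_id is not None:
                    pwms.append(_finish_pwm(motif_id, rows))
                motif_id = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                vals = line[1:].replace("[", " ").replace("]", " ").split()
                rows[base] = [float(v) for v in vals]
    if motif_id is not None:
        pwms.append(_finish_pwm(motif_id, rows))
    return pwms


def _finish_pwm(motif_id, rows):
    from .regmut import Pwm

    matrix = np.array([rows[b] for b in "ACGT"]).T  # width x 4
    return Pwm(motif_id=motif_id, matrix=matrix)


def write_pwms(pwms, path: PathLike) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.6f}" for v in pwm.matrix[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# bedGraph (profile output)
# ---------------------------------------------------------------------------

def write_bedgraph(
    chrom: str, resolution: int, values: Sequence[float], path: PathLike
) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * resolution}\t{(i + 1) * resolution}\t{v:.6g}\n")
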
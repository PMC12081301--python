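"""Synthetic cohort generator.

Generates a fully in-silico tumor cohort with the statistical structure the
downstream analyses assume -- planted enhancer-driven, copy-driven and null
genes; cell-type-specific, shared and ambiguous E-P loops; allele-biased
regulatory variants with a local H3K27ac boost; and focal amplifications with
junction-spanning loops -- together with ground-truth labels for every
planted entity.

Design choices: contact and read counts carry Poisson noise; peak signal
carries log-normal multiplicative noise; one chromosome holds all genes,
peaks, loops and variants (amplicons live on their own contigs); all
randomness flows from a single seed through named substreams, so any
component regenerates identically in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cnv import CnvProfile, ploidy_and_qc
from .contacts import ContactMatrix
from .genome import GeneModel, GenomicInterval, LoopRecord
from .sv import AMPLICON_CLASSES, Amplicon

CHROM = "chr1"

#: substream names, spawned from the master seed in this fixed order
_STREAMS = (
    "layout", "samples", "cnv", "rna", "peaks", "loops",
    "tme", "variants", "tracks", "amplicons", "contacts", "subcomp",
)


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults give 60 samples over 4 cancer types on a 30-Mb chromosome at
    10-kb loop resolution, with 20 enhancer-driven, 20 copy-driven and 20
    null genes; null genes carry no E-P loops (no regulatory linkage is what
    makes them null). Effect sizes give near-binary driver classes, matching
    strongly driven oncogenes.
    """

    n_samples: int = 60
    n_cancer_types: int = 4
    resolution: int = 10_000
    n_bins: int = 3000
    n_enhancer_genes: int = 20
    n_copy_genes: int = 20
    n_null_genes: int = 20
    n_peaks: int = 300
    n_background_loops: int = 300
    loop_distance_range: tuple[int, int] = (40_000, 2_000_000)
    decay_exponent: float = 1.0
    library_size_range: tuple[float, float] = (0.6, 1.6)
    seed: int = 0

    # effect sizes (log2 expression scale)
    rna_base: float = 6.0
    enh_rna_effect: float = 1.5
    cn_rna_effect: float = 1.2
    rna_noise_sd: float = 0.6
    null_rna_noise_sd: float = 1.2
    peak_latent_effect: float = 1.0
    peak_noise_sd: float = 0.5
    peak_base: float = 200.0
    loop_base: float = 30.0
    type_specific_factor: float = 3.0

    # TME
    total_cells: int = 2000
    dirichlet_alpha: tuple[float, ...] = (8.0, 2.0, 1.5, 1.5)
    cell_types: tuple[str, ...] = ("malignant", "myeloid", "tcell", "bcell")

    # variants
    n_variants: int = 300
    coverage_range: tuple[int, int] = (60, 200)
    regulatory_fraction: float = 0.05
    af_shift: float = 0.3
    window_boost: float = 3.0
    variant_spacing: int = 3000

    # amplicons
    n_amplicons_per_class: int = 6
    neoloop_rates: dict = field(
        default_factory=lambda: {
            "cyclic": 6.0, "complex": 3.5, "BFB": 2.0, "linear": 0.8,
        }
    )
    background_loop_rate_per_mb: float = 5.0

    # contact maps (merged per cancer type, coarse bins)
    contact_resolution: int = 100_000
    contact_base_intensity: float = 10.0
    loop_enrichment: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "n_samples", "n_cancer_types", "resolution", "n_bins", "n_peaks",
            "n_enhancer_genes", "n_copy_genes", "n_null_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.loop_distance_range
        if not (0 < lo < hi <= self.n_bins * self.resolution):
            raise ValueError("loop distance range must lie within the chromosome")
        max_pairs = self.n_bins * (self.n_bins - 1) // 2
        if self.n_background_loops > max_pairs:
            raise ValueError("more loops requested than available bin pairs")

    @property
    def n_genes(self) -> int:
        return self.n_enhancer_genes + self.n_copy_genes + self.n_null_genes

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.resolution


@dataclass
class GroundTruth:
    """Planted labels for every simulated entity."""

    gene_class: dict[str, str]              # enhancer-driven | copy-driven | null
    loop_labels: dict[str, str]             # specific:<ct> | shared | ambiguous | background
    variant_regulatory: pd.Series           # bool per variant row
    amplicon_class: dict[str, str]
    neoloop_counts: dict[str, int]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    samples: list[str]
    cancer_type: pd.Series
    library_size: pd.Series
    genes: list[GeneModel]
    peaks: list[GenomicInterval]
    linked_peaks: dict[str, list[int]]      # gene -> planted enhancer peak rows
    peak_signal: pd.DataFrame               # peaks x samples, raw counts
    loops: list[LoopRecord]                 # union loop set
    sample_loops: dict[str, list[LoopRecord]]
    loop_signal: pd.DataFrame               # loops x samples, raw counts
    expression: pd.DataFrame                # genes x samples, normalized counts
    tpm: pd.DataFrame
    cnv_profiles: dict[str, CnvProfile]
    cnv_segments: dict[str, list[tuple[GenomicInterval, float]]]
    contact_maps: dict[str, ContactMatrix]  # per cancer type
    subcompartment_ranks: pd.DataFrame      # coarse bins x samples
    celltype_peaks: dict[str, list]         # sample -> list[CellTypePeaks]
    cell_fractions: pd.DataFrame            # cell types x samples
    variants: pd.DataFrame
    variant_carriers: dict[str, list[str]]
    tracks: pd.DataFrame                    # 100-bp bins x samples
    amplicons: list[Amplicon]
    amplicon_loops: dict[str, list[LoopRecord]]
    truth: GroundTruth

    def write(self, outdir) -> None:
        """Write every cohort table in its on-disk format, plus a manifest."""
        from . import io as lio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lio.write_bed(self.peaks, outdir / "peaks.bed")
        lio.write_loop_table(self.loops, outdir / "union_loops.tsv")
        lio.write_genes(self.genes, outdir / "genes.tsv")
        lio.write_seg(self.cnv_segments, outdir / "cnv.seg")
        lio.write_signal_matrix(self.peak_signal, outdir / "peak_signal.tsv")
        lio.write_signal_matrix(self.loop_signal, outdir / "loop_signal.tsv")
        lio.write_signal_matrix(self.expression, outdir / "expression.tsv")
        lio.write_signal_matrix(self.tpm, outdir / "tpm.tsv")
        lio.write_variant_table(self.variants, outdir / "variants.tsv")
        for ct, cm in self.contact_maps.items():
            lio.write_contact_matrix(cm, outdir / f"contacts_{ct}.tsv")
        cfg = asdict(self.config)
        (outdir / "manifest.json").write_text(
            json.dumps({"config": cfg, "seed": self.config.seed}, indent=2)
        )


# ---------------------------------------------------------------------------
# Component simulators
# ---------------------------------------------------------------------------

def simulate_contact_map(
    n_bins: int,
    loops: Sequence,
    cnv_track: np.ndarray,
    decay_exponent: float,
    seed: int,
    resolution: int = 10_000,
    chrom: str = CHROM,
    base_intensity: float = 10.0,
    loop_enrichment: float = 4.0,
) -> ContactMatrix:
    """Distance-decay contact map with CN scaling and planted loop enrichment.

    The expected count at bin pair (i, j) is
    ``base * (1 + |i - j|) ** -decay_exponent * cn_i * cn_j``, multiplied by
    ``loop_enrichment`` at planted loop pairs, with independent Poisson noise.
    ``loops`` holds (bin_i, bin_j) pairs or LoopRecords at ``resolution``.
    """
    rng = np.random.default_rng(seed)
    cnv_track = np.asarray(cnv_track, dtype=float)
    if cnv_track.shape[0] != n_bins:
        raise ValueError("cnv_track length must equal n_bins")
    pairs = []
    for lp in loops:
        if isinstance(lp, LoopRecord):
            b1 = (lp.anchor1.start + lp.anchor1.end) // 2 // resolution
            b2 = (lp.anchor2.start + lp.anchor2.end) // 2 // resolution
        else:
            b1, b2 = lp
        if not (0 <= b1 < n_bins and 0 <= b2 < n_bins):
            raise ValueError(f"loop ({b1}, {b2}) outside matrix of {n_bins} bins")
        pairs.append((min(b1, b2), max(b1, b2)))
    if len(pairs) > n_bins * (n_bins - 1) // 2:
        raise ValueError("more loops than bin pairs")

    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = base_intensity * (1.0 + dist) ** (-decay_exponent)
    lam *= np.outer(cnv_track, cnv_track)
    for b1, b2 in pairs:
        lam[b1, b2] *= loop_enrichment
        lam[b2, b1] = lam[b1, b2]
    upper = np.triu(rng.poisson(lam)).astype(float)
    mat = upper + np.triu(upper, 1).T
    total = float(np.triu(mat).sum())
    return ContactMatrix(
        chrom=chrom, resolution=resolution, matrix=mat,
        total_valid_pairs=max(total, 1.0), state="raw",
    )


def simulate_allele_counts(
    n_variants: int,
    coverage_range: tuple[int, int],
    regulatory_fraction: float,
    af_shift: float,
    seed: int,
    chrom: str = CHROM,
    spacing: int = 3000,
) -> pd.DataFrame:
    """Somatic variant table with WGS and HiChIP ref/alt read counts.

    WGS allele fraction reflects the clonal fraction (uniform in
    [0.25, 0.55]); regulatory variants draw their HiChIP allele fraction
    shifted up by ``af_shift`` (allele-specific regulatory activity), capped
    at 0.98. Coverage per assay is uniform over ``coverage_range``.
    """
    if not (0.0 <= af_shift < 1.0):
        raise ValueError("af_shift must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = coverage_range
    pos = 2000 + np.arange(n_variants) * spacing
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, n_variants)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    is_reg = rng.random(n_variants) < regulatory_fraction
    wgs_af = rng.uniform(0.25, 0.55, n_variants)
    hic_af = np.where(is_reg, np.minimum(wgs_af + af_shift, 0.98), wgs_af)
    wgs_cov = rng.integers(lo, hi + 1, n_variants)
    hic_cov = rng.integers(lo, hi + 1, n_variants)
    wgs_alt = rng.binomial(wgs_cov, wgs_af)
    hic_alt = rng.binomial(hic_cov, hic_af)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "wgs_ref": wgs_cov - wgs_alt,
            "wgs_alt": wgs_alt,
            "hichip_ref": hic_cov - hic_alt,
            "hichip_alt": hic_alt,
            "is_regulatory": is_reg,
        }
    )


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _bin_interval(b: int, resolution: int, chrom: str = CHROM) -> GenomicInterval:
    return GenomicInterval(chrom, b * resolution, (b + 1) * resolution)


def simulate_cohort(config: Optional[CohortConfig] = None) -> SyntheticCohort:
    """Generate the full synthetic cohort with ground truth."""
    cfg = config or CohortConfig()
    rngs = _spawn_rngs(cfg.seed)
    res = cfg.resolution

    samples = [f"S{i:02d}" for i in range(cfg.n_samples)]
    cancer_type = pd.Series(
        [f"CT{i % cfg.n_cancer_types}" for i in range(cfg.n_samples)],
        index=samples, name="cancer_type",
    )
    lib = pd.Series(
        rngs["samples"].uniform(*cfg.library_size_range, cfg.n_samples),
        index=samples, name="library_size",
    )

    # ---- gene layout: one gene per slot along the chromosome --------------
    rng_l = rngs["layout"]
    slot = cfg.chrom_length // cfg.n_genes
    if slot < 500_000:
        raise ValueError(
            "chromosome too short for the requested gene count: each gene "
            f"needs a >= 500 kb slot, got {slot}"
        )
    gene_classes = (
        ["enhancer-driven"] * cfg.n_enhancer_genes
        + ["copy-driven"] * cfg.n_copy_genes
        + ["null"] * cfg.n_null_genes
    )
    rng_l.shuffle(gene_classes)
    genes: list[GeneModel] = []
    for gi, gclass in enumerate(gene_classes):
        start = gi * slot + 200_000
        strand = "+" if gi % 2 == 0 else "-"
        genes.append(
            GeneModel(
                gene_id=f"G{gi:03d}",
                interval=GenomicInterval(CHROM, start, start + 20_000),
                strand=strand,
            )
        )
    gene_class = {g.gene_id: c for g, c in zip(genes, gene_classes)}

    # ---- CNV segments: one segment per gene slot per sample ---------------
    rng_c = rngs["cnv"]
    total_cn_gene = pd.DataFrame(index=[g.gene_id for g in genes], columns=samples,
                                 dtype=float)
    for g in genes:
        if gene_class[g.gene_id] == "copy-driven":
            cn = rng_c.choice([1, 2, 3, 4, 6, 8], size=cfg.n_samples,
                              p=[0.1, 0.3, 0.2, 0.2, 0.1, 0.1])
        else:
            cn = rng_c.choice([1, 2, 3], size=cfg.n_samples, p=[0.15, 0.7, 0.15])
        total_cn_gene.loc[g.gene_id] = cn.astype(float)
    cnv_segments: dict[str, list[tuple[GenomicInterval, float]]] = {}
    cnv_profiles: dict[str, CnvProfile] = {}
    for s in samples:
        segs = []
        for gi, g in enumerate(genes):
            seg = GenomicInterval(CHROM, gi * slot, min((gi + 1) * slot,
                                                        cfg.chrom_length))
            segs.append((seg, float(total_cn_gene.at[g.gene_id, s])))
        cnv_segments[s] = segs
        cnv_profiles[s] = ploidy_and_qc(s, segs)
    rel_cn_gene = total_cn_gene.copy()
    for s in samples:
        rel_cn_gene[s] = total_cn_gene[s] / cnv_profiles[s].ploidy

    # ---- peaks: planted enhancer + promoter + background -------------------
    rng_p = rngs["peaks"]
    peaks: list[GenomicInterval] = []
    linked_peaks: dict[str, list[int]] = {}
    n_linked = {"enhancer-driven": 3, "copy-driven": 3, "null": 0}
    pca_genes = set()
    enh_genes = [g for g in genes if gene_class[g.gene_id] == "enhancer-driven"]
    for k, g in enumerate(enh_genes):
        if k % 3 == 2:  # every third enhancer gene exercises the PCA path
            pca_genes.add(g.gene_id)
    for g in genes:
        nlk = n_linked[gene_class[g.gene_id]]
        if g.gene_id in pca_genes:
            nlk = 7
        idxs = []
        offsets = rng_p.choice(
            np.arange(60_000, 270_000, 10_000), size=nlk, replace=False
        ) if nlk else []
        for off in offsets:
            pstart = g.tss + int(off)
            peaks.append(GenomicInterval(CHROM, pstart, pstart + 2000))
            idxs.append(len(peaks) - 1)
        linked_peaks[g.gene_id] = idxs
    for g in genes:  # active promoters carry their own H3K27ac peak
        peaks.append(GenomicInterval(CHROM, max(0, g.tss - 1000), g.tss + 1000))
    n_planted = len(peaks)
    n_bg_peaks = max(cfg.n_peaks - n_planted, 0)
    for _ in range(n_bg_peaks):
        gi = int(rng_p.integers(0, cfg.n_genes))
        off = int(rng_p.integers(300_000, 480_000))
        pstart = gi * slot + off
        peaks.append(GenomicInterval(CHROM, pstart, min(pstart + 2000,
                                                        cfg.chrom_length)))
    # cancer-type-specific background peaks (1D signal carries type identity)
    n_type_peaks = min(n_bg_peaks, 20 * cfg.n_cancer_types)
    peak_type = {}  # peak index -> cancer type with boosted signal
    for k in range(n_type_peaks):
        peak_type[n_planted + k] = f"CT{k % cfg.n_cancer_types}"

    # ---- latent enhancer activity and expression ---------------------------
    rng_r = rngs["rna"]
    myeloid_genes = [g.gene_id for g in enh_genes[:3]]  # EIS tracks myeloid fraction
    fractions = pd.DataFrame(
        rngs["tme"].dirichlet(cfg.dirichlet_alpha, cfg.n_samples).T,
        index=list(cfg.cell_types), columns=samples,
    )
    latent = pd.DataFrame(index=[g.gene_id for g in genes], columns=samples,
                          dtype=float)
    for g in genes:
        if gene_class[g.gene_id] != "enhancer-driven":
            latent.loc[g.gene_id] = 0.0
            continue
        if g.gene_id in myeloid_genes:
            f = fractions.loc["myeloid"].to_numpy()
            z = (f - f.mean()) / f.std()
            latent.loc[g.gene_id] = z + rng_r.normal(0, 0.3, cfg.n_samples)
        else:
            latent.loc[g.gene_id] = rng_r.normal(0, 1, cfg.n_samples)

    log_expr = pd.DataFrame(index=latent.index, columns=samples, dtype=float)
    for g in genes:
        gclass = gene_class[g.gene_id]
        noise_sd = cfg.null_rna_noise_sd if gclass == "null" else cfg.rna_noise_sd
        eps = rng_r.normal(0, noise_sd, cfg.n_samples)
        if gclass == "enhancer-driven":
            mu = cfg.rna_base + cfg.enh_rna_effect * latent.loc[g.gene_id].to_numpy()
        elif gclass == "copy-driven":
            r = rel_cn_gene.loc[g.gene_id].to_numpy(dtype=float)
            mu = cfg.rna_base + cfg.cn_rna_effect * (r - 1.0)
        else:
            mu = np.full(cfg.n_samples, cfg.rna_base)
        log_expr.loc[g.gene_id] = mu + eps
    expression = (2.0 ** log_expr) - 1.0
    tpm = expression.copy()

    # ---- raw peak signal ----------------------------------------------------
    peak_signal = pd.DataFrame(
        index=[f"peak_{i}" for i in range(len(peaks))], columns=samples,
        dtype=float,
    )
    gene_of_peak = {}
    for gid, idxs in linked_peaks.items():
        for pi in idxs:
            gene_of_peak[pi] = gid
    for pi, pk in enumerate(peaks):
        gid = gene_of_peak.get(pi)
        lognoise = rng_p.normal(0, cfg.peak_noise_sd, cfg.n_samples)
        if gid is not None and gene_class[gid] == "enhancer-driven":
            z = latent.loc[gid].to_numpy()
            mean_log = cfg.peak_latent_effect * z + lognoise
        else:
            mean_log = lognoise
        vals = cfg.peak_base * lib.to_numpy() * (2.0 ** mean_log)
        # raw reads scale with local DNA copies
        if gid is not None:
            vals = vals * np.maximum(rel_cn_gene.loc[gid].to_numpy(dtype=float),
                                     0.25)
        if pi in peak_type:
            boost = (cancer_type == peak_type[pi]).to_numpy()
            vals = vals * np.where(boost, cfg.type_specific_factor, 1.0)
        peak_signal.iloc[pi] = vals

    # ---- loops: planted E-P per driver gene + background -------------------
    rng_lo = rngs["loops"]
    loops: list[LoopRecord] = []
    loop_meta: list[dict] = []
    for g in genes:
        for pi in linked_peaks[g.gene_id]:
            pk = peaks[pi]
            b_t = g.tss // res
            b_p = ((pk.start + pk.end) // 2) // res
            lp = LoopRecord(
                anchor1=_bin_interval(b_t, res),
                anchor2=_bin_interval(b_p, res),
                signal=1.0, qvalue=0.001,
            )
            loops.append(lp)
            loop_meta.append({"gene": g.gene_id, "peak": pi, "kind": "planted"})
    min_b = cfg.loop_distance_range[0] // res
    max_b = cfg.loop_distance_range[1] // res
    for k in range(cfg.n_background_loops):
        b1 = int(rng_lo.integers(0, cfg.n_bins - min_b - 1))
        b2 = b1 + int(rng_lo.integers(min_b, min(max_b, cfg.n_bins - 1 - b1)))
        loops.append(
            LoopRecord(
                anchor1=_bin_interval(b1, res),
                anchor2=_bin_interval(b2, res),
                signal=1.0, qvalue=0.01,
            )
        )
        loop_meta.append({"gene": None, "peak": None, "kind": "background"})
    loop_type = {}
    n_type_loops = min(cfg.n_background_loops, 15 * cfg.n_cancer_types)
    first_bg = len(loops) - cfg.n_background_loops
    for k in range(n_type_loops):
        loop_type[first_bg + k] = f"CT{k % cfg.n_cancer_types}"
    for i, lp in enumerate(loops):
        lp.loop_id = f"loop_{i}"

    # ---- per-sample loop signal --------------------------------------------
    loop_signal = pd.DataFrame(
        0.0, index=[lp.loop_id for lp in loops], columns=samples
    )
    for i, (lp, meta) in enumerate(zip(loops, loop_meta)):
        base = cfg.loop_base * lib.to_numpy()
        gid = meta["gene"]
        if gid is not None and gene_class[gid] == "enhancer-driven":
            base = base * 2.0 ** (0.8 * latent.loc[gid].to_numpy())
        if gid is not None:
            base = base * np.maximum(
                rel_cn_gene.loc[gid].to_numpy(dtype=float), 0.25
            )
        if i in loop_type:
            boost = (cancer_type == loop_type[i]).to_numpy()
            base = base * np.where(boost, cfg.type_specific_factor, 1.0)
        loop_signal.iloc[i] = rng_lo.poisson(base).astype(float)
    sample_loops: dict[str, list[LoopRecord]] = {}
    for s in samples:
        col = loop_signal[s]
        sl = []
        for lp in loops:
            sig = float(col[lp.loop_id])
            if sig > 0:
                sl.append(
                    LoopRecord(
                        anchor1=lp.anchor1, anchor2=lp.anchor2,
                        signal=sig, qvalue=lp.qvalue, loop_id=lp.loop_id,
                    )
                )
        sample_loops[s] = sl

    # ---- TME: pseudobulk accessibility and loop specificity labels ---------
    from .tme import CellTypePeaks

    copy_genes = [g for g in genes if gene_class[g.gene_id] == "copy-driven"]
    ambiguous_genes = {g.gene_id for g in copy_genes[:2]}
    shared_genes = {g.gene_id for g in copy_genes[2:]}
    malignant_genes = {
        g.gene_id for g in enh_genes if g.gene_id not in myeloid_genes
    }
    loop_labels: dict[str, str] = {}
    for lp, meta in zip(loops, loop_meta):
        gid = meta["gene"]
        if gid is None:
            loop_labels[lp.loop_id] = "background"
        elif gid in ambiguous_genes:
            loop_labels[lp.loop_id] = "ambiguous"
        elif gid in shared_genes:
            loop_labels[lp.loop_id] = "shared"
        elif gid in myeloid_genes:
            loop_labels[lp.loop_id] = "specific:myeloid"
        else:
            loop_labels[lp.loop_id] = "specific:malignant"

    promoter_atac = [
        GenomicInterval(CHROM, max(0, g.tss - 500), g.tss + 500)
        for g in genes if g.gene_id not in ambiguous_genes
    ]
    atac_sets: dict[str, list[GenomicInterval]] = {
        ct: list(promoter_atac) for ct in cfg.cell_types
    }
    for gid, idxs in linked_peaks.items():
        for pi in idxs:
            pk = peaks[pi]
            if gid in ambiguous_genes:
                continue
            elif gid in shared_genes:
                for ct in cfg.cell_types:
                    atac_sets[ct].append(pk)
            elif gid in myeloid_genes:
                atac_sets["myeloid"].append(pk)
            else:
                atac_sets["malignant"].append(pk)
    for pi in range(n_planted, len(peaks)):  # background peaks: broadly open
        for ct in cfg.cell_types:
            atac_sets[ct].append(peaks[pi])

    celltype_peaks: dict[str, list[CellTypePeaks]] = {}
    for s in samples:
        cells = np.round(fractions[s].to_numpy() * cfg.total_cells).astype(int)
        celltype_peaks[s] = [
            CellTypePeaks(
                cell_type=ct,
                peaks=atac_sets[ct],
                n_cells=int(cells[k]),
                fraction=float(fractions.at[ct, s]),
                malignant=(ct == "malignant"),
            )
            for k, ct in enumerate(cfg.cell_types)
        ]

    # ---- variants, carriers and 100-bp signal tracks ------------------------
    variants = simulate_allele_counts(
        cfg.n_variants, cfg.coverage_range, cfg.regulatory_fraction,
        cfg.af_shift, seed=int(rngs["variants"].integers(0, 2**31 - 1)),
        spacing=cfg.variant_spacing,
    )
    rng_t = rngs["tracks"]
    carriers = {
        f"{c}:{p}": [samples[int(rng_t.integers(0, cfg.n_samples))]]
        for c, p in zip(variants["chrom"], variants["pos"])
    }
    track_len = int(variants["pos"].max()) + 2000
    n_track_bins = track_len // 100 + 1
    base_track = rng_t.lognormal(mean=np.log(20.0), sigma=0.3,
                                 size=(n_track_bins, cfg.n_samples))
    tracks = pd.DataFrame(base_track * lib.to_numpy()[None, :],
                          columns=samples)
    for row in variants.itertuples(index=False):
        if not row.is_regulatory:
            continue
        vid = f"{row.chrom}:{row.pos}"
        first = (row.pos - 1000) // 100
        for s in carriers[vid]:
            tracks.loc[first:first + 19, s] *= cfg.window_boost

    # ---- amplicons -----------------------------------------------------------
    rng_a = rngs["amplicons"]
    n_breaks = {"cyclic": 3, "BFB": 2, "complex": 4, "linear": 1}
    amplicons: list[Amplicon] = []
    amplicon_loops: dict[str, list[LoopRecord]] = {}
    neoloop_counts: dict[str, int] = {}
    amplicon_class: dict[str, str] = {}
    for cls in AMPLICON_CLASSES:
        for k in range(cfg.n_amplicons_per_class):
            aid = f"amp_{cls}_{k}"
            chrom = f"chrA_{cls}_{k}"
            size_mb = float(rng_a.uniform(1.0, 4.0))
            n_abins = int(size_mb * 1e6 // res)
            iv = GenomicInterval(chrom, 0, n_abins * res)
            nb = n_breaks[cls]
            bps = sorted(
                int(b) * res
                for b in rng_a.choice(
                    np.arange(20, n_abins - 20), size=nb, replace=False
                )
            )
            amp = Amplicon(aid, cls, [iv], [(chrom, b) for b in bps])
            alos: list[LoopRecord] = []
            n_neo = int(rng_a.poisson(cfg.neoloop_rates[cls] * size_mb))
            for _ in range(n_neo):
                b = bps[int(rng_a.integers(0, nb))]
                bb = b // res
                k1 = int(rng_a.integers(1, min(15, bb) + 1))
                k2 = int(rng_a.integers(2, min(16, n_abins - bb) + 1))
                alos.append(
                    LoopRecord(
                        anchor1=_bin_interval(bb - k1, res, chrom),
                        anchor2=_bin_interval(bb + k2 - 1, res, chrom),
                        signal=float(rng_a.poisson(20) + 1),
                    )
                )
            # background loops confined to inter-breakpoint segments
            bounds = [0] + [b // res for b in bps] + [n_abins]
            n_bg = int(rng_a.poisson(cfg.background_loop_rate_per_mb * size_mb))
            for _ in range(n_bg):
                seg_i = int(rng_a.integers(0, len(bounds) - 1))
                lo_b, hi_b = bounds[seg_i], bounds[seg_i + 1]
                if hi_b - lo_b < 8:
                    continue
                b1 = int(rng_a.integers(lo_b, hi_b - 5))
                b2 = int(rng_a.integers(b1 + 4, hi_b))
                alos.append(
                    LoopRecord(
                        anchor1=_bin_interval(b1, res, chrom),
                        anchor2=_bin_interval(b2, res, chrom),
                        signal=float(rng_a.poisson(20) + 1),
                    )
                )
            amplicons.append(amp)
            amplicon_loops[aid] = alos
            neoloop_counts[aid] = n_neo
            amplicon_class[aid] = cls

    # ---- contact maps (merged per cancer type, coarse bins) -----------------
    rng_cm = rngs["contacts"]
    coarse = cfg.contact_resolution
    n_coarse = cfg.chrom_length // coarse
    contact_maps = {}
    for ct in sorted(cancer_type.unique()):
        members = cancer_type.index[cancer_type == ct]
        cn_track = np.ones(n_coarse)
        for gi, g in enumerate(genes):
            r = float(rel_cn_gene.loc[g.gene_id, members].mean())
            lo_b = (gi * slot) // coarse
            hi_b = min(((gi + 1) * slot) // coarse, n_coarse)
            cn_track[lo_b:hi_b] = r
        coarse_pairs = []
        for lp in loops:
            b1 = (lp.anchor1.start + lp.anchor1.end) // 2 // coarse
            b2 = (lp.anchor2.start + lp.anchor2.end) // 2 // coarse
            if b1 != b2:
                coarse_pairs.append((b1, b2))
        contact_maps[ct] = simulate_contact_map(
            n_coarse, coarse_pairs, cn_track, cfg.decay_exponent,
            seed=int(rng_cm.integers(0, 2**31 - 1)), resolution=coarse,
            base_intensity=cfg.contact_base_intensity,
            loop_enrichment=cfg.loop_enrichment,
        )

    # ---- subcompartment rank vectors (weak type signal) ---------------------
    rng_sc = rngs["subcomp"]
    shared_pattern = np.convolve(
        rng_sc.normal(0, 1, n_coarse), np.ones(5) / 5, mode="same"
    )
    type_patterns = {
        ct: rng_sc.normal(0, 1, n_coarse) for ct in sorted(cancer_type.unique())
    }
    sub = pd.DataFrame(index=range(n_coarse), columns=samples, dtype=float)
    for s in samples:
        raw = (
            shared_pattern
            + 0.15 * type_patterns[cancer_type[s]]
            + 0.5 * rng_sc.normal(0, 1, n_coarse)
        )
        sub[s] = rankdata(raw)

    truth = GroundTruth(
        gene_class=gene_class,
        loop_labels=loop_labels,
        variant_regulatory=variants["is_regulatory"].copy(),
        amplicon_class=amplicon_class,
        neoloop_counts=neoloop_counts,
    )
    return SyntheticCohort(
        config=cfg,
        samples=samples,
        cancer_type=cancer_type,
        library_size=lib,
        genes=genes,
        peaks=peaks,
        linked_peaks=linked_peaks,
        peak_signal=peak_signal,
        loops=loops,
        sample_loops=sample_loops,
        loop_signal=loop_signal,
        expression=expression,
        tpm=tpm,
        cnv_profiles=cnv_profiles,
        cnv_segments=cnv_segments,
        contact_maps=contact_maps,
        subcompartment_ranks=sub,
        celltype_peaks=celltype_peaks,
        cell_fractions=fractions,
        variants=variants,
        variant_carriers=carriers,
        tracks=tracks,
        amplicons=amplicons,
        amplicon_loops=amplicon_loops,
        truth=truth,
    )
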
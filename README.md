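# loopscape

Copy-number-aware analysis of H3K27ac HiChIP enhancer connectomes in cancer
cohorts.

H3K27ac HiChIP jointly measures enhancer activity and chromatin contacts, so
a single assay links distal enhancers to the genes they regulate. In tumors,
however, both the 1D peak signal and the 2D loop signal are confounded by
copy-number variation, and oncogene overexpression can arise either from
enhancer gain or from DNA amplification. `loopscape` implements the
integrative analyses needed to work with such cohorts:

- **Loop annotation** — classify significant loops as E–P, E–E, P–P, E–N,
  P–N by overlap of their anchors with promoter windows (TSS ± 1 kb) and
  H3K27ac peaks; build union loop/peak sets and per-sample signal matrices.
- **Normalization** — median-of-ratios size factors; ploidy estimation with
  hyper-segmentation QC (> 1,000 segments); copy-number correction of peak
  signal (divide by relative CN where > 1) and loop signal (divide by the
  product of the two anchors' relative CN).
- **Contact-matrix tools** — Knight–Ruiz balancing, observed/expected
  transform, A/B compartment eigenvector with reference-oriented sign, and
  virtual-4C enhancer interaction (EIS) profiles.
- **Driver model** — per gene, ordinary least squares of expression on
  enhancer terms and copy number,

  `RNA ~ H3K27ac + CN`

  where the H3K27ac terms are the gene's loop-linked peaks (≤ 5 peaks:
  individual standardized signals; > 5: the first five principal
  components), and each term's share of the model R² is the
  Lindeman–Merenda–Gold (LMG) importance — the average over all predictor
  orderings of the term's incremental R². Genes are classified
  enhancer-driven or copy-driven by the winning term.
- **TME deconvolution** — rule-based classification of E–P loops as
  cell-type-specific, shared or ambiguous using per-cell-type pseudobulk
  scATAC peaks, plus Spearman correlation of EIS with cell fractions.
- **Regulatory-mutation nomination** — allele-frequency contrast between
  HiChIP and WGS reads (Fisher's exact test, BH), local H3K27ac contrast in
  a 2-kb / 20 × 100-bp window (Welch t), and motif gain in the 21-bp variant
  context with exact PWM score-distribution p-values.
- **SV rewiring statistics** — neoloops (loops spanning an SV breakpoint)
  per Mb of focal amplification, rank-sum comparisons across amplicon
  classes (cyclic/ecDNA, BFB, complex, linear), and co-amplification
  frequency at a CN > 4.5 seed threshold.
- **Cluster evaluation** — pairwise-complete Pearson correlation of samples,
  complete-linkage clustering, and purity/entropy against cancer-type labels.
- **Synthetic cohorts** — a generator that plants enhancer-driven,
  copy-driven and null genes, cell-type-specific loops, allele-biased
  regulatory variants and junction-spanning amplicon loops, with ground-truth
  labels, so the whole pipeline is testable without controlled-access data.

## Worked example

```python
import loopscape as ls

cohort = ls.simulate_cohort(ls.CohortConfig(seed=1))   # 60 samples, 60 genes
model = ls.OncogeneDriverModel(
    cohort.expression, cohort.tpm, cohort.genes, cohort.peaks,
    ls.normalize_counts(cohort.peak_signal), cohort.loops,
    cohort.cnv_profiles,
)
results = model.fit(alpha=0.05)
print(results.summary())
```

prints

```
Oncogene expression variance partition (RNA ~ H3K27ac + CN)
  genes fitted:            60
  enhancer-driven:         20
  copy-driven:             21
  unclassified (p >= 0.05): 19
  below variance floor (1): 7
  median model R^2:        0.728
```

The cohort plants 20 enhancer-driven, 20 copy-driven and 20 null genes: all
40 drivers are recovered in their true class, one null gene is a false
positive at alpha = 0.05 (hence 21 copy-driven), and the remaining null genes
stay unclassified. `results.table` holds the per-gene classification, R²,
LMG importances and winning-term p-value.

A command-line interface mirrors the library
(`loopscape simulate | annotate-loops | normalize | compartments | v4c |
driver-model | tme | regmut | sv | cluster-eval`), e.g.

```bash
loopscape simulate --seed 1 --out cohort/
loopscape annotate-loops --loops cohort/union_loops.tsv \
    --genes cohort/genes.tsv --peaks cohort/peaks.bed --out annotated.tsv
```

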
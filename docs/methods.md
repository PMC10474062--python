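# Methods

`statemi` analyzes a gene-by-sample expression matrix from a 2×2 factorial
design — leukemic status (non-CML vs CML) crossed with genotype (wt vs KO),
giving the four conditions wt, KO, CP (= CML/wt) and BC (= CML/KO) — and
asks two questions about a candidate gene set:

1. does the set alone reconstruct the sample geometry of the whole
   transcriptome (the "state-space"), and
2. is the set denser in information about the condition labels than the
   remaining transcriptome, beyond what its content of differentially
   expressed genes would explain?

## Normalization

Raw counts are transformed to `log2(CPM + pseudocount)` with library-size
(column-sum) denominators and pseudocount 1, then each gene row is centered
across samples. CPM rather than gene-length-aware units is appropriate
because all comparisons are within-gene across samples. Externally computed
size factors (e.g. TMM-derived effective library sizes) can be passed to
`normalize_log` to override the column sums. Genes with all-zero counts are
retained: they center to a constant-zero row, carry zero mutual information
and do not perturb any test, while dropping them would silently shrink the
gene universe used by the hypergeometric and rank-sum tests. Centering is
idempotent, and is recomputed implicitly for every analysis universe (row
centering is unaffected by subsetting genes).

## State-space construction

A thin SVD of the centered matrix `M = U S Vᵀ` (genes × samples) defines
per-sample coordinates `Vᵀ` scaled by the singular values — the sample
scores — and orthonormal gene loadings `U`. Sign ambiguity is removed by
fixing each component's largest-magnitude gene loading to be positive, so
repeated fits are bit-identical.

* **Scree elbow.** The elbow of the singular-value scree is the interior
  index with maximal perpendicular distance to the chord joining the first
  and last scree points; ties go to the smallest interior index. Endpoints
  are excluded because an elbow at either end is not meaningful. A manual
  override is available at the pipeline level.
* **Axis selection.** Per component and factor, separation is scored as
  between-group sum of squares over total sum of squares of the sample
  coordinates (in [0, 1]; expectation 1/(n−1) for a random axis). The
  disease axis is the component with the top leukemic-factor score; the
  genotype axis is the top-scoring remaining component.
* **Rotation.** The selected 2-D plane is rotated (counterclockwise, in
  degrees) so the vector from the non-leukemic centroid to the leukemic
  centroid lies along +x. The rotation is an isometry of the plane; all
  other components are untouched. Auto mode computes the angle from the
  centroids; a fixed angle can be supplied instead. Centroid alignment is
  a deliberate, reproducible choice of objective — fitted angles from any
  particular dataset are descriptive, not parameters of the method.
* **Sub-space comparison.** A gene-set state-space is fitted the same way
  on the set's rows only. Axis-wise agreement with the full space is the
  squared Pearson correlation of the rotated disease-axis (and
  genotype-axis) coordinates across samples; it is invariant to sign flips
  and common rescaling. Pre-rotation R² is reported alongside for
  transparency. A zero-variance axis yields an undefined R², reported as
  NaN with a flag.

## Mutual information

Expression values are discretized into k = 3 bins. Bin boundaries are the
1/3 and 2/3 empirical quantiles (order statistics) of the *pooled* centered
values of all genes across the samples in the contrast — equal-frequency
binning, which maximizes the entropy of the binned variable. Boundaries are
shared by all genes. Assignment convention: `x ≤ b₁ → bin 0`,
`b₁ < x ≤ b₂ → bin 1`, `x > b₂ → bin 2`. By default boundaries are refit
for each contrast because the sample subset changes; a mode that reuses
the 4-condition boundaries is provided. Binning fails loudly when ties
collapse two boundaries onto one value.

Per gene, with X the binned expression over the contrast's samples and Y
the condition label,

    I(X:Y) = H(X) + H(Y) − H(X,Y)   (bits; plug-in entropies, 0·log 0 ≡ 0)

Values within 1e-12 below zero are clamped to 0. Three contrasts are
supported: all four conditions; CP vs BC (leukemic samples only); and wt
vs KO (non-leukemic samples only). No small-sample bias correction is
applied; the plug-in estimator's upward bias (≈ (|X|−1)(|Y|−1)/(2N ln 2))
is shared by set and rest genes and cancels in the rank-based comparison.

**MI density.** The set-vs-rest comparison is a one-sided Wilcoxon
rank-sum (Mann–Whitney) test of the set's MI being stochastically greater
than the rest's, with mid-ranks for ties. When the pooled values are
tie-free and `n_set · n_rest ≤ 200` the exact null distribution is used;
otherwise the normal approximation with tie-corrected variance and
continuity correction. If every value is tied the test degenerates and
p = 1 is reported with an explicit method tag.

## DEG-balance check

The question "is the set's MI advantage just DEG over-representation?" is
answered by a hypergeometric test on the 2×2 table of set membership ×
DEG status: upper-tail p = P(X ≥ k) for X ~ Hypergeom(N, K, n), with N
the gene universe, K the DEG count, n the set size and k the DEGs inside
the set. A two-sided option (doubled smaller tail, capped at 1) exists;
upper-tail is the default and is recorded in the output.

DEG calling on synthetic data uses a clearly tagged stand-in: per-gene
Welch two-sample t-test on log-CPM with Benjamini–Hochberg adjustment and
threshold q < 0.05. Genes with zero variance in both groups get p = 1 by
policy. Count-model likelihood-ratio callers are deliberately out of
scope; externally computed DEG flags can be supplied as a TSV and are
tagged `external` in all outputs.

## Synthetic data generator

The generator emulates the study design the analysis assumes, not any
particular dataset:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | gene universe |
| `n_per_group` | 5 | samples per condition (4 conditions) |
| `baseline_log_mean_mu`, `_sd` | 2.0, 1.0 | lognormal relative abundance (natural log) |
| `dispersion` | 0.1 | NB φ, var = μ + φμ² (single global φ) |
| `library_size_mean`, `_cv` | 1e6, 0.1 | lognormal sequencing depth |
| `leukemic_lfc` | 1.5 | log2 FC on leukemic-responsive genes (CML samples) |
| `genotype_lfc` | 1.5 | log2 FC on genotype-responsive genes (KO samples) |
| `n_leukemic_responsive` | 400 | background disease genes (outside the planted set) |
| `n_genotype_responsive` | 150 | background genotype genes (outside the planted set) |
| `planted_set_size` | 655 | planted informative set |
| `planted_set_responsive_frac` | 0.3 | fraction of the set shifting on *both* axes |

Counts are NB(μ, φ) with
`μ(g, s) = rel_g · L_s · 2^(lfc_leuk(g)·[s is CML] + lfc_geno(g)·[s is KO])`,
where `rel` is the normalized baseline profile and `L_s` the sample's
library size. Background responsive genes carry the signed configured
fold-change; the responsive fraction of the planted set draws signs ±1
equiprobably on each axis, so the set is informative about the condition
without being uniformly up- or down-regulated. Responsive background
genes are sampled outside the planted set so the truth flags stay
unambiguous. The leukemic axis dominates (more responsive genes), making
the disease axis land on component 1. Realized library sizes are the
drawn lognormal values times a condition-dependent composition factor
(effects are not renormalized away); this keeps the configured
fold-changes exactly recoverable from raw counts, and depth differences
are removed by CPM normalization downstream. One RNG stream per dataset,
seeded from the config; the seed is recorded in the dataset metadata.

What the generator does **not** emulate: per-gene dispersion trends,
gene–gene correlation beyond library-size coupling, batch structure,
zero-inflation and length biases of real bulk RNA-seq. Passing tests
therefore demonstrate correctness and calibration of the method under
its stated model, not performance on any real dataset.

### Behavior worth knowing about

* Under the default design, the planted set shows a strong MI-density
  advantage in the two-group contrasts, but *not* in the 4-condition
  contrast: the 400 background disease genes carry most of the 4-way
  information, and they sit in the "rest".
* With the default |lfc| = 1.5 the planted set's responsive genes are
  individually strong DEGs, so the DEG-balance test is significant. The
  regime where a set is informative in aggregate while containing no
  excess of individually significant genes appears at modest effect
  sizes (≈ 0.75 log2 on the genotype axis with no background genotype
  DEGs, five samples per group); `examples/04_deg_balance.py` and a
  dedicated test exercise exactly that scenario.

## Numerical and design choices

* Log base 2 everywhere (bits for entropies, log2 for fold-changes),
  recorded in outputs.
* Equal-frequency quantiles use the inverted-CDF (order-statistic)
  definition, so `1..9` yields boundaries (3, 6) exactly.
* The rank-sum statistic reported is the set's mid-rank sum W; the
  implementation delegates the null distribution to a standard library
  routine and is tested against exhaustive enumeration of rank
  assignments.
* Rotation angles follow the counterclockwise-positive convention; the
  auto angle is `−atan2(Δy, Δx)` of the centroid difference.
* SVD components with singular value ≤ 1e-8 × σ₁ span numerical null
  space (row-centered matrices always annihilate the all-ones vector);
  their coordinates are noise and excluded from oracle comparisons.
* The pipeline derives named per-stage sub-seeds from one global seed,
  so stage-level reruns reproduce end-to-end numbers exactly. Analysis
  stages themselves are deterministic; only simulation consumes
  randomness.
* No multiplicity correction is applied across the three MI contrasts or
  across gene sets by default (one set is the intended use); a
  BH-across-sets helper is available via `bh_adjust`.

## Problem sizes

Simulation-based tests use the default design (2000 genes × 20 samples);
calibration studies use 200 no-signal replicates and recovery studies 50
seeds, sizes at which binomial noise on the reported rates is a few
percent. The whole test suite runs in well under a minute on one CPU.

## Known limitations

* The plug-in MI estimator with 5–20 samples is strongly biased upward;
  only *comparisons* between gene collections sharing the same sample
  size are meaningful, never absolute MI values.
* The Welch-t stand-in DEG caller is less powerful than count-model
  tests at n = 5; DEG counts on synthetic data are conservative.
* The scree-elbow heuristic is a convention; different reasonable
  heuristics can disagree by one component, which is why the selected
  axes are chosen by separation score, not by the elbow.
* Auto-rotation assumes two clearly separated centroid clouds; it errors
  on coincident centroids rather than guessing.
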
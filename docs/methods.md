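# Methods

This note documents the models, conventions and numerical choices behind
`epoch`, and what the synthetic-data experiments do and do not establish
about real data.

## Synthetic reporter fields

Cells are concentric disks: a nuclear disk (radius sampled uniformly
from `nucleus_radius_range`, default 5–8 px) inside a cytoplasmic disk
(11–15 px), placed by rejection sampling so whole cells fit the canvas
and never overlap; placement failure after a bounded number of attempts
raises rather than silently crowding the field. Morphology is
deliberately schematic: every downstream readout (per-cell Pearson r,
cytoplasmic means, puncta counts) depends only on how intensity is
co-distributed between channels, not on cell shape.

Intensity bookkeeping is exact. Each cell carries a fixed total mCherry
mass; a fraction `mislocalization_fraction` (f) is relocated from the
nucleus into `puncta_per_cell` cytoplasmic puncta — isotropic Gaussian
spots (σ = `puncta_radius`) truncated at 3σ and normalized by their
pixel sum, so mass is conserved to machine precision across f. Puncta
are kept ≥ 4.5σ apart when the annulus allows, so planted spots remain
resolvable as distinct connected components; in crowded annuli overlap
is accepted. eGFP splits between cytoplasm and nucleus by
`egfp_nuclear_leak`. Background is a constant plus Gaussian noise
clipped at zero; float images are written to 16-bit TIFF by linear
scaling with the scale recorded in a sidecar.

At f = 0 the channels are anti-correlated over a cell (mCherry nuclear,
eGFP cytoplasmic, per-cell r ≈ −1); as f grows, mCherry mass moves into
eGFP-rich cytoplasm and mean r rises monotonically (≈ +0.3 at f = 1
under default noise). This reproduces the direction of the senescent
phenotype, not the absolute r values of any particular microscope.

What the image simulator does **not** emulate: realistic morphology,
uneven illumination, focus drift, touching cells, autofluorescence.
Passing tests show the quantification is correct on its stated model;
robustness on real micrographs (where the study's original analysis
used CellProfiler) is explicitly out of scope.

## NCC quantification conventions

- Pearson r is computed **per cell** over the union of that cell's
  nucleus and cytoplasm pixels, on raw intensities (no thresholded or
  Manders variants), and aggregated as mean ± SD per condition. Cells
  with < 2 pixels or zero variance in either channel are flagged invalid
  and excluded from aggregates.
- Segmentation without ground truth: Otsu threshold on the smoothed
  mCherry channel for nuclei (nuclear by construction in healthy cells),
  distance-transform watershed to split touching nuclei, whole cells by
  a watershed of the combined-channel foreground seeded at the nuclei,
  cytoplasm = cell minus nucleus. An all-background image returns zero
  cells. In strongly mislocalized fields the nuclear channel fades, so
  pipeline quantification defaults to simulator ground-truth masks;
  Otsu–watershed segmentation is available via configuration.
- Puncta counting applies a white top-hat (disk radius 5 px) to flatten
  smooth background before thresholding; components of area ≥ `min_area`
  within the cell's cytoplasm count.
- Line profiles use bilinear interpolation; pixel coordinates are
  0-based (row, column).
- Z-factor uses sample SDs (ddof = 1) and raises when the control means
  are equal. It is symmetric in the two controls and invariant to common
  affine transforms of all values.
- Condition comparisons use the Welch (unequal-variance) t-test by
  default — a deliberate choice over the pooled form for robustness,
  with `equal_var=True` available — and `anova_bonferroni` runs a
  one-way ANOVA F-test plus pairwise t-tests at
  p_corrected = min(1, m·p) over the m pairs performed.

## Count simulation

Counts are negative binomial, `var = μ + φμ²`, with log2-scale gene
means: baseline b_g ~ Normal(5, 2) (median ≈ 32 counts at typical
library depth), ± `senescence_log2fc` for senescence genes in senescent
groups (cancelled in treated groups for the planted "reversed" subset),
and slope_g·(age − 50) for age genes with slopes ~ Normal(0,
`age_slope_sd`). Relative abundances are rescaled per sample so expected
totals equal library sizes drawn log-uniformly from
`library_size_range`, which exercises normalization and realistic
composition bias. Defaults: φ = 0.1, log2FC = 2, 100 + 100 senescence
genes, reversal fractions 0.5 — magnitudes chosen as plausible for a
strong senescence program, not estimated from any dataset. The gene
model (baselines, assignments, slopes) can be reused across simulations
so an aging cohort and a treatment experiment share age-dependent genes;
this is how the pipeline gives treated samples a genuinely "younger"
transcriptome.

All randomness flows from a single seed through named streams
(`SeedSequence([seed, crc32(key)...])`), so stages and modules draw
independent, refactor-stable streams, and adding a stage never perturbs
another stage's numbers.

## Differential expression

Median-of-ratios size factors (reference = genes with no zero count)
feed `y = log2(normalized + 1)`. The default test is a **moderated t**:
per-gene pooled variances are shrunk toward a lowess trend on mean log
expression, with prior degrees of freedom estimated by moment-matching
the log variances against a scaled-F model (the standard
empirical-Bayes squeeze); p-values come from t with d + d₀ degrees of
freedom. At n = 3–4 per group this recovers most of the power a
count-model engine with dispersion shrinkage would give — with plain
Welch t, planted log2FC = 2.5 signatures are only ~25% recoverable at
p_adj < 0.01, versus ~98% moderated — while keeping type-I error at
~4% on null NB simulations. `method="welch"` and `"pooled"` select the
unmoderated forms. Fewer than 30 testable genes fall back to a flat
(global-mean) variance prior, since a lowess trend is meaningless there.
Genes with zero counts everywhere are dropped; the log2 fold change uses
a pseudocount of 1, which slightly attenuates fold changes of
low-abundance genes.

The signature rule is directional: up = `p_adj < 0.01` and
log2FC > log2(2); down is the mirror image. Reversal classification is
direction-aware — an up-signature gene counts as reversed only when
significantly *decreased* under treatment (and mirrored for down) —
because "changed by treatment" without direction would count
exacerbated genes as rescued. Reversed/exacerbated/unchanged partition
each signature; percentages are rounded to one decimal, matching the
precision such results are reported at.

Note the reversal percentage conflates the true reversal fraction with
detection power: with weak effects or few replicates it underestimates
the planted fraction. The demo study therefore plants a strong program
(log2FC = 2.5) so recovery is power-saturated; at log2FC = 2 the same
pipeline reads ~41% for a planted 50%.

## GSEA

Ranking metric: `−log10(p)·sgn(log2FC)` (sgn(0) = 0), descending, ties
broken lexicographically by gene id; p = 0 is clamped to the smallest
positive float and the number of clamps recorded. The orientation puts
significant upregulation at the top; the literal `log(p)·sgn(lfc)` form,
which inverts the list, is available behind `literal_sign=True`.

The enrichment score is the weighted KS running sum with weight
exponent 1 (hits add |score|/Σ_set|score|, misses subtract 1/(N−K)),
evaluated in O(K) from hit positions — the running sum is piecewise
linear, so its extrema occur only adjacent to hits. When the maximal
positive and negative deviations tie exactly, the positive branch is
returned. If all set scores are zero, hits fall back to equal weights.

The null is gene permutation: size-matched random subsets of the ranked
universe, `n_perm` per set size, with the permutation stream keyed by
(seed, K) so results are independent of set order and count. The
p-value is the add-one estimator against same-sign null scores (floor
1/(1 + n_perm)); NES divides ES by the mean |null ES| of the same sign;
BH runs across retained sets; significance is called at p_adj < 0.1.
This is the simple permutation estimator — no multilevel/adaptive
refinement — and it bounds attainable p-values accordingly.

## Transcriptomic clock

Published clock coefficients are not reproduced; the package ships a
trainer and treats application as the procedure of record. Training:
z-scale log2(normalized + 1) per gene (zero-SD genes excluded), elastic
net (default l1_ratio 0.5, 30 penalties log-spaced over six decades,
5-fold shuffled CV on MSE, fixed seed) targeting chronological age in
years. The model stores genes, coefficients, intercept and per-gene
training means/SDs as one JSON document.

Application scales a new cohort with the **training** statistics; clock
genes absent from the cohort are imputed at the training mean — z = 0,
contributing nothing beyond the intercept — and the imputation count is
reported. ΔtAge = tAge − median tAge of the designated control samples
(quiescent in the demo), which pins the control median at exactly zero
and is idempotent. Group comparisons use two-sided Welch t-tests
(pooled form behind a flag) with BH adjustment across pairs.

On simulated cohorts (n = 200, 300 age genes, slope SD 0.02/yr, φ = 0.1)
held-out predicted-vs-true age correlation is ≥ 0.99; this demonstrates
parameter recovery under the generative model, not clock accuracy on
real tissue.

## Signature association

For each pair of signatures: take the union of each one's top-300
lowest-p genes (ties broken by gene id), keep genes present in both,
and compute Spearman rho of the log2 fold changes (average ranks for
ties; p from the t approximation). Genes missing from one signature are
dropped from that pair and the per-pair n is reported. BH runs over the
upper triangle; the diagonal is rho = 1 with p = p_adj = 0 by
convention and excluded from adjustment; failing pairs become NaN with
a warning rather than aborting the matrix.

## Pipeline

One YAML config (validated by a strict schema — unknown keys rejected)
drives the stages in dependency order: images → counts → {gsea, clock,
assoc}. Each stage writes into its own subdirectory (TSV/JSON only) and
contributes key numbers to `report.json`; a failure is recorded in the
report before the error propagates. Stage streams are independent, so
disabling one stage leaves the others' numbers bit-identical. The demo
study sizes (2000 genes, 4 samples/group, 120-sample cohort, 500
permutations, one 256² field per condition) keep a full run under half
a minute on one core while leaving every statistic comfortably inside
its operating range.

## Known limitations

- The DE engine is a moderated t on log-transformed normalized counts,
  not an NB GLM; no independent filtering or dispersion shrinkage across
  contrasts.
- Image analysis targets the simulator's geometry; no illumination
  correction, no 3-D, no time series.
- The GSEA p-value floor is permutation-limited; very small p-values
  require raising `n_perm`.
- The clock targets chronological age only; lifespan-adjusted biological
  ages and cross-species mapping are out of scope.
- Reversal percentages are power-dependent (see above) — a property of
  the statistic itself, not of the implementation.
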
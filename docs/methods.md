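# Methods

This note documents the statistical model behind `cthbench`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic benchmark can and cannot say about real data.

## 1. The synthetic purified-methylome model

The generator emulates a matched purified-cell experiment: for each of
`n_samples` individuals it produces one methylome per cell type over a
common CpG index, so that every bulk mixture can be formed from *that
individual's own* purified profiles.

**Latent-Gaussian beta values.** A beta value is a proportion in [0, 1]
whose technical and biological noise shrinks near the boundaries. We
model a sample's value at CpG *g* in cell type *k* as

    beta = expit( logit(m_gk) + e ),   e ~ N(0, sigma_bio^2)

with a per-CpG per-cell-type mean `m_gk` and independent draws per
individual, clipped to [0.001, 0.999]. By the delta method the implied
beta-scale standard deviation is approximately `m(1-m) * sigma_bio`:
with the default `sigma_bio = 0.3` (logit scale) this is ~0.075 at
mid-range CpGs and ~0.014 near beta = 0.05 or 0.95. Measurement noise
(`sigma_meas = 0.01`, beta scale) is added once, when profiles are mixed
into bulk.

**Baseline means.** Methylomes are bimodal, so shared (non-marker) CpGs
draw a single mean used by *all* cell types: 40% from Beta(0.3, 3) (low
methylation), 40% from Beta(3, 0.3) (high), 20% uniform on [0.2, 0.8].
Consequently the only systematic between-cell-type differences in the
simulation sit at marker CpGs — a deliberate simplification (see §7).

**Marker CpGs.** Each cell type receives `markers_per_type` (default 50)
planted markers, alternating hypermethylated (marked type at 0.95, rest
at 0.05) and hypomethylated (the reverse). The planted gap of 0.9 leaves
margin above the `marker_delta = 0.8` requirement after the noisy means
shrink slightly toward 0.5. The spike target (monocyte by default)
additionally receives an `n_dmcs`-sized *reserved* pool of markers that
is never eligible for the deconvolution reference, so spiked effects
cannot bias the fraction estimates.

**Spike-in DMCs.** `n_dmcs = 1000` ground-truth DMCs are drawn from the
reserved pool; absolute effects are uniform on
[`effect_low`, `effect_high`] = [0.01, 0.2], the range typical of blood
EWAS hits (1–10%) up to disease-scale changes (10–20%). The sign
hypermethylates CpGs whose baseline is below 0.5 and hypomethylates the
rest, avoiding systematic clipping; the truth table records both the
drawn effect and the realized (post-clip) mean shift.

**Cell fractions.** Per-sample fractions follow
Dirichlet(`c * mu`) with mean `mu = (0.70, 0.20, 0.10)` for
neutrophils/CD4+ T cells/monocytes and concentration `c = 30`, giving
per-type standard deviations of ~0.08/0.07/0.05 — a plausible surrogate
for empirical whole-blood variation (granulocyte-dominated, monocytes a
~10% minority) rather than a fit to any published cohort. The
composition-shift scenario draws cases and controls from Dirichlets with
different means (defaults 0.80/0.13/0.07 vs 0.65/0.23/0.12) and spikes
nothing, so composition is the *only* case/control difference.

**Seeding.** One global seed; each pipeline stage draws from a child
stream keyed by the stage name, so outputs are bit-reproducible
stage-by-stage and replicate seeds are derived deterministically.

## 2. Reference construction and deconvolution

Markers are selected by the one-vs-rest *difference of mean betas* (not a
t-statistic): deconvolution rests on large absolute differences, and the
mean gap is the quantity that enters the mixture equation. Selection is
balanced between hyper- and hypomethylated markers when both qualify at
`delta_min`; reference entries are the per-cell-type mean betas.

Three estimators share the contract *fractions >= 0*:

* **constrained** (default): per sample, minimise `||R w - b||` subject to
  `w >= 0`, `sum(w) <= 1`. Solved by non-negative least squares on a
  slack-augmented system (an extra column for `1 - sum(w)` and a heavily
  weighted sum-to-one row, weight 1e3), which is deterministic and exact
  to solver tolerance (~1e-8) on noise-free mixtures.
* **robust**: Huber-weighted iteratively reweighted least squares
  (50 iterations max, coefficient tolerance 1e-6), negatives truncated,
  rows renormalised to sum exactly to 1. Preferable when a fraction of
  reference rows may be corrupted.
* **hierarchical**: two-level estimation for nested panels — level 1
  yields a parent-lineage fraction `f_p` (e.g. total immune), level 2 the
  within-parent proportions `p_k` (renormalised level-2 constrained
  estimates); subtype fractions are `f_p * p_k`, and non-parent level-1
  fractions pass through unchanged.

Bulk matrices missing up to 20% of reference markers are handled by
dropping the missing rows with a warning; below 80% overlap estimation
refuses to proceed. Reference column condition numbers above 1e8 are
rejected as collinear.

## 3. Differential-methylation tests

All tests are ordinary least squares on beta values with two-sided
t-tests, vectorised across CpGs (one shared design matrix per mode).
OLS-on-beta keeps effect sizes on the methylation-difference scale and
admits closed-form oracles; an M-value transform is deliberately not the
default.

* *unadjusted*: `beta ~ 1 + exposure` (equivalent to the pooled-variance
  two-sample t-test);
* *adjusted*: `beta ~ 1 + exposure + W_{-j}`, dropping the fraction
  column with the largest mean to break the sum-constraint collinearity.
  When fraction rows sum exactly to one the exposure inference is
  invariant to which column is dropped (the design spans the same space);
  constrained estimates may sum to slightly less than one, in which case
  the choice is a genuine (numerically negligible) modelling decision —
  the largest-mean column is the most stable default.
* *cell-type-specific*: `beta ~ sum_k w_k + sum_k (w_k * exposure)`
  without a global intercept; the interaction coefficient for cell type
  *k* estimates the within-*k* case/control beta difference. The
  minority-cell-type interaction is weakly identified in small cohorts —
  attribution to the correct cell type is reliable at the default 139
  samples but not at a few dozen.

Zero-variance CpGs are retained with p = 1 and a `degenerate` flag
(keeping the CpG universe stable for set algebra); perfect fits with a
nonzero coefficient get p = 0. Benjamini–Hochberg q-values are computed
per result table (per cell type for the interaction mode), with NaN
p-values excluded from the ranking and propagated. Significance defaults
to q <= 0.05.

The three-class partition splits CpGs significant in either analysis
into *unadjusted-only* (composition-driven), *adjusted-only* (revealed
by adjustment) and *both*.

## 4. Variance structure and clustering

PCA centers CpGs but does not variance-scale them, preserving the
beta-scale effect-size structure; fVAR is each retained PC's share of the
top-`n_pcs` (default 15) variance. PC–factor association uses the
linear-model F-test for numeric factors and one-way ANOVA for
categorical ones, annotating each PC with its minimum-p factor.
Exposure-correlated PCs are ranked by absolute point-biserial
correlation; a `marginal` flag is raised when even the best PC has
p > 0.05, warning that clustering over those PCs is not expected to
track the exposure. Clustering is agglomerative (Euclidean, average
linkage, cut at k = 2), scored by the adjusted Rand index against the
exposure and a 2x2 Fisher exact test. CTH adjustment for the clustering
arm residualises each CpG on K-1 fraction columns (intercept retained,
residuals re-centered at the CpG mean); the operation is idempotent.

## 5. The three-arm benchmark

Each replicate: generate → spike → mix → deconvolve → test in three arms
(*oracle* = purified target-cell profiles, *unadjusted* = raw mixtures,
*adjusted* = mixtures + estimated fractions) → score against truth →
PCA/clustering panels per arm. Detection metrics at q <= 0.05:
sensitivity TP/(TP+FN), FPR FP/(FP+TN), precision TP/(TP+FP), with
precision reported as flagged NaN when an arm makes no calls. Multiple
replicates run under derived child seeds and report per-replicate and
mean metrics. The default report uses the full-size conditions
(50,000 CpGs, 139 samples, 1000 spikes); one replicate takes a few
seconds on one CPU, so the five-replicate headline run stays under a
minute.

## 6. What the benchmark shows

Under the defaults the pattern is stable across seeds: the unadjusted
arm detects essentially none of the minority-cell-type spikes
(sensitivity ~0, except for occasional seeds where a chance case/control
imbalance in the Dirichlet fractions — a ~2 sd event — lets the
composition confounding itself reach significance at marker CpGs: an
instructive failure in its own right); the adjusted arm recovers roughly
half of the spikes at precision fluctuating around the ceiling
`1 - alpha * pi0 ≈ 0.95` implied by BH at alpha = 0.05 with 2% true
signals; the oracle arm detects nearly all. In the composition-shift
scenario the unadjusted analysis calls hundreds of CpGs (the cell-type
markers) and the adjusted analysis essentially none. Fraction recovery
is near-exact (pooled R^2 ~ 1.0) because the reference markers are
planted with clean 0.9 gaps and the noise model is benign at extreme
betas — real-array reference mismatch would push this down toward the
0.8 regime reported for blood.

## 7. Known limitations

* **Independent noise across CpGs.** Real inter-individual methylation
  variation is strongly structured (genetic, technical and global
  factors induce correlated, low-rank variation). The iid latent noise
  here spreads residual variance isotropically across all sample-space
  directions, which has two visible consequences: (i) the adjusted arm
  is *more* powerful than a real bulk experiment at the same nominal
  noise level, because marker CpGs near beta 0/1 are nearly noise-free
  under the logit model; and (ii) after residualising the mixtures on
  fractions, the diluted spike signal (~0.1 x effect) does not rise
  above the isotropic noise floor in the top PCs, so the clustering-
  after-adjustment panel does not segregate by exposure the way purified
  data do — with realistically structured (low-rank) residual noise the
  adjusted panel would separate much more cleanly.
* **Between-cell-type differences confined to markers.** Shared CpGs
  have identical means in all cell types, so composition shifts only
  act through planted markers; real methylomes differ genome-wide.
* **No array artefacts.** No probe effects, batch structure, normalisation
  issues, genomic annotation, or covariates beyond the binary exposure
  (optional sex/age nuisance factors are available for the variance
  diagnostics).
* **Three cell types.** Real whole-blood panels resolve 6–7 types;
  the hierarchical estimator exists precisely to extend to nested
  panels, but the shipped defaults are the three-type experiment.
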
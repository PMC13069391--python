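# Methods

This note documents the statistical machinery implemented in
`morphodelim`, the defaults and numerical choices, and what the synthetic
test conditions do and do not establish about real data.

## Data model and allometric correction

A dataset is a strictly positive specimen-by-character matrix with an OTU
label and a designated body-size column (e.g. snout–vent length, SVL) per
specimen.  Positivity is required because all downstream modelling is on
the log10 scale.  Singleton OTUs are flagged rather than rejected —
removing them is a curation decision that belongs to the user.  The
outlier screen is a robust within-OTU z-score, |x − median| / (MAD ×
1.4826), default threshold 3.5; when the MAD is zero but the group is not
constant, off-median values are reported with an infinite score rather
than silently skipped (only fully constant groups are skipped).  The
statistic and threshold are this package's choice of a standard robust
screen; nothing downstream depends on them.

Size correction uses

    X_adj = log10(X) − β (log10(SVL) − mean log10(SVL)),

with β per character.  In `pooled` mode (the default, appropriate for
multispecies data) β is the common within-group slope obtained by
regressing group-mean-centred log characters on group-mean-centred log
size, so group mean differences cannot leak into the slope; the reference
size is the grand mean of log10(SVL).  `per-otu` estimates β within each
OTU (each OTU then needs ≥ 2 specimens and non-constant size);
`none` log10-transforms without any slope term — the log transform is
kept even here because every downstream Gaussian model is better served
by it, and a raw passthrough would silently change the meaning of the
fitted parameters.  Corrected datasets carry a `log_scale` tag and a
second correction is refused.  Base-10 logarithms are used throughout;
only the reference constant would change with the base.

## The constrained-covariance Gaussian mixture engine

Component covariances are parameterised as Σ_k = λ_k D_k A_k D_kᵀ with
volume λ_k > 0, shape A_k (diagonal, det 1) and orientation D_k
(orthogonal).  The fourteen families EII … VVV fix each element as Equal
across components, Variable, or Identity.  Free-parameter counts follow
the standard eigen-decomposition enumeration (e.g. VEE in d dimensions
with G components: G volumes + (d−1) shape + d(d−1)/2 orientation); BIC
is computed on the maximised scale, BIC = 2 log L − k ln n, and every
comparison picks the larger value, breaking ties by fewer parameters,
then fewer components, then alphabetical family code.

M-steps are the closed-form maximum-likelihood updates where they exist.
Four cases iterate:

* VEI / VEV / VEE alternate the shared shape (or shared det-1 covariance)
  with the per-component volumes — a fixed point reached in a few sweeps
  (tolerance 1e−8, cap 100);
* EVE / VVE (shared orientation, variable shape) minimise
  Σ_k tr(A_k⁻¹ D^T W_k D)/λ_k over orthogonal D by a minorise–maximise
  scheme: the concave part is linearised at the current D and the
  resulting Procrustes subproblem solved by SVD.  During EM the sweeps
  are capped at 10 and the orientation is warm-started from the previous
  M-step, which makes the update a generalised-EM step (never worse than
  the previous parameters, so the log-likelihood stays monotone); a
  single supervised fit runs the flip-flop to full convergence.

EM starts from a deterministic hard partition: Ward agglomeration on
z-scored data cut at G (so results are reproducible without a seed);
random responsibility starts are available.  Convergence is a relative
log-likelihood change below 1e−8 (cap 500 iterations).  A component whose
responsibility mass falls below 1e−6 n triggers a perturbed restart (up
to 3), then an error.  Covariances whose smallest eigenvalue falls under
1e−10 × mean total variance mark the fit degenerate; degenerate cells are
recorded as missing in the model-selection table and never win selection.
The agglomerative initialisation is a documented substitute for other
hierarchical variants in circulation; BIC values on real data can differ
in the last digits from implementations with a different start.

## Unsupervised and supervised delimitation

`unsupervised_cluster` fits the full (G = 1..Gmax) × family grid
(defaults: Gmax 9, all 14 families) and reports the BIC surface, the best
fit and — given OTU labels — the cluster×OTU cross-tabulation with a
qualitative tag: a cluster is *mixed* when ≥ 2 OTUs each contribute ≥ 2
of its specimens, an OTU is *split* when ≥ 2 clusters each hold ≥ 2 of
its specimens, and single stragglers are listed without changing the tag
(the patterns are qualitative; the ≥ 2 thresholds make them robust to one
mislabelled specimen).

The supervised layer (EDDA: one Gaussian per known group, family
constraints shared across groups) has no membership EM — parameters are
the ML estimates given the labels, and the classified log-likelihood
Σ_i log[π_{z_i} φ(x_i | μ_{z_i}, Σ_{z_i})] feeds the same BIC.  Mixing
proportions are the group frequencies and are counted as K−1 free
parameters; a toggle (`count_proportions=False`) exposes the alternative
convention since published BIC tables do not always state it.  Groups
need ≥ 2 specimens; families that are not estimable for a grouping (e.g.
a full per-group covariance with fewer specimens than dimensions, or any
covariance hitting the eigenvalue floor) are skipped with the scheme
scored by the remaining families.

`merge_path` starts from the OTU labels and, at each level, scores every
unordered pair-merge by its best-family BIC, committing the highest
(ties: lexicographically first pair; merged groups are named
"A-B" in sorted order).  The path is a single greedy trajectory — it
does not search all partitions, which grows as the Bell numbers.
`compare_schemes` scores arbitrary user-defined schemes (lumps *or*
splits) the same way, so a merge-path level and an identical explicit
scheme get identical BICs by construction.  Ranking uses ΔBIC_i =
BIC_best − BIC_i, BF_i = exp(ΔBIC_i/2) (evidence against scheme i) and
flat-prior posteriors PP_i ∝ exp(−ΔBIC_i/2); posteriors are computed via
a softmax on −ΔBIC/2 and are overflow-safe, Bayes factors above 1e6 are
formatted in scientific notation with 4 significant digits.  Prior
weights other than flat are deliberately not exposed.

## Diagnostic characters

`boruta_select` implements the shadow-feature wrapper: each run appends
one freshly permuted shadow per surviving character, trains a random
forest (default 500 trees, `sqrt` feature subsampling), and scores a hit
for characters whose importance exceeds the best shadow's.  Two-sided
binomial tests on hits (success probability ½, Bonferroni-corrected
across the character set, α = 0.01) promote to Confirmed or demote to
Rejected after each run (cap 100 runs); rejected characters and their
shadows leave the forest.  Importance defaults to Gini impurity decrease
— the convention of the widely used Python port of the algorithm — which
is obtained free of charge from the fitted forest and is calibrated
against the shadows on exactly the same scale; a permutation-importance
backend (mean accuracy drop when a column is scrambled) is available for
users who want an importance with an error-rate interpretation, at a
substantial runtime cost.  A genuinely constant character can never beat
a shadow and is always Rejected.  Note the honest limitation: with ~100
specimens, one in several truly-uninformative characters will show
enough *in-sample* association with the labels to keep beating fresh
shadows; such characters correctly end Tentative rather than Rejected —
that is the category's purpose, not a failure of the procedure.

Univariate tests default to Welch's t (unequal variances; Student's t and
one-way ANOVA available) with adjustment across characters (none /
Bonferroni / Holm / Benjamini–Hochberg; the significance flag follows the
adjusted value, and "none" — the common convention for figure
asterisks — leaves p unchanged).  `diagnostic_report` crosses the two
analyses; the informative disagreement cells are "discriminatory, not
mean-shifted" (e.g. variance or joint-structure signal) and
"mean-shifted, weak classifier".

## Ordination and PERMANOVA

PCA eigen-decomposes the covariance (or correlation) matrix with a
deterministic sign convention (largest-magnitude loading positive).
DAPC reduces to n_pcs leading components ("auto": smallest number
explaining ≥ 90% variance, capped at n/3) and fits linear discriminant
axes on the retained scores; n_pcs must stay below n − K.  PERMANOVA uses
Euclidean geometry, where the distance-matrix partition equals the
coordinate sums-of-squares partition: pseudo-F = [SS_b/(K−1)] /
[SS_w/(n−K)], R² = SS_b/SS_total, and p = (b+1)/(P+1) under seeded label
permutations — so the smallest attainable p with 50,000 permutations is
1/50001 ≈ 0.000020.  When specimen ids are supplied the rows are sorted
by id before permuting, making the p-value invariant to input order.
Pairwise tests run on each pair's subset with Bonferroni adjustment by
default (Holm and BH available).  Default distance input is the full set
of PCA scores, which is numerically identical to the corrected data;
`--n-pcs` restricts it.

## Synthetic data

The generators produce exactly what the models assume.
`simulate_gaussian_groups` draws each group from a specified multivariate
normal (SPD-checked).  `simulate_allometric` builds log10-linear growth,
log10 X = a_gj + b_j (log10 SVL − mean) + ε with ε ~ N(0, sd²) and SVL
log-uniform over a size range, exponentiated back to measurement scale —
so the package's own correction model is exactly recoverable.
`desmognathus_mimic` is the standing three-OTU fixture: n = 69/21/26,
17 characters, salamander-scale intercepts (log10 mm), slopes 0.68–1.05,
residual SD 0.04 (≈ 10% coefficient of variation on raw scale), SVL
35–95 mm; OTU2 and OTU3 share one shape distribution and OTU1 is offset
by 6 within-group standard deviations along the equi-angular direction.
The separation and noise level were fixed once as a realistic
strongly-diagnosable-species scenario.  All randomness flows through one
seeded generator; a seed reproduces a dataset bit for bit.

What the synthetic conditions do **not** exercise: non-Gaussian trait
distributions, measurement error correlated with size, missing data,
meristic or categorical characters, and unbalanced singleton-heavy
sampling.  Passing tests therefore validate the estimators and the
selection arithmetic under the model's own assumptions, not robustness to
their violation — on real data, normality of each group remains an
assumption the user must judge.

## Problem sizes used in the validation suite

The test suite validates delimitation recovery on the mimic with Gmax = 3
over all 14 families across 100 seeds (the under- and over-shooting
competitors of the true cluster count), EM properties on 20 seeded
fixtures, type-I calibration of PERMANOVA over 200 null replicates at
999 permutations, and shadow-feature behaviour over 20 seeded replicates
at the module defaults (500 trees, up to 100 runs) — smaller forests or
run caps measurably erode noise rejection, so the defaults are the
smallest configuration at which that claim is stable.  Elsewhere the
sizes were chosen as the smallest at which the respective statistical
claims hold; larger grids change nothing qualitatively, and the package
defaults (Gmax 9, 50,000 permutations) remain the recommendation for
real analyses.
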
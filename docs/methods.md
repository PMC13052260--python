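# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that matter for reproducing
results.

## Synthetic cohorts

Each cell subpopulation is a Gaussian component in arcsinh space — the
standard modelling convention for transformed CyTOF intensities, where
per-cluster marker distributions are approximately normal. A cohort is
drawn as follows: each sample belongs to one group (e.g. `non_irAE` /
`irAE`) and one acquisition batch; its events are a multinomial draw
over clusters with group-specific weights; event values are
`Normal(mean_ck + shift, sd_ck)` per cluster c and marker k, where
`shift` collects the planted (group, cluster, marker) effects. Values
are mapped to the raw scale with `sinh(v) * cofactor`, clipped at zero
(ion counts are non-negative), and batch distortions
`x -> x * scale + shift` are applied there — on the same scale order as
real acquisition effects, so that batch correction is exercised through
the nonlinearity of the transform rather than on conveniently additive
data.

The default configuration mirrors the study shape: 26 clusters over a
41-marker PBMC panel whose first 26 markers form the cross-cohort
shared panel, ~10 samples per group, 10,000 events per sample, two
batches. Cluster identity is encoded the way real PBMC subpopulations
are: each cluster expresses a small random subset (5–8) of shared-panel
markers highly (≈ 2.8 arcsinh units) over a low background (≈ 0.4),
with within-cluster sd 0.35. Planted structure includes an arcsinh
additive decrease of CXCR3 and CCR6 in several case-group clusters
(default −1.0 ≈ 2.9 within-cluster sd; the source study reports no
per-cluster effect sizes, so the default is chosen for testability),
one cluster with weight exactly zero in the case group (the "Cluster
22" analogue), one frequency-shifted cluster (the "Response Cluster 19"
analogue), and a five-analyte plasma panel (CCL20, CXCL9, CXCL10,
CXCL11, PF4V1) drawn log-normally — concentrations are positive and
right-skewed — with CXCL9/10/11 fold-changes > 1 in the case group.

What the generator does *not* emulate: doublets, bead and debris
events, acquisition drift within a run, heavy-tailed or zero-inflated
marker noise, correlated markers within a cluster, and biological
between-sample variation in cluster means (samples of a group share
their cluster means, so between-sample variance is sampling noise
only). Passing tests therefore demonstrate the correctness of the
machinery under a well-specified mixture model, not performance on real
cytometry, where effect sizes are smaller and nuisance structure
richer. All draws flow from a single integer seed; identical
configurations reproduce byte-identical data.

## Preprocessing

Arcsinh cofactor defaults to 5, the mass-cytometry community
convention. The transform is strictly monotone and recorded in the
event-matrix metadata; transforming twice is an error.

Batch correction is the parametric empirical-Bayes location/scale
model: per marker g, batch i, event j, `x_ijg = α_g + γ_ig + δ_ig ε`.
Markers are standardised by the batch-size-weighted grand mean and
pooled residual variance; per-batch location (γ) and scale (δ²)
estimates are shrunk toward Gaussian / inverse-gamma priors whose
hyperparameters come from across-marker moments, via the standard
coupled fixed-point iteration (tolerance 1e-8). Events are pooled
across samples within batch; no biological covariates are modelled
(group proportions are assumed comparable across batches, as in the
source design). After adjustment each marker is recentred exactly to
its grand mean — EB shrinkage otherwise leaves an O(1/n) offset — which
makes the "grand mean preserved" invariant exact rather than
approximate. Markers with zero pooled variance are left untouched with
a warning; a single batch reduces to the identity with a warning;
batches with fewer than two events are rejected. The implementation is
cross-checked in the test suite against an independent single-cell
implementation of the same estimator (agreement limited by that
reference's looser 1e-4 fixed-point tolerance).

Comparability after correction is quantified by PCA: per component,
the fraction of score variance explained by batch membership
(between-batch sum of squares over total). Values near zero on the
leading components indicate comparable cohorts.

## Clustering

Events are pooled with a per-group uniform downsampling cap (default
100,000) and clustered by Leiden modularity optimisation
(RB-configuration objective) on an undirected k-nearest-neighbour graph
(k = 30, Euclidean in arcsinh space). The resolution grid 0.5–3.0 in
steps of 0.02 is scanned in full; the chosen resolution minimises
|K(r) − target| with ties resolved toward the smallest resolution
(coarser, more stable partitions). The full grid record is part of the
result. Cluster ids are relabelled 0..K−1 by descending event count so
that naming (C01, C02, …) is stable across runs; the Leiden seed is
fixed by the estimator's `random_state`. Degenerate input (all events
identical) yields a single cluster with a warning. Community detection
is not strictly monotone in resolution, so only the aggregate trend of
achieved K versus r is asserted in tests (≥ 90 % of adjacent grid pairs
non-decreasing).

Centroid profiles are per-cluster marker means; z-scoring standardises
each marker across clusters with the sample sd (n−1) — the convention
is recorded in the output — and drops markers constant across clusters,
which carry no direction.

## Recapitulation and transfer

The recapitulation forest (scikit-learn random forest, 500 trees)
predicts full-panel cluster labels from shared-marker values only.
Reconstruction fidelity is the adjusted Rand index on a stratified
20 % holdout (the evaluation split is this package's choice); the
final model is refit on all events. The ARI is computed from the label
contingency table,

    ARI = (Σ_ij C(n_ij,2) − E) / (½(Σ_i C(a_i,2) + Σ_j C(b_j,2)) − E),
    E = Σ_i C(a_i,2) Σ_j C(b_j,2) / C(n,2),

returning 1.0 when the denominator vanishes (both partitions trivial).
Transfer to an external cohort keeps each cell's argmax class with its
probability; cells are retained only when that probability *strictly*
exceeds the threshold (default 0.8). The threshold applies to the
argmax class probability (not the matched-cluster probability — the
natural reading of a per-cell confidence filter). Per-cluster marker
relevance uses one-vs-rest forests with permutation importance (10
permutations, holdout accuracy drop) plus holdout accuracy and
sensitivity; clusters with fewer than two members on either side of
the one-vs-rest split are skipped.

## Cluster matching

Cross-dataset correspondence is the per-source argmax of cosine
similarity between z-scored centroid profiles over the common marker
set. Greedy argmax mirrors "best-matching clusters" semantics: two
source clusters may claim one target, and such collisions are surfaced
in the result rather than resolved (an optimal one-to-one Hungarian
assignment is available behind a flag). Matches with similarity below
a configurable floor (default 0.5) are flagged low-quality; the floor
is a reporting aid, not a filter.

## Feature tables and group comparison

Per sample: cluster frequencies as percent of the sample's own events
(summing to 100), per-cluster marker means, holistic (all-event)
means, and plasma concentrations. A cluster absent from a sample has
frequency 0 and missing expression, excluded pairwise from tests
rather than imputed. Group contrasts use the two-tailed equal-variance
Student's t-test; expression summaries are means (a median option
exists but is not the default). No multiple-testing correction is
applied by default — the readout convention is raw p < 0.05 across
markers and clusters — but Benjamini-Hochberg q-values are always
emitted alongside for transparency. Features constant in both groups
or with fewer than two values per group are skipped with a warning.

irAE onset is classified early (0–90 days inclusive after the first
checkpoint-inhibitor dose) versus late (> 90 days); day 90 is early,
per the printed closed interval. Cohort summaries report computed
fractions to one decimal; empty strata yield `None` rather than a
number.

## Biomarker evaluation and scoring

AUC is the tie-corrected pairwise concordance (ties credit ½),
computed from midranks — identical to the trapezoidal area under the
empirical ROC curve, and asserted equal to brute-force pair counting
within 1e-12 in the tests. Orientation is explicit: "lower" negates
scores (for markers decreased in the at-risk group: CXCR3, CCR6, PD-1,
TIGIT), "auto" picks the direction with AUC ≥ 0.5 and records it.
Confidence intervals default to the DeLong structural-components
variance (Hanley–McNeil normal approximation as an option), clipped to
[0, 1]; the p-value tests AUC = 0.5 with the DeLong normal
approximation. The original analyses used a spreadsheet package's
"Wilson/Brown" hybrid whose exact AUC recipe is not public; DeLong is
the standard, documented replacement, and the CI method is recorded in
every result. With a degenerate DeLong variance (perfect separation)
the p-value is reported as 0 and the CI collapses; small-sample CIs
near the boundary should be read with that in mind.

Bivariate logistic models are fit by Newton/IRLS maximum likelihood
(statsmodels). Complete separation — diverging coefficients or
non-convergence — is detected, flagged on the returned model, and the
fit falls back to a lightly penalised solution so that fitted
probabilities and their ROC remain usable.

The benefit score ships the published cut-offs as defaults: Response-
Cluster-19 frequency > 1.219 % → 2 points, Cluster-22 frequency >
0.025 % → 1 point, C07 CCR6 mean > 1.238 → 1 point; total ≥ 2 →
beneficial. All comparisons are strict (a value exactly at a cut-off
scores nothing), frequencies are percent of total events, and all
thresholds are configurable. How the original cut-offs were derived is
not stated; a Youden-threshold utility is provided for exploration but
the shipped defaults are never re-derived from data.

## Pipeline and formats

`run_pipeline` chains transform → combat → cluster → recapitulate →
transfer → match → features → diff → roc → score. Cross-cohort ComBat
uses cohort as the batch and operates on the shared panel; the
discovery cohort is clustered on its full panel. Every stage draws its
seed from a single top-level seed via seed-sequence spawning, and the
manifest records per-stage seeds, SHA-256 content hashes and captured
warnings; a failing stage aborts with its name while earlier artifacts
are preserved. Interchange formats are deliberately plain text:
per-sample delimited event matrices (header = marker names), CSV
metadata and feature tables, JSON reports. Channel names are resolved
against the panel by case-insensitive name or alias; technical
channels are dropped on read. FCS containers are not parsed; export
from acquisition software to text matrices is assumed.

## Problem sizes in tests and the acceptance script

The shipped checks run the same code paths as a full-scale analysis on
desk-scale data: cluster-count recovery uses 10,000 events (target
K = 3, blobs 8 sd apart in a 30-dimensional, panel-like space — in
very low dimension a kNN graph of a large Gaussian blob has genuine
spatial substructure that community detection legitimately resolves,
so low-dimensional blob fixtures understate clustering performance)
and 12,000 events over 26 clusters (target K = 26); recapitulation and
matching use two cohorts of 8 planted clusters with 500-tree forests;
effect detection uses 100 simulated cohorts of 20 samples × 800
events, with a planted 3-within-cluster-sd CXCR3 decrease in three
clusters and ~28,000 aggregate null features for calibration. These
sizes are the package's validation conditions, chosen so the whole
suite runs in minutes while keeping every statistical claim
well-powered.

## Known limitations

- The generator's independence assumptions (uncorrelated markers, no
  between-sample random effects) make planted effects easier to detect
  than in real cohorts; detection rates here are upper bounds.
- ComBat assumes comparable group composition across batches; strongly
  confounded designs (group ≈ batch) will remove biology with batch.
- Greedy cosine matching can map two source clusters onto one target;
  collisions are reported but deciding them is left to the analyst.
- DeLong intervals are asymptotic; with ~10 samples per group (the
  scale of the motivating study) they are approximate, and exact
  small-sample inference is out of scope.
- The benefit score is a fixed decision rule, not a calibrated model;
  no cross-validation or recalibration is performed.
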
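# cytoscore

Peripheral-blood CyTOF immune profiling for checkpoint-inhibitor
cohorts: batch correction, target-count graph clustering, cross-panel
cluster recapitulation, differential marker/frequency testing, ROC
biomarker evaluation, and a 4-point treatment-benefit score.

## The problem

Immune checkpoint inhibitors (anti-PD-1 antibodies) can trigger
immune-related adverse events (irAEs) — autoimmune-like toxicities
graded 1–4 — and only a fraction of patients respond. Baseline
peripheral-blood mononuclear cell (PBMC) profiles measured by mass
cytometry (CyTOF, ~40 proteins per cell) carry predictive signal for
both outcomes: chemokine receptors such as CXCR3 and CCR6 are decreased
in specific PBMC subpopulations of patients who later develop irAEs,
a distinct dendritic-cell cluster can be absent from the irAE group,
and the frequency of a CCR6⁺CXCR5⁺ B-cell cluster tracks response.

`cytoscore` implements the full analysis chain that turns per-sample
event × marker matrices into such biomarkers, together with a synthetic
cohort generator that plants all of these effects with known ground
truth, so every stage is testable end to end.

## The method

For sample *s* with raw ion counts *x*, per-marker intensities are
variance-stabilised as `asinh(x / c)` with cofactor `c = 5`. Cohort or
acquisition-run batch effects are removed per marker with parametric
empirical-Bayes location/scale adjustment (the ComBat model
`x_ijg = α_g + γ_ig + δ_ig ε`, batch effects shrunk toward
across-marker priors), validated by the fraction of principal-component
score variance explained by batch.

Pooled, per-group-downsampled events are clustered by Leiden community
detection on a k-nearest-neighbour graph (k = 30). Because Leiden's
native dial is a resolution parameter, a grid search over
`r ∈ [0.5, 3.0]` (step 0.02) selects the resolution whose achieved
cluster count is closest to a target K (e.g. 26), ties going to the
smaller resolution.

To carry a full-panel clustering (41 markers) into an external cohort
that shares only ~26 markers, a 500-tree random forest is trained to
predict cluster labels from the shared markers alone; reconstruction
fidelity is the adjusted Rand index (ARI) on a stratified holdout, and
external cells are retained when their top class probability strictly
exceeds 0.8. Cluster correspondence between independently clustered
datasets uses cosine similarity of z-scored centroid profiles (per
marker, across clusters).

Candidate biomarkers — per-sample holistic marker means, per-cluster
marker means, cluster frequencies, plasma ligand concentrations — are
compared between groups with the two-tailed equal-variance Student's
t-test and evaluated as classifiers by tie-corrected AUC with DeLong
95% confidence intervals; pairs of markers combine via maximum-
likelihood logistic regression. Finally the benefit score awards
2 points for Response-Cluster-19 frequency > 1.219 %, 1 point for
Cluster-22 frequency > 0.025 %, and 1 point for mean CCR6 in cluster
C07 > 1.238 (arcsinh units); ≥ 2 points marks a regimen beneficial.

## Worked example

```python
import cytoscore as cs

cfg = cs.make_default_config(seed=1, n_clusters=8, samples_per_group=6,
                             events_per_sample=1000)
matrices, meta, truth = cs.generate_cohort(cfg)          # raw ion counts
transformed = [cs.arcsinh_transform(m) for m in matrices]
corrected, _ = cs.combat_correct(transformed)            # across batches

table = cs.sample_features(corrected, truth.labels, meta)
res = cs.group_compare(table, "group", ("non_irAE", "irAE"),
                       features=["expr.C01.CXCR3", "expr.C03.CCR6",
                                 "holistic.CXCR3"])
print(res[["mean_non_irAE", "mean_irAE", "t", "p", "direction"]].round(4))
```

```
                mean_non_irAE  mean_irAE        t    p  direction
feature
expr.C01.CXCR3         0.4003     0.0223 -56.5915  0.0  decreased
expr.C03.CCR6          2.8740     1.8998 -59.5380  0.0  decreased
holistic.CXCR3         1.2710     0.9778 -13.8259  0.0  decreased
```

The generator planted an arcsinh-scale CXCR3/CCR6 decrease in the irAE
group's clusters C01 and C03; both are recovered with the correct
direction, and the holistic (all-event) CXCR3 mean is dragged down with
them. The per-sample cluster means then act as classifiers
(`orientation="lower"`: lower expression predicts irAE):

```python
y = (table["group"] == "irAE").astype(int).to_numpy()
roc = cs.roc_auc(table["expr.C01.CXCR3"].to_numpy(), y, orientation="lower")
print(f"AUC {roc.auc:.4f} (95% CI {roc.ci_low:.4f}-{roc.ci_high:.4f})")
# AUC 1.0000 (95% CI 1.0000-1.0000)

card = cs.benefit_score(freq_rc19=2.1, freq_c22=0.04, ccr6_c07=1.10)
print(card.points, card.total, card.decision)
# {'rc19': 2, 'c22': 1, 'ccr6_c07': 0} 3 beneficial
```

The same stages are available as CLI subcommands
(`cytoscore simulate | preprocess | cluster | recapitulate | transfer |
match | features | diff | roc | score | run`); `cytoscore run` chains
all ten stages and writes a manifest with per-stage seeds and content
hashes.

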
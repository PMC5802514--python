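# stresscov

Cross-species structural covariance network analysis of chronic stress.

Chronic stress reshapes brain anatomy not only region by region but in how
regional volumes co-vary across subjects. `stresscov` implements the full
analysis chain used to study this in a mouse chronic-stress model (UCMS,
unpredictable chronic mild stress) and in humans stratified by childhood
trauma: it integrates multi-test behavioral batteries into a single
emotionality score, compares ROI volumes between groups with FDR control,
builds group-wise structural covariance networks across a density grid,
computes weighted graph metrics from first principles, tests group
differences by label permutation with area-under-curve aggregation, and
characterizes focal "hub" changes such as the amygdala's gain in degree and
strength. A synthetic cohort generator reproduces the statistical structure
of both designs so the whole pipeline is testable without any data download.

## The model in brief

For each group *g* (control or stress) the structural covariance network is
the Pearson correlation matrix of ROI volumes across that group's subjects,

&nbsp;&nbsp;&nbsp;&nbsp;*W⁽ᵍ⁾ᵢⱼ* = corr(*vᵢ*, *vⱼ*) over subjects in *g*,

with negative correlations discarded and the matrix thresholded to keep
exactly the top *d* fraction of the strongest edges for each density *d* in
a grid (default 0.10–0.30 in steps of 0.01). On each weighted graph the
package computes segregation metrics — Onnela-style weighted transitivity
and clustering coefficient, Newman modularity *Q* maximized by multi-restart
Louvain — the characteristic path length on 1/*w* distances, and nodal
hubness (degree, strength, betweenness, closeness, degree rank). Group
differences Δ(*d*) = metric(stress) − metric(control) are tested against a
null distribution obtained by shuffling group labels over the pooled
subjects and rebuilding both networks, with two-tailed empirical p-values

&nbsp;&nbsp;&nbsp;&nbsp;*p* = (#{|Δ*perm*| ≥ |Δ*obs*|} + 1)/(*n_perm* + 1)

per density and for the trapezoidal area under Δ(*d*) across the grid.

Behavioral emotionality follows the z-score integration convention: each
variable is z-scored against the control group, oriented so larger means
more emotional, averaged within and then across tests; PCA on the pooled
standardized battery yields an emotionality-oriented first component.

## Worked example

```python
import stresscov as sc
from stresscov.networks import density_grid

spec = sc.mouse_default_spec(seed=1)                 # 12 vs 12 mice, 155 ROIs
labels = sc.default_roi_labels(spec, "mouse")
volumes, behavior = sc.generate_cohort(spec, roi_labels=labels)

pca = sc.behavioral_pca(behavior, n_components=3)
print(f"PC1 explains {100 * pca.explained_variance_fraction[0]:.1f}% of behavior")

res = sc.permute_metrics(
    volumes,
    density_grid(0.10, 0.30, 0.05),
    ["modularity", ("degree", "amygdala")],
    n_perm=1000,
    seed=7,
)
for key, r in res.items():
    print(f"{key}: mean diff {r.observed_diff.mean():+.3f}, AUC p = {r.auc_p:.3f}")
```

Output (seed 1):

```
PC1 explains 45.3% of behavior
modularity: mean diff -0.298, AUC p = 0.017
degree[amygdala]: mean diff +70.800, AUC p = 0.001
```

PC1 captures nearly half the behavioral variance and separates the groups;
under stress the network loses modularity (negative difference, significant
in aggregate across the density grid) while the amygdala gains on average
~71 direct covariance connections — the focal-hub-gain versus
global-declustering trade-off the analysis is designed to expose.

The same stages are available from the shell:

```bash
stresscov simulate --species mouse --seed 1 --out-dir cohort/
stresscov permute --volumes cohort/volumes.csv --grid 0.10:0.30:0.05 \
    --node amygdala --n-perm 1000 --seed 7 --out-dir results/
stresscov run --config config.yaml        # full pipeline from a YAML config
```

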
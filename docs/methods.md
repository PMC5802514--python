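# Methods

This note documents the statistical model behind `stresscov`, the defaults
and why they have the values they do, what the synthetic cohorts do and do
not emulate, and the numerical conventions that make results reproducible.

## Structural covariance networks

A structural covariance network is a *group-level* object: the Pearson
correlation of ROI volumes across the subjects of one group, for every ROI
pair. There is no per-subject network; consequently the only exchangeable
unit for inference is the subject's group label.

Construction follows the standard recipe. Negative correlations are set to
structural zeros (absent edges, excluded from degree counts), and the
nonnegative matrix is thresholded to exactly k = round(d·M) edges at each
density d on the grid, where M = n(n−1)/2 is the number of ROI pairs and
rounding is half-up. Comparing groups at equal edge counts separates
topology from overall correlation level. Ties at the cutoff are broken by
(−weight, i, j) lexicographic order; because the tie-break is deterministic,
edge sets are nested across increasing densities, which the test suite
asserts. The default grid spans densities 0.10–0.30 in steps of 0.01
(21 points).

Correlation is computed on volumes exactly as passed in. The mouse preset
correlates raw volumes; the human preset first divides by total brain
volume and residualizes on sex, since large human samples carry sex-driven
scale structure that would otherwise dominate the covariance.

## Graph metrics

All metrics follow the conventions used for weighted undirected brain
networks and are implemented from first principles (no graph-library calls
in the computational core; networkx appears only for GraphML export and as
an independent oracle in the tests):

- **Transitivity / clustering coefficient** (segregation): weights are
  rescaled by the maximum weight, each triangle contributes the geometric
  mean of its three rescaled weights. Transitivity is the global ratio of
  total triangle intensity to connected triples; the clustering coefficient
  is the mean of the nodal ratios with degree-<2 nodes contributing 0.
- **Modularity** (segregation): Newman's Q on the weights, maximized by a
  multi-restart Louvain whose local-move sweep is numba-compiled. Restarts
  draw node orders from a seed-determined stream; the best Q over restarts
  is reported, so more restarts can only improve the value and rerunning
  with the same seed is bit-identical. The default is 100 restarts for
  one-off network descriptions and a small number (1–5) inside permutation
  loops, where the same estimator noise enters observed and null values
  symmetrically and therefore does not bias the test.
- **Path length** (integration): mean shortest-path distance over connected
  ordered pairs with edge distance 1/weight, by a hand-rolled Dijkstra;
  unreachable pairs are excluded and the component count is reported.
- **Nodal hubness**: binary degree on the thresholded graph, strength as
  the weight sum, Brandes betweenness (endpoints excluded, normalized by
  (n−1)(n−2)/2), and reachable-scaled (Wasserman–Faust) closeness so
  fragmented graphs still yield finite values. Degree ranks are 1-based
  with ties sharing the minimum rank — the conservative choice for hubness
  claims.

Every metric is checked against exhaustive brute-force enumeration on 200
random graphs of ≤7 nodes to 1e−9, and betweenness/closeness additionally
against networkx.

## Permutation inference

Each permutation shuffles group labels over the pooled subjects, preserving
group sizes, then rebuilds both correlation matrices and re-thresholds at
every density. One shared permutation schedule serves all densities and all
metrics in a run: this makes the area-under-curve aggregation coherent (the
null AUCs come from the same shuffles) and saves recomputation. Empirical
p-values use the +1-corrected two-tailed formula
p = (#{|null| ≥ |observed|} + 1)/(n_perm + 1), which is never exactly zero
and is exactly valid at finite n_perm. AUC is the trapezoid of the signed
difference over the density grid (degenerating to the single value on a
one-point grid). The design default is n_perm = 10,000; tests and the
acceptance script use 200–1000, which changes only the resolution of p.

Nodal significance uses an a-priori run-length criterion: a node is flagged
when p < α at ≥ 2 consecutive grid densities (both α and the run length are
configurable). Calibration is verified on 500 effect-free cohorts: the
modularity test rejects at the 5% level at a rate inside [0.03, 0.07].

## The synthetic cohort generator

Volumes are drawn from a latent-factor model: v = μ + σ·(Λf + ε), with a
global factor giving every ROI pair the between-module correlation, one
factor per module raising within-module correlation, and independent noise
completing unit variance. PSD of the implied correlation is checked before
sampling and violations name the offending parameter. Baseline volume is
μ = 10 mm³ with σ = 0.5 mm³ (μ/σ = 20), so nonpositive draws are
practically impossible; if one occurs it is an error, never clipped.

Stress effects are three orthogonal knobs applied to the stress group:

- **demodularization** δ multiplies the within-module loadings, so the
  stress within-module correlation falls from w to b + (w−b)·δ².
- **hub_gain** g adds a factor shared by the hub ROI and its target set
  with *asymmetric* loadings: the hub loads a = √(1 − its communality), the
  targets load b = g/a, making the hub-target correlation increment exactly
  g while the unavoidable target-target increment is only b². (A symmetric
  √g loading would give the targets the full increment among themselves,
  creating a clique in which the hub is the *least* connected member — the
  opposite of the hub-centered phenomenon the knob models. A single shared
  factor of some form is forced by positive semidefiniteness: one variable
  cannot gain correlation g with many mutually independent targets once
  their squared correlations sum past 1.)
- **volume_effect_size** d shifts the mean of a small a-priori ROI set by
  d·σ in the stress group. The centered emotionality trait replaces a
  fraction κ = 0.3 of those ROIs' latent signal (variance-preserving), so
  their volumes track emotionality within groups without inflating their
  variance — an inflation would dilute the ROI's covariance with the rest
  of the brain and silently weaken the hub effect when the hub is also an
  a-priori volume ROI, as it is in both default designs.

Behavior: each variable loads λ = 0.5 on the latent emotionality trait
(group mean difference = emotionality_effect_size, SD 1) with the loading
sign flipped for variables whose metadata says lower values are more
emotional, plus independent noise. Directions alternate across generated
variables so the sign-flip path is always exercised.

RNG: the master seed is split into independent streams for the trait, the
volume table and the behavior table, so each table is individually
reproducible.

### Default designs and how they were chosen

The mouse design is 12 vs 12 subjects over 155 ROIs; the human design is
237 (low trauma) vs 299 (high trauma) over 56 ROIs. Both use a
between-module correlation of 0.45 (within-module 0.90 mouse, 0.88 human),
hub_gain 0.3, demodularization 0.7 (mouse) or 0.55 (human), and place the
amygdala (the hub) in a singleton micro-module so that in the control state it is an unremarkable
low-rank node. The mouse hub gains 96 targets (24 per large module), the human hub
18 (6 per module); mouse volume effects are 1.5 SD on four a-priori ROIs
with a 2-SD latent emotionality shift over a 34-variable battery, human
volume effects 0.4 SD on one ROI with a 1-SD shift over a 5-subscale
questionnaire.

These values were fixed by a design study against the question the
generator exists to answer: *are the injected effects recoverable by this
pipeline at the study's own sample sizes?* Two facts drive the choices.
First, a sample correlation at n = 12 has standard error ≈ (1−r²)/√(n−3),
about 0.3 at r = 0.5 but only 0.07 at r = 0.9 — weak-correlation regimes
drown a +0.3 covariance increment at mouse sample sizes no matter how the
modules are arranged, while strong baselines (realistic for anatomical
covariance, where inter-regional volume correlations are routinely above
0.8) make it recoverable. Second, at a fixed edge count the network can
only reveal a gained hub edge if that correlation crosses the inclusion
threshold, and the hub's gain is diluted if its own control-state edges sit
mid-band where inclusion noise is maximal; a singleton hub module keeps the
control hub stably below the band, and a large target set at the mouse
scale (small at the human scale, where precise correlations would otherwise
let the target-target side band dominate low densities) puts the stress hub
stably above it. The human demodularization is deeper (0.55) for the
complementary reason: with hundreds of subjects the sample correlations are
nearly exact, so the thresholded stress topology only loses modular
structure if the attenuated within-module band actually falls below the
strongest cross-module correlations — at 0.7 the within band still tops the
ranking everywhere and the modularity contrast vanishes.

## What the generator does and does not emulate

It emulates: two-group designs at the studies' sample sizes and ROI counts,
modular anatomical covariance with realistic correlation magnitudes, a
focal stress-induced hub gain against a global loss of modular structure,
volume increases in a small a-priori set coupled to a latent emotionality
trait, and multi-test behavioral batteries loading on that trait.

It does not emulate: non-Gaussian volume distributions, hemispheric or
spatial autocorrelation structure, heterogeneous module sizes or per-ROI
variances, measurement artifacts of segmentation pipelines, missing data,
or longitudinal behavior. Passing tests therefore demonstrate that the
pipeline recovers known effects from data with the assumed covariance
geometry — not that real acquisitions satisfy those assumptions.

## Numerical conventions and degenerate inputs

- Half-up rounding for edge counts; deterministic (−weight, i, j)
  tie-breaks; density grids built from integer step counts to avoid
  floating-point drift.
- Zero within-group variance in any ROI, non-PSD generator parameters,
  constant PC1 scores, zero control-group SDs, empty graphs, degenerate
  enrichment margins and double normalization are all hard errors naming
  the offender, never silently patched.
- Emotionality z-scores use the control group's mean and SD (control mean
  exactly 0; stress effects in control-SD units); PCA standardizes with the
  pooled mean/SD because both groups enter the decomposition as one sample,
  and component signs are oriented so the stress group's mean score is ≥
  the control group's.
- GLM association strength for ranking is the absolute t statistic of the
  group coefficient (scale-free); variance explained is the partial R² of
  the group term; BH adjustment is applied across all tested ROIs. With no
  covariates the GLM p equals the equal-variance two-sample t-test p to
  1e−10.
- The chi-square enrichment test uses no continuity correction.
- Pipeline manifests record configuration, seed and package version but no
  wall-clock timings, so a rerun from the same manifest is byte-identical.

## Problem sizes used by the test suite and acceptance script

The test suite runs the permutation machinery at n_perm = 200–1000 with
grids of 1–5 densities (500 null cohorts for calibration; 25 replicate
cohorts at the full mouse dimensions for effect recovery), and the
acceptance script reports both species' designs at n_perm = 500 on the
0.10–0.30 grid in steps of 0.05 plus a 200-cohort calibration. These sizes
keep a complete run in the tens of minutes on one core while leaving every
observed quantity identical to the full-resolution analysis; only the
granularity of the empirical p-values changes.

## Known limitations

- Betweenness and closeness inside permutation loops use the full
  shortest-path machinery per permutation and are orders of magnitude
  slower than degree/strength; permuting them at n_perm = 10,000 on 155
  ROIs is possible but slow.
- Louvain is a heuristic; Q values are lower bounds on the true maximum
  modularity. Restart counts trade accuracy for speed, and the package
  keeps the trade-off explicit via `modularity_runs`.
- The human preset residualizes on sex before correlation as a fixed
  choice; other covariate schemes are expressible through the pipeline
  configuration but not separately validated here.
- The empirical-p lower bound is 1/(n_perm+1); AUC p-values at small
  n_perm are correspondingly coarse.
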
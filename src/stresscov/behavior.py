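"""Behavioral emotionality integration: z-score summarization and PCA.

A multi-test battery is collapsed into one per-subject emotionality score by
z-scoring every variable against the control group, orienting each variable
so larger means more emotional, averaging within test and then across tests.
PCA on the pooled standardized battery extracts dimensions of behavioral
variance; component signs are oriented so the stress group scores at least
as high as the control group, making the first component read directly as an
emotionality axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .tables import BehaviorTable, CONTROL, STRESS

__all__ = ["EmotionalityResult", "PCAResult", "emotionality_zscore", "behavioral_pca"]


@dataclass
class EmotionalityResult:
    subject_id: list[str]
    group: list[str]
    per_subject_z: np.ndarray          # (n_subjects,)
    per_test_z: np.ndarray             # (n_subjects, n_tests)
    test_names: list[str]
    group_difference_p: float


@dataclass
class PCAResult:
    subject_id: list[str]
    group: list[str]
    scores: np.ndarray                 # (n_subjects, n_components)
    loadings: np.ndarray               # (n_variables, n_components)
    explained_variance_fraction: np.ndarray
    var_names: list[str]


def emotionality_zscore(b: BehaviorTable) -> EmotionalityResult:
    """Integrate a behavioral battery into one emotionality z-score per subject.

    Each variable is z-scored against the control group's mean and SD and
    sign-flipped where its direction metadata says lower values indicate
    more emotionality; scores are averaged within each test, then across
    tests.  The control-group mean of the result is 0 by construction and
    stress effects are expressed in control-SD units.  The group contrast is
    a two-sample t-test.
    """
    ctrl = b.group_mask(CONTROL)
    if not ctrl.any():
        raise ValueError("control group is empty")
    mu = b.values[ctrl].mean(axis=0)
    sd = b.values[ctrl].std(axis=0, ddof=1)
    bad = np.flatnonzero(~np.isfinite(sd) | (sd == 0))
    if bad.size:
        names = [b.var_names[i] for i in bad]
        raise ValueError(f"zero or undefined control-group SD for variable(s): {names}")
    z = (b.values - mu) / sd
    for j, name in enumerate(b.var_names):
        if b.var_meta[name][1] == "lower_is_more_emotional":
            z[:, j] = -z[:, j]

    tests = b.tests
    per_test = np.empty((b.n_subjects, len(tests)))
    for k, t in enumerate(tests):
        cols = [j for j, v in enumerate(b.var_names) if b.var_meta[v][0] == t]
        per_test[:, k] = z[:, cols].mean(axis=1)
    per_subject = per_test.mean(axis=1)

    strs = b.group_mask(STRESS)
    if strs.any() and ctrl.sum() > 1 and strs.sum() > 1:
        p = float(stats.ttest_ind(per_subject[strs], per_subject[ctrl]).pvalue)
    else:
        p = float("nan")
    return EmotionalityResult(
        subject_id=list(b.subject_id),
        group=list(b.group),
        per_subject_z=per_subject,
        per_test_z=per_test,
        test_names=tests,
        group_difference_p=p,
    )


def behavioral_pca(b: BehaviorTable, n_components: int) -> PCAResult:
    """PCA of the standardized battery, oriented toward the stress group.

    Variables are standardized with the pooled (all-subject) mean and SD
    before decomposition, since both groups enter the analysis as one
    sample.  Each component's sign is chosen so the stress-group mean score
    is >= the control-group mean; with a genuine stress dimension in the
    data, the first component then indexes emotionality.
    """
    n, p = b.values.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 subjects and 2 variables")
    if not np.all(np.isfinite(b.values)):
        raise ValueError("behavior table contains missing or non-finite values")
    max_comp = min(n - 1, p)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(n_subjects-1, n_vars)={max_comp}")

    mu = b.values.mean(axis=0)
    sd = b.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [b.var_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant variable(s) cannot be standardized: {bad}")
    x = (b.values - mu) / sd

    pca = PCA(n_components=max_comp, svd_solver="full")
    scores_full = pca.fit_transform(x)
    loadings_full = pca.components_.T  # orthonormal: scores @ loadings.T == x

    ctrl = b.group_mask(CONTROL)
    strs = b.group_mask(STRESS)
    if ctrl.any() and strs.any():
        flip = scores_full[strs].mean(axis=0) < scores_full[ctrl].mean(axis=0)
        scores_full[:, flip] *= -1
        loadings_full[:, flip] *= -1

    evf = pca.explained_variance_ratio_
    return PCAResult(
        subject_id=list(b.subject_id),
        group=list(b.group),
        scores=scores_full[:, :n_components],
        loadings=loadings_full[:, :n_components],
        explained_variance_fraction=evf[:n_components],
        var_names=list(b.var_names),
    )
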
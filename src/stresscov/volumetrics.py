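"""Per-ROI volumetric group statistics.

Group comparisons use an ordinary least-squares model per ROI
(``volume ~ group [+ covariates]``) with Benjamini–Hochberg control of the
false discovery rate across ROIs; with no covariates this reduces exactly to
the equal-variance two-sample t-test.  Association strength for ranking is
the absolute t statistic of the group coefficient.  Volume–behavior coupling
is a simple per-ROI regression on the behavioral first principal component
across all subjects pooled.  Enrichment of an a-priori ROI set among the
top-ranked effects is a 2x2 chi-square test without continuity correction.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .tables import VolumeTable, CONTROL, STRESS

__all__ = [
    "normalize_volumes",
    "roi_group_glm",
    "volume_behavior_regression",
    "apriori_enrichment",
    "total_brain_volume_test",
]


def normalize_volumes(v: VolumeTable, mode: str = "none") -> VolumeTable:
    """Optionally express each ROI volume as a fraction of total brain volume.

    ``mode="divide_by_total"`` requires a positive ``total_brain_volume``
    covariate for every subject and may be applied only once per table.
    """
    if mode == "none":
        return v
    if mode != "divide_by_total":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if v.normalized:
        raise ValueError("volumes are already normalized; refusing to divide twice")
    if "total_brain_volume" not in v.covariates:
        raise ValueError("divide_by_total requires a total_brain_volume covariate")
    total = v.covariates["total_brain_volume"]
    bad = np.flatnonzero(~np.isfinite(total) | (total <= 0))
    if bad.size:
        raise ValueError(
            f"nonpositive or missing total_brain_volume for subject(s): "
            f"{[v.subject_id[i] for i in bad]}"
        )
    out = replace(
        v,
        volumes=v.volumes / total[:, None],
        covariates={k: c.copy() for k, c in v.covariates.items()},
        normalized=True,
    )
    return out


def _design_matrix(v: VolumeTable, covariates: list[str]) -> np.ndarray:
    group = v.group_mask(STRESS).astype(float)
    cols = [np.ones(v.n_subjects), group]
    for name in covariates:
        if name not in v.covariates:
            raise ValueError(f"covariate {name!r} missing from table")
        cols.append(v.covariates[name])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (collinear covariates: {covariates})")
    return X


def roi_group_glm(v: VolumeTable, covariates: list[str] | None = None) -> pd.DataFrame:
    """Per-ROI linear model of volume on group (stress vs control) + covariates.

    Returns a DataFrame indexed by ROI label with columns ``effect_size``
    (group coefficient, stress minus control, in the table's volume units),
    ``t`` (its t statistic), ``variance_explained`` (partial R^2 of the
    group term), ``p``, ``q`` (BH-adjusted) and ``rank`` (1 = strongest
    association by |t|).
    """
    covariates = list(covariates or [])
    n_c = v.group_mask(CONTROL).sum()
    n_s = v.group_mask(STRESS).sum()
    if min(n_c, n_s) < 3:
        raise ValueError("each group needs at least 3 subjects")
    X = _design_matrix(v, covariates)
    rows = []
    df_resid = v.n_subjects - X.shape[1]
    for j, label in enumerate(v.roi_labels):
        fit = sm.OLS(v.volumes[:, j], X).fit()
        t = float(fit.tvalues[1])
        rows.append(
            {
                "roi": label,
                "effect_size": float(fit.params[1]),
                "t": t,
                "variance_explained": t**2 / (t**2 + df_resid),
                "p": float(fit.pvalues[1]),
            }
        )
    out = pd.DataFrame(rows).set_index("roi")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    order = np.argsort(-np.abs(out["t"].to_numpy()), kind="stable")
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out


def volume_behavior_regression(v: VolumeTable, pc1: np.ndarray) -> pd.DataFrame:
    """Per-ROI simple regression of volume on the behavioral PC1 score.

    Both groups are pooled, mirroring the dimensional read of the first
    behavioral component.  Returns r_squared and p per ROI.
    """
    pc1 = np.asarray(pc1, dtype=float)
    if pc1.shape != (v.n_subjects,):
        raise ValueError("PC1 scores do not align with the volume table's subjects")
    if np.ptp(pc1) == 0:
        raise ValueError("PC1 scores are constant; regression is undefined")
    rows = []
    for j, label in enumerate(v.roi_labels):
        fit = stats.linregress(pc1, v.volumes[:, j])
        rows.append({"roi": label, "r_squared": fit.rvalue**2, "p": fit.pvalue})
    return pd.DataFrame(rows).set_index("roi")


def apriori_enrichment(
    stats_table: pd.DataFrame, apriori_set: list[str], top_k: int
) -> tuple[float, float]:
    """Chi-square test for overrepresentation of a-priori ROIs among the top-k.

    Builds the 2x2 table of (in/out a-priori set) x (in/out the ``top_k``
    strongest associations by rank) and applies the chi-square test without
    continuity correction.
    """
    n_roi = len(stats_table)
    if not 0 < top_k < n_roi:
        raise ValueError("top_k must be positive and smaller than the number of ROIs")
    labels = set(stats_table.index)
    apriori = set(apriori_set)
    if not apriori:
        raise ValueError("a-priori ROI set is empty")
    unknown = apriori - labels
    if unknown:
        raise ValueError(f"a-priori ROIs not in the stats table: {sorted(unknown)}")
    if len(apriori) >= n_roi:
        raise ValueError("a-priori set covers every ROI; margins are degenerate")
    top = set(stats_table.index[stats_table["rank"] <= top_k])
    a = len(apriori & top)
    b = len(apriori - top)
    c = len(top - apriori)
    d = n_roi - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def total_brain_volume_test(v: VolumeTable) -> float:
    """Two-sample t-test p-value for a group difference in total brain volume.

    Uses the ``total_brain_volume`` covariate when present, otherwise the
    per-subject sum of ROI volumes.
    """
    total = v.covariates.get("total_brain_volume")
    if total is None:
        total = v.volumes.sum(axis=1)
    ctrl = v.group_mask(CONTROL)
    strs = v.group_mask(STRESS)
    if ctrl.sum() < 2 or strs.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    return float(stats.ttest_ind(total[strs], total[ctrl]).pvalue)
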
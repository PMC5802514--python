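"""Permutation inference on group differences in network metrics.

Because a structural covariance network is a group-level object, the only
exchangeable unit is the subject's group label: each permutation reshuffles
labels over the pooled subjects (preserving group sizes), rebuilds both
groups' correlation matrices, re-thresholds at every density on the grid,
and recomputes the metric difference (stress minus control).  Empirical
two-tailed p-values use the +1-corrected formula

    p = (#{ |null| >= |observed| } + 1) / (n_perm + 1),

which is never exactly zero.  One shared permutation schedule is used
across all densities and all metrics within a run, so the area-under-curve
aggregation across the density grid has a coherent null of its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import (
    mean_clustering,
    modularity_louvain,
    path_length,
    transitivity,
)
from .networks import DensityGrid, build_covariance, discard_negatives
from .tables import VolumeTable, CONTROL, STRESS

__all__ = [
    "PermutationResult",
    "permute_metric",
    "permute_metrics",
    "node_significance_profile",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = ("transitivity", "clustering_coefficient", "modularity", "path_length")
NODAL_METRIC_NAMES = ("degree", "strength", "betweenness", "closeness")


@dataclass
class PermutationResult:
    metric_name: str
    node: str | None
    densities: np.ndarray
    observed_diff: np.ndarray      # (n_density,) stress - control
    null_diffs: np.ndarray         # (n_perm, n_density)
    p_per_density: np.ndarray
    auc_observed: float
    auc_p: float
    n_perm: int

    def key(self) -> str:
        return self.metric_name if self.node is None else f"{self.metric_name}[{self.node}]"


def _empirical_p(observed: float, null: np.ndarray) -> float:
    return (np.sum(np.abs(null) >= abs(observed)) + 1) / (null.size + 1)


def _metric_requests(metrics, node: str | None):
    """Normalize the metric request list to (name, node) pairs."""
    out = []
    for m in metrics:
        if isinstance(m, tuple):
            name, nd = m
        else:
            name, nd = m, None
        if name in GLOBAL_METRIC_NAMES:
            out.append((name, None))
        elif name in NODAL_METRIC_NAMES:
            nd = nd if nd is not None else node
            if nd is None:
                raise ValueError(f"nodal metric {name!r} requires a node label")
            out.append((name, nd))
        else:
            raise ValueError(
                f"unknown metric {name!r}; expected one of "
                f"{GLOBAL_METRIC_NAMES + NODAL_METRIC_NAMES}"
            )
    return out


def _node_value(w: np.ndarray, name: str, idx: int) -> float:
    if name == "degree":
        return float((w[idx] > 0).sum())
    if name == "strength":
        return float(w[idx].sum())
    # betweenness / closeness need the full shortest-path machinery
    from .metrics import _betweenness_closeness

    bc, cc = _betweenness_closeness(w)
    return float(bc[idx]) if name == "betweenness" else float(cc[idx])


def _evaluate(
    w: np.ndarray,
    requests: list[tuple[str, str | None]],
    label_index: dict[str, int],
    mod_rng: np.random.Generator,
    modularity_runs: int,
) -> list[float]:
    vals: list[float] = []
    slow: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, nd in requests:
        if name == "transitivity":
            vals.append(transitivity(w))
        elif name == "clustering_coefficient":
            vals.append(mean_clustering(w))
        elif name == "modularity":
            q, _ = modularity_louvain(w, runs=modularity_runs, seed=mod_rng)
            vals.append(q)
        elif name == "path_length":
            vals.append(path_length(w)[0])
        elif name in ("degree", "strength"):
            vals.append(_node_value(w, name, label_index[nd]))
        else:  # betweenness / closeness: compute once per matrix
            if "bc" not in slow:
                from .metrics import _betweenness_closeness

                slow["bc"] = _betweenness_closeness(w)
            bc, cc = slow["bc"]
            idx = label_index[nd]
            vals.append(float(bc[idx]) if name == "betweenness" else float(cc[idx]))
    return vals


def _group_diffs(
    volumes: np.ndarray,
    stress_mask: np.ndarray,
    densities: np.ndarray,
    requests,
    label_index,
    mod_rng,
    modularity_runs: int,
) -> np.ndarray:
    """(n_metrics, n_density) stress-minus-control metric differences for one
    labelling of the pooled subjects."""
    n = volumes.shape[1]
    iu, ju = np.triu_indices(n, 1)
    m = iu.size
    per_group: dict[bool, np.ndarray] = {}
    out = np.empty((len(requests), densities.size))
    # control first, then stress, so RNG consumption order is fixed
    for stressed in (False, True):
        x = volumes[stress_mask == stressed]
        c = np.corrcoef(x, rowvar=False)
        c = np.where(c > 0, c, 0.0)
        np.fill_diagonal(c, 0.0)
        wvec = c[iu, ju]
        order = np.argsort(-wvec, kind="stable")
        vals = np.empty((len(requests), densities.size))
        for di, d in enumerate(densities):
            k = int(np.floor(d * m + 0.5))
            if int(np.count_nonzero(wvec > 0)) < k:
                raise ValueError(
                    f"not enough positive correlations to reach density {d}"
                )
            top = order[:k]
            w = np.zeros((n, n))
            w[iu[top], ju[top]] = wvec[top]
            w += w.T
            vals[:, di] = _evaluate(w, requests, label_index, mod_rng, modularity_runs)
        per_group[stressed] = vals
    out = per_group[True] - per_group[False]
    return out


def permute_metrics(
    v: VolumeTable,
    grid: DensityGrid,
    metrics,
    n_perm: int = 10_000,
    seed: int = 0,
    node: str | None = None,
    roi_exclude: list[str] | None = None,
    modularity_runs: int = 5,
) -> dict[str, PermutationResult]:
    """Permutation test for several metrics under one shared schedule.

    ``metrics`` is a list of metric names or ``(name, node_label)`` pairs;
    the ``node`` argument supplies a default node for nodal metrics.  The
    same label shuffles are reused for every metric and density, and both
    groups' networks are rebuilt from scratch for every permutation.
    Fully reproducible under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    requests = _metric_requests(metrics, node)
    # validate once: build per-group correlation with the real labels
    _c, labels = build_covariance(v, CONTROL, roi_exclude)
    _s, _ = build_covariance(v, STRESS, roi_exclude)
    discard_negatives(_c)
    label_index = {lab: i for i, lab in enumerate(labels)}
    for _, nd in requests:
        if nd is not None and nd not in label_index:
            raise ValueError(f"unknown node label {nd!r}")

    keep = [i for i, lab in enumerate(v.roi_labels) if lab in label_index]
    volumes = v.volumes[:, keep]
    stress_mask = v.group_mask(STRESS)
    densities = np.asarray(list(grid), dtype=float)

    ss = np.random.SeedSequence(seed)
    perm_seed, mod_seed = ss.spawn(2)
    perm_rng = np.random.default_rng(perm_seed)
    mod_rng = np.random.default_rng(mod_seed)

    observed = _group_diffs(
        volumes, stress_mask, densities, requests, label_index, mod_rng, modularity_runs
    )
    null = np.empty((n_perm, len(requests), densities.size))
    for p in range(n_perm):
        shuffled = perm_rng.permutation(stress_mask)
        null[p] = _group_diffs(
            volumes, shuffled, densities, requests, label_index, mod_rng, modularity_runs
        )

    results: dict[str, PermutationResult] = {}
    for mi, (name, nd) in enumerate(requests):
        obs = observed[mi]
        nulls = null[:, mi, :]
        p_per_density = np.array(
            [_empirical_p(obs[di], nulls[:, di]) for di in range(densities.size)]
        )
        if densities.size > 1:
            auc_obs = float(np.trapezoid(obs, densities))
            auc_null = np.trapezoid(nulls, densities, axis=1)
        else:
            auc_obs = float(obs[0])
            auc_null = nulls[:, 0]
        res = PermutationResult(
            metric_name=name,
            node=nd,
            densities=densities.copy(),
            observed_diff=obs.copy(),
            null_diffs=nulls.copy(),
            p_per_density=p_per_density,
            auc_observed=auc_obs,
            auc_p=_empirical_p(auc_obs, auc_null),
            n_perm=n_perm,
        )
        results[res.key()] = res
    return results


def permute_metric(
    v: VolumeTable,
    grid: DensityGrid,
    metric: str,
    n_perm: int = 10_000,
    seed: int = 0,
    node: str | None = None,
    roi_exclude: list[str] | None = None,
    modularity_runs: int = 5,
) -> PermutationResult:
    """Single-metric convenience wrapper around :func:`permute_metrics`."""
    results = permute_metrics(
        v,
        grid,
        [metric],
        n_perm=n_perm,
        seed=seed,
        node=node,
        roi_exclude=roi_exclude,
        modularity_runs=modularity_runs,
    )
    return next(iter(results.values()))


def node_significance_profile(
    results: dict[str, PermutationResult],
    alpha: float = 0.05,
    min_consecutive: int = 2,
) -> dict[str, bool]:
    """Flag results significant at ``alpha`` for a run of consecutive densities.

    A node/metric is flagged when its per-density p-value drops below
    ``alpha`` at at least ``min_consecutive`` consecutive grid densities —
    the a-priori criterion used for nodal hubness claims.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    flags: dict[str, bool] = {}
    for key, res in results.items():
        sig = res.p_per_density < alpha
        run = best = 0
        for s in sig:
            run = run + 1 if s else 0
            best = max(best, run)
        flags[key] = best >= min_consecutive
    return flags
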
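"""Group-level structural covariance networks.

A structural covariance network is built per group: Pearson correlation of
every ROI pair across that group's subjects, negative correlations removed,
and the result thresholded so that exactly the top ``d`` fraction of the
strongest possible edges survive, for each density ``d`` on a grid.  Equal
edge counts across groups make the group comparison a comparison of
topology, not of overall correlation level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .tables import VolumeTable

__all__ = [
    "CovarianceNetwork",
    "DensityGrid",
    "build_covariance",
    "discard_negatives",
    "threshold_by_density",
    "density_grid",
    "max_density",
]


@dataclass
class CovarianceNetwork:
    """Symmetric nonnegative weighted graph at one density threshold."""

    group: str
    roi_labels: list[str]
    weights: np.ndarray
    density: float
    retained_edges: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.roi_labels)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape does not match roi_labels")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_roi(self) -> int:
        return len(self.roi_labels)

    def degree(self) -> np.ndarray:
        """Binary degree: number of incident (strictly positive) edges."""
        return (self.weights > 0).sum(axis=1)

    def neighbors(self, label: str) -> set[str]:
        i = self.roi_labels.index(label) if label in self.roi_labels else None
        if i is None:
            raise KeyError(f"unknown ROI label {label!r}")
        return {self.roi_labels[j] for j in np.flatnonzero(self.weights[i] > 0)}


@dataclass
class DensityGrid:
    densities: list[float]

    def __post_init__(self) -> None:
        d = list(self.densities)
        if not d:
            raise ValueError("density grid is empty")
        if any(not 0 < x < 1 for x in d):
            raise ValueError("densities must lie strictly between 0 and 1")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be strictly increasing")
        self.densities = d

    def __iter__(self):
        return iter(self.densities)

    def __len__(self):
        return len(self.densities)


def density_grid(lo: float = 0.10, hi: float = 0.30, step: float = 0.01) -> DensityGrid:
    """Evenly spaced density grid; the default covers the top 10–30% of
    connections in 1% increments (21 densities)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0 < lo <= hi < 1:
        raise ValueError(f"need 0 < lo <= hi < 1, got lo={lo}, hi={hi}")
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return DensityGrid([round(lo + i * step, 10) for i in range(n)])


def build_covariance(
    v: VolumeTable, group: str, roi_exclude: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Full Pearson correlation matrix across one group's subjects.

    Returns the symmetric unit-diagonal correlation matrix together with the
    retained ROI labels (after exclusions, e.g. ventricles).
    """
    roi_exclude = list(roi_exclude or [])
    unknown = set(roi_exclude) - set(v.roi_labels)
    if unknown:
        raise ValueError(f"excluded ROIs not in table: {sorted(unknown)}")
    keep = [i for i, lab in enumerate(v.roi_labels) if lab not in roi_exclude]
    labels = [v.roi_labels[i] for i in keep]
    mask = v.group_mask(group)
    if mask.sum() < 4:
        raise ValueError(f"group {group!r} needs at least 4 subjects for covariance")
    x = v.volumes[np.ix_(mask, keep)]
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero within-group variance for ROI(s): {[labels[i] for i in flat]}"
        )
    c = np.corrcoef(x, rowvar=False)
    return c, labels


def discard_negatives(c: np.ndarray) -> np.ndarray:
    """Zero out negative correlations and the diagonal.

    Discarded entries become structural zeros (absent edges).  Emits a
    warning if nothing survives.
    """
    c = np.asarray(c, dtype=float)
    if not np.allclose(c, c.T):
        raise ValueError("correlation matrix must be symmetric")
    out = np.where(c > 0, c, 0.0)
    np.fill_diagonal(out, 0.0)
    if not np.any(out > 0):
        warnings.warn("all correlations are nonpositive; the graph is empty", stacklevel=2)
    return out


def _edge_count(n: int, d: float) -> int:
    m = n * (n - 1) // 2
    return int(math.floor(d * m + 0.5))  # half-up rounding


def max_density(c: np.ndarray) -> float:
    """Largest achievable density given the number of positive entries."""
    n = c.shape[0]
    m = n * (n - 1) // 2
    pos = int(np.count_nonzero(np.triu(c, 1) > 0))
    return pos / m


def threshold_by_density(
    c: np.ndarray,
    d: float,
    group: str = "control",
    roi_labels: list[str] | None = None,
) -> CovarianceNetwork:
    """Keep exactly the top ``round(d * M)`` strongest edges, M = n(n-1)/2.

    Surviving edges retain their correlation values as weights.  Ties at the
    cutoff are broken deterministically by (-weight, i, j) lexicographic
    order, which makes edge sets nested across increasing densities.
    """
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    if roi_labels is None:
        roi_labels = [f"roi_{i:03d}" for i in range(n)]
    if not 0 < d < 1:
        raise ValueError("density must lie strictly between 0 and 1")
    if np.any(c < 0):
        raise ValueError("thresholding expects a nonnegative matrix (discard negatives first)")
    k = _edge_count(n, d)
    iu, ju = np.triu_indices(n, 1)
    w = c[iu, ju]
    pos = int(np.count_nonzero(w > 0))
    if pos < k:
        raise ValueError(
            f"only {pos} positive edges available; requested density {d} needs {k} "
            f"(maximum achievable density {max_density(c):.4f})"
        )
    # lexicographic (-weight, i, j): stable sort on (i, j) order then by -weight
    order = np.argsort(-w, kind="stable")[:k]
    out = np.zeros_like(c)
    out[iu[order], ju[order]] = w[order]
    out += out.T
    return CovarianceNetwork(
        group=group,
        roi_labels=list(roi_labels),
        weights=out,
        density=float(d),
        retained_edges=k,
    )
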
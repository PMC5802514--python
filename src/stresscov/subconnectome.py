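"""Focal-node neighborhood comparison across groups.

Characterizes how one ROI's direct structural-covariance neighborhood
changes under stress at a matched density: its degree rank in each group's
network, and the partition of its neighbors into those common to both
groups, those gained under stress, and those lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import degree_ranks
from .networks import CovarianceNetwork

__all__ = ["NeighborhoodComparison", "compare_neighborhood"]


@dataclass
class NeighborhoodComparison:
    node: str
    density: float
    rank_control: int
    rank_stress: int
    common_neighbors: set[str]
    stress_only: set[str]
    control_only: set[str]


def compare_neighborhood(
    gc: CovarianceNetwork, gs: CovarianceNetwork, node: str
) -> NeighborhoodComparison:
    """Compare ``node``'s neighborhood between a control and a stress network.

    Both networks must share ROI labels and density.  Degree ranks are
    computed within each group's own network (1 = highest degree; ties share
    the minimum rank).
    """
    if gc.roi_labels != gs.roi_labels:
        raise ValueError("networks must share identical ROI labels")
    if gc.density != gs.density:
        raise ValueError(
            f"networks must share a density (got {gc.density} vs {gs.density})"
        )
    if node not in gc.roi_labels:
        raise KeyError(f"unknown node label {node!r}")
    idx = gc.roi_labels.index(node)
    nc = gc.neighbors(node)
    ns = gs.neighbors(node)
    rank_c = int(degree_ranks(gc.degree())[idx])
    rank_s = int(degree_ranks(gs.degree())[idx])
    return NeighborhoodComparison(
        node=node,
        density=gc.density,
        rank_control=rank_c,
        rank_stress=rank_s,
        common_neighbors=nc & ns,
        stress_only=ns - nc,
        control_only=nc - ns,
    )
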
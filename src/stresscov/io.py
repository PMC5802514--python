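"""CSV/JSON readers and writers for tables, networks and results.

Interchange is deliberately plain: tidy CSV for tables (one row per
subject), a JSON sidecar holding ROI labels, variable metadata and the
generating cohort spec when there is one, CSV edge lists, and GraphML for
external network visualization.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .networks import CovarianceNetwork
from .subconnectome import NeighborhoodComparison
from .tables import BehaviorTable, VolumeTable

__all__ = [
    "write_volume_table",
    "read_volume_table",
    "write_behavior_table",
    "read_behavior_table",
    "write_edge_list",
    "write_graphml_bundle",
]

KNOWN_COVARIATES = ("sex", "total_brain_volume")


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def _check_header(path: Path) -> list[str]:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicated column(s) in {path}: {dupes}")
    return header


def write_volume_table(v: VolumeTable, path: str | Path, spec: dict | None = None) -> None:
    path = Path(path)
    v.to_frame().to_csv(path, index=False)
    meta = {
        "table": "volume",
        "roi_labels": v.roi_labels,
        "covariates": list(v.covariates),
        "normalized": v.normalized,
    }
    if spec is not None:
        meta["cohort_spec"] = spec
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_volume_table(path: str | Path) -> VolumeTable:
    path = Path(path)
    header = _check_header(path)
    if "subject_id" not in header or "group" not in header:
        raise ValueError(f"{path}: need subject_id and group columns")
    df = pd.read_csv(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        roi_labels = meta["roi_labels"]
        cov_names = meta.get("covariates", [])
        normalized = bool(meta.get("normalized", False))
        missing = [c for c in roi_labels + cov_names if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: columns named in sidecar are missing: {missing}")
    else:
        cov_names = [c for c in df.columns if c in KNOWN_COVARIATES]
        roi_labels = [
            c for c in df.columns if c not in ("subject_id", "group") and c not in cov_names
        ]
        normalized = False
    vols = df[roi_labels]
    non_numeric = [c for c in roi_labels if not np.issubdtype(vols[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric volume column(s): {non_numeric}")
    return VolumeTable(
        subject_id=df["subject_id"].astype(str).tolist(),
        group=df["group"].tolist(),
        volumes=vols.to_numpy(dtype=float),
        roi_labels=list(roi_labels),
        covariates={c: df[c].to_numpy(dtype=float) for c in cov_names},
        normalized=normalized,
    )


def write_behavior_table(b: BehaviorTable, path: str | Path, spec: dict | None = None) -> None:
    path = Path(path)
    b.to_frame().to_csv(path, index=False)
    meta = {
        "table": "behavior",
        "var_meta": {v: {"test": t, "direction": d} for v, (t, d) in b.var_meta.items()},
    }
    if spec is not None:
        meta["cohort_spec"] = spec
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_behavior_table(path: str | Path) -> BehaviorTable:
    path = Path(path)
    _check_header(path)
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: need subject_id and group columns")
    var_names = [c for c in df.columns if c not in ("subject_id", "group")]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())["var_meta"]
        var_meta = {v: (m["test"], m["direction"]) for v, m in raw.items()}
    else:
        # without metadata every variable stands alone and is assumed to
        # increase with emotionality
        var_meta = {v: (v, "higher_is_more_emotional") for v in var_names}
    return BehaviorTable(
        subject_id=df["subject_id"].astype(str).tolist(),
        group=df["group"].tolist(),
        values=df[var_names].to_numpy(dtype=float),
        var_names=var_names,
        var_meta=var_meta,
    )


def write_edge_list(net: CovarianceNetwork, path: str | Path) -> None:
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    df = pd.DataFrame(
        {
            "i_label": [net.roi_labels[i] for i in iu],
            "j_label": [net.roi_labels[j] for j in ju],
            "weight": net.weights[iu, ju],
        }
    )
    df.to_csv(path, index=False)


def _to_nx(net: CovarianceNetwork) -> nx.Graph:
    g = nx.Graph(group=net.group, density=net.density)
    g.add_nodes_from(net.roi_labels)
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    for i, j in zip(iu, ju):
        g.add_edge(net.roi_labels[i], net.roi_labels[j], weight=float(net.weights[i, j]))
    return g


def write_graphml_bundle(
    gc: CovarianceNetwork,
    gs: CovarianceNetwork,
    comparison: NeighborhoodComparison,
    path_control: str | Path,
    path_stress: str | Path,
) -> None:
    """Export both networks as GraphML with each focal edge tagged
    ``common``, ``stress_only`` or ``control_only``."""
    node = comparison.node
    for net, out in ((gc, path_control), (gs, path_stress)):
        g = _to_nx(net)
        for u, v in g.edges:
            other = v if u == node else u if v == node else None
            if other is None:
                continue
            if other in comparison.common_neighbors:
                tag = "common"
            elif other in comparison.stress_only:
                tag = "stress_only"
            else:
                tag = "control_only"
            g.edges[u, v]["focal_edge"] = tag
        nx.write_graphml(g, out)
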
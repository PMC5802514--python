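"""End-to-end pipeline driver.

Sequences the full analysis on a volume table (and optionally a behavior
table): emotionality scoring and PCA, per-ROI volumetrics with FDR,
structural covariance network construction per group across the density
grid, permutation inference on global and focal nodal metrics, and the
focal node's subconnectome comparison.  Species presets fix the defaults
each design uses: the mouse (UCMS) preset correlates raw volumes and fits
the group-only model; the human (childhood-trauma) preset divides by total
brain volume, uses sex as a model covariate, and residualizes on sex before
correlation.

The run writes tidy CSV outputs plus a JSON manifest (configuration, seed,
package version); a rerun from the same manifest reproduces every output
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import behavioral_pca, emotionality_zscore
from .io import (
    read_behavior_table,
    read_volume_table,
    write_edge_list,
    write_graphml_bundle,
)
from .networks import build_covariance, density_grid, discard_negatives, threshold_by_density
from .permutation import (
    GLOBAL_METRIC_NAMES,
    node_significance_profile,
    permute_metrics,
)
from .subconnectome import compare_neighborhood
from .tables import CONTROL, STRESS, VolumeTable
from .volumetrics import (
    apriori_enrichment,
    normalize_volumes,
    roi_group_glm,
    total_brain_volume_test,
    volume_behavior_regression,
)

__all__ = ["PipelineConfig", "run_pipeline", "residualize_volumes"]

log = logging.getLogger("stresscov")

PRESETS = {
    "mouse": {"normalization": "none", "glm_covariates": [], "residualize_on": []},
    "human": {
        "normalization": "divide_by_total",
        "glm_covariates": ["sex"],
        "residualize_on": ["sex"],
    },
    "custom": {},
}


@dataclass
class PipelineConfig:
    volumes_path: str
    output_dir: str
    behavior_path: str | None = None
    species_preset: str = "custom"
    normalization: str = "none"
    glm_covariates: list[str] = field(default_factory=list)
    residualize_on: list[str] = field(default_factory=list)
    roi_exclude: list[str] = field(default_factory=list)
    apriori_rois: list[str] = field(default_factory=list)
    top_k: int = 20
    density_lo: float = 0.10
    density_hi: float = 0.30
    density_step: float = 0.01
    metrics: list[str] = field(default_factory=lambda: list(GLOBAL_METRIC_NAMES))
    focal_nodes: list[str] = field(default_factory=list)
    nodal_metrics: list[str] = field(default_factory=lambda: ["degree", "strength"])
    n_perm: int = 10_000
    modularity_runs: int = 5
    pca_components: int = 3
    alpha: float = 0.05
    min_consecutive: int = 2
    report_density: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_preset not in PRESETS:
            raise ValueError(f"unknown species_preset {self.species_preset!r}")
        for key, val in PRESETS[self.species_preset].items():
            setattr(self, key, list(val) if isinstance(val, list) else val)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.volumes_path).exists():
            raise FileNotFoundError(f"volumes file not found: {self.volumes_path}")
        if self.behavior_path and not Path(self.behavior_path).exists():
            raise FileNotFoundError(f"behavior file not found: {self.behavior_path}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def residualize_volumes(v: VolumeTable, covariates: list[str]) -> VolumeTable:
    """Replace each ROI volume by its residual against the given covariates,
    with the ROI mean added back so values stay positive."""
    if not covariates:
        return v
    cols = [np.ones(v.n_subjects)]
    for name in covariates:
        if name not in v.covariates:
            raise ValueError(f"covariate {name!r} missing from table")
        cols.append(v.covariates[name])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, v.volumes, rcond=None)
    resid = v.volumes - X @ beta + v.volumes.mean(axis=0)
    if np.any(resid <= 0):
        raise ValueError("residualized volumes are not strictly positive")
    return dataclasses.replace(
        v, volumes=resid, covariates={k: c.copy() for k, c in v.covariates.items()}
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle to ``cfg.output_dir``."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "stages": {},
    }

    volumes = read_volume_table(cfg.volumes_path)
    behavior = read_behavior_table(cfg.behavior_path) if cfg.behavior_path else None

    # -- behavior scoring ---------------------------------------------------
    pc1 = None
    if behavior is not None:
        t = time.time()
        emo = emotionality_zscore(behavior)
        pca = behavioral_pca(behavior, n_components=cfg.pca_components)
        pc1 = pca.scores[:, 0]
        pd.DataFrame(
            {
                "subject_id": emo.subject_id,
                "group": emo.group,
                "emotionality_z": emo.per_subject_z,
                **{f"PC{i + 1}": pca.scores[:, i] for i in range(pca.scores.shape[1])},
            }
        ).to_csv(out / "behavior_scores.csv", index=False)
        pd.DataFrame(
            pca.loadings,
            index=pca.var_names,
            columns=[f"PC{i + 1}" for i in range(pca.loadings.shape[1])],
        ).to_csv(out / "pca_loadings.csv", index_label="variable")
        summary["stages"]["behavior"] = {
            "emotionality_group_p": emo.group_difference_p,
            "explained_variance_fraction": pca.explained_variance_fraction.tolist(),
        }
        log.info("behavior scoring done in %.2fs (p=%.3g)", time.time() - t, emo.group_difference_p)

    # -- volumetrics --------------------------------------------------------
    t = time.time()
    vnorm = normalize_volumes(volumes, cfg.normalization)
    stats = roi_group_glm(vnorm, cfg.glm_covariates)
    stats.to_csv(out / "roi_stats.csv")
    vol_stage: dict = {
        "n_fdr_significant": int((stats["q"] < 0.05).sum()),
        "total_brain_volume_p": total_brain_volume_test(volumes),
    }
    if pc1 is not None:
        reg = volume_behavior_regression(vnorm, pc1)
        reg.to_csv(out / "volume_pc1_regression.csv")
    if cfg.apriori_rois:
        chi2, p = apriori_enrichment(stats, cfg.apriori_rois, cfg.top_k)
        vol_stage["apriori_enrichment"] = {"chi2": chi2, "p": p, "top_k": cfg.top_k}
    summary["stages"]["volumetrics"] = vol_stage
    log.info("volumetrics done in %.2fs", time.time() - t)

    # -- networks -----------------------------------------------------------
    t = time.time()
    vnet = residualize_volumes(vnorm, cfg.residualize_on)
    grid = density_grid(cfg.density_lo, cfg.density_hi, cfg.density_step)
    corr: dict[str, np.ndarray] = {}
    labels: list[str] = []
    for grp in (CONTROL, STRESS):
        c, labels = build_covariance(vnet, grp, cfg.roi_exclude)
        corr[grp] = c
        pd.DataFrame(c, index=labels, columns=labels).to_csv(out / f"correlation_{grp}.csv")
    summary["stages"]["networks"] = {
        "n_roi": len(labels),
        "densities": list(grid),
    }
    log.info("networks built in %.2fs", time.time() - t)

    # -- permutation inference ---------------------------------------------
    t = time.time()
    requests: list = list(cfg.metrics)
    for node in cfg.focal_nodes:
        requests += [(m, node) for m in cfg.nodal_metrics]
    results = permute_metrics(
        vnet,
        grid,
        requests,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        roi_exclude=cfg.roi_exclude,
        modularity_runs=cfg.modularity_runs,
    )
    for key, res in results.items():
        pd.DataFrame(
            {
                "density": res.densities,
                "observed_diff": res.observed_diff,
                "p": res.p_per_density,
            }
        ).to_csv(out / f"permutation_{key.replace('[', '_').rstrip(']')}.csv", index=False)
    flags = node_significance_profile(
        results, alpha=cfg.alpha, min_consecutive=cfg.min_consecutive
    )
    summary["stages"]["permutation"] = {
        "n_perm": cfg.n_perm,
        "auc_p": {k: r.auc_p for k, r in results.items()},
        "flagged": flags,
    }
    log.info("permutation inference done in %.2fs", time.time() - t)

    # -- subconnectome ------------------------------------------------------
    if cfg.focal_nodes:
        t = time.time()
        report_d = cfg.report_density
        if report_d is None:
            # lowest density at which any focal nodal difference is significant
            nodal_keys = [k for k in results if "[" in k]
            report_d = None
            for di, d in enumerate(grid):
                if any(results[k].p_per_density[di] < cfg.alpha for k in nodal_keys):
                    report_d = float(d)
                    break
            if report_d is None:
                report_d = float(list(grid)[len(grid) // 2])
        nets = {
            grp: threshold_by_density(
                discard_negatives(corr[grp]), report_d, group=grp, roi_labels=labels
            )
            for grp in (CONTROL, STRESS)
        }
        for grp, net in nets.items():
            write_edge_list(net, out / f"edges_{grp}_d{report_d:.2f}.csv")
        sub_stage: dict = {"report_density": report_d}
        for node in cfg.focal_nodes:
            comp = compare_neighborhood(nets[CONTROL], nets[STRESS], node)
            write_graphml_bundle(
                nets[CONTROL],
                nets[STRESS],
                comp,
                out / f"subconnectome_{node}_control.graphml",
                out / f"subconnectome_{node}_stress.graphml",
            )
            rows = (
                [(n, "common") for n in sorted(comp.common_neighbors)]
                + [(n, "stress_only") for n in sorted(comp.stress_only)]
                + [(n, "control_only") for n in sorted(comp.control_only)]
            )
            pd.DataFrame(rows, columns=["neighbor", "status"]).to_csv(
                out / f"neighbors_{node}.csv", index=False
            )
            sub_stage[node] = {
                "rank_control": comp.rank_control,
                "rank_stress": comp.rank_stress,
                "n_common": len(comp.common_neighbors),
                "n_stress_only": len(comp.stress_only),
                "n_control_only": len(comp.control_only),
            }
        summary["stages"]["subconnectome"] = sub_stage
        log.info("subconnectome done in %.2fs", time.time() - t)

    log.info("pipeline finished in %.2fs", time.time() - t0)
    (out / "manifest.json").write_text(
        json.dumps(summary, indent=2, default=_json_default, sort_keys=True)
    )
    return summary
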
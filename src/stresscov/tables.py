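"""Core tabular containers shared across the pipeline.

Both containers wrap a :class:`pandas.DataFrame` (one row per subject) plus
the metadata the analysis needs: group membership, covariates, and per-column
annotations.  They are deliberately thin — every analysis stage receives one
of these, validates what it needs, and returns plain results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
STRESS = "stress"
GROUPS = (CONTROL, STRESS)


def _check_groups(group: pd.Series) -> None:
    bad = set(group.unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")


@dataclass
class VolumeTable:
    """Subjects x ROI volumes with group labels and covariates.

    Parameters
    ----------
    subject_id
        Unique subject identifiers, one per row.
    group
        Per-subject label, ``"control"`` or ``"stress"``.
    volumes
        ``(n_subjects, n_roi)`` array of strictly positive regional volumes
        (mm^3, or unitless fractions after total-volume normalization).
    roi_labels
        Unique ROI names, one per column of ``volumes``.
    covariates
        Optional per-subject numeric covariates (e.g. ``sex``,
        ``total_brain_volume``), keyed by name.
    normalized
        Set by :func:`stresscov.volumetrics.normalize_volumes`; guards
        against double normalization.
    """

    subject_id: list[str]
    group: list[str]
    volumes: np.ndarray
    roi_labels: list[str]
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.subject_id = list(self.subject_id)
        self.group = list(self.group)
        self.roi_labels = list(self.roi_labels)
        n, p = self.volumes.shape
        if len(self.subject_id) != n:
            raise ValueError("subject_id length does not match volume rows")
        if len(set(self.subject_id)) != n:
            raise ValueError("duplicate subject identifiers")
        if len(self.group) != n:
            raise ValueError("group length does not match volume rows")
        _check_groups(pd.Series(self.group))
        if len(self.roi_labels) != p:
            raise ValueError("roi_labels length does not match volume columns")
        if len(set(self.roi_labels)) != p:
            raise ValueError("duplicate ROI labels")
        if not np.all(np.isfinite(self.volumes)):
            raise ValueError("non-finite volume values")
        if np.any(self.volumes <= 0):
            raise ValueError("all volumes must be strictly positive")
        for name, vals in self.covariates.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n,):
                raise ValueError(f"covariate {name!r} has wrong length")
            self.covariates[name] = vals

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_roi(self) -> int:
        return self.volumes.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return np.asarray([g == group for g in self.group])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.volumes, columns=self.roi_labels)
        df.insert(0, "subject_id", self.subject_id)
        df.insert(1, "group", self.group)
        for i, (name, vals) in enumerate(self.covariates.items()):
            df.insert(2 + i, name, vals)
        return df

    def roi_index(self, label: str) -> int:
        try:
            return self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label {label!r}") from None


@dataclass
class BehaviorTable:
    """Subjects x behavioral variables with per-variable test/direction metadata.

    ``var_meta`` maps each variable name to ``(test_name, direction)`` where
    direction is ``"higher_is_more_emotional"`` or
    ``"lower_is_more_emotional"`` — the sign convention used when variables
    are folded into a single emotionality score.
    """

    subject_id: list[str]
    group: list[str]
    values: np.ndarray
    var_names: list[str]
    var_meta: dict[str, tuple[str, str]]

    DIRECTIONS = ("higher_is_more_emotional", "lower_is_more_emotional")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_id = list(self.subject_id)
        self.group = list(self.group)
        self.var_names = list(self.var_names)
        n, p = self.values.shape
        if len(self.subject_id) != n or len(set(self.subject_id)) != n:
            raise ValueError("subject_id must be unique and match value rows")
        if len(self.group) != n:
            raise ValueError("group length does not match value rows")
        _check_groups(pd.Series(self.group))
        if len(self.var_names) != p or len(set(self.var_names)) != p:
            raise ValueError("var_names must be unique and match value columns")
        missing = [v for v in self.var_names if v not in self.var_meta]
        if missing:
            raise ValueError(f"variables without metadata: {missing}")
        for v in self.var_names:
            test, direction = self.var_meta[v]
            if direction not in self.DIRECTIONS:
                raise ValueError(
                    f"variable {v!r}: direction must be one of {self.DIRECTIONS}"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def tests(self) -> list[str]:
        seen: list[str] = []
        for v in self.var_names:
            t = self.var_meta[v][0]
            if t not in seen:
                seen.append(t)
        return seen

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return np.asarray([g == group for g in self.group])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.var_names)
        df.insert(0, "subject_id", self.subject_id)
        df.insert(1, "group", self.group)
        return df
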
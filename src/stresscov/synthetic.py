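"""Synthetic cohorts with controllable structural-covariance effects.

Regional volumes are drawn from a latent-factor model whose implied
correlation matrix has a block (modular) structure: a global factor shared by
all ROIs sets the between-module correlation, one factor per module raises
within-module correlation, and independent noise fills the remaining
variance.  Chronic-stress effects enter as three orthogonal knobs applied to
the stress group only:

* ``demodularization`` — multiplicative attenuation of the within-module
  factor loadings, flattening the modular structure (global loss of
  clustering/modularity);
* ``hub_gain`` — an extra factor shared by one hub ROI and a target set,
  adding correlation between the hub and its targets (focal gain in hubness);
* ``volume_effect_size`` — a mean volume increase on a small a-priori ROI
  set, modulated by each subject's latent emotionality trait.

Behavioral batteries load on the same latent emotionality trait, with the
stress group shifted by ``emotionality_effect_size`` standard deviations,
so behavior scoring and volume-behavior regressions have real signal to
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .tables import BehaviorTable, VolumeTable, CONTROL, STRESS

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "mouse_default_spec",
    "human_default_spec",
    "default_roi_labels",
]

#: Baseline ROI volume (mm^3).  Kept >= 10x the default noise_sd so that
#: Gaussian sampling essentially never produces nonpositive volumes; a
#: nonpositive draw is an error, never clipped.
VOLUME_MEAN = 10.0

#: Loading of each behavioral variable on the latent emotionality trait.
#: 0.5 gives per-variable group effects of about half the latent effect,
#: typical of single behavioral read-outs in rodent batteries.
BEHAVIOR_LOADING = 0.5

#: Correlation between a subject's centered emotionality trait and the
#: volume of each a-priori effect ROI.  The trait replaces this fraction of
#: the ROI's latent signal (variance-preserving), so volumes track
#: emotionality within groups without inflating the ROI's variance or
#: diluting its covariance with the rest of the brain by more than
#: sqrt(1 - coupling^2).
VOLUME_TRAIT_COUPLING = 0.3


@dataclass
class CohortSpec:
    """Full parameterization of a two-group synthetic cohort."""

    n_control: int
    n_stress: int
    n_roi: int
    module_sizes: list[int]
    within_module_corr: float = 0.6
    between_module_corr: float = 0.2
    hub_roi: int = 0
    hub_target_set: list[int] = field(default_factory=list)
    hub_gain: float = 0.0
    demodularization: float = 1.0
    volume_effect_rois: list[int] = field(default_factory=list)
    volume_effect_size: float = 0.0
    n_behavior_tests: int = 1
    vars_per_test: list[int] = field(default_factory=lambda: [1])
    emotionality_effect_size: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 1 or self.n_stress < 1:
            raise ValueError("both groups need at least one subject")
        if sum(self.module_sizes) != self.n_roi:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, expected n_roi={self.n_roi}"
            )
        if any(m < 1 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not 0 <= self.between_module_corr <= self.within_module_corr < 1:
            raise ValueError(
                "need 0 <= between_module_corr <= within_module_corr < 1 "
                f"(got between={self.between_module_corr}, within={self.within_module_corr})"
            )
        if not 0 <= self.hub_gain < 1:
            raise ValueError("hub_gain must be in [0, 1)")
        if not 0 < self.demodularization <= 1:
            raise ValueError("demodularization must be in (0, 1]")
        for name, idx in [("hub_roi", [self.hub_roi])] + [
            ("hub_target_set", self.hub_target_set),
            ("volume_effect_rois", self.volume_effect_rois),
        ]:
            for i in idx:
                if not 0 <= i < self.n_roi:
                    raise ValueError(f"{name} index {i} out of range for n_roi={self.n_roi}")
        for name, lst in [
            ("hub_target_set", self.hub_target_set),
            ("volume_effect_rois", self.volume_effect_rois),
        ]:
            if len(set(lst)) != len(lst):
                raise ValueError(f"duplicate indices in {name}")
        if self.hub_roi in self.hub_target_set:
            raise ValueError("hub_roi may not appear in its own hub_target_set")
        if len(self.vars_per_test) != self.n_behavior_tests:
            raise ValueError("vars_per_test length must equal n_behavior_tests")
        if any(v < 1 for v in self.vars_per_test):
            raise ValueError("each test needs at least one variable")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_behavior_vars(self) -> int:
        return sum(self.vars_per_test)

    def module_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)

    def to_dict(self) -> dict:
        return asdict(self)


def _loadings(spec: CohortSpec, stressed: bool) -> np.ndarray:
    """Factor loading matrix for one group.

    Columns: global factor, one per module, optionally one hub factor.
    The implied correlation is ``L @ L.T + diag(unique)`` with unit diagonal.
    """
    n = spec.n_roi
    modules = spec.module_assignment()
    n_mod = len(spec.module_sizes)
    cols = 1 + n_mod + 1
    L = np.zeros((n, cols))
    L[:, 0] = np.sqrt(spec.between_module_corr)
    within_extra = spec.within_module_corr - spec.between_module_corr
    atten = spec.demodularization if stressed else 1.0
    for m in range(n_mod):
        if spec.module_sizes[m] > 1:  # a singleton has no within pairs
            L[modules == m, 1 + m] = np.sqrt(within_extra) * atten
    if stressed and spec.hub_gain > 0 and spec.hub_target_set:
        # Asymmetric loadings: the hub loads a, every target loads b with
        # a*b = hub_gain, so the hub-target correlation increment equals
        # hub_gain exactly while the unavoidable target-target increment is
        # only b^2.  The hub uses all of its spare variance, which keeps b —
        # and hence the target-target side effect — as small as the PSD
        # constraint allows.
        base_hub = float(np.sum(L[spec.hub_roi] ** 2))
        a_sq = 1.0 - base_hub
        if a_sq <= 0:
            raise ValueError(
                "hub_gain: no variance left on the hub ROI for the hub factor; "
                "reduce within_module_corr/between_module_corr or hub_gain"
            )
        a = np.sqrt(min(1.0, a_sq))
        if spec.hub_gain / a > 1.0:
            raise ValueError(
                "hub_gain too large for the hub ROI's spare variance; "
                "reduce hub_gain or the baseline correlations"
            )
        L[spec.hub_roi, 1 + n_mod] = a
        L[spec.hub_target_set, 1 + n_mod] = spec.hub_gain / a
    return L


def implied_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    """Population ROI-ROI correlation matrix the generator targets for ``group``."""
    spec.validate()
    L = _loadings(spec, stressed=(group == STRESS))
    unique = 1.0 - np.sum(L * L, axis=1)
    if np.any(unique < -1e-12):
        i = int(np.argmin(unique))
        raise ValueError(
            f"implied variance of ROI {i} exceeds 1 (communality {1 - unique[i]:.3f}); "
            "reduce within_module_corr, between_module_corr or hub_gain"
        )
    C = L @ L.T
    np.fill_diagonal(C, 1.0)
    # Belt-and-braces PSD check on the implied correlation before sampling.
    lo = float(np.linalg.eigvalsh(C)[0])
    if lo < -1e-8:
        raise ValueError(f"implied correlation is not PSD (min eigenvalue {lo:.3e})")
    return C


def _sample_group(
    spec: CohortSpec, stressed: bool, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance latent ROI scores for ``n`` subjects of one group."""
    L = _loadings(spec, stressed)
    unique = 1.0 - np.sum(L * L, axis=1)
    if np.any(unique < -1e-12):
        raise ValueError(
            "implied correlation is not PSD; check within/between correlations and hub_gain"
        )
    unique = np.clip(unique, 0.0, None)
    f = rng.standard_normal((n, L.shape[1]))
    eps = rng.standard_normal((n, spec.n_roi))
    return f @ L.T + eps * np.sqrt(unique)


def generate_cohort(
    spec: CohortSpec, roi_labels: list[str] | None = None
) -> tuple[VolumeTable, BehaviorTable]:
    """Draw one cohort: a volume table and a behavior table.

    Reproducible under ``spec.seed``; volume and behavior generation use
    independent RNG streams split from the master seed (the shared latent
    emotionality trait has its own stream), so each table is individually
    reproducible.
    """
    spec.validate()
    if roi_labels is None:
        roi_labels = [f"roi_{i:03d}" for i in range(spec.n_roi)]
    if len(roi_labels) != spec.n_roi or len(set(roi_labels)) != spec.n_roi:
        raise ValueError("roi_labels must be unique and match n_roi")

    ss = np.random.SeedSequence(spec.seed)
    trait_rng, vol_rng, beh_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    n_c, n_s = spec.n_control, spec.n_stress
    groups = np.array([CONTROL] * n_c + [STRESS] * n_s)
    subject_id = [f"sub_{i:04d}" for i in range(n_c + n_s)]
    stressed = groups == STRESS

    # Latent emotionality trait: unit SD, stress mean shifted by the effect size.
    trait = trait_rng.standard_normal(n_c + n_s)
    trait[stressed] += spec.emotionality_effect_size

    z = np.vstack(
        [
            _sample_group(spec, stressed=False, n=n_c, rng=vol_rng),
            _sample_group(spec, stressed=True, n=n_s, rng=vol_rng),
        ]
    )
    if spec.volume_effect_rois and spec.volume_effect_size != 0:
        # Effect ROIs: blend the centered emotionality trait into the latent
        # signal (variance-preserving) and add a pure group mean shift of
        # volume_effect_size * noise_sd, so the group contrast is exactly
        # the requested Cohen's d and volume tracks emotionality within
        # groups.
        kappa = VOLUME_TRAIT_COUPLING
        centered = trait - np.where(stressed, spec.emotionality_effect_size, 0.0)
        idx = spec.volume_effect_rois
        z[:, idx] = np.sqrt(1 - kappa**2) * z[:, idx] + kappa * centered[:, None]
        z[:, idx] += spec.volume_effect_size * stressed.astype(float)[:, None]
    volumes = VOLUME_MEAN + spec.noise_sd * z
    if np.any(volumes <= 0):
        raise ValueError(
            "sampled a nonpositive volume; noise_sd is too large relative to the "
            f"baseline mean {VOLUME_MEAN}"
        )

    covariates = {
        "sex": vol_rng.integers(0, 2, size=n_c + n_s).astype(float),
        "total_brain_volume": volumes.sum(axis=1),
    }
    vol_table = VolumeTable(
        subject_id=subject_id,
        group=list(groups),
        volumes=volumes,
        roi_labels=list(roi_labels),
        covariates=covariates,
    )

    # Behavioral battery: each variable loads on the trait with a
    # direction-dependent sign, plus independent noise.
    var_names: list[str] = []
    var_meta: dict[str, tuple[str, str]] = {}
    signs = []
    for t in range(spec.n_behavior_tests):
        test = f"test_{t:02d}"
        for v in range(spec.vars_per_test[t]):
            name = f"{test}_var{v:02d}"
            # Alternate directions so the sign-flip path is always exercised.
            direction = (
                "higher_is_more_emotional" if v % 2 == 0 else "lower_is_more_emotional"
            )
            var_names.append(name)
            var_meta[name] = (test, direction)
            signs.append(1.0 if direction == "higher_is_more_emotional" else -1.0)
    signs_arr = np.asarray(signs)
    lam = BEHAVIOR_LOADING
    noise = beh_rng.standard_normal((n_c + n_s, len(var_names)))
    values = signs_arr * lam * trait[:, None] + np.sqrt(1 - lam**2) * noise
    beh_table = BehaviorTable(
        subject_id=subject_id,
        group=list(groups),
        values=values,
        var_names=var_names,
        var_meta=var_meta,
    )
    return vol_table, beh_table


def _spread_targets(module_sizes: list[int], per_module: int, hub: int) -> list[int]:
    """Pick ``per_module`` evenly spaced ROIs from every module, skipping the hub."""
    targets: list[int] = []
    start = 0
    for size in module_sizes:
        idx = np.linspace(start, start + size - 1, per_module + 2)[1:-1]
        for i in np.round(idx).astype(int):
            if i != hub and i not in targets:
                targets.append(int(i))
        start += size
    return targets


def mouse_default_spec(seed: int = 0) -> CohortSpec:
    """UCMS-style design: 12 mice per group, 155 network ROIs.

    Defaults inject the three stress effects at magnitudes detectable at
    this sample size: hub_gain 0.3 on a 96-ROI target set, demodularization
    0.7, and a 1.5-SD volume increase on four a-priori ROIs tied to a 2-SD
    latent emotionality shift expressed through a 34-variable battery.  The
    hub forms its own singleton micro-module, so in the control state it is
    an unremarkable mid-to-low-rank node; strong baseline correlations
    (0.90 within modules, 0.45 between) reflect the high cross-subject
    synchrony of regional anatomy and keep sampling noise at n = 12 small
    enough for the injected effects to be recoverable.
    """
    module_sizes = [1, 38, 38, 39, 39]
    hub = 0
    return CohortSpec(
        n_control=12,
        n_stress=12,
        n_roi=155,
        module_sizes=module_sizes,
        within_module_corr=0.90,
        between_module_corr=0.45,
        hub_roi=hub,
        hub_target_set=_spread_targets(module_sizes, per_module=24, hub=hub),
        hub_gain=0.3,
        demodularization=0.7,
        volume_effect_rois=[0, 39, 77, 116],
        volume_effect_size=1.5,
        n_behavior_tests=7,
        vars_per_test=[5, 5, 5, 5, 5, 5, 4],
        emotionality_effect_size=2.0,
        noise_sd=0.5,
        seed=seed,
    )


def human_default_spec(seed: int = 0) -> CohortSpec:
    """Childhood-trauma design: 237 low-CTQ vs 299 high-CTQ subjects, 56 ROIs.

    Effects mirror the mouse structure but with a milder volume effect
    (large-sample design): hub_gain 0.3 on 18 targets, demodularization
    0.55, a 0.4-SD volume effect on one ROI, and a 1-SD latent trait shift
    expressed through a five-subscale questionnaire.
    """
    module_sizes = [1, 18, 18, 19]
    hub = 0
    return CohortSpec(
        n_control=237,
        n_stress=299,
        n_roi=56,
        module_sizes=module_sizes,
        within_module_corr=0.88,
        between_module_corr=0.45,
        hub_roi=hub,
        hub_target_set=_spread_targets(module_sizes, per_module=6, hub=hub),
        hub_gain=0.3,
        demodularization=0.55,
        volume_effect_rois=[1],
        volume_effect_size=0.4,
        n_behavior_tests=1,
        vars_per_test=[5],
        emotionality_effect_size=1.0,
        noise_sd=0.5,
        seed=seed,
    )


def default_roi_labels(spec: CohortSpec, species: str) -> list[str]:
    """Readable ROI labels for the two default designs.

    The hub is labelled ``amygdala`` in both species; the mouse a-priori
    volume-effect ROIs carry the corticolimbic names they emulate, and the
    human volume-effect ROI is the occipital fusiform gyrus.
    """
    labels = [f"roi_{i:03d}" for i in range(spec.n_roi)]
    labels[spec.hub_roi] = "amygdala"
    if species == "mouse":
        named = ["cingulate_area_32", "medial_orbital_cortex", "frontal_association_cortex"]
        extra = [i for i in spec.volume_effect_rois if i != spec.hub_roi]
        for i, name in zip(extra, named):
            labels[i] = name
    elif species == "human":
        for i in spec.volume_effect_rois:
            if i != spec.hub_roi:
                labels[i] = "occipital_fusiform_gyrus"
    else:
        raise ValueError("species must be 'mouse' or 'human'")
    return labels
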
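import numpy as np
import pytest

from stresscov import CohortSpec, generate_cohort
from stresscov.networks import CovarianceNetwork


def small_null_spec(seed: int = 0, n: int = 12, n_roi: int = 30) -> CohortSpec:
    """A cohort spec with no injected effects: both groups share one
    generative law."""
    return CohortSpec(
        n_control=n,
        n_stress=n,
        n_roi=n_roi,
        module_sizes=[n_roi // 3] * 3,
        within_module_corr=0.6,
        between_module_corr=0.2,
        hub_roi=0,
        hub_target_set=[],
        hub_gain=0.0,
        demodularization=1.0,
        volume_effect_rois=[],
        volume_effect_size=0.0,
        n_behavior_tests=2,
        vars_per_test=[3, 3],
        emotionality_effect_size=0.0,
        seed=seed,
    )


@pytest.fixture
def null_cohort():
    return generate_cohort(small_null_spec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_network(rng: np.random.Generator, n: int, p_edge: float = 0.6) -> CovarianceNetwork:
    """Random connected-ish weighted graph wrapped as a network object."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    mask = rng.random(iu.size) < p_edge
    vals = rng.uniform(0.05, 1.0, iu.size) * mask
    w[iu, ju] = vals
    w += w.T
    k = int(np.count_nonzero(vals))
    return CovarianceNetwork(
        group="control",
        roi_labels=[f"n{i}" for i in range(n)],
        weights=w,
        density=max(k / iu.size, 1e-9),
        retained_edges=k,
    )
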
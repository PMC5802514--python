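"""ROI volumetrics: GLM, FDR, volume-behavior regression, enrichment."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from stresscov import (
    VolumeTable,
    apriori_enrichment,
    generate_cohort,
    normalize_volumes,
    roi_group_glm,
    total_brain_volume_test,
    volume_behavior_regression,
)

from .conftest import small_null_spec
from .oracles import brute_bh


def _vol(volumes, groups, covariates=None, labels=None):
    volumes = np.asarray(volumes, dtype=float)
    n, p = volumes.shape
    return VolumeTable(
        subject_id=[f"s{i}" for i in range(n)],
        group=groups,
        volumes=volumes,
        roi_labels=labels or [f"r{j}" for j in range(p)],
        covariates=covariates or {},
    )


class TestNormalize:
    def test_divide_by_total(self):
        v = _vol(
            [[10.0, 30.0], [20.0, 20.0]],
            ["control", "stress"],
            covariates={"total_brain_volume": np.array([100.0, 200.0])},
        )
        out = normalize_volumes(v, "divide_by_total")
        np.testing.assert_allclose(out.volumes, [[0.1, 0.3], [0.1, 0.1]])
        assert out.normalized
        # input untouched
        assert v.volumes[0, 0] == 10.0 and not v.normalized

    def test_mode_none_is_identity(self):
        v = _vol([[1.0, 2.0]], ["control"])
        assert normalize_volumes(v, "none") is v

    def test_double_normalization_rejected(self):
        v = _vol(
            [[10.0, 30.0]],
            ["control"],
            covariates={"total_brain_volume": np.array([100.0])},
        )
        once = normalize_volumes(v, "divide_by_total")
        with pytest.raises(ValueError, match="already normalized"):
            normalize_volumes(once, "divide_by_total")

    def test_missing_total_names_requirement(self):
        v = _vol([[1.0]], ["control"])
        with pytest.raises(ValueError, match="total_brain_volume"):
            normalize_volumes(v, "divide_by_total")


class TestGroupGLM:
    def test_identical_groups_no_signal(self):
        rng = np.random.default_rng(0)
        block = rng.random((5, 4)) + 1
        v = _vol(np.vstack([block, block]), ["control"] * 5 + ["stress"] * 5)
        out = roi_group_glm(v)
        np.testing.assert_allclose(out["effect_size"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p"], 1.0, atol=1e-10)

    def test_covariate_free_glm_equals_t_test(self):
        rng = np.random.default_rng(1)
        v = _vol(rng.random((16, 6)) + 1, ["control"] * 8 + ["stress"] * 8)
        out = roi_group_glm(v)
        for j, roi in enumerate(v.roi_labels):
            t = sps.ttest_ind(v.volumes[8:, j], v.volumes[:8, j], equal_var=True)
            assert out.loc[roi, "p"] == pytest.approx(t.pvalue, abs=1e-10)

    def test_bh_adjustment_matches_stepup_oracle(self):
        # worked 4-value example plus random vectors against brute force
        from statsmodels.stats.multitest import multipletests

        q = multipletests(np.array([0.01, 0.02, 0.04, 0.05]), method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.05, 0.05])
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(int(rng.integers(3, 50)))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], brute_bh(p), atol=1e-12
            )

    def test_injected_effect_rois_dominate_ranking(self):
        """ROIs carrying a 1.5-SD group effect cluster at the top of the
        association ranking over replicate cohorts.  At n = 12/group the
        effect t-statistics (mean ~3) overlap the extreme order statistics
        of 26 null ROIs, so exact top-4 recovery happens in a majority of
        cohorts, not almost surely; top-8 containment is the stronger
        regularity."""
        top4 = top8 = 0
        n_rep = 60
        effect = {"roi_000", "roi_007", "roi_014", "roi_021"}
        for seed in range(n_rep):
            spec = dataclasses.replace(
                small_null_spec(seed=seed),
                volume_effect_rois=[0, 7, 14, 21],
                volume_effect_size=1.5,
                emotionality_effect_size=2.0,
            )
            vol, _ = generate_cohort(spec)
            out = roi_group_glm(vol)
            top4 += set(out.index[out["rank"] <= 4]) == effect
            top8 += effect.issubset(set(out.index[out["rank"] <= 8]))
        assert top4 / n_rep > 0.5
        assert top8 / n_rep > 0.8

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        cov = rng.random(10)
        v = _vol(
            rng.random((10, 3)) + 1,
            ["control"] * 5 + ["stress"] * 5,
            covariates={"a": cov, "b": 2 * cov},
        )
        with pytest.raises(ValueError, match="collinear|rank"):
            roi_group_glm(v, ["a", "b"])

    def test_rank_column_is_permutation(self):
        rng = np.random.default_rng(4)
        v = _vol(rng.random((12, 9)) + 1, ["control"] * 6 + ["stress"] * 6)
        out = roi_group_glm(v)
        assert sorted(out["rank"]) == list(range(1, 10))
        assert np.all(out["q"] >= out["p"] - 1e-15)


class TestVolumeBehaviorRegression:
    def test_perfectly_linear_volume_gives_r2_one(self):
        pc1 = np.linspace(-2, 2, 12)
        v = _vol(
            np.column_stack([3 + 0.5 * pc1, 5 - 0.2 * pc1]),
            ["control"] * 6 + ["stress"] * 6,
        )
        out = volume_behavior_regression(v, pc1)
        np.testing.assert_allclose(out["r_squared"], 1.0)

    def test_independent_volume_r2_near_zero(self):
        rng = np.random.default_rng(5)
        v = _vol(rng.random((1000, 8)) + 1, ["control"] * 500 + ["stress"] * 500)
        out = volume_behavior_regression(v, rng.standard_normal(1000))
        assert out["r_squared"].mean() < 0.01

    def test_r2_recovers_squared_correlation(self):
        rng = np.random.default_rng(6)
        n = 2000
        pc1 = rng.standard_normal(n)
        rho = 0.6
        vol = 10 + rho * pc1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        v = _vol(vol[:, None], ["control"] * 1000 + ["stress"] * 1000)
        out = volume_behavior_regression(v, pc1)
        assert out["r_squared"].iloc[0] == pytest.approx(0.36, abs=0.05)

    def test_constant_pc1_rejected(self):
        v = _vol([[1.0], [2.0]], ["control", "stress"])
        with pytest.raises(ValueError, match="constant"):
            volume_behavior_regression(v, np.array([1.0, 1.0]))


class TestEnrichment:
    @staticmethod
    def _stats_frame(n_roi):
        import pandas as pd

        return pd.DataFrame(
            {"rank": np.arange(1, n_roi + 1)},
            index=[f"r{j}" for j in range(n_roi)],
        )

    def test_perfect_overlap_maximal_chi2(self):
        stats_table = self._stats_frame(159)
        apriori = [f"r{j}" for j in range(20)]  # exactly the top 20 ranks
        chi2, p = apriori_enrichment(stats_table, apriori, top_k=20)
        # forced 2x2 table (20,0;0,139) has chi2 = n = 159
        assert chi2 == pytest.approx(159.0)
        assert p < 1e-6

    def test_null_enrichment_p_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(300):
            stats_table = self._stats_frame(159)
            apriori = list(rng.choice(stats_table.index, size=26, replace=False))
            ps.append(apriori_enrichment(stats_table, apriori, top_k=20)[1])
        # the 2x2 support is discrete, so only a coarse uniformity check
        # is meaningful
        ks = sps.kstest(ps, "uniform")
        assert ks.statistic < 0.25

    def test_degenerate_margins_rejected(self):
        stats_table = self._stats_frame(10)
        with pytest.raises(ValueError, match="top_k"):
            apriori_enrichment(stats_table, ["r0"], top_k=10)
        with pytest.raises(ValueError, match="empty"):
            apriori_enrichment(stats_table, [], top_k=3)


class TestTotalBrainVolume:
    def test_identical_distributions_p_one(self):
        block = np.array([[1.0, 2.0], [2.0, 3.0], [1.5, 2.5]])
        v = _vol(np.vstack([block, block]), ["control"] * 3 + ["stress"] * 3)
        assert total_brain_volume_test(v) == pytest.approx(1.0, abs=1e-10)

    def test_huge_shift_detected(self):
        rng = np.random.default_rng(8)
        ctrl = rng.normal(10, 1, size=(12, 3))
        strs = rng.normal(15, 1, size=(12, 3))  # 5 pooled SDs on the total
        v = _vol(np.vstack([ctrl, strs]), ["control"] * 12 + ["stress"] * 12)
        assert total_brain_volume_test(v) < 0.001

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(10, 1, size=(24, 2))
            v = _vol(x, ["control"] * 12 + ["stress"] * 12)
            rejections += total_brain_volume_test(v) < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07
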
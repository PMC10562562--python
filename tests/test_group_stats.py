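"""Group inference: GLM t, TFCE, permutation FWE, FDR, ROI tests.

Oracles are implemented independently here: TFCE by explicit per-threshold
breadth-first component search, and GLM t-statistics by direct normal
equations.
"""

import numpy as np
import pytest
from scipy import stats

from vmadapt import group_stats as gs


# ---------------------------------------------------------------- oracles
def tfce_bruteforce(vol, E=0.5, H=2.0, dh=0.1):
    """Per-threshold BFS cluster labeling, 26-connectivity, direct sum."""
    vol = np.asarray(vol, dtype=float)
    out = np.zeros_like(vol)
    hmax = vol.max(initial=0.0)
    n = int(np.floor(hmax / dh + 1e-9))
    for k in range(1, n + 1):
        h = k * dh
        above = vol >= h - 1e-9 * max(hmax, 1.0)
        seen = np.zeros_like(above)
        for idx in np.argwhere(above):
            idx = tuple(idx)
            if seen[idx]:
                continue
            # BFS over the 26-neighborhood
            comp, queue = [], [idx]
            seen[idx] = True
            while queue:
                cur = queue.pop()
                comp.append(cur)
                for off in np.ndindex(3, 3, 3):
                    nb = tuple(np.array(cur) + np.array(off) - 1)
                    if any(c < 0 or c >= s for c, s in zip(nb, vol.shape)):
                        continue
                    if above[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
            for v in comp:
                out[v] += len(comp) ** E * h**H * dh
    return out


def glm_t_oracle(y, X, j):
    """Scalar-response GLM t for coefficient j via explicit normal equations."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[j, j])
    return beta[j] / se


# ---------------------------------------------------------------- group t
class TestGroupGlmT:
    def test_intercept_only_equals_one_sample_t(self):
        rng = np.random.default_rng(0)
        maps = [rng.standard_normal((4, 4, 3)) + 0.4 for _ in range(12)]
        t = gs.group_glm_t(maps)
        ref = stats.ttest_1samp(np.stack(maps), 0.0, axis=0).statistic
        assert np.allclose(t, ref)

    def test_zero_variance_guarded(self):
        maps = [np.full((2, 2, 2), 3.0)] * 5
        t = gs.group_glm_t(maps)
        assert np.all(t == 1e6)  # documented large-finite convention

    def test_intercept_with_uncentered_confound_matches_oracle(self):
        rng = np.random.default_rng(1)
        n = 5
        conf = np.array([0.3, 0.9, 0.1, 0.7, 0.5])
        maps = [rng.standard_normal((2, 2, 1)) + 1.0 for _ in range(n)]
        design = gs.GroupDesign(regressors={"confound": conf}, tested="intercept")
        t = gs.group_glm_t(maps, design)
        X = np.column_stack([np.ones(n), conf])
        Y = np.stack(maps).reshape(n, -1)
        for v in range(Y.shape[1]):
            assert t.ravel()[v] == pytest.approx(glm_t_oracle(Y[:, v], X, 0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            gs.group_glm_t([np.zeros((2, 2, 2))] * 2)

    def test_rank_deficient_design_rejected(self):
        maps = [np.zeros((2, 2, 2))] * 6
        design = gs.GroupDesign(regressors={"c": np.ones(6)})  # duplicates intercept
        with pytest.raises(np.linalg.LinAlgError):
            gs.group_glm_t(maps, design)


# ------------------------------------------------------------------- TFCE
class TestTfce:
    def test_zero_map(self):
        assert np.allclose(gs.tfce(np.zeros((4, 4, 4))), 0.0)

    def test_single_voxel_closed_form(self):
        vol = np.zeros((5, 5, 5))
        vol[2, 2, 2] = 2.0
        got = gs.tfce(vol, dh=0.1)[2, 2, 2]
        hs = 0.1 * np.arange(1, 21)
        assert got == pytest.approx(np.sum(1.0**0.5 * hs**2 * 0.1))

    def test_two_voxel_line_cluster_matches_bruteforce(self):
        vol = np.zeros((5, 1, 1))
        vol[1, 0, 0] = 1.0
        vol[2, 0, 0] = 1.5
        assert np.allclose(gs.tfce(vol, dh=0.1), tfce_bruteforce(vol, dh=0.1))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_volumes_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        vol = np.clip(rng.standard_normal((5, 5, 5)), 0, None)
        assert np.allclose(gs.tfce(vol, dh=0.2), tfce_bruteforce(vol, dh=0.2))

    def test_monotone_in_stat_map(self):
        rng = np.random.default_rng(3)
        vol = np.clip(rng.standard_normal((5, 5, 5)), 0, None)
        bumped = vol + 0.3
        dh = 0.05
        assert np.all(gs.tfce(bumped, dh=dh) >= gs.tfce(vol, dh=dh) - 1e-12)

    def test_nan_background_preserved(self):
        vol = np.full((3, 3, 3), np.nan)
        vol[1, 1, 1] = 1.0
        out = gs.tfce(vol)
        assert np.isnan(out[0, 0, 0]) and out[1, 1, 1] > 0

    def test_invalid_dh(self):
        with pytest.raises(ValueError):
            gs.tfce(np.ones((2, 2, 2)), dh=0.0)


# ------------------------------------------------------- permutation FWE
class TestPermutationFwe:
    def test_strong_signal_attains_minimum_p(self):
        rng = np.random.default_rng(0)
        maps = [rng.standard_normal((4, 4, 3)) * 0.01 + 5.0 for _ in range(10)]
        res = gs.permutation_fwe(maps, n_perm=199, rng=1)
        assert np.nanmin(res.p_fwe) == pytest.approx(1.0 / 200.0)

    def test_single_permutation_discreteness(self):
        rng = np.random.default_rng(2)
        maps = [rng.standard_normal((3, 3, 2)) for _ in range(8)]
        res = gs.permutation_fwe(maps, n_perm=1, rng=3)
        assert set(np.unique(res.p_fwe[np.isfinite(res.p_fwe)])) <= {0.5, 1.0}

    def test_scheme_design_compatibility(self):
        maps = [np.zeros((2, 2, 2))] * 6
        design = gs.GroupDesign(
            regressors={"x": np.arange(6.0)}, tested="x"
        )
        with pytest.raises(ValueError, match="sign-flip"):
            gs.permutation_fwe(maps, design, scheme="sign_flip", n_perm=10)

    def test_covariate_defaults_to_freedman_lane(self):
        rng = np.random.default_rng(4)
        x = np.linspace(-1, 1, 10)
        maps = [rng.standard_normal((3, 3, 2)) + 2.0 * xi for xi in x]
        design = gs.GroupDesign(regressors={"x": x}, tested="x")
        res = gs.permutation_fwe(maps, design, n_perm=99, rng=5)
        assert np.nanmin(res.p_fwe) < 0.05

    def test_invalid_args(self):
        maps = [np.zeros((2, 2, 2))] * 5
        with pytest.raises(ValueError):
            gs.permutation_fwe(maps, n_perm=0)
        with pytest.raises(ValueError):
            gs.permutation_fwe(maps, statistic="z", n_perm=5)
        with pytest.raises(ValueError):
            gs.permutation_fwe(maps, scheme="bootstrap", n_perm=5)


# ------------------------------------------------------------------- FDR
class TestFdr:
    def test_all_equal_p_unchanged(self):
        p = np.full((3, 3, 1), 0.03)
        assert np.allclose(gs.fdr_bh(p), 0.03)

    def test_hand_computed_step_up(self):
        p = np.array([0.01, 0.04, 0.03, 0.9]).reshape(4, 1, 1)
        q = gs.fdr_bh(p).ravel()
        assert q == pytest.approx([0.04, 4 * 0.04 / 3, 4 * 0.04 / 3, 0.9])

    def test_q_dominates_p(self):
        rng = np.random.default_rng(0)
        p = rng.random((4, 4, 4))
        assert np.all(gs.fdr_bh(p) >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            gs.fdr_bh(np.array([[[1.2]]]))


# --------------------------------------------- correlation and ROI tests
class TestCorrelation:
    def test_planted_negative_slope_recovered(self):
        rng = np.random.default_rng(0)
        perf = np.linspace(1.0, 2.0, 14)
        maps = [2.0 - 1.5 * p + 0.05 * rng.standard_normal((3, 3, 2)) for p in perf]
        res = gs.accuracy_performance_correlation(maps, perf)
        assert np.all(res.t < -5)

    def test_shuffled_performance_breaks_link(self):
        rng = np.random.default_rng(1)
        perf = np.linspace(1.0, 2.0, 14)
        maps = [2.0 - 1.5 * p + 0.05 * rng.standard_normal((3, 3, 2)) for p in perf]
        shuffled = rng.permutation(perf)
        res = gs.accuracy_performance_correlation(maps, shuffled)
        dof = 14 - 2
        crit = stats.t.ppf(0.005, dof)
        assert np.mean(res.t < crit) < 0.5  # no systematic strong effect

    def test_slope_t_matches_partial_regression_oracle(self):
        rng = np.random.default_rng(2)
        n = 6
        perf = np.array([1.2, 1.5, 1.1, 1.9, 1.4, 1.7])
        conf = np.array([0.2, 0.6, 0.3, 0.9, 0.1, 0.5])
        maps = [rng.standard_normal((2, 1, 1)) - p for p in perf]
        res = gs.accuracy_performance_correlation(maps, perf, confound=conf)
        X = np.column_stack([np.ones(n), perf, conf])
        Y = np.stack(maps).reshape(n, -1)
        for v in range(Y.shape[1]):
            assert res.t.ravel()[v] == pytest.approx(glm_t_oracle(Y[:, v], X, 1))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            gs.accuracy_performance_correlation([np.zeros((2, 2, 1))] * 4, [1.0, 2.0])


class TestResultsTable:
    def test_clusters_summarized(self):
        t = np.zeros((6, 6, 4))
        p = np.ones((6, 6, 4))
        t[1:3, 1:3, 1] = 4.0
        p[1:3, 1:3, 1] = 0.01
        t[4, 4, 2] = 6.0
        p[4, 4, 2] = 0.002
        table = gs.results_table(gs.GroupStatMap(t=t, p_fwe=p))
        assert len(table) == 2
        assert sorted(table.n_voxels) == [1, 4]
        peak = table.loc[table.n_voxels == 1].iloc[0]
        assert (peak.peak_x, peak.peak_y, peak.peak_z) == (4, 4, 2)
        assert peak.peak_t == 6.0

    def test_empty_when_nothing_significant(self):
        table = gs.results_table(
            gs.GroupStatMap(t=np.zeros((3, 3, 3)), p_fwe=np.ones((3, 3, 3)))
        )
        assert len(table) == 0

    def test_requires_p_values(self):
        with pytest.raises(ValueError):
            gs.results_table(gs.GroupStatMap(t=np.zeros((2, 2, 2))))


class TestRoi:
    def test_all_zero_maps_give_zero_t(self):
        maps = [np.zeros((3, 3, 2)) for _ in range(6)]
        mask = np.ones((3, 3, 2), dtype=bool)
        t, p = gs.roi_test(maps, mask)
        assert t == 0.0

    def test_toy_matches_hand_solved_glm(self):
        vals = np.array([1.0, 2.0, 1.5, 2.5, 2.0])
        conf = np.array([0.1, 0.6, 0.2, 0.8, 0.4])
        maps = [np.full((2, 2, 1), v) for v in vals]
        mask = np.ones((2, 2, 1), dtype=bool)
        design = gs.GroupDesign(regressors={"confound": conf}, tested="intercept")
        t, p = gs.roi_test(maps, mask, design)
        X = np.column_stack([np.ones(5), conf])
        assert t == pytest.approx(glm_t_oracle(vals, X, 0))
        assert p == pytest.approx(float(stats.t.sf(t, 3)))

    def test_single_voxel_roi_equals_voxelwise(self):
        rng = np.random.default_rng(3)
        maps = [rng.standard_normal((3, 3, 2)) for _ in range(8)]
        mask = np.zeros((3, 3, 2), dtype=bool)
        mask[1, 2, 0] = True
        t, _ = gs.roi_test(maps, mask)
        tv = gs.group_glm_t(maps)
        assert t == pytest.approx(tv[1, 2, 0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            gs.roi_test([np.zeros((2, 2, 2))] * 4, np.zeros((2, 2, 2), dtype=bool))
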
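"""Group-level inference on accuracy (or activation) maps.

One-sample and confound-adjusted GLM t-tests are computed voxelwise across
subjects.  Family-wise error is controlled by max-statistic permutation on
the TFCE-transformed t-map: sign-flipping for intercept (one-sample) tests
and Freedman-Lane residual permutation for covariate tests.  Benjamini-
Hochberg FDR q-values are provided as the weaker control.

The "t-test with a confound" follows the uncentered-confound construction:
the group design contains an intercept and the confound column left
uncentered, and the test is one-sided on the intercept coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupDesign",
    "GroupStatMap",
    "group_glm_t",
    "tfce",
    "permutation_fwe",
    "fdr_bh",
    "accuracy_performance_correlation",
    "roi_test",
    "results_table",
    "one_sample_design",
]

# 26-connectivity in 3-D
_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class GroupDesign:
    """Subject-level regressors and the coefficient under test.

    ``regressors`` maps names to per-subject vectors; an "intercept" column
    is added automatically.  The confound convention of the source analyses
    is honored by *not* centering any column: an intercept test with an
    uncentered confound evaluates the response at confound zero.
    """

    regressors: dict = field(default_factory=dict)
    tested: str = "intercept"
    n_subjects: int | None = None

    def matrix(self, n_subjects: int) -> np.ndarray:
        cols = [np.ones(n_subjects)]
        names = ["intercept"]
        for name, v in self.regressors.items():
            v = np.asarray(v, dtype=float)
            if len(v) != n_subjects:
                raise ValueError(f"regressor {name!r} has wrong length")
            cols.append(v)
            names.append(name)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("group design is rank deficient")
        self._names = names
        return X

    def tested_index(self) -> int:
        return self._names.index(self.tested)


def one_sample_design() -> GroupDesign:
    return GroupDesign()


@dataclass
class GroupStatMap:
    t: np.ndarray
    tfce: np.ndarray | None = None
    p_fwe: np.ndarray | None = None
    q_fdr: np.ndarray | None = None
    n_permutations: int = 0
    seed: int | None = None


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=float) for m in maps])
    return arr


def _glm_t(Y: np.ndarray, X: np.ndarray, j: int) -> np.ndarray:
    """t-statistic of coefficient j from voxelwise OLS; Y is (n, voxels)."""
    n, p = X.shape
    if n <= p:
        raise ValueError("need more subjects than regressors")
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y
    resid = Y - X @ coef
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[j, j], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[j] / se
    # (near-)zero-variance voxels: sign convention, collapsed to large finite t
    degenerate = se <= 1e-10 * (np.abs(coef[j]) + 1.0)
    t = np.where(degenerate, np.sign(coef[j]) * 1e6, t)
    return t


def group_glm_t(maps, design: GroupDesign | None = None, mask: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise group GLM t-map for the tested regressor.

    ``maps`` is a sequence of equally shaped subject volumes (NaNs allowed
    off-mask).  With the default intercept-only design this is the plain
    one-sample t-test.
    """
    design = design or one_sample_design()
    Y4 = _stack(maps)
    n = Y4.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    shape = Y4.shape[1:]
    if mask is None:
        mask = ~np.any(np.isnan(Y4), axis=0)
    Y = Y4[:, mask]
    X = design.matrix(n)
    t = _glm_t(Y, X, design.tested_index())
    out = np.full(shape, np.nan)
    out[mask] = t
    return out


def tfce(
    stat: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive branch.

    For each voxel, sum over thresholds h (step dh, default max/100) of
    e(h)**E * h**H * dh, where e(h) is the extent of the 26-connected
    cluster supporting the voxel at height h.  NaNs are treated as
    background and preserved in the output.
    """
    s = np.asarray(stat, dtype=float)
    nanmask = np.isnan(s)
    s = np.where(nanmask, 0.0, s)
    pos = np.clip(s, 0.0, None)
    out = np.zeros_like(pos)
    hmax = pos.max()
    if hmax > 0:
        if dh is None:
            dh = hmax / n_steps
        if dh <= 0:
            raise ValueError("dh must be positive")
        tol = 1e-9 * max(hmax, 1.0)
        n = int(np.floor(hmax / dh + 1e-9))
        for k in range(1, n + 1):
            h = k * dh
            above = pos >= h - tol
            labels, n_lab = ndimage.label(above, structure=_CONN26)
            if n_lab:
                sizes = np.bincount(labels.ravel())
                extent = sizes[labels] * above
                out += (extent.astype(float) ** E) * (h**H) * dh * above
    out[nanmask] = np.nan
    return out


def _sign_flip_stats(Y, X, j, transform, rng, n_perm):
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=Y.shape[0])
        t = _glm_t(signs[:, None] * Y, X, j)
        maxima[i] = np.nanmax(transform(t))
    return maxima


def _freedman_lane_stats(Y, X, j, transform, rng, n_perm):
    # regress out nuisance (all columns but j), permute residuals, refit
    keep = [k for k in range(X.shape[1]) if k != j]
    Z = X[:, keep]
    Hz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    resid = Y - Hz @ Y
    fitted = Hz @ Y
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        Ystar = fitted + resid[perm]
        t = _glm_t(Ystar, X, j)
        maxima[i] = np.nanmax(transform(t))
    return maxima


def permutation_fwe(
    maps,
    design: GroupDesign | None = None,
    statistic: str = "tfce",
    n_perm: int = 5000,
    scheme: str | None = None,
    rng=None,
    mask: np.ndarray | None = None,
    tfce_kwargs: dict | None = None,
) -> GroupStatMap:
    """Max-statistic permutation FWE p-values for a group GLM.

    ``statistic`` is "t" or "tfce" (TFCE applied to the t-map).  ``scheme``
    defaults to sign-flipping for intercept tests and Freedman-Lane
    residual permutation for covariate tests.  One-sided (positive) test;
    p = (1 + #{perm max >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = design or one_sample_design()
    if scheme is None:
        scheme = "sign_flip" if design.tested == "intercept" else "freedman_lane"
    if scheme == "sign_flip" and design.tested != "intercept":
        raise ValueError("sign-flipping applies to intercept tests only")
    if scheme not in ("sign_flip", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme: {scheme!r}")
    if statistic not in ("t", "tfce"):
        raise ValueError(f"unknown statistic: {statistic!r}")

    rng = np.random.default_rng(rng)
    Y4 = _stack(maps)
    shape = Y4.shape[1:]
    if mask is None:
        mask = ~np.any(np.isnan(Y4), axis=0)
    Y = Y4[:, mask]
    n = Y4.shape[0]
    X = design.matrix(n)
    j = design.tested_index()
    tkw = tfce_kwargs or {}

    if statistic == "tfce":

        def transform(tvec):
            vol = np.zeros(shape)
            vol[mask] = tvec
            vol[~mask] = np.nan
            return tfce(vol, **tkw)[mask]

    else:

        def transform(tvec):
            return tvec

    t_obs_vec = _glm_t(Y, X, j)
    enh_obs = transform(t_obs_vec)

    if scheme == "sign_flip":
        maxima = _sign_flip_stats(Y, X, j, transform, rng, n_perm)
    else:
        maxima = _freedman_lane_stats(Y, X, j, transform, rng, n_perm)

    exceed = (maxima[:, None] >= enh_obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)

    t_map = np.full(shape, np.nan)
    t_map[mask] = t_obs_vec
    enh_map = np.full(shape, np.nan)
    enh_map[mask] = enh_obs
    p_map = np.full(shape, np.nan)
    p_map[mask] = p

    dof = n - X.shape[1]
    p_unc = stats.t.sf(t_obs_vec, dof)
    q_map = np.full(shape, np.nan)
    q_map[mask] = _bh_q(p_unc)

    return GroupStatMap(
        t=t_map,
        tfce=enh_map if statistic == "tfce" else None,
        p_fwe=p_map,
        q_fdr=q_map,
        n_permutations=n_perm,
    )


def _bh_q(p: np.ndarray) -> np.ndarray:
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fdr_bh(p: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over in-mask voxels."""
    p = np.asarray(p, dtype=float)
    if mask is None:
        mask = ~np.isnan(p)
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    out[mask] = _bh_q(vals)
    return out


def accuracy_performance_correlation(
    maps,
    performance,
    confound=None,
    n_perm: int = 0,
    rng=None,
    mask: np.ndarray | None = None,
) -> GroupStatMap:
    """Regression of decoding accuracy on behavioral performance.

    Returns the t-map for the performance slope; the hypothesized direction
    is negative (higher performance, more representation commonality, lower
    accuracy), so the one-sided permutation test, when requested, is run on
    the sign-flipped slope.
    """
    performance = np.asarray(performance, dtype=float)
    if len(performance) != len(maps):
        raise ValueError("one performance value per subject required")
    regs = {"performance": performance}
    if confound is not None:
        regs["confound"] = np.asarray(confound, dtype=float)
    design = GroupDesign(regressors=regs, tested="performance")
    t = group_glm_t(maps, design, mask=mask)
    if n_perm:
        neg = permutation_fwe(
            [-np.asarray(m, dtype=float) for m in maps],
            GroupDesign(
                regressors={**regs, "performance": -performance}, tested="performance"
            ),
            statistic="tfce",
            n_perm=n_perm,
            rng=rng,
            mask=mask,
        )
        return GroupStatMap(
            t=t, tfce=neg.tfce, p_fwe=neg.p_fwe, q_fdr=neg.q_fdr, n_permutations=n_perm
        )
    return GroupStatMap(t=t)


def results_table(stat: GroupStatMap, alpha: float = 0.05):
    """Cluster summary of a thresholded group map.

    Returns a DataFrame with one row per 26-connected cluster of voxels
    with p_FWE < alpha: size, peak t, peak coordinates (voxel indices),
    and the cluster-minimum p_fwe / q_fdr.
    """
    import pandas as pd

    if stat.p_fwe is None:
        raise ValueError("stat map carries no FWE p-values")
    sig = np.isfinite(stat.p_fwe) & (stat.p_fwe < alpha)
    labels, n_lab = ndimage.label(sig, structure=_CONN26)
    rows = []
    for lab in range(1, n_lab + 1):
        voxels = np.argwhere(labels == lab)
        t_vals = stat.t[labels == lab]
        peak_local = voxels[np.argmax(t_vals)]
        rows.append(
            dict(
                cluster=lab,
                n_voxels=len(voxels),
                peak_x=int(peak_local[0]),
                peak_y=int(peak_local[1]),
                peak_z=int(peak_local[2]),
                peak_t=float(np.max(t_vals)),
                min_p_fwe=float(np.nanmin(stat.p_fwe[labels == lab])),
                min_q_fdr=(
                    float(np.nanmin(stat.q_fdr[labels == lab]))
                    if stat.q_fdr is not None
                    else np.nan
                ),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "n_voxels",
            "peak_x",
            "peak_y",
            "peak_z",
            "peak_t",
            "min_p_fwe",
            "min_q_fdr",
        ],
    )


def roi_test(maps, roi_mask: np.ndarray, design: GroupDesign | None = None):
    """Mean-over-ROI per subject, then the specified group GLM test.

    Returns (t, p) with a one-sided (positive for intercept tests, negative
    for covariate tests) parametric p-value.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    design = design or one_sample_design()
    vals = np.array([float(np.nanmean(np.asarray(m)[roi_mask])) for m in maps])
    n = len(vals)
    X = design.matrix(n)
    j = design.tested_index()
    t = float(_glm_t(vals[:, None], X, j)[0])
    dof = n - X.shape[1]
    if design.tested == "intercept":
        p = float(stats.t.sf(t, dof))
    else:
        p = float(stats.t.cdf(t, dof))
    return t, p
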
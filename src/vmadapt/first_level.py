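"""First-level GLM machinery: HRF convolution, design matrices, OLS fits,
outlier-scan flagging, and Gaussian volume smoothing.

Two design-matrix variants are supported.  The mass-univariate variant pools
erasing trials into one box-car regressor per context; the MVPA variant
models each block separately with one regressor per erasing direction (the
block's first trial goes to a null regressor) so that the per-block
direction betas can serve as decoding features.  Both variants add
preparation/score/termination regressors, one regressor per outlier trial,
motion parameters and their gradients, one spike regressor per flagged
scan, and a discrete-cosine drift basis up to the 1/128 Hz cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

from .task_design import SessionDesign

__all__ = [
    "HrfParams",
    "DesignMatrix",
    "hrf_kernel",
    "hrf_convolve",
    "dct_drift_basis",
    "build_design_matrix",
    "fit_glm",
    "framewise_displacement",
    "flag_outlier_scans",
    "smooth_volume",
]

HIGHPASS_CUTOFF_HZ = 1.0 / 128.0


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp_s: float = 1.0
    undershoot_disp_s: float = 1.0
    ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self):
        if min(self.peak_delay_s, self.undershoot_delay_s, self.length_s) <= 0:
            raise ValueError("HRF delays and length must be positive")


def hrf_kernel(hrf: HrfParams | None = None, dt: float = 0.1) -> np.ndarray:
    """Double-gamma HRF sampled at dt, peak-normalized to 1."""
    hrf = hrf or HrfParams()
    t = np.arange(0, hrf.length_s, dt)
    peak = gamma_dist.pdf(t, hrf.peak_delay_s / hrf.peak_disp_s, scale=hrf.peak_disp_s)
    under = gamma_dist.pdf(
        t, hrf.undershoot_delay_s / hrf.undershoot_disp_s, scale=hrf.undershoot_disp_s
    )
    h = peak - under / hrf.ratio
    return h / h.max()


def hrf_convolve(
    boxcar: np.ndarray, hrf: HrfParams | None = None, dt: float = 0.1
) -> np.ndarray:
    """Causal convolution of a high-resolution box-car with the HRF.

    Input and output are sampled at ``dt``; resampling to scan times is the
    caller's concern (see build_design_matrix).
    """
    boxcar = np.asarray(boxcar, dtype=float)
    kernel = hrf_kernel(hrf, dt)
    return np.convolve(boxcar, kernel)[: len(boxcar)] * dt


def dct_drift_basis(n_scans: int, tr: float, cutoff_hz: float = HIGHPASS_CUTOFF_HZ) -> np.ndarray:
    """Orthonormal discrete-cosine drift columns below the high-pass cutoff.

    Component k has frequency k / (2 * n_scans * tr); the constant term is
    excluded (an explicit intercept is added separately).
    """
    order = int(np.floor(2.0 * n_scans * tr * cutoff_hz))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (n + 0.5) * k / n_scans)
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


@dataclass
class DesignMatrix:
    frame: pd.DataFrame  # scans x named regressors
    column_classes: dict  # name -> class tag

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def names(self) -> list:
        return list(self.frame.columns)

    def columns_of_class(self, *classes) -> list:
        return [n for n in self.names if self.column_classes[n] in classes]


def _event_regressor(spans, n_scans, tr, hrf, dt=0.1):
    """HRF-convolved box-car over (onset, duration) spans, TR-sampled."""
    n_hi = int(np.ceil(n_scans * tr / dt)) + 1
    box = np.zeros(n_hi)
    for onset, dur in spans:
        i0 = int(round(onset / dt))
        i1 = int(round((onset + max(dur, dt)) / dt))
        box[i0 : max(i1, i0 + 1)] = 1.0
    conv = hrf_convolve(box, hrf, dt)
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return conv[scan_idx]


def build_design_matrix(
    session: SessionDesign,
    trials=None,
    variant: str = "mvpa",
    nuisance: pd.DataFrame | None = None,
    hrf: HrfParams | None = None,
    n_scans: int | None = None,
    tr: float | None = None,
    outlier_scans: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the first-level design matrix for one session.

    ``trials`` is an optional list of behavior.TrialRecord carrying per-trial
    outlier flags; without it no trial is treated as an outlier.  ``nuisance``
    is a table with columns trans_x/y/z, rot_x/y/z (and optionally
    global_signal); motion gradients are backward differences.
    """
    if variant not in ("univariate", "mvpa"):
        raise ValueError(f"unknown design variant: {variant!r}")
    timing = session.timing
    tr = tr or timing.tr_s
    n_scans = n_scans or session.n_scans
    hrf = hrf or HrfParams()

    outlier_of = {}
    if trials is not None:
        outlier_of = {(t.block_index, t.trial_index): t.outlier for t in trials}

    trial_events = {}  # (block, trial) -> (onset, dur)
    prep_events, score_events, term_events = {}, {}, {}
    for onset, dur, etype, b_idx, t_idx in session.events:
        if etype == "trial":
            trial_events[(b_idx, t_idx)] = (onset, dur)
        elif etype == "prep":
            prep_events[b_idx] = (onset, dur)
        elif etype == "score":
            score_events[b_idx] = (onset, dur)
        elif etype == "termination":
            term_events[b_idx] = (onset, dur)

    columns, classes = {}, {}

    def add(name, spans, cls):
        if not spans:
            return
        columns[name] = _event_regressor(spans, n_scans, tr, hrf)
        classes[name] = cls

    outlier_spans = []
    if variant == "univariate":
        ctx_spans = {}
        for (b, t), span in sorted(trial_events.items()):
            if outlier_of.get((b, t), False):
                outlier_spans.append(((b, t), span))
            else:
                ctx_spans.setdefault(session.blocks[b].context.name, []).append(span)
        for ctx, spans in ctx_spans.items():
            add(f"erasing_{ctx}", spans, "task")
        add("prep", list(prep_events.values()), "preparation")
        add("score", list(score_events.values()), "score")
        add("termination", list(term_events.values()), "termination")
    else:
        for block in session.blocks:
            b = block.block_index
            dir_spans = {}
            null_spans = []
            usable = 0
            for t_idx in range(timing.n_trials_per_block):
                span = trial_events.get((b, t_idx))
                if span is None:
                    continue
                if outlier_of.get((b, t_idx), False):
                    # an outlier first trial is modeled once, as an outlier
                    outlier_spans.append(((b, t_idx), span))
                    continue
                if t_idx == 0:
                    null_spans.append(span)
                    continue
                direction = block.trial_sequence[t_idx]
                dir_spans.setdefault(direction.value, []).append(span)
                usable += 1
            if usable == 0:
                raise ValueError(f"block {b}: every direction trial is an outlier")
            for dname, spans in dir_spans.items():
                add(f"block{b:02d}_dir_{dname}", spans, "task")
            add(f"block{b:02d}_null", null_spans, "null_first_trial")
            if b in prep_events:
                add(f"block{b:02d}_prep", [prep_events[b]], "preparation")
            if b in score_events:
                add(f"block{b:02d}_score", [score_events[b]], "score")
            if b in term_events:
                add(f"block{b:02d}_term", [term_events[b]], "termination")

    for (b, t), span in outlier_spans:
        add(f"outlier_trial_b{b:02d}_t{t:02d}", [span], "outlier_trial")

    if nuisance is not None:
        motion_cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        for col in motion_cols:
            v = nuisance[col].to_numpy()[:n_scans]
            columns[col] = v
            classes[col] = "motion"
            g = np.diff(v, prepend=v[0])
            columns[f"{col}_grad"] = g
            classes[f"{col}_grad"] = "motion_gradient"

    if outlier_scans is not None:
        for k in np.flatnonzero(np.asarray(outlier_scans)[:n_scans]):
            spike = np.zeros(n_scans)
            spike[k] = 1.0
            columns[f"spike_{k:04d}"] = spike
            classes[f"spike_{k:04d}"] = "spike"

    drift = dct_drift_basis(n_scans, tr)
    for k in range(drift.shape[1]):
        columns[f"drift_{k + 1:02d}"] = drift[:, k]
        classes[f"drift_{k + 1:02d}"] = "drift"
    columns["intercept"] = np.ones(n_scans)
    classes["intercept"] = "drift"

    frame = pd.DataFrame(columns)
    return DesignMatrix(frame, classes)


def fit_glm(series: np.ndarray, design: DesignMatrix):
    """Voxelwise OLS fit of a 4-D series (x, y, z, t) or 2-D (t, voxels).

    Returns (betas, resid_var) where betas maps regressor name to a volume
    (or 1-D array in the 2-D case).  Raises on rank deficiency, naming the
    collinear columns.
    """
    X = design.values
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        _, _, piv = sla.qr(X, mode="economic", pivoting=True)
        bad = sorted(design.names[i] for i in piv[rank:])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {', '.join(bad)}"
        )

    if series.ndim == 4:
        spatial = series.shape[:3]
        Y = series.reshape(-1, series.shape[3]).T
    elif series.ndim == 2:
        spatial = None
        Y = series
    else:
        raise ValueError("series must be 4-D (x,y,z,t) or 2-D (t,voxels)")
    if Y.shape[0] != X.shape[0]:
        raise ValueError("time dimension of series does not match design")

    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = max(X.shape[0] - X.shape[1], 1)
    resid_var = np.sum(resid**2, axis=0) / dof

    betas = {}
    for i, name in enumerate(design.names):
        b = coef[i]
        betas[name] = b.reshape(spatial) if spatial else b
    return betas, (resid_var.reshape(spatial) if spatial else resid_var)


def framewise_displacement(motion: pd.DataFrame, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """FD per scan: sum of absolute backward differences of the six
    realignment parameters, rotations expressed as arc length on a 50-mm
    sphere.  The first scan has FD 0."""
    trans = motion[["trans_x", "trans_y", "trans_z"]].to_numpy()
    rot = motion[["rot_x", "rot_y", "rot_z"]].to_numpy() * rotation_radius_mm
    d = np.vstack([np.zeros(6), np.diff(np.hstack([trans, rot]), axis=0)])
    return np.sum(np.abs(d), axis=1)


def flag_outlier_scans(
    motion: pd.DataFrame,
    global_signal: np.ndarray,
    fd_threshold_mm: float = 0.9,
    global_z_threshold: float = 5.0,
) -> np.ndarray:
    """Flag scans with FD > 0.9 mm or |z| of the global signal > 5."""
    g = np.asarray(global_signal, dtype=float)
    if len(g) != len(motion):
        raise ValueError("motion and global signal must have equal length")
    fd = framewise_displacement(motion)
    sd = g.std()
    z = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    return (fd > fd_threshold_mm) | (np.abs(z) > global_z_threshold)


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 3.0) -> np.ndarray:
    """Separable 3-D Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2))."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma_vox)
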
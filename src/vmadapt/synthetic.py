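"""Synthetic multi-subject neural data with plantable representations.

Each subject gets a session design, simulated erasing behavior, and a beta
series (one volume per block x {direction, null, prep} regressor) on a small
common grid.  Four disjoint regions carry the plantable signals:

* ``visual_region`` — a distinct spatial pattern per visual direction,
  shared across contexts (supports visual decoding only);
* ``movement_region`` — a pattern per hand-movement direction, shared
  across contexts (supports movement decoding only);
* ``context_region`` — a pattern per task context, independent of
  direction (supports context decoding only);
* ``null_region`` — noise only.

The key knob is the commonality parameter rho: the population correlation
between the two rotation-context patterns (and, separately, between the
rotation family and the mirror pattern).  A monotone link maps a subject's
behavioral performance to rho, embodying the structural-learning hypothesis
that better performers share more context representation — and therefore
show *lower* context-decoding accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import first_level as fl
from .task_design import (
    MIRROR,
    ROT_MINUS90,
    ROT_PLUS90,
    Direction,
    SessionDesign,
    TimingParams,
    build_session,
    required_movement,
)

__all__ = [
    "VolumeGrid",
    "PatternModel",
    "BetaSeries",
    "SubjectDataset",
    "default_grid",
    "default_pattern_model",
    "affine_link",
    "plant_correlated_patterns",
    "sample_cohort",
    "simulate_bold",
]


@dataclass
class VolumeGrid:
    dims: tuple
    voxel_size_mm: float = 3.0
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        if any(d <= 0 for d in self.dims):
            raise ValueError("grid dims must be positive")
        if self.brain_mask is None:
            self.brain_mask = _ellipsoid_mask(self.dims)
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")

    @property
    def n_voxels_in_mask(self) -> int:
        return int(self.brain_mask.sum())


def _ellipsoid_mask(dims) -> np.ndarray:
    center = (np.array(dims) - 1) / 2.0
    semi = np.array(dims) / 2.0 - 0.5
    idx = np.indices(dims).reshape(3, -1).T
    r = np.sum(((idx - center) / semi) ** 2, axis=1)
    return (r <= 1.0).reshape(dims)


def _box_mask(dims, corner, size) -> np.ndarray:
    m = np.zeros(dims, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    m[sl] = True
    return m


def default_grid(dims=(24, 24, 18), voxel_size_mm=3.0) -> VolumeGrid:
    return VolumeGrid(tuple(dims), voxel_size_mm)


def default_region_masks(grid: VolumeGrid, box_size: int | None = None) -> dict:
    """Four disjoint cubic regions near the in-plane corners of the brain.

    The box edge shrinks on small grids so the regions never overlap; on
    grids of 24 voxels and up the regions are also separated by more than
    the default 9-mm searchlight radius.
    """
    nx, ny, nz = grid.dims
    s = box_size or max(2, min(4, (min(nx, ny) - 2) // 3))
    ax, ay = nx // 4, ny // 4
    bx, by = nx - ax - s, ny - ay - s
    if bx < ax + s or by < ay + s:
        raise ValueError("grid too small for four disjoint regions")
    cz = max(nz // 2 - s // 2, 0)
    size = (s, s, s)
    masks = {
        "visual_region": _box_mask(grid.dims, (ax, ay, cz), size),
        "movement_region": _box_mask(grid.dims, (ax, by, cz), size),
        "context_region": _box_mask(grid.dims, (bx, ay, cz), size),
        "null_region": _box_mask(grid.dims, (bx, by, cz), size),
    }
    for name, m in masks.items():
        masks[name] = m & grid.brain_mask
        if not masks[name].any():
            raise ValueError(f"{name} fell outside the brain mask")
    return masks


def affine_link(slope: float, intercept: float, lo: float = 0.0, hi: float = 1.0):
    """Affine performance->rho link, clipped to [lo, hi]."""

    def link(performance: float) -> float:
        return float(np.clip(intercept + slope * performance, lo, hi))

    return link


@dataclass
class PatternModel:
    """Amplitudes, noise level, and the performance->commonality link.

    Amplitudes and noise_sd are in the same arbitrary signal units as the
    generated betas.  Defaults are calibrated so that, at cohort sizes of
    8-22 subjects on the default grid, each planted level is decodable by
    its own analysis while context-decoding accuracy stays off ceiling and
    tracks rho (see docs/methods.md).
    """

    grid: VolumeGrid = field(default_factory=default_grid)
    region_masks: dict | None = None
    visual_amplitude: float = 1.0
    movement_amplitude: float = 1.0
    context_amplitude: float = 0.7
    prep_amplitude: float = 0.7
    noise_sd: float = 1.0
    allow_overlap: bool = False
    rotation_link: "Callable | None" = None  # rotation performance -> rho(-90, +90)
    mirror_link: "Callable | None" = None  # mirror performance -> rho(rot family, mirror)

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.region_masks is None:
            self.region_masks = default_region_masks(self.grid)
        if not self.allow_overlap:
            total = sum(int(m.sum()) for m in self.region_masks.values())
            union = np.zeros(self.grid.dims, dtype=bool)
            for m in self.region_masks.values():
                union |= m
            if int(union.sum()) != total:
                raise ValueError(
                    "region masks overlap; pass allow_overlap=True to permit"
                )
        if self.rotation_link is None:
            self.rotation_link = affine_link(1.0, -1.0)
        if self.mirror_link is None:
            self.mirror_link = affine_link(0.55, -0.85)


def default_pattern_model(**overrides) -> PatternModel:
    return PatternModel(**overrides)


@dataclass
class BetaSeries:
    """Per-(block, regressor) coefficient volumes plus their labels."""

    grid: VolumeGrid
    coefficients: dict  # (block_index, regressor_name) -> 3-D array
    labels: dict  # (block_index, regressor_name) -> dict(context=..., direction=...)

    def direction_beta(self, block_index: int, direction: Direction) -> np.ndarray:
        return self.coefficients[(block_index, f"dir_{direction.value}")]

    def prep_beta(self, block_index: int) -> np.ndarray:
        return self.coefficients[(block_index, "prep")]


@dataclass
class SubjectDataset:
    subject_id: str
    session: SessionDesign
    trials: list
    performance: bhv.SubjectPerformance
    betas: BetaSeries
    rho_rotation: float
    rho_mirror: float
    bold: np.ndarray | None = None
    nuisance: pd.DataFrame | None = None


def plant_correlated_patterns(mask: np.ndarray, rho: float, amplitude: float, rng):
    """Two zero-mean patterns on ``mask`` with population correlation rho.

    Gaussian mixing: p2 = rho * z1 + sqrt(1 - rho^2) * z2, both scaled by
    ``amplitude``; the sample correlation converges to rho as the voxel
    count grows.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    n = int(np.asarray(mask).sum())
    if n == 0:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(rng)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    p1 = amplitude * z1
    p2 = amplitude * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    return p1, p2


def _context_patterns(model: PatternModel, rho_rot: float, rho_mir: float, rng) -> dict:
    """Three context patterns with corr(-90,+90)=rho_rot and
    corr(rotation family, mirror)=rho_mir (population values)."""
    mask = model.region_masks["context_region"]
    n = int(mask.sum())
    amp = model.context_amplitude
    shared = rng.standard_normal(n)
    e1, e2, e3 = (rng.standard_normal(n) for _ in range(3))
    a = np.sqrt(max(rho_rot, 0.0))
    b = np.sqrt(max(1.0 - rho_rot, 0.0))
    p_m90 = a * shared + b * e1
    p_p90 = a * shared + b * e2
    # the rotation-family mean has variance (1 + rho_rot)/2; standardize it
    fam = (p_m90 + p_p90) / 2.0
    fam_sd = np.sqrt((1.0 + max(rho_rot, 0.0)) / 2.0)
    fam_std = fam / fam_sd if fam_sd > 0 else e3
    p_mir = rho_mir * fam_std + np.sqrt(max(1.0 - rho_mir**2, 0.0)) * e3
    return {
        ROT_MINUS90.name: amp * p_m90,
        ROT_PLUS90.name: amp * p_p90,
        MIRROR.name: amp * p_mir,
    }


def _mover_for(context, rng, rotation_speed, mirror_speed, jitter_sd,
               p_explore=0.04):
    speed = mirror_speed if context is MIRROR else rotation_speed
    trial_speed = max(speed + rng.normal(0.0, 3.0), 1.0)
    if rng.random() < p_explore:
        # occasional confused trial: fast, meandering, long cursor path
        return bhv.StraightMover(trial_speed * 2.2, angle_jitter_sd=1.2)
    return bhv.StraightMover(trial_speed, angle_jitter_sd=jitter_sd)


def _simulate_behavior(session, rng, rotation_speed, mirror_speed, jitter_sd=0.25):
    trials = []
    for block in session.blocks:
        for t_idx, vis in enumerate(block.trial_sequence):
            mover = _mover_for(block.context, rng, rotation_speed, mirror_speed, jitter_sd)
            trials.append(
                bhv.simulate_erasing_trial(
                    block.context,
                    vis,
                    mover,
                    rng=rng,
                    block_index=block.block_index,
                    trial_index=t_idx,
                    max_duration_s=session.timing.trial_window_s,
                    dt=0.05,
                )
            )
    return trials


def _subject_betas(model, session, rho_rot, rho_mir, rng, planted=None) -> BetaSeries:
    grid = model.grid
    masks = model.region_masks
    brain = grid.brain_mask
    planted = planted if planted is not None else {"visual", "movement", "context", "prep"}

    vis_patterns = {
        d: model.visual_amplitude * rng.standard_normal(int(masks["visual_region"].sum()))
        for d in Direction
    }
    mov_patterns = {
        d: model.movement_amplitude * rng.standard_normal(int(masks["movement_region"].sum()))
        for d in Direction
    }
    ctx_patterns = _context_patterns(model, rho_rot, rho_mir, rng)

    coeffs, labels = {}, {}

    def new_volume():
        v = np.zeros(grid.dims)
        v[brain] = rng.normal(0.0, model.noise_sd, grid.n_voxels_in_mask)
        return v

    for block in session.blocks:
        ctx = block.context
        for d in Direction:
            vol = new_volume()
            if "visual" in planted:
                vol[masks["visual_region"]] += vis_patterns[d]
            if "movement" in planted:
                vol[masks["movement_region"]] += mov_patterns[required_movement(ctx, d)]
            if "context" in planted:
                vol[masks["context_region"]] += ctx_patterns[ctx.name]
            key = (block.block_index, f"dir_{d.value}")
            coeffs[key] = vol
            labels[key] = dict(
                context=ctx.name,
                visual_direction=d.value,
                movement_direction=required_movement(ctx, d).value,
            )
        vol = new_volume()
        if "prep" in planted:
            vol[masks["context_region"]] += (
                model.prep_amplitude / model.context_amplitude
            ) * ctx_patterns[ctx.name]
        coeffs[(block.block_index, "prep")] = vol
        labels[(block.block_index, "prep")] = dict(
            context=ctx.name, visual_direction=None, movement_direction=None
        )
        vol = new_volume()
        coeffs[(block.block_index, "null")] = vol
        labels[(block.block_index, "null")] = dict(
            context=ctx.name, visual_direction=None, movement_direction=None
        )
    return BetaSeries(grid, coeffs, labels)


def sample_cohort(
    n_subjects: int,
    pattern_model: PatternModel | None = None,
    timing: TimingParams | None = None,
    rng=None,
    *,
    planted=None,
    rotation_speed_mean: float = 27.4,
    mirror_speed_mean: float = 38.3,
    speed_sd: float = 2.5,
    mode: str = "betas",
) -> list:
    """Draw a cohort of synthetic subjects.

    Per subject: behavioral proficiency (hand speed, px/s) is drawn per
    context family; erasing trials are simulated; rho values come from the
    model's links applied to the subject's mean performances; betas are
    planted patterns plus voxelwise Gaussian noise.  ``planted`` restricts
    which levels carry signal (subset of {"visual","movement","context",
    "prep"}); an empty set gives an all-noise cohort.  ``mode="bold"``
    additionally simulates a 4-D series from the planted betas.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    model = pattern_model or default_pattern_model()
    timing = timing or TimingParams()
    rng = np.random.default_rng(rng)

    subjects = []
    for i in range(n_subjects):
        srng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        session = build_session(timing, srng)
        rot_speed = srng.normal(rotation_speed_mean, speed_sd)
        mir_speed = srng.normal(mirror_speed_mean, speed_sd)
        trials = _simulate_behavior(session, srng, rot_speed, mir_speed)
        perf = bhv.summarize_performance(trials)
        rho_rot = model.rotation_link(perf.mean_rotation_speed)
        rho_mir = model.mirror_link(perf.mean_mirror_speed)
        for name, rho in (("rotation", rho_rot), ("mirror", rho_mir)):
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"{name} link produced invalid rho {rho}")
        betas = _subject_betas(model, session, rho_rot, rho_mir, srng, planted)
        subj = SubjectDataset(
            subject_id=f"sub-{i + 1:02d}",
            session=session,
            trials=trials,
            performance=perf,
            betas=betas,
            rho_rotation=rho_rot,
            rho_mirror=rho_mir,
        )
        if mode == "bold":
            subj.bold, subj.nuisance = simulate_bold(session, betas, rng=srng)
        subjects.append(subj)
    return subjects


def simulate_bold(
    session: SessionDesign,
    betas: BetaSeries,
    hrf_params: fl.HrfParams | None = None,
    noise_params: dict | None = None,
    rng=None,
):
    """Forward model: series = design @ planted betas + AR(1) noise.

    ``noise_params`` keys: sigma (innovation SD, default 0), ar1 (phi,
    default 0), motion_sd (random-walk step of motion params, default 0),
    fd_spike_scans / global_spike_scans (lists of scan indices given a
    planted 2-mm translation jump or a 6-SD global excursion).  Returns the
    4-D series and a nuisance table (6 motion params + global signal).
    """
    noise = dict(sigma=0.0, ar1=0.0, motion_sd=0.0,
                 fd_spike_scans=(), global_spike_scans=())
    noise.update(noise_params or {})
    rng = np.random.default_rng(rng)
    grid = betas.grid
    design = fl.build_design_matrix(session, variant="mvpa", hrf=hrf_params)
    n_scans = design.frame.shape[0]

    name_of = {}
    for (b, reg) in betas.coefficients:
        if reg.startswith("dir_"):
            name_of[f"block{b:02d}_{reg}"] = (b, reg)
        elif reg == "null":
            name_of[f"block{b:02d}_null"] = (b, reg)
        elif reg == "prep":
            name_of[f"block{b:02d}_prep"] = (b, reg)

    n_vox = grid.n_voxels_in_mask
    Y = np.zeros((n_scans, n_vox))
    X = design.frame
    for col in X.columns:
        key = name_of.get(col)
        if key is not None:
            Y += np.outer(X[col].to_numpy(), betas.coefficients[key][grid.brain_mask])

    if noise["sigma"] > 0:
        eps = rng.normal(0.0, noise["sigma"], (n_scans, n_vox))
        phi = noise["ar1"]
        if phi:
            for t in range(1, n_scans):
                eps[t] += phi * eps[t - 1]
        Y += eps

    if noise["motion_sd"] > 0:
        steps = rng.normal(0.0, noise["motion_sd"], (n_scans, 6))
        steps[:, 3:] /= 50.0  # rotations in radians; ~equal FD share on a 50-mm sphere
        motion = np.cumsum(steps, axis=0)
    else:
        motion = np.zeros((n_scans, 6))
    for k in noise["fd_spike_scans"]:
        motion[k:, 0] += 2.0  # 2-mm translation jump at scan k
    nuisance = pd.DataFrame(
        motion, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    )
    global_signal = Y.mean(axis=1)
    if noise["global_spike_scans"]:
        sd = global_signal.std() or 1.0
        mu = global_signal.mean()
        global_signal = global_signal.copy()
        for k in noise["global_spike_scans"]:
            global_signal[k] = mu + 6.0 * sd  # a 6-SD excursion
    nuisance["global_signal"] = global_signal

    series = np.zeros(grid.dims + (n_scans,))
    series[grid.brain_mask, :] = Y.T
    return series, nuisance
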
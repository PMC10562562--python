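"""Erasing-trial mechanics and the erasing-speed performance metric.

A trial presents a line of seven 16-px square dots extending from the
cursor's start position along the trial's visual direction.  The subject
moves the hand; the active context transform maps hand displacement to
cursor displacement; a dot is erased when the cursor center lies strictly
inside its square, and dots can only be erased in order.  A trial ends when
all dots are erased or at the 3.5-s window.

Performance is the erasing speed, dots erased per second of trial duration.
Trials whose cursor path exceeds one and a half line lengths
(1.5 * 7 * 16 = 168 px) are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_design import (
    ContextTransform,
    Direction,
    ROTATION_CONTEXTS,
    MIRROR,
    required_movement,
)

__all__ = [
    "ErasingGeometry",
    "TrialRecord",
    "SubjectPerformance",
    "StraightMover",
    "simulate_erasing_trial",
    "erasing_speed",
    "detect_outlier_trial",
    "summarize_performance",
]


@dataclass(frozen=True)
class ErasingGeometry:
    n_dots: int = 7
    dot_size_px: float = 16.0
    cursor_diameter_px: float = 12.0

    @property
    def line_length_px(self) -> float:
        return self.n_dots * self.dot_size_px

    @property
    def outlier_path_px(self) -> float:
        # "further than one-and-a-half line lengths": 1.5 * 7 * 16 = 168 px
        return 1.5 * self.line_length_px


@dataclass
class TrialRecord:
    block_index: int
    trial_index: int
    context: ContextTransform
    visual_direction: Direction
    movement_direction: Direction
    n_erased: int
    duration_s: float
    path_length_px: float
    outlier: bool

    def __post_init__(self):
        if not 0 <= self.n_erased:
            raise ValueError("n_erased must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class SubjectPerformance:
    """Context-level erasing-speed summaries for one subject (dots/s)."""

    mean_speed_by_context: dict  # context name -> mean speed

    @property
    def mean_rotation_speed(self) -> float:
        return float(
            np.mean([self.mean_speed_by_context[c.name] for c in ROTATION_CONTEXTS])
        )

    @property
    def mean_mirror_speed(self) -> float:
        return float(self.mean_speed_by_context[MIRROR.name])

    @property
    def abs_rotation_mirror_diff(self) -> float:
        return abs(self.mean_rotation_speed - self.mean_mirror_speed)


class StraightMover:
    """Constant-speed hand mover along the required movement direction.

    ``angle_jitter_sd`` (radians) adds per-step directional noise, which
    lengthens the cursor path without much slowing progress along the line;
    large jitter produces the meandering trials the outlier rule targets.
    """

    def __init__(self, speed_px_s: float, angle_jitter_sd: float = 0.0):
        if speed_px_s < 0:
            raise ValueError("speed must be non-negative")
        self.speed_px_s = float(speed_px_s)
        self.angle_jitter_sd = float(angle_jitter_sd)

    def __call__(self, context, visual_direction, geometry, dt, n_steps, rng):
        direction = required_movement(context, visual_direction).unit_vector
        base = np.tile(direction, (n_steps, 1))
        if self.angle_jitter_sd > 0:
            theta = rng.normal(0.0, self.angle_jitter_sd, n_steps)
            cos, sin = np.cos(theta), np.sin(theta)
            base = np.stack(
                [
                    cos * base[:, 0] - sin * base[:, 1],
                    sin * base[:, 0] + cos * base[:, 1],
                ],
                axis=1,
            )
        return base * self.speed_px_s * dt


def simulate_erasing_trial(
    context: ContextTransform,
    visual_direction: Direction,
    mover_policy,
    geometry: ErasingGeometry | None = None,
    rng=None,
    *,
    block_index: int = 0,
    trial_index: int = 0,
    max_duration_s: float = 3.5,
    dt: float = 0.01,
) -> TrialRecord:
    """Run one erasing trial and return its record.

    The policy is called once with (context, visual_direction, geometry, dt,
    n_steps, rng) and must return an (n_steps, 2) array of per-step hand
    displacements in px.  Dot k's center sits ``dot_size_px * (k+1)`` px from
    the start along the visual direction; erasure requires the cursor center
    strictly inside the dot's axis-aligned square, in sequence.
    """
    geometry = geometry or ErasingGeometry()
    rng = np.random.default_rng(rng)
    n_steps = int(round(max_duration_s / dt))
    steps = np.asarray(
        mover_policy(context, visual_direction, geometry, dt, n_steps, rng),
        dtype=float,
    )
    if steps.shape != (n_steps, 2) or not np.all(np.isfinite(steps)):
        raise ValueError("mover policy must return a finite (n_steps, 2) path")

    cursor_steps = steps @ context.matrix.T  # row-vector form of matrix @ v
    cursor = np.vstack([[0.0, 0.0], np.cumsum(cursor_steps, axis=0)])
    path_length = float(np.sum(np.linalg.norm(cursor_steps, axis=1)))

    vis = visual_direction.unit_vector
    half = geometry.dot_size_px / 2.0
    centers = vis[None, :] * geometry.dot_size_px * (
        np.arange(1, geometry.n_dots + 1)[:, None]
    )

    # sequential erasure: dot k can only be hit after dot k-1
    step_norms = np.linalg.norm(cursor_steps, axis=1)
    cum_path = np.concatenate([[0.0], np.cumsum(step_norms)])
    inside = np.all(
        np.abs(cursor[:, None, :] - centers[None, :, :]) < half, axis=2
    )  # (n_steps+1, n_dots)
    n_erased, duration = 0, max_duration_s
    idx = 0
    for k in range(geometry.n_dots):
        hits = np.flatnonzero(inside[idx:, k])
        if hits.size == 0:
            break
        idx += hits[0]
        n_erased += 1
    if n_erased == geometry.n_dots:
        duration = idx * dt
        path_length = float(cum_path[idx])

    return TrialRecord(
        block_index=block_index,
        trial_index=trial_index,
        context=context,
        visual_direction=visual_direction,
        movement_direction=required_movement(context, visual_direction),
        n_erased=n_erased,
        duration_s=duration,
        path_length_px=path_length,
        outlier=detect_outlier_trial(path_length, geometry),
    )


def erasing_speed(trial: TrialRecord) -> float:
    """Dots erased per second: n_erased / trial duration."""
    if trial.duration_s <= 0:
        raise ValueError("trial duration must be positive")
    return trial.n_erased / trial.duration_s


def detect_outlier_trial(path_length_px: float, geometry: ErasingGeometry | None = None) -> bool:
    """True iff the cursor path is strictly longer than 1.5 line lengths."""
    if path_length_px < 0:
        raise ValueError("path length must be non-negative")
    geometry = geometry or ErasingGeometry()
    return path_length_px > geometry.outlier_path_px


def summarize_performance(trials, include_outliers: bool = True) -> SubjectPerformance:
    """Per-context mean erasing speeds and the rotation/mirror summaries.

    Outlier trials enter the behavioral means by default; they are excluded
    only from GLM task regressors, not from performance summaries.
    """
    by_context: dict = {}
    for tr in trials:
        if not include_outliers and tr.outlier:
            continue
        by_context.setdefault(tr.context.name, []).append(erasing_speed(tr))
    missing = [name for name in ("rot_minus90", "rot_plus90", "mirror") if not by_context.get(name)]
    if missing:
        raise ValueError(f"no usable trials for context(s): {', '.join(missing)}")
    return SubjectPerformance(
        mean_speed_by_context={k: float(np.mean(v)) for k, v in by_context.items()}
    )
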
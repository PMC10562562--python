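"""Experimental design for the multi-context visuomotor-adaptation task.

The task asks subjects to erase a 7-dot line with a mouse cursor under one of
three visuomotor mappings per block: a -90 deg rotation, a +90 deg rotation,
or a horizontal mirror reversal.  A session holds 15 blocks (each context
five times, order permuted); each block holds 17 erasing trials whose
direction order follows a type-1 index-1 continuous-carryover (serially
balanced) sequence over the four cardinal directions.

Screen coordinates are left-handed: x grows rightward, y grows downward, so
"up" on screen is (0, -1).  Context matrices map hand displacement to cursor
displacement; the movement a subject must produce for a given on-screen
(visual) direction is therefore the inverse matrix applied to that direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "ContextTransform",
    "ROT_MINUS90",
    "ROT_PLUS90",
    "MIRROR",
    "CONTEXTS",
    "TimingParams",
    "BlockDesign",
    "SessionDesign",
    "generate_carryover_sequence",
    "assign_directions",
    "required_movement",
    "visual_of_movement",
    "apply_context_transform",
    "build_session",
    "CARRYOVER_TEMPLATE",
]


class Direction(Enum):
    """One of the four cardinal erasing directions (screen convention)."""

    UP = "up"
    DOWN = "down"
    LEFT = "left"
    RIGHT = "right"

    @property
    def unit_vector(self) -> np.ndarray:
        return np.array(_DIRECTION_VECTORS[self], dtype=float)

    @property
    def opposite(self) -> "Direction":
        return _OPPOSITES[self]

    @property
    def axis(self) -> frozenset:
        """The unordered {d, -d} axis this direction lies on."""
        return frozenset((self, self.opposite))


# y grows downward on screen, hence up = (0, -1).
_DIRECTION_VECTORS = {
    Direction.UP: (0, -1),
    Direction.DOWN: (0, 1),
    Direction.LEFT: (-1, 0),
    Direction.RIGHT: (1, 0),
}

_OPPOSITES = {
    Direction.UP: Direction.DOWN,
    Direction.DOWN: Direction.UP,
    Direction.LEFT: Direction.RIGHT,
    Direction.RIGHT: Direction.LEFT,
}

DIRECTION_AXES = (
    frozenset((Direction.UP, Direction.DOWN)),
    frozenset((Direction.LEFT, Direction.RIGHT)),
)


def _direction_from_vector(vec: np.ndarray) -> Direction:
    for d, v in _DIRECTION_VECTORS.items():
        if np.array_equal(np.asarray(v), vec):
            return d
    raise ValueError(f"vector {vec!r} is not a cardinal unit vector")


@dataclass(frozen=True)
class ContextTransform:
    """A visuomotor context: a 2x2 integer map from hand to cursor motion."""

    name: str
    matrix: np.ndarray
    inverse: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=int)
        inv = np.asarray(self.inverse, dtype=int)
        if not np.array_equal(m @ inv, np.eye(2, dtype=int)):
            raise ValueError(f"{self.name}: matrix @ inverse is not identity")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "inverse", inv)

    def __hash__(self):
        return hash(self.name)

    def __eq__(self, other):
        return isinstance(other, ContextTransform) and self.name == other.name

    @property
    def is_rotation(self) -> bool:
        return int(round(np.linalg.det(self.matrix))) == 1


# Under the left-handed screen convention a -90 deg (counterclockwise on
# screen) rotation of cursor relative to hand is [[0, 1], [-1, 0]].
ROT_MINUS90 = ContextTransform(
    "rot_minus90", np.array([[0, 1], [-1, 0]]), np.array([[0, -1], [1, 0]])
)
ROT_PLUS90 = ContextTransform(
    "rot_plus90", np.array([[0, -1], [1, 0]]), np.array([[0, 1], [-1, 0]])
)
MIRROR = ContextTransform(
    "mirror", np.array([[-1, 0], [0, 1]]), np.array([[-1, 0], [0, 1]])
)

CONTEXTS = {c.name: c for c in (ROT_MINUS90, ROT_PLUS90, MIRROR)}
ROTATION_CONTEXTS = (ROT_MINUS90, ROT_PLUS90)


@dataclass(frozen=True)
class TimingParams:
    """Session timing constants (seconds unless noted)."""

    trial_window_s: float = 3.5
    iti_s: float = 6.0
    prep_s: float = 8.0
    score_s: float = 4.0
    n_context_reps: int = 5
    n_trials_per_block: int = 17
    tr_s: float = 2.3

    def __post_init__(self):
        for name in ("trial_window_s", "iti_s", "prep_s", "score_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_context_reps < 1 or self.n_trials_per_block < 1:
            raise ValueError("counts must be strictly positive")

    @property
    def n_blocks(self) -> int:
        return 3 * self.n_context_reps

    @property
    def block_duration_s(self) -> float:
        trial = self.trial_window_s + self.iti_s
        return self.prep_s + self.n_trials_per_block * trial + self.score_s


# Printed type-1 index-1 continuous-carryover order template over conditions
# 1..4; each ordered pair of conditions occurs exactly once among the 16
# transitions.
CARRYOVER_TEMPLATE = (1, 2, 2, 3, 4, 4, 1, 1, 3, 3, 1, 4, 2, 4, 3, 2, 1)


def _transition_counts(seq: Sequence[int], n: int) -> np.ndarray:
    counts = np.zeros((n, n), dtype=int)
    for a, b in zip(seq[:-1], seq[1:]):
        counts[a - 1, b - 1] += 1
    return counts


def generate_carryover_sequence(n_conditions: int = 4, rng=None) -> tuple:
    """Return a serially balanced condition sequence of length n**2 + 1.

    Every ordered pair of conditions (self-pairs included) occurs exactly
    once among the n**2 transitions.  For the default ``n_conditions=4`` the
    sequence is a label permutation of the published order template; for
    other n an Eulerian circuit of the complete digraph with self-loops is
    constructed.  Conditions are numbered 1..n.
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be at least 2")
    if not hasattr(rng, "permutation"):
        rng = np.random.default_rng(rng)
    if n_conditions == 4:
        relabel = dict(zip((1, 2, 3, 4), rng.permutation(4) + 1))
        return tuple(int(relabel[c]) for c in CARRYOVER_TEMPLATE)
    return _eulerian_carryover(n_conditions, rng)


def _eulerian_carryover(n: int, rng: np.random.Generator) -> tuple:
    # Hierholzer's algorithm on the complete digraph (self-loops included);
    # every vertex has in-degree = out-degree = n, so an Eulerian circuit
    # exists and visits each ordered pair exactly once.
    succ = {u: list(rng.permutation(n) + 1) for u in range(1, n + 1)}
    start = int(rng.integers(1, n + 1))
    stack, circuit = [start], []
    while stack:
        u = stack[-1]
        if succ[u]:
            stack.append(succ[u].pop())
        else:
            circuit.append(stack.pop())
    seq = tuple(reversed(circuit))
    assert len(seq) == n * n + 1 and seq[0] == seq[-1]
    return seq


def assign_directions(sequence: Sequence[int], rng=None) -> list:
    """Map condition numbers bijectively onto random directions."""
    if not hasattr(rng, "permutation"):
        rng = np.random.default_rng(rng)
    labels = sorted(set(sequence))
    directions = list(Direction)
    if len(labels) > len(directions):
        raise ValueError("more condition labels than directions")
    order = rng.permutation(len(directions))[: len(labels)]
    mapping = {lab: directions[i] for lab, i in zip(labels, order)}
    return [mapping[c] for c in sequence]


def required_movement(context: ContextTransform, visual: Direction) -> Direction:
    """Hand-movement direction that produces cursor motion ``visual``."""
    return _direction_from_vector(
        context.inverse @ np.asarray(_DIRECTION_VECTORS[visual])
    )


def visual_of_movement(context: ContextTransform, movement: Direction) -> Direction:
    """Cursor (visual) direction produced by hand motion ``movement``."""
    return _direction_from_vector(
        context.matrix @ np.asarray(_DIRECTION_VECTORS[movement])
    )


def apply_context_transform(
    context: ContextTransform, hand_displacement
) -> np.ndarray:
    """Map a hand displacement (px) to the cursor displacement it produces."""
    v = np.asarray(hand_displacement, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("hand displacement must be finite")
    return context.matrix @ v


@dataclass
class BlockDesign:
    block_index: int
    context: ContextTransform
    trial_sequence: list  # 17 Direction labels
    onset_s: float

    @property
    def repetition(self) -> int:
        """Set by build_session: 0-based repetition index of this context."""
        return self._repetition

    @repetition.setter
    def repetition(self, value: int):
        self._repetition = value


@dataclass
class SessionDesign:
    """Full per-subject timeline: blocks, trial sequences and event onsets."""

    blocks: list
    block_order_seed: int
    timing: TimingParams
    events: list = field(default_factory=list)  # (onset, dur, type, block, trial)

    @property
    def n_scans(self) -> int:
        end = max(on + du for on, du, *_ in self.events)
        return int(np.ceil((end + 10.0) / self.timing.tr_s))

    def blocks_of_context(self, context: ContextTransform) -> list:
        return [b for b in self.blocks if b.context == context]

    def to_events_frame(self) -> pd.DataFrame:
        """Tab-separable events table (BIDS-events-like dialect)."""
        rows = []
        for onset, dur, etype, b_idx, t_idx in self.events:
            block = self.blocks[b_idx]
            if etype == "trial" and t_idx is not None:
                vis = block.trial_sequence[t_idx]
                mov = required_movement(block.context, vis)
                vis_name, mov_name = vis.value, mov.value
            else:
                vis_name = mov_name = "n/a"
            rows.append(
                dict(
                    onset=round(onset, 3),
                    duration=round(dur, 3),
                    trial_type=etype,
                    block=b_idx,
                    context=block.context.name,
                    visual_direction=vis_name,
                    movement_direction=mov_name,
                )
            )
        return pd.DataFrame(rows)


def build_session(timing: TimingParams | None = None, rng=None) -> SessionDesign:
    """Assemble one session: permuted block order, fresh carryover sequences,
    and prep/trial/score/termination event onsets."""
    timing = timing or TimingParams()
    seed_rng = np.random.default_rng(rng)
    block_order_seed = int(seed_rng.integers(0, 2**31 - 1))
    rng = np.random.default_rng(block_order_seed)

    contexts = [c for c in CONTEXTS.values() for _ in range(timing.n_context_reps)]
    order = rng.permutation(len(contexts))
    blocks, events = [], []
    rep_counter = {name: 0 for name in CONTEXTS}
    t = 0.0
    for b_idx, ctx_i in enumerate(order):
        context = contexts[ctx_i]
        seq = generate_carryover_sequence(4, rng)
        dirs = assign_directions(seq, rng)
        if timing.n_trials_per_block != len(dirs):
            # non-default block lengths truncate/tile the balanced sequence
            reps = -(-timing.n_trials_per_block // len(dirs))
            dirs = (dirs * reps)[: timing.n_trials_per_block]
        block = BlockDesign(b_idx, context, dirs, onset_s=t)
        block.repetition = rep_counter[context.name]
        rep_counter[context.name] += 1
        blocks.append(block)

        events.append((t, timing.prep_s, "prep", b_idx, None))
        t += timing.prep_s
        for t_idx in range(timing.n_trials_per_block):
            events.append((t, timing.trial_window_s, "trial", b_idx, t_idx))
            t += timing.trial_window_s + timing.iti_s
        events.append((t, timing.score_s, "score", b_idx, None))
        t += timing.score_s
        events.append((t, 0.0, "termination", b_idx, None))
    return SessionDesign(blocks, block_order_seed, timing, events)
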
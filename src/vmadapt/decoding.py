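"""Conjunctional cross-context searchlight decoding.

The core idea: train a linear SVM on one set of condition cells and test on
another, chosen so that generalization can only be supported by the targeted
representation level.

* Visual analysis — train up-vs-down (or left-vs-right) *visual* directions
  in one context, test the same visual labels in another context; the
  paired movement directions differ between train and test, so neither
  movement nor context information can carry over.  12 directed pairs.
* Movement analysis — the same with visual and movement roles swapped.
  12 directed pairs.
* Context analyses — train on one cell per context matched on one level
  (e.g., the same visual direction in both contexts), test on cells matched
  on the other level (the same movement direction), with the matched
  directions chosen so no visual or movement label repeats between train
  and test for a class.  8 unordered set-pairs for -90 vs +90, 16 for
  rotation vs mirror (8 per rotation context); every set-pair is evaluated
  in both train/test directions and the two accuracies averaged.

Erasing-context analyses subdivide each pair with leave-two-block-out CV
(5 folds); the correlation-analysis variant skips the subdivision.
Preparation-period context decoding uses leave-two-out CV over repetition
pairs (5 folds; 10 for rotation-vs-mirror).

Features are per-block GLM direction betas inside a 9-mm searchlight
sphere; each sphere's accuracy is averaged over pairs/folds and reported
as accuracy minus the 50% binary chance level, in percentage points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC, _libsvm

_libsvm.set_verbosity_wrap(0)

from .synthetic import SubjectDataset, VolumeGrid
from .task_design import (
    CONTEXTS,
    MIRROR,
    ROT_MINUS90,
    ROT_PLUS90,
    Direction,
    required_movement,
    visual_of_movement,
)

__all__ = [
    "ConditionKey",
    "TrainTestPair",
    "AccuracyMap",
    "ClassifierConfig",
    "ANALYSES",
    "enumerate_pairs",
    "leave_two_block_out_folds",
    "searchlight_spheres",
    "classify",
    "run_searchlight_decoding",
    "preparation_decoding",
    "pairs_table",
]

ANALYSES = (
    "visual",
    "movement",
    "context_rot_rot",
    "context_rot_mirror",
    "prep_rot_rot",
    "prep_rot_mirror",
)


@dataclass(frozen=True)
class ConditionKey:
    """One condition cell: a context plus a direction at a labeled level.

    ``level`` is "visual" or "movement"; the direction at the other level
    follows from the context transform.  Preparation cells carry no
    direction (level "prep").
    """

    context: str
    level: str
    direction: str | None

    @property
    def visual_direction(self) -> Direction | None:
        if self.level == "prep":
            return None
        d = Direction(self.direction)
        if self.level == "visual":
            return d
        return visual_of_movement(CONTEXTS[self.context], d)

    @property
    def movement_direction(self) -> Direction | None:
        if self.level == "prep":
            return None
        d = Direction(self.direction)
        if self.level == "movement":
            return d
        return required_movement(CONTEXTS[self.context], d)


@dataclass
class TrainTestPair:
    """One cross-decoding unit: labeled train cells and labeled test cells.

    ``bidirectional`` pairs are evaluated with either side as the training
    set and the two accuracies averaged (the Fig-3 counting convention).
    """

    analysis: str
    train: list  # [(ConditionKey, class_label)]
    test: list
    bidirectional: bool = False

    def evaluation_orders(self):
        yield self.train, self.test
        if self.bidirectional:
            yield self.test, self.train


@dataclass
class AccuracyMap:
    grid: VolumeGrid
    values: np.ndarray  # accuracy minus chance, percentage points; NaN off-mask
    analysis: str
    subject_id: str


@dataclass(frozen=True)
class ClassifierConfig:
    C: float = 1.0
    center_features: bool = True


_AXES = (
    (Direction.UP, Direction.DOWN),
    (Direction.LEFT, Direction.RIGHT),
)


def _direction_pairs_differ(c_train, c_test, level, axis) -> bool:
    """Does every class label carry a different other-level direction
    between the two contexts?"""
    for d in axis:
        k_tr = ConditionKey(c_train.name, level, d.value)
        k_te = ConditionKey(c_test.name, level, d.value)
        if level == "visual":
            if k_tr.movement_direction == k_te.movement_direction:
                return False
        else:
            if k_tr.visual_direction == k_te.visual_direction:
                return False
    return True


def _level_pairs(analysis: str, level: str, directed: bool) -> list:
    """Fig-2 style pairs: same-label train/test across different contexts."""
    pairs = []
    contexts = list(CONTEXTS.values())
    for c_train, c_test in itertools.permutations(contexts, 2):
        if not directed and c_train.name > c_test.name:
            continue
        for axis in _AXES:
            if not _direction_pairs_differ(c_train, c_test, level, axis):
                continue
            train = [(ConditionKey(c_train.name, level, d.value), d.value) for d in axis]
            test = [(ConditionKey(c_test.name, level, d.value), d.value) for d in axis]
            pairs.append(
                TrainTestPair(analysis, train, test, bidirectional=not directed)
            )
    return pairs


def _context_pairs_for(analysis, ctx_a, ctx_b, directed) -> list:
    """Fig-3 style pairs for one context contrast: train cells matched on
    one level, test cells matched on the other, with no visual or movement
    label shared between a class's train and test cells."""
    pairs = []
    for v in Direction:
        # train matched on visual direction v
        train = [
            (ConditionKey(ctx_a.name, "visual", v.value), ctx_a.name),
            (ConditionKey(ctx_b.name, "visual", v.value), ctx_b.name),
        ]
        excluded = {
            required_movement(ctx_a, v),
            required_movement(ctx_b, v),
        }
        for m in Direction:
            if m in excluded:
                continue
            test = [
                (ConditionKey(ctx_a.name, "movement", m.value), ctx_a.name),
                (ConditionKey(ctx_b.name, "movement", m.value), ctx_b.name),
            ]
            # the matched-movement cells must not reuse the train visual label
            if any(k.visual_direction == v for k, _ in test):
                continue
            pairs.append(TrainTestPair(analysis, train, test, bidirectional=True))
    if directed:
        out = []
        for p in pairs:
            out.append(TrainTestPair(analysis, p.train, p.test))
            out.append(TrainTestPair(analysis, p.test, p.train))
        return out
    return pairs


def enumerate_pairs(analysis: str, directed: bool | None = None) -> list:
    """Enumerate the train/test set pairs of one decoding analysis.

    With ``directed=None`` each analysis follows its own published counting
    convention: the visual and movement analyses list directed pairs (12
    each); the context analyses list unordered, bidirectionally evaluated
    set-pairs (8 for -90 vs +90; 16 for rotation vs mirror).  Pass
    ``directed=True``/``False`` to force one convention.
    """
    if analysis == "visual":
        return _level_pairs(analysis, "visual", True if directed is None else directed)
    if analysis == "movement":
        return _level_pairs(analysis, "movement", True if directed is None else directed)
    if analysis == "context_rot_rot":
        return _context_pairs_for(
            analysis, ROT_MINUS90, ROT_PLUS90, bool(directed)
        )
    if analysis == "context_rot_mirror":
        return _context_pairs_for(
            analysis, ROT_MINUS90, MIRROR, bool(directed)
        ) + _context_pairs_for(analysis, ROT_PLUS90, MIRROR, bool(directed))
    raise ValueError(f"unknown analysis: {analysis!r}")


def audit_pair(pair: TrainTestPair) -> None:
    """Assert the leakage guarantees of one pair (exhaustive, per class)."""
    train_cells = {(k.context, k.level, k.direction) for k, _ in pair.train}
    test_cells = {(k.context, k.level, k.direction) for k, _ in pair.test}
    if train_cells & test_cells:
        raise AssertionError("train and test share a condition cell")
    by_label_train = {lab: k for k, lab in pair.train}
    by_label_test = {lab: k for k, lab in pair.test}
    if pair.analysis in ("visual", "movement"):
        for lab in by_label_train:
            k_tr, k_te = by_label_train[lab], by_label_test[lab]
            if k_tr.context == k_te.context:
                raise AssertionError("train and test contexts must differ")
            if pair.analysis == "visual":
                if k_tr.movement_direction == k_te.movement_direction:
                    raise AssertionError("movement label leaks")
            else:
                if k_tr.visual_direction == k_te.visual_direction:
                    raise AssertionError("visual label leaks")
    else:
        for lab in by_label_train:
            k_tr, k_te = by_label_train[lab], by_label_test[lab]
            if k_tr.visual_direction == k_te.visual_direction:
                raise AssertionError("visual label leaks")
            if k_tr.movement_direction == k_te.movement_direction:
                raise AssertionError("movement label leaks")
        for side in (pair.train, pair.test):
            levels = {k.level for k, _ in side}
            dirs = {k.direction for k, _ in side}
            if len(levels) != 1 or len(dirs) != 1:
                raise AssertionError("context-analysis side must be matched on one level")


def leave_two_block_out_folds(pair: TrainTestPair, n_reps: int = 5) -> list:
    """Five CV folds: fold k tests on the k-th repetition block of each
    class and trains on the remaining repetitions."""
    folds = []
    for k in range(n_reps):
        test_reps = (k,)
        train_reps = tuple(r for r in range(n_reps) if r != k)
        folds.append((train_reps, test_reps))
    return folds


def searchlight_sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets within center-to-center distance <= radius."""
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    r_vox = int(np.floor(radius_mm / voxel_size_mm))
    offs = []
    for dx in range(-r_vox, r_vox + 1):
        for dy in range(-r_vox, r_vox + 1):
            for dz in range(-r_vox, r_vox + 1):
                if (dx * dx + dy * dy + dz * dz) * voxel_size_mm**2 <= radius_mm**2:
                    offs.append((dx, dy, dz))
    return np.array(offs, dtype=int)


def searchlight_spheres(grid: VolumeGrid, radius_mm: float = 9.0, centers=None):
    """Yield (center_flat_index, in-mask voxel flat indices) per sphere.

    Centers iterate over in-mask voxels (optionally restricted to the
    boolean volume ``centers``); sphere members are clipped to the grid and
    the brain mask.  Flat indices are positions within the mask's own voxel
    ordering (C order), matching the feature matrices used by the
    searchlight driver.
    """
    mask = grid.brain_mask
    dims = np.array(grid.dims)
    offsets = searchlight_sphere_offsets(radius_mm, grid.voxel_size_mm)
    mask_pos = -np.ones(grid.dims, dtype=int)
    mask_pos[mask] = np.arange(int(mask.sum()))
    center_mask = mask if centers is None else (mask & centers)
    for c in np.argwhere(center_mask):
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < dims), axis=1)
        pts = pts[ok]
        pos = mask_pos[pts[:, 0], pts[:, 1], pts[:, 2]]
        yield int(mask_pos[tuple(c)]), pos[pos >= 0]


def classify(
    train_features,
    train_labels,
    test_features,
    test_labels,
    config: ClassifierConfig | None = None,
) -> float:
    """Soft-margin linear SVM accuracy on the test set (libsvm backend)."""
    config = config or ClassifierConfig()
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.asarray(test_features, dtype=float)
    ytr = np.asarray(train_labels)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set must contain two classes")
    if config.center_features:
        mu = Xtr.mean(axis=0)
        Xtr = Xtr - mu
        Xte = Xte - mu
    clf = SVC(kernel="linear", C=config.C)
    clf.fit(Xtr, ytr)
    return float(np.mean(clf.predict(Xte) == np.asarray(test_labels)))


def _cell_features(subject: SubjectDataset, key: ConditionKey) -> np.ndarray:
    """(n_reps, n_mask_voxels) features for one condition cell, ordered by
    repetition index."""
    grid = subject.betas.grid
    ctx = CONTEXTS[key.context]
    blocks = sorted(subject.session.blocks_of_context(ctx), key=lambda b: b.repetition)
    rows = []
    for b in blocks:
        if key.level == "prep":
            vol = subject.betas.prep_beta(b.block_index)
        else:
            vol = subject.betas.direction_beta(b.block_index, key.visual_direction)
        rows.append(vol[grid.brain_mask])
    return np.vstack(rows)


def _svm_accuracy(Xtr, ytr, Xte, yte, config: ClassifierConfig) -> float:
    """Linear soft-margin SVM accuracy via the libsvm backend directly.

    Same solver and results as :func:`classify` (sklearn's SVC wraps this
    binding) but without per-call estimator overhead; the searchlight
    driver runs millions of tiny fits.
    """
    if config.center_features:
        mu = Xtr.mean(axis=0)
        Xtr = Xtr - mu
        Xte = Xte - mu
    model = _libsvm.fit(
        np.ascontiguousarray(Xtr), ytr, svm_type=0, kernel="linear", C=config.C
    )
    pred = _libsvm.predict(
        np.ascontiguousarray(Xte), *model[:7], svm_type=0, kernel="linear"
    )
    return float(np.mean(pred == yte))


def _compile_evaluations(pairs, folds, n_reps):
    """Flatten pairs x directions x folds into reusable evaluation specs.

    Each entry: (pair_id, train_rows, test_rows, ytr, yte) where *_rows is
    a list of (ConditionKey, rep-row list) and the label vectors are libsvm
    float class codes aligned with those rows.
    """
    compiled = []
    all_reps = list(range(n_reps))
    for pid, pair in enumerate(pairs):
        for train_side, test_side in pair.evaluation_orders():
            lab01 = {
                lab: float(i)
                for i, lab in enumerate(sorted({lab for _, lab in train_side}))
            }
            for train_reps, test_reps in folds or [(all_reps, all_reps)]:
                tr = [(k, list(train_reps)) for k, _ in train_side]
                te = [(k, list(test_reps)) for k, _ in test_side]
                ytr = np.concatenate(
                    [[lab01[lab]] * len(train_reps) for _, lab in train_side]
                )
                yte = np.concatenate(
                    [[lab01[lab]] * len(test_reps) for _, lab in test_side]
                )
                compiled.append((pid, tr, te, ytr, yte))
    return compiled


def _searchlight(subject, pairs, folds, config, radius_mm, centers_mask=None):
    grid = subject.betas.grid
    keys = {k for p in pairs for k, _ in itertools.chain(p.train, p.test)}
    features = {k: _cell_features(subject, k) for k in keys}
    n_reps = next(iter(features.values())).shape[0]
    compiled = _compile_evaluations(pairs, folds, n_reps)

    n_pairs = len(pairs)
    n_mask = grid.n_voxels_in_mask
    out = np.full(n_mask, np.nan)
    pair_acc = np.empty(n_pairs)
    pair_cnt = np.empty(n_pairs)
    for center, sphere in searchlight_spheres(grid, radius_mm, centers_mask):
        sub = {k: f[:, sphere] for k, f in features.items()}
        pair_acc[:] = 0.0
        pair_cnt[:] = 0
        for pid, tr, te, ytr, yte in compiled:
            Xtr = np.concatenate([sub[k][rows] for k, rows in tr])
            Xte = np.concatenate([sub[k][rows] for k, rows in te])
            pair_acc[pid] += _svm_accuracy(Xtr, ytr, Xte, yte, config)
            pair_cnt[pid] += 1
        # per-pair averaging first, then across pairs, then minus chance
        out[center] = (np.mean(pair_acc / pair_cnt) - 0.5) * 100.0
    vol = np.full(grid.dims, np.nan)
    vol[grid.brain_mask] = out
    return vol


def run_searchlight_decoding(
    subject: SubjectDataset,
    analysis: str,
    config: ClassifierConfig | None = None,
    *,
    radius_mm: float = 9.0,
    subdivide_folds: bool = True,
    n_reps: int | None = None,
    centers_mask: np.ndarray | None = None,
) -> AccuracyMap:
    """Whole-brain searchlight accuracy-minus-chance map for one analysis.

    Context analyses subdivide every pair with leave-two-block-out CV
    unless ``subdivide_folds=False`` (the correlation-analysis variant).
    ``centers_mask`` restricts sphere centers to a region of interest
    (features still come from the full sphere); off-center voxels stay NaN.
    """
    config = config or ClassifierConfig()
    n_reps = n_reps or subject.session.timing.n_context_reps
    pairs = enumerate_pairs(analysis)
    if analysis in ("context_rot_rot", "context_rot_mirror") and subdivide_folds:
        folds = leave_two_block_out_folds(pairs[0], n_reps)
    else:
        folds = None
    values = _searchlight(subject, pairs, folds, config, radius_mm, centers_mask)
    tag = analysis if subdivide_folds else f"{analysis}_nofold"
    return AccuracyMap(subject.betas.grid, values, tag, subject.subject_id)


def _prep_pairs(contrast: str) -> list:
    if contrast == "rot_rot":
        contrasts = [(ROT_MINUS90, ROT_PLUS90)]
    elif contrast == "rot_mirror":
        contrasts = [(ROT_MINUS90, MIRROR), (ROT_PLUS90, MIRROR)]
    else:
        raise ValueError(f"unknown preparation contrast: {contrast!r}")
    pairs = []
    for ca, cb in contrasts:
        train = [
            (ConditionKey(ca.name, "prep", None), ca.name),
            (ConditionKey(cb.name, "prep", None), cb.name),
        ]
        pairs.append(TrainTestPair(f"prep_{contrast}", train, train))
    return pairs


def preparation_decoding(
    subject: SubjectDataset,
    contrast: str,
    config: ClassifierConfig | None = None,
    *,
    radius_mm: float = 9.0,
) -> AccuracyMap:
    """Context decoding from preparation-period betas.

    Leave-two-out CV over repetition pairs: 5 folds for -90 vs +90; for
    rotation vs mirror both -90-vs-mirror and +90-vs-mirror schemes run and
    all 10 fold accuracies are averaged.
    """
    config = config or ClassifierConfig()
    n_reps = subject.session.timing.n_context_reps
    grid = subject.betas.grid
    pairs = _prep_pairs(contrast)
    folds = leave_two_block_out_folds(pairs[0], n_reps)

    keys = {k for p in pairs for k, _ in p.train}
    features = {k: _cell_features(subject, k) for k in keys}
    n_mask = grid.n_voxels_in_mask
    out = np.full(n_mask, np.nan)
    for center, sphere in searchlight_spheres(grid, radius_mm):
        accs = []
        for pair in pairs:
            feats = [(features[k][:, sphere], lab) for k, lab in pair.train]
            for train_reps, test_reps in folds:
                Xtr = np.vstack([f[list(train_reps)] for f, _ in feats])
                ytr = np.concatenate([[lab] * len(train_reps) for _, lab in feats])
                Xte = np.vstack([f[list(test_reps)] for f, _ in feats])
                yte = np.concatenate([[lab] * len(test_reps) for _, lab in feats])
                accs.append(classify(Xtr, ytr, Xte, yte, config))
        out[center] = (np.mean(accs) - 0.5) * 100.0
    vol = np.full(grid.dims, np.nan)
    vol[grid.brain_mask] = out
    return AccuracyMap(grid, vol, f"prep_{contrast}", subject.subject_id)


def pairs_table(analysis: str):
    """Audit table of one analysis's pairs (tab-separable DataFrame)."""
    import pandas as pd

    rows = []
    for i, pair in enumerate(enumerate_pairs(analysis)):
        for role, side in (("train", pair.train), ("test", pair.test)):
            for key, label in side:
                rows.append(
                    dict(
                        analysis=analysis,
                        pair=i,
                        role=role,
                        context=key.context,
                        level=key.level,
                        direction=key.direction,
                        class_label=label,
                        bidirectional=pair.bidirectional,
                    )
                )
    return pd.DataFrame(rows)
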
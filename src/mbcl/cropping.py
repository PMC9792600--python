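"""Sliding-window cropping and leakage-safe trial-level splitting.

Cropped training multiplies the number of training samples by cutting each
trial into overlapping windows; every crop inherits its parent trial's label
and, crucially, its parent trial's train/test membership, so no trial ever
contributes crops to both sides of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .signals import EpochSet

__all__ = ["CropSet", "SplitPlan", "slide", "make_folds", "session_split",
           "crops_for_split"]


@dataclass
class CropSet:
    """Windowed sub-epochs carrying parent-trial indices."""

    crops: np.ndarray          # crop x channel x sample
    labels: np.ndarray         # per-crop class index
    parent_trial: np.ndarray   # per-crop trial index
    fs: float
    window_s: float
    stride_s: float
    n_classes: int

    def __post_init__(self):
        self.crops = np.asarray(self.crops)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.parent_trial = np.asarray(self.parent_trial, dtype=np.int64)
        if not (len(self.crops) == len(self.labels) == len(self.parent_trial)):
            raise ValueError("crops, labels and parent_trial must align")

    @property
    def n_crops(self) -> int:
        return len(self.crops)

    def subset(self, mask: np.ndarray) -> "CropSet":
        return CropSet(self.crops[mask], self.labels[mask],
                       self.parent_trial[mask], self.fs,
                       self.window_s, self.stride_s, self.n_classes)


@dataclass
class SplitPlan:
    """Per-trial train/test membership for every (repetition, fold) cell."""

    n_trials: int
    n_folds: int
    n_repetitions: int
    seed: int | None
    # (rep, fold) -> (train trial indices, test trial indices)
    assignments: dict = field(default_factory=dict)

    def train_test(self, rep: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        return self.assignments[(rep, fold)]

    def cells(self):
        return sorted(self.assignments.keys())

    def to_table(self) -> str:
        """Plain-text audit table: trial_id, repetition, fold, role."""
        lines = ["trial_id\trepetition\tfold\trole"]
        for (rep, fold), (tr, te) in sorted(self.assignments.items()):
            for t in tr:
                lines.append(f"{t}\t{rep}\t{fold}\ttrain")
            for t in te:
                lines.append(f"{t}\t{rep}\t{fold}\ttest")
        return "\n".join(lines) + "\n"


def crop_count(n_samples: int, window: int, stride: int) -> int:
    """floor((L - W)/S) + 1 crops fit in a trial of L samples."""
    if window > n_samples:
        raise ValueError("window longer than trial")
    return (n_samples - window) // stride + 1


def slide(epochs: EpochSet, window_s: float, stride_s: float,
          stride_rounding: str = "nearest") -> CropSet:
    """Cut every trial into crops of ``window_s`` seconds every ``stride_s``.

    Fractional strides in samples are rounded to the nearest integer sample
    by default (``stride_rounding="floor"`` truncates instead). The first
    crop starts at sample 0; crops are ordered by (trial, offset).
    """
    if stride_s <= 0:
        raise ValueError("stride must be positive")
    n_trials, _, n_samples = epochs.epochs.shape
    window = int(round(window_s * epochs.fs))
    raw_stride = stride_s * epochs.fs
    stride = int(raw_stride) if stride_rounding == "floor" \
        else int(round(raw_stride))
    stride = max(stride, 1)
    if window > n_samples:
        raise ValueError(
            f"window of {window} samples exceeds trial length {n_samples}")
    per_trial = crop_count(n_samples, window, stride)
    offsets = np.arange(per_trial) * stride
    crops = np.stack([epochs.epochs[t, :, o:o + window]
                      for t in range(n_trials) for o in offsets])
    labels = np.repeat(epochs.labels, per_trial)
    parents = np.repeat(np.arange(n_trials), per_trial)
    return CropSet(crops=crops, labels=labels, parent_trial=parents,
                   fs=epochs.fs, window_s=window_s, stride_s=stride_s,
                   n_classes=epochs.n_classes)


def make_folds(epochs: EpochSet, k: int = 5, reps: int = 5,
               seed: int = 0) -> SplitPlan:
    """Repeated stratified k-fold at the trial level, independently
    reshuffled per repetition; deterministic under the seed."""
    labels = epochs.labels
    counts = np.bincount(labels, minlength=epochs.n_classes)
    for cls, cnt in enumerate(counts):
        if 0 < cnt < k:
            raise ValueError(
                f"class {cls} has only {cnt} trials, fewer than k={k}")
    plan = SplitPlan(n_trials=epochs.n_trials, n_folds=k,
                     n_repetitions=reps, seed=seed)
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + 1000 * rep)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)),
                                                  labels)):
            plan.assignments[(rep, fold)] = (tr.copy(), te.copy())
    return plan


def session_split(train_epochs: EpochSet, test_epochs: EpochSet) -> SplitPlan:
    """Fixed split for session-based protocols: every first-session trial
    trains, every second-session trial tests.  Trial indices refer to the
    concatenation (train session first)."""
    if train_epochs.n_trials == 0 or test_epochs.n_trials == 0:
        raise ValueError("both sessions must contain trials")
    if train_epochs.epochs.shape[1:] != test_epochs.epochs.shape[1:]:
        raise ValueError("sessions differ in channel/sample geometry")
    if train_epochs.n_classes != test_epochs.n_classes:
        raise ValueError("sessions differ in class set")
    n_tr, n_te = train_epochs.n_trials, test_epochs.n_trials
    plan = SplitPlan(n_trials=n_tr + n_te, n_folds=1, n_repetitions=1,
                     seed=None)
    plan.assignments[(0, 0)] = (np.arange(n_tr), np.arange(n_tr, n_tr + n_te))
    return plan


def crops_for_split(crops: CropSet, plan: SplitPlan, rep: int,
                    fold: int) -> tuple[CropSet, CropSet]:
    """Route crops by their parent trial's membership in the given cell."""
    train_trials, test_trials = plan.train_test(rep, fold)
    known = set(train_trials) | set(test_trials)
    present = set(crops.parent_trial.tolist())
    unknown = present - known
    if unknown:
        raise ValueError(f"crops reference trials absent from the plan: "
                         f"{sorted(unknown)[:5]}")
    tr_mask = np.isin(crops.parent_trial, train_trials)
    te_mask = np.isin(crops.parent_trial, test_trials)
    return crops.subset(tr_mask), crops.subset(te_mask)
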
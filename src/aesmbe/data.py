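"""EEG runs, 1 s windows, per-window normalization and run-wise folds.

The atomic unit for train/test splitting is the *run* (one continuous
recording).  Windows are cut only after a run-level split is fixed, so
temporally correlated samples can never straddle the two sides of a fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TASKS",
    "OTHER_SUBJECT",
    "PRETRAIN_CLASSES",
    "Run",
    "Window",
    "SplitTemplate",
    "PRETRAINING_TEMPLATE",
    "REGISTRATION_TEMPLATE",
    "normalize_window",
    "degenerate_channels",
    "segment_run",
    "make_folds",
    "check_no_leakage",
    "task_for_run_index",
    "read_edf_run",
    "relabel_for_pretraining",
]

#: The three task conditions of the reference protocol.
TASKS = ("rest", "motor_execution", "motor_imagery")

#: Label used for negative (non-target subject) samples in pre-training.
OTHER_SUBJECT = "other_subject"

#: Canonical 4-class label order for the pre-training stage.
PRETRAIN_CLASSES = TASKS + (OTHER_SUBJECT,)


@dataclass
class Run:
    """One continuous recording session with a single task label."""

    subject_id: int
    run_index: int  # 1-based, matching the reference dataset's numbering
    task: str
    data: np.ndarray  # channels x samples
    fs: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("run data must be a non-empty channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Window:
    """One normalized segment (channels x H) with inherited labels."""

    data: np.ndarray
    subject_id: int
    task: str
    run_index: int
    window_index: int
    degenerate: np.ndarray = field(default=None)  # bool per channel

    @property
    def H(self) -> int:
        return self.data.shape[1]


def degenerate_channels(raw: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Boolean mask of channels whose within-window std is below ``eps``."""
    raw = np.asarray(raw, dtype=np.float64)
    return raw.std(axis=1) < eps


def normalize_window(raw: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Zero-mean unit-variance scaling per channel, within one window.

    The mean and the population standard deviation are computed inside the
    window only; no statistics are shared across windows, runs, or between
    train and test data.  Channels with (near-)zero variance are returned
    as all zeros instead of NaN; use :func:`degenerate_channels` to flag
    them.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[1] < 2:
        raise ValueError("window must be channels x H with H >= 2")
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)  # population (divide by H)
    out = np.zeros_like(raw)
    ok = sd[:, 0] >= eps
    out[ok] = (raw[ok] - mu[ok]) / sd[ok]
    return out


def segment_run(run: Run, H: int = 160) -> list[Window]:
    """Cut a run into floor(samples/H) non-overlapping normalized windows.

    Each window inherits the parent run's subject, task and run index;
    trailing samples that do not fill a whole window are discarded.
    """
    n = run.n_samples // H
    if n == 0:
        warnings.warn(
            f"run {run.run_index} of subject {run.subject_id} has "
            f"{run.n_samples} samples (< H={H}); no windows produced",
            stacklevel=2,
        )
        return []
    windows = []
    for w in range(n):
        raw = run.data[:, w * H : (w + 1) * H]
        windows.append(
            Window(
                data=normalize_window(raw),
                subject_id=run.subject_id,
                task=run.task,
                run_index=run.run_index,
                window_index=w,
                degenerate=degenerate_channels(raw),
            )
        )
    return windows


# --------------------------------------------------------------------- folds
@dataclass(frozen=True)
class SplitTemplate:
    """Fixed run-level fold template for one training stage."""

    stage: str  # "pretraining" | "registration"
    folds: tuple  # of (train_run_indices, test_run_indices) tuples

    def __post_init__(self):
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError(f"{self.stage} template: train/test runs overlap")


def _template(stage: str, test_sets: list[set], all_runs=range(1, 15)) -> SplitTemplate:
    folds = tuple(
        (tuple(sorted(set(all_runs) - t)), tuple(sorted(t))) for t in test_sets
    )
    return SplitTemplate(stage=stage, folds=folds)


#: Default 3-fold template for the pre-training stage: 5 runs held out per
#: fold, the remaining 9 runs train.  Rest runs (1-2) deliberately appear in
#: some test sets so resting data is also evaluated under run-wise hold-out.
PRETRAINING_TEMPLATE = _template(
    "pretraining", [{1, 2, 5, 9, 13}, {3, 6, 10, 11, 14}, {4, 7, 8, 12, 13}]
)

#: Default 3-fold template for the registration stage: 4 runs held out per
#: fold, the remaining 10 runs train.
REGISTRATION_TEMPLATE = _template(
    "registration", [{3, 7, 11, 14}, {4, 8, 12, 13}, {5, 6, 9, 10}]
)


def make_folds(
    runs: list[Run], template: SplitTemplate, H: int = 160
) -> list[tuple[list[Window], list[Window]]]:
    """Realize a template into (train windows, test windows) per fold.

    Runs are partitioned first; windowing happens strictly afterwards, so a
    window can only ever belong to one side of a fold.
    """
    available = {r.run_index for r in runs}
    realized = []
    for train_idx, test_idx in template.folds:
        missing = (set(train_idx) | set(test_idx)) - available
        if missing:
            raise ValueError(
                f"{template.stage} template references runs {sorted(missing)} "
                f"absent from the available set {sorted(available)}"
            )
        train_w, test_w = [], []
        for r in runs:
            if r.run_index in test_idx:
                test_w.extend(segment_run(r, H))
            elif r.run_index in train_idx:
                train_w.extend(segment_run(r, H))
        realized.append((train_w, test_w))
    return realized


def check_no_leakage(
    train: list[Window], test: list[Window]
) -> set[tuple[int, int]]:
    """Return the set of (subject, run) pairs present on *both* sides.

    An empty set means the fold is leakage-free.
    """
    train_runs = {(w.subject_id, w.run_index) for w in train}
    test_runs = {(w.subject_id, w.run_index) for w in test}
    return train_runs & test_runs


# ----------------------------------------------------------------------- EDF
def task_for_run_index(run_index: int) -> str:
    """Task label convention of the reference motor-imagery dataset.

    Runs 1-2 are resting-state recordings; from run 3 on, odd runs are
    motor execution and even runs motor imagery.
    """
    if run_index in (1, 2):
        return "rest"
    return "motor_execution" if run_index % 2 == 1 else "motor_imagery"


def read_edf_run(path, subject_id: int, run_index: int) -> Run:
    """Load one EDF file as a :class:`Run` (channel order as stored)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various subclasses
        raise IOError(f"could not parse EDF file {path}: {exc}") from exc
    data = raw.get_data()
    if data.shape[0] < 1:
        raise IOError(f"EDF file {path} contains no signals")
    return Run(
        subject_id=subject_id,
        run_index=run_index,
        task=task_for_run_index(run_index),
        data=data,
        fs=float(raw.info["sfreq"]),
    )


# ------------------------------------------------------- pre-training labels
def relabel_for_pretraining(
    windows: list[Window], target_subject: int, seed: int = 0
) -> tuple[list[Window], np.ndarray]:
    """4-class labeling for subject-specific pre-training.

    The target subject's windows keep their task labels (rest / motor
    execution / motor imagery); windows from every other subject become
    negative ``other_subject`` samples and are subsampled (seeded, without
    replacement) to match the target's total window count, so the negative
    class cannot dominate the loss.

    Returns the retained windows and an aligned array of string labels
    drawn from :data:`PRETRAIN_CLASSES`.
    """
    target = [w for w in windows if w.subject_id == target_subject]
    others = [w for w in windows if w.subject_id != target_subject]
    if not target:
        raise ValueError(f"target subject {target_subject} absent from windows")
    if not others:
        raise ValueError("pre-training relabeling needs windows from >= 2 subjects")
    rng = np.random.default_rng(seed)
    n_keep = min(len(target), len(others))
    keep = rng.choice(len(others), size=n_keep, replace=False)
    kept_others = [others[i] for i in sorted(keep)]
    out = target + kept_others
    labels = np.array(
        [w.task for w in target] + [OTHER_SUBJECT] * len(kept_others), dtype=object
    )
    return out, labels
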
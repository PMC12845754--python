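"""Verification metrics (FAR / FRR / EER) derived from closed-set
posteriors, plus standard identification metrics.

No separate verification classifier exists: every trial score is a softmax
posterior of the identification model.  For each test sample with true
identity y, all K possible identity claims are enumerated — one genuine
trial (claim == y, score = P[y]) and K-1 impostor trials (claim != y,
score = P[claim]).  A claim is accepted when its score is >= the threshold
tau; sweeping tau over all observed scores yields the FAR/FRR trade-off
curve, and the equal error rate is read off at the FAR = FRR crossing
(linear interpolation between the bracketing thresholds; if the curves
meet without a strict sign change, the midpoint (FAR+FRR)/2 at the
threshold minimizing |FAR-FRR| is reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_score, recall_score

__all__ = [
    "TrialSet",
    "ErrorCurve",
    "enumerate_trials",
    "far_frr_at",
    "error_curve_and_eer",
    "identification_metrics",
]


@dataclass(frozen=True)
class TrialSet:
    """Genuine and impostor verification scores from one evaluation set."""

    genuine_scores: np.ndarray
    impostor_scores: np.ndarray
    n_samples: int
    n_classes: int

    def __post_init__(self):
        object.__setattr__(
            self, "genuine_scores", np.asarray(self.genuine_scores, dtype=np.float64)
        )
        object.__setattr__(
            self, "impostor_scores", np.asarray(self.impostor_scores, dtype=np.float64)
        )


@dataclass(frozen=True)
class ErrorCurve:
    """FAR/FRR as functions of the acceptance threshold, plus the EER."""

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float
    tau_star: float


def enumerate_trials(posteriors: np.ndarray, true_labels) -> TrialSet:
    """All (sample, claimed identity) verification trials.

    ``posteriors`` is (n, K) with rows summing to 1; ``true_labels`` holds
    0-based class indices.  Each sample contributes exactly one genuine
    score and K-1 impostor scores, in deterministic (sample-major,
    class-minor) order.
    """
    posteriors = np.asarray(posteriors, dtype=np.float64)
    if posteriors.ndim != 2:
        raise ValueError("posteriors must be (n_samples, n_classes)")
    n, k = posteriors.shape
    labels = np.asarray(true_labels, dtype=np.intp)
    if labels.shape != (n,):
        raise ValueError("labels must align with posterior rows")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    rows = np.arange(n)
    genuine = posteriors[rows, labels]
    mask = np.ones((n, k), dtype=bool)
    mask[rows, labels] = False
    impostor = posteriors[mask]  # row-major: sample-major, class-minor
    return TrialSet(
        genuine_scores=genuine,
        impostor_scores=impostor,
        n_samples=n,
        n_classes=k,
    )


def far_frr_at(trials: TrialSet, tau: float) -> tuple[float, float]:
    """False acceptance and false rejection rates at threshold ``tau``.

    Accept iff score >= tau (equality accepts): FAR is the fraction of
    impostor trials accepted, FRR the fraction of genuine trials rejected.
    """
    g, i = trials.genuine_scores, trials.impostor_scores
    if g.size == 0 or i.size == 0:
        raise ValueError("trial set needs both genuine and impostor trials")
    far = float(np.count_nonzero(i >= tau) / i.size)
    frr = float(np.count_nonzero(g < tau) / g.size)
    return far, frr


def error_curve_and_eer(trials: TrialSet) -> ErrorCurve:
    """Threshold sweep over all unique scores (plus sentinels) and the EER.

    The sweep at tau=0 accepts everything (FAR=1, FRR=0) and at a sentinel
    just above the maximum score rejects everything (FAR=0, FRR=1), so the
    monotone curves always bracket a crossing.
    """
    g, i = trials.genuine_scores, trials.impostor_scores
    if g.size == 0 or i.size == 0:
        raise ValueError("trial set needs both genuine and impostor trials")
    scores = np.concatenate([g, i])
    taus = np.unique(np.concatenate([[0.0], scores, [scores.max() + 1e-9]]))
    # vectorized counting via sorted positions
    gs = np.sort(g)
    is_ = np.sort(i)
    far = 1.0 - np.searchsorted(is_, taus, side="left") / is_.size
    frr = np.searchsorted(gs, taus, side="left") / gs.size
    diff = far - frr
    eer = None
    tau_star = None
    for j in range(len(taus) - 1):
        if diff[j] == 0.0:
            eer = float(far[j])
            tau_star = float(taus[j])
            break
        if diff[j] > 0.0 and diff[j + 1] < 0.0:
            # strict sign change: linearly interpolate both curves in tau
            t0, t1 = taus[j], taus[j + 1]
            w = diff[j] / (diff[j] - diff[j + 1])
            eer = float(far[j] + (far[j + 1] - far[j]) * w)
            tau_star = float(t0 + (t1 - t0) * w)
            break
    if eer is None:
        j = int(np.argmin(np.abs(diff)))
        eer = float((far[j] + frr[j]) / 2.0)
        tau_star = float(taus[j])
    return ErrorCurve(thresholds=taus, far=far, frr=frr, eer=eer, tau_star=tau_star)


def identification_metrics(predictions, true_labels) -> dict:
    """Accuracy plus macro-averaged precision and recall.

    ``predictions`` may be hard labels or one-hot rows.  Classes absent
    from the ground truth are excluded from the macro recall average (a
    warning is emitted).
    """
    preds = np.asarray(predictions)
    if preds.ndim == 2:  # one-hot rows
        preds = np.argmax(preds, axis=1)
    truth = np.asarray(true_labels)
    if preds.shape != truth.shape:
        raise ValueError("predictions and labels must align")
    if preds.size == 0:
        raise ValueError("empty evaluation set")
    present = np.unique(truth)
    predicted_only = np.setdiff1d(np.unique(preds), present)
    if predicted_only.size:
        warnings.warn(
            f"classes {predicted_only.tolist()} were predicted but never occur "
            "in the ground truth; they are excluded from macro averaging",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision = precision_score(
            truth, preds, labels=present, average="macro", zero_division=0.0
        )
        recall = recall_score(
            truth, preds, labels=present, average="macro", zero_division=0.0
        )
    return {
        "accuracy": float(np.mean(preds == truth)),
        "precision_macro": float(precision),
        "recall_macro": float(recall),
    }
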
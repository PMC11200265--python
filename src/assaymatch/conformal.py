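"""Mondrian (class-conditional) inductive conformal prediction.

Wraps the matcher's probabilistic output with per-class validity guarantees.
Calibration items of true class c contribute the nonconformity score
1 - p_hat(c); at test time each class receives the conservative conformal
p-value

    p_c = (1 + #{calibration scores of class c >= test nonconformity}) / (n_c + 1)

and is included in the prediction set iff p_c > 1 - epsilon. Because scores
are kept per class (the "Mondrian" taxonomy), coverage holds for actives and
inactives separately, not just marginally. A singleton prediction set is a
"confident" prediction; at the default confidence level epsilon = 0.80 a
well-calibrated matcher leaves roughly the hard cases with both classes in
the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateCalibrationError, InsufficientDataError

DEFAULT_EPSILON = 0.80


@dataclass(frozen=True)
class CalibrationResult:
    """Per-class sorted nonconformity scores plus the confidence level."""

    scores_class0: np.ndarray
    scores_class1: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        for name in ("scores_class0", "scores_class1"):
            arr = np.sort(np.asarray(getattr(self, name), dtype=np.float64))
            if arr.size == 0:
                raise DegenerateCalibrationError(f"{name} is empty")
            object.__setattr__(self, name, arr)
        if not 0 < self.epsilon < 1:
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")

    def scores(self, cls: int) -> np.ndarray:
        return self.scores_class1 if cls == 1 else self.scores_class0


@dataclass(frozen=True)
class PredictionSet:
    """Conformal output for one pair: subset of {0, 1} plus per-class p-values."""

    classes: frozenset
    p_values: dict
    confident: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "confident", len(self.classes) == 1)


def calibrate(
    probs: np.ndarray, labels: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> CalibrationResult:
    """Build per-class calibration scores from held-out matcher probabilities.

    ``probs`` are p_hat(active); an item with true class c scores 1 - p_hat(c).
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have matching shapes")
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be 0/1")
    mask1 = labels == 1
    if not mask1.any() or mask1.all():
        raise DegenerateCalibrationError(
            "calibration set must contain both classes"
        )
    return CalibrationResult(
        scores_class0=probs[~mask1],  # 1 - p_hat(0) = p_hat(1)
        scores_class1=1.0 - probs[mask1],
        epsilon=epsilon,
    )


def predict_set(
    cal: CalibrationResult, p_hat: float, epsilon: float | None = None
) -> PredictionSet:
    """Conformal prediction set for one test probability p_hat(active).

    Conservative (non-smoothed) p-values with the +1 correction; ties between
    the test score and calibration scores count toward inclusion.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    eps = cal.epsilon if epsilon is None else epsilon
    p_values: dict[int, float] = {}
    included = []
    for cls in (0, 1):
        p_cls = p_hat if cls == 1 else 1.0 - p_hat
        nonconf = 1.0 - p_cls
        scores = cal.scores(cls)
        n_c = scores.size
        n_ge = n_c - int(np.searchsorted(scores, nonconf, side="left"))
        p_val = (1 + n_ge) / (n_c + 1)
        p_values[cls] = p_val
        if p_val > 1.0 - eps:
            included.append(cls)
    return PredictionSet(classes=frozenset(included), p_values=p_values)


def predict_sets(
    cal: CalibrationResult, probs: np.ndarray, epsilon: float | None = None
) -> list[PredictionSet]:
    """Vector version of :func:`predict_set`."""
    return [predict_set(cal, float(p), epsilon) for p in np.asarray(probs, dtype=float)]


def confident_mask(sets: list[PredictionSet]) -> tuple[np.ndarray, float]:
    """Boolean mask of singleton prediction sets and their overall fraction."""
    if not sets:
        raise InsufficientDataError("no prediction sets supplied")
    mask = np.array([s.confident for s in sets], dtype=bool)
    return mask, float(mask.mean())
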
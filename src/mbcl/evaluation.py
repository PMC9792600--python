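"""Metrics, statistical comparisons and timing for decoding experiments.

Chance-corrected agreement uses Cohen's kappa against the balanced chance
level p_e = 1/n_classes:  kappa = (p0 - p_e) / (1 - p_e).  Method
comparisons follow the convention of testing each accuracy sample for
normality (Shapiro-Wilk) and comparing methods with a two-sided
Mann-Whitney U test; p < 0.05 is read as a significant difference.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import silhouette_score

__all__ = ["EvalReport", "accuracy", "cohens_kappa", "confusion",
           "compare_methods", "representation_compactness",
           "prediction_time", "trial_level_probs"]


def accuracy(preds: np.ndarray, truth: np.ndarray) -> float:
    preds = np.asarray(preds)
    truth = np.asarray(truth)
    if preds.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if preds.size == 0:
        raise ValueError("empty prediction set")
    return float((preds == truth).mean())


def cohens_kappa(p0: float, n_classes: int) -> float:
    """kappa from accuracy under the balanced chance level 1/n_classes."""
    if not 0 <= p0 <= 1:
        raise ValueError("accuracy must be in [0, 1]")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    pe = 1.0 / n_classes
    return (p0 - pe) / (1.0 - pe)


def confusion(preds: np.ndarray, truth: np.ndarray,
              n_classes: int) -> np.ndarray:
    """counts[c_true, c_pred]; rows sum to per-class support."""
    preds = np.asarray(preds, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    for name, arr in (("preds", preds), ("truth", truth)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contain labels outside [0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (truth, preds), 1)
    return mat


def compare_methods(acc_a, acc_b) -> tuple[float, float, float]:
    """(Shapiro-Wilk p of a, of b, two-sided Mann-Whitney U p of a vs b).

    Identical samples compare at p = 1.0 by definition; a constant sample
    has no defined Shapiro-Wilk statistic and reports NaN.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per method")

    def _sw(x):
        if np.ptp(x) == 0:
            return float("nan")
        return float(stats.shapiro(x).pvalue)

    if np.array_equal(a, b):
        mw = 1.0
    else:
        mw = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return _sw(a), _sw(b), mw


def representation_compactness(z: np.ndarray, y: np.ndarray) -> float:
    """Mean silhouette score (Euclidean) of embeddings grouped by label —
    a scalar proxy for how compactly classes cluster."""
    z = np.asarray(z)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    return float(silhouette_score(z, y, metric="euclidean"))


def prediction_time(predict, x: np.ndarray) -> float:
    """Mean wall-clock milliseconds per sample for ``predict(x)``.

    Hardware-dependent; reported, never asserted against reference values.
    """
    if len(x) == 0:
        raise ValueError("empty test set")
    t0 = time.perf_counter()
    predict(x)
    return (time.perf_counter() - t0) * 1000.0 / len(x)


def trial_level_probs(crop_probs: np.ndarray,
                      parent_trial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-crop probabilities to one prediction per trial by
    averaging softmax outputs over each trial's crops.

    Returns (unique trial ids, trial x cls mean probabilities).
    """
    parent_trial = np.asarray(parent_trial)
    trials = np.unique(parent_trial)
    out = np.stack([crop_probs[parent_trial == t].mean(axis=0)
                    for t in trials])
    return trials, out


@dataclass
class EvalReport:
    """Aggregated experiment outcome."""

    method: str
    cell_accuracies: dict = field(default_factory=dict)   # (rep, fold) -> acc
    mean_accuracy: float = float("nan")
    kappa: float = float("nan")
    confusion_matrix: list = field(default_factory=list)
    trial_accuracy: float | None = None
    silhouette_before: float | None = None
    silhouette_after: float | None = None
    voting_weights: list | None = None
    prediction_ms_per_sample: float | None = None
    n_classes: int = 0
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def finalize(self, n_classes: int) -> None:
        accs = list(self.cell_accuracies.values())
        self.mean_accuracy = float(np.mean(accs))
        self.kappa = cohens_kappa(self.mean_accuracy, n_classes)
        self.n_classes = n_classes

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["cell_accuracies"] = {f"{r}:{f}": v
                                for (r, f), v in self.cell_accuracies.items()}
        return d

    def comparable_dict(self) -> dict:
        """Report content with hardware-dependent timing removed."""
        d = self.to_dict()
        d.pop("prediction_ms_per_sample", None)
        return d
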
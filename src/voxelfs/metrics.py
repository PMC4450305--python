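"""Confusion-matrix statistics for binary voxel segmentation.

The foreground class (hippocampus in the motivating application) is called
``A`` and coded as label ``1``; background is ``B`` / ``0``.  All derived
quantities are fractions in [0, 1]; reporting helpers can render them as whole
percentages, which is how segmentation tables are conventionally printed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "total_efficiency",
    "purity",
    "completeness",
    "contamination",
    "dice",
    "dice_from_rates",
    "summarize",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion matrix; rows are true classes, columns predicted.

    ``n_aa`` counts true-A voxels predicted A (true positives for the
    foreground), ``n_ab`` true-A predicted B (misses), ``n_ba`` true-B
    predicted A (false alarms), ``n_bb`` true-B predicted B.
    """

    n_aa: int
    n_ab: int
    n_ba: int
    n_bb: int

    def __post_init__(self) -> None:
        for name in ("n_aa", "n_ab", "n_ba", "n_bb"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_aa + self.n_ab + self.n_ba + self.n_bb

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_aa, self.n_ab], [self.n_ba, self.n_bb]], dtype=int)

    def to_dict(self) -> dict:
        return {
            "n_aa": int(self.n_aa),
            "n_ab": int(self.n_ab),
            "n_ba": int(self.n_ba),
            "n_bb": int(self.n_bb),
        }


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count the four true/predicted label combinations.

    Both inputs are flat binary arrays with 1 = foreground class A.
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    t = y_true.astype(bool)
    p = y_pred.astype(bool)
    return ConfusionMatrix(
        n_aa=int(np.count_nonzero(t & p)),
        n_ab=int(np.count_nonzero(t & ~p)),
        n_ba=int(np.count_nonzero(~t & p)),
        n_bb=int(np.count_nonzero(~t & ~p)),
    )


def total_efficiency(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified voxels, (N_AA + N_BB) / N."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix: total count is 0")
    return (cm.n_aa + cm.n_bb) / cm.total


def _check_class(cls: str) -> str:
    if cls not in ("A", "B"):
        raise ValueError(f"class must be 'A' or 'B', got {cls!r}")
    return cls


def purity(cm: ConfusionMatrix, cls: str = "A") -> float:
    """Fraction of voxels predicted as `cls` that truly belong to it (precision)."""
    _check_class(cls)
    if cls == "A":
        denom = cm.n_aa + cm.n_ba
        if denom == 0:
            raise ValueError("purity of class A undefined: no voxels predicted A")
        return cm.n_aa / denom
    denom = cm.n_ab + cm.n_bb
    if denom == 0:
        raise ValueError("purity of class B undefined: no voxels predicted B")
    return cm.n_bb / denom


def completeness(cm: ConfusionMatrix, cls: str = "A") -> float:
    """Fraction of true `cls` voxels recovered by the prediction (recall)."""
    _check_class(cls)
    if cls == "A":
        denom = cm.n_aa + cm.n_ab
        if denom == 0:
            raise ValueError("completeness of class A undefined: no true A voxels")
        return cm.n_aa / denom
    denom = cm.n_ba + cm.n_bb
    if denom == 0:
        raise ValueError("completeness of class B undefined: no true B voxels")
    return cm.n_bb / denom


def contamination(cm: ConfusionMatrix, cls: str = "A") -> float:
    """Complement of purity: fraction of predicted `cls` voxels that are wrong."""
    return 1.0 - purity(cm, cls)


def dice(cm: ConfusionMatrix) -> float:
    """Dice overlap (F1) of the foreground class: 2*N_AA / (2*N_AA + N_BA + N_AB).

    When there is neither a predicted nor a true foreground voxel the overlap
    is undefined; it is reported as 0 with a warning (a conservative
    convention for averaging across subjects).
    """
    denom = 2 * cm.n_aa + cm.n_ba + cm.n_ab
    if denom == 0:
        warnings.warn(
            "Dice undefined (no true or predicted foreground voxels); returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return 2 * cm.n_aa / denom


def dice_from_rates(purity_a: float, completeness_a: float) -> float:
    """Dice as the harmonic mean of foreground purity and completeness.

    Algebraically identical to :func:`dice`; useful for recomputing overlap
    from tabulated purity/completeness percentages.
    """
    if purity_a + completeness_a == 0:
        return 0.0
    return 2.0 * purity_a * completeness_a / (purity_a + completeness_a)


def summarize(values) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of per-subject scores."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a sample standard deviation")
    return float(values.mean()), float(values.std(ddof=1))


def report(cm: ConfusionMatrix, round_percent: bool = True) -> dict:
    """Full indicator table for one confusion matrix.

    Fractions are always included; with ``round_percent`` the whole-percent
    rendering used in printed tables is added.
    """
    out = {
        "confusion": cm.to_dict(),
        "total_efficiency": total_efficiency(cm),
        "dice": dice(cm),
    }
    for cls in ("A", "B"):
        out[f"purity_{cls}"] = purity(cm, cls)
        out[f"completeness_{cls}"] = completeness(cm, cls)
        out[f"contamination_{cls}"] = contamination(cm, cls)
    if round_percent:
        out["percent"] = {
            k: round(100 * v)
            for k, v in out.items()
            if isinstance(v, float)
        }
    return out
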
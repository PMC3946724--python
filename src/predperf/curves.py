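"""ROC and Lorenz curves, and the geometric forms of AUC, Gini and Pietra.

The ROC curve sweeps a threshold from high to low over the distinct
predicted probabilities and plots (FPR, TPR); its trapezoidal area equals
the pairwise AUC (ties scored one half) exactly.

The Lorenz curve sorts subjects by ascending predicted probability and
plots the cumulative population fraction against the cumulative share of
total predicted risk.  Twice the area between the curve and the diagonal is
the classical Gini coefficient of the probability distribution; the maximum
vertical deviation from the diagonal is the classical Pietra statistic.
Dividing each by (1 − p̄) yields the standardized indices of
:mod:`predperf.core_measures`, which compare the model against an
error-free one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_measures import DegenerateSampleError, LabeledPredictions

__all__ = [
    "ROCCurve",
    "LorenzCurve",
    "roc_curve",
    "lorenz_curve",
    "gini_from_lorenz",
    "pietra_from_lorenz",
]


def _write_xy_tsv(points: np.ndarray, path: str | Path, header: tuple[str, str]) -> None:
    lines = ["\t".join(header)]
    lines += [f"{x:.12g}\t{y:.12g}" for x, y in points]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) vertices, from (0, 0) to (1, 1)."""

    points: np.ndarray  # shape (k, 2)

    @property
    def area(self) -> float:
        """Trapezoidal area under the curve."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(np.trapezoid(y, x))

    def to_tsv(self, path: str | Path) -> None:
        _write_xy_tsv(self.points, path, ("fpr", "tpr"))


@dataclass(frozen=True)
class LorenzCurve:
    """Ordered (population fraction, cumulative risk share) vertices.

    Built from the predicted probabilities alone (outcomes are not used);
    the normalizing mean here is therefore always the mean prediction.
    """

    points: np.ndarray  # shape (k, 2), starts (0,0), ends (1,1)

    @property
    def area_between_diagonal(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(np.trapezoid(x - y, x))

    @property
    def classical_gini(self) -> float:
        """Twice the area between the diagonal and the curve."""
        return 2.0 * abs(self.area_between_diagonal)

    @property
    def max_deviation(self) -> float:
        """Largest vertical distance from the diagonal (at a vertex)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(np.max(np.abs(x - y)))

    def to_tsv(self, path: str | Path) -> None:
        _write_xy_tsv(self.points, path, ("population_fraction", "risk_fraction"))


def roc_curve(data: LabeledPredictions) -> ROCCurve:
    """Empirical ROC curve with one vertex per distinct threshold.

    Thresholds are the distinct predicted probabilities swept from high to
    low; a subject is called diseased when its probability is at or above
    the threshold.  Tied probabilities produce a single diagonal jump,
    which is what makes the trapezoidal area agree with the tie-aware
    pairwise AUC.
    """
    data.require_both_classes()
    p = data.probabilities
    d = data.outcomes
    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    d_sorted = d[order]
    # indices where a run of tied probabilities ends
    last_of_run = np.flatnonzero(np.diff(p_sorted) != 0)
    last_of_run = np.r_[last_of_run, p_sorted.size - 1]
    tp = np.cumsum(d_sorted)[last_of_run]
    fp = np.cumsum(1.0 - d_sorted)[last_of_run]
    tpr = tp / data.n_diseased
    fpr = fp / data.n_nondiseased
    pts = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    return ROCCurve(points=pts)


def lorenz_curve(data: LabeledPredictions) -> LorenzCurve:
    """Lorenz curve of the predicted-probability distribution.

    Subjects are sorted by ascending probability; tied values are grouped
    into a single segment so no artificial vertices appear.
    """
    p = np.sort(data.probabilities)
    total = float(p.sum())
    if total <= 0.0:
        raise DegenerateSampleError("all predicted probabilities are zero; "
                                    "total risk is zero")
    n = p.size
    last_of_run = np.flatnonzero(np.diff(p) != 0)
    last_of_run = np.r_[last_of_run, n - 1]
    pop = (last_of_run + 1) / n
    risk = np.cumsum(p)[last_of_run] / total
    pts = np.column_stack([np.r_[0.0, pop], np.r_[0.0, risk]])
    return LorenzCurve(points=pts)


def _check_one_minus_pbar(one_minus_pbar: float) -> None:
    if not 0.0 < one_minus_pbar < 1.0:
        raise DegenerateSampleError(
            f"1 − p̄ = {one_minus_pbar} is degenerate (need p̄ strictly in (0,1))"
        )


def gini_from_lorenz(curve: LorenzCurve, one_minus_pbar: float) -> float:
    """Standardized Gini from Lorenz geometry: classical Gini ÷ (1 − p̄)."""
    _check_one_minus_pbar(one_minus_pbar)
    return curve.classical_gini / one_minus_pbar


def pietra_from_lorenz(curve: LorenzCurve, one_minus_pbar: float) -> float:
    """Standardized Pietra from Lorenz geometry: max deviation ÷ (1 − p̄)."""
    _check_one_minus_pbar(one_minus_pbar)
    return curve.max_deviation / one_minus_pbar
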
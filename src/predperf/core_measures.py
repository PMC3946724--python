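"""Absolute performance indices for risk-prediction models.

Given a cohort of ``N`` subjects with binary disease indicators ``D_i`` and
predicted probabilities ``p_i`` from some model, this module computes the
*absolute* discrimination measures:

``auc``
    Probability that a randomly chosen diseased subject's predicted
    probability exceeds that of a randomly chosen non-diseased subject;
    ties score one half.
``gini``
    Mean absolute pairwise difference of the predicted probabilities,
    standardized by its value under an error-free model (one that predicts
    ``p_i = D_i``).  Quantifies *separation* — how much the model spreads
    subjects apart.
``pietra``
    Mean absolute deviation of the predicted probabilities from the prior
    ``p̄``, standardized the same way.  Quantifies *gain* — how far the
    model moves subjects away from the a-priori risk.
``brier`` / ``sbrier``
    Mean squared prediction error, and one minus its ratio to the Brier
    score of the constant-``p̄`` predictor.  The scaled version is 1 for an
    error-free model, 0 for the uninformative one, and prevalence-free.
``sbrier_gain``
    The squared-gain ratio ``Σ(p_i − p̄)² / (N·p̄(1−p̄))``; coincides with
    ``sbrier`` whenever the predictions are calibrated in-sample.

The reference probability ``p̄`` defaults to the observed prevalence
``N1/N``; for a model that is calibrated in-sample (e.g. any in-sample
logistic fit with an intercept) this equals the mean predicted probability,
and the two conventions coincide.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "LabeledPredictions",
    "PerformanceReport",
    "DegenerateSampleError",
    "auc",
    "gini",
    "pietra",
    "brier",
    "sbrier",
    "sbrier_gain",
    "evaluate_all",
    "read_labeled_predictions",
]

logger = logging.getLogger(__name__)

Reference = Literal["prevalence", "mean_probability"]


class DegenerateSampleError(ValueError):
    """Raised when a sample cannot support an index (e.g. one class absent)."""


@dataclass(frozen=True)
class LabeledPredictions:
    """Binary outcomes paired with one model's predicted probabilities.

    Parameters
    ----------
    outcomes
        Binary disease indicators, values in {0, 1}.
    probabilities
        Predicted probabilities in [0, 1], same length and subject order.
    reference
        How the reference probability ``p̄`` is formed: ``"prevalence"``
        (observed ``N1/N``, the default) or ``"mean_probability"``.
    """

    outcomes: np.ndarray
    probabilities: np.ndarray
    reference: Reference = "prevalence"

    def __post_init__(self) -> None:
        d = np.asarray(self.outcomes, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if d.ndim != 1 or p.ndim != 1 or d.shape != p.shape:
            raise ValueError(
                f"outcomes and probabilities must be 1-d and equally long, "
                f"got shapes {d.shape} and {p.shape}"
            )
        if d.size < 2:
            raise ValueError("need at least 2 subjects")
        if not np.isin(d, (0.0, 1.0)).all():
            raise ValueError("outcomes must be binary 0/1")
        if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if self.reference not in ("prevalence", "mean_probability"):
            raise ValueError(f"unknown reference {self.reference!r}")
        object.__setattr__(self, "outcomes", d)
        object.__setattr__(self, "probabilities", p)

    @property
    def n(self) -> int:
        return self.outcomes.size

    @property
    def n_diseased(self) -> int:
        return int(self.outcomes.sum())

    @property
    def n_nondiseased(self) -> int:
        return self.n - self.n_diseased

    @property
    def pbar(self) -> float:
        """Reference probability p̄ (prevalence or mean prediction)."""
        if self.reference == "prevalence":
            return self.n_diseased / self.n
        return float(self.probabilities.mean())

    def require_both_classes(self) -> None:
        if self.n_diseased == 0:
            raise DegenerateSampleError("no diseased subjects (all outcomes 0)")
        if self.n_nondiseased == 0:
            raise DegenerateSampleError("no non-diseased subjects (all outcomes 1)")

    def require_informative_pbar(self) -> None:
        pb = self.pbar
        if not 0.0 < pb < 1.0:
            raise DegenerateSampleError(
                f"reference probability p̄ = {pb} is degenerate; the "
                "error-free normalizer p̄(1−p̄) vanishes"
            )


@dataclass(frozen=True)
class PerformanceReport:
    """All absolute indices for one model on one sample."""

    auc: float
    gini: float
    pietra: float
    brier: float
    sbrier: float
    sbrier_gain: float
    n: int
    n_diseased: int
    reference_probability: float

    _MEASURES = ("auc", "gini", "pietra", "brier", "sbrier", "sbrier_gain")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                self._MEASURES + ("n", "n_diseased", "reference_probability")}

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path | None = None) -> str:
        """One-row TSV with a header line."""
        d = self.to_dict()
        header = "\t".join(d)
        row = "\t".join(f"{v:.10g}" if isinstance(v, float) else str(v)
                        for v in d.values())
        text = header + "\n" + row + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def auc(data: LabeledPredictions) -> float:
    """Concordance probability (AUC / c-statistic), ties scored 0.5.

    Computed with midranks in O(N log N); exactly equal to the pairwise
    definition (1/(N1·N0)) Σ s(p_i, p_j) over diseased × non-diseased
    pairs, where s scores 1 for a concordant pair, 0.5 for a tie, 0
    otherwise.
    """
    data.require_both_classes()
    ranks = rankdata(data.probabilities)  # midranks handle ties
    n1 = data.n_diseased
    n0 = data.n_nondiseased
    rank_sum = ranks[data.outcomes == 1].sum()
    return float((rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _pairwise_abs_sum(p: np.ndarray) -> float:
    # Σ_i Σ_j |p_i − p_j| over ordered pairs = 2 Σ_k (2k − N − 1) p_(k),
    # ascending sort, k = 1..N.  numpy's pairwise-summation keeps the
    # accumulation stable.
    ps = np.sort(p)
    n = ps.size
    k = np.arange(1, n + 1, dtype=float)
    return float(2.0 * np.sum((2.0 * k - n - 1.0) * ps))


def gini(data: LabeledPredictions) -> float:
    """Standardized Gini: mean |p_i − p_j| over its error-free maximum.

    [Σ_i Σ_j |p_i − p_j|] / [2 N² p̄ (1 − p̄)], the double sum running over
    all ordered pairs including i = j.
    """
    data.require_informative_pbar()
    pb = data.pbar
    n = data.n
    return _pairwise_abs_sum(data.probabilities) / (2.0 * n * n * pb * (1.0 - pb))


def pietra(data: LabeledPredictions) -> float:
    """Standardized Pietra: mean |p_i − p̄| over its error-free maximum."""
    data.require_informative_pbar()
    pb = data.pbar
    num = float(np.abs(data.probabilities - pb).sum())
    return num / (2.0 * data.n * pb * (1.0 - pb))


def brier(data: LabeledPredictions) -> float:
    """Mean squared prediction error (1/N) Σ (D_i − p_i)²."""
    return float(np.mean((data.outcomes - data.probabilities) ** 2))


def sbrier(data: LabeledPredictions) -> float:
    """Scaled Brier score: 1 − Brier / (p̄(1−p̄)).

    Equals 1 for the error-free model and 0 for the constant-p̄ predictor.
    A negative value (model worse than the constant predictor) is returned
    as-is with a warning — it is diagnostic of miscalibration.
    """
    data.require_informative_pbar()
    pb = data.pbar
    value = 1.0 - brier(data) / (pb * (1.0 - pb))
    if value < 0.0:
        logger.warning(
            "sBrier = %.4g is negative: the model predicts worse than the "
            "constant-p̄ predictor (miscalibration)", value,
        )
    return value


def sbrier_gain(data: LabeledPredictions) -> float:
    """Squared-gain ratio Σ (p_i − p̄)² / (N p̄ (1 − p̄)).

    Always in [0, 1] for probabilities in [0, 1]; coincides with
    :func:`sbrier` when the predictions are calibrated in-sample.
    """
    data.require_informative_pbar()
    pb = data.pbar
    num = float(np.sum((data.probabilities - pb) ** 2))
    return num / (data.n * pb * (1.0 - pb))


def evaluate_all(data: LabeledPredictions) -> PerformanceReport:
    """Bundle every absolute index into a :class:`PerformanceReport`."""
    return PerformanceReport(
        auc=auc(data),
        gini=gini(data),
        pietra=pietra(data),
        brier=brier(data),
        sbrier=sbrier(data),
        sbrier_gain=sbrier_gain(data),
        n=data.n,
        n_diseased=data.n_diseased,
        reference_probability=data.pbar,
    )


def read_labeled_predictions(
    path: str | Path,
    outcome: str,
    probability: str,
    *,
    delimiter: str | None = None,
    reference: Reference = "prevalence",
) -> LabeledPredictions:
    """Read outcomes and one probability column from a delimited text table.

    The file must have a header row.  ``delimiter`` defaults to sniffing
    (',' for .csv, tab for .tsv, else pandas' sniffer).  Rows with missing
    values in the used columns are rejected, reporting 1-based data line
    numbers.
    """
    frame = _read_table(path, delimiter)
    for col in (outcome, probability):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path} "
                             f"(columns: {list(frame.columns)})")
    used = frame[[outcome, probability]]
    bad = used.isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +1 header +1 one-based
        raise ValueError(f"missing values in {path} at line(s) {lines}")
    return LabeledPredictions(
        outcomes=used[outcome].to_numpy(dtype=float),
        probabilities=used[probability].to_numpy(dtype=float),
        reference=reference,
    )


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        suffix = path.suffix.lower()
        if suffix == ".csv":
            delimiter = ","
        elif suffix in (".tsv", ".tab"):
            delimiter = "\t"
    if delimiter is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=delimiter)
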
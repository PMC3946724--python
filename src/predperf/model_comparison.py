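"""Relative measures between a baseline and an extended prediction model.

Implements the reclassification family — NRI over explicit risk
categories, the continuous (sign-based) cNRI, and the IDI (change in
discrimination slope) — together with deltas of the absolute indices, and
a transitivity audit.  NRI-type measures compare *pairs* of models and can
order three models cyclically (A better than B, B better than C, yet C
better than A); the absolute indices are plain real numbers per model and
can never do that.  ``transitivity_audit`` checks a set of models for such
cycles, and ``find_nri_paradox`` searches random small cohorts for a
concrete cyclic instance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_measures import (
    DegenerateSampleError,
    LabeledPredictions,
    PerformanceReport,
    evaluate_all,
)

__all__ = [
    "PairedPredictions",
    "RiskCategories",
    "ComparisonReport",
    "TransitivityAudit",
    "nri",
    "nri_components",
    "cnri",
    "idi",
    "compare",
    "transitivity_audit",
    "find_nri_paradox",
]


@dataclass(frozen=True)
class PairedPredictions:
    """Outcomes with old-model and new-model probabilities, same subjects."""

    outcomes: np.ndarray
    old_probabilities: np.ndarray
    new_probabilities: np.ndarray

    def __post_init__(self) -> None:
        old = LabeledPredictions(self.outcomes, self.old_probabilities)
        new = LabeledPredictions(self.outcomes, self.new_probabilities)
        object.__setattr__(self, "outcomes", old.outcomes)
        object.__setattr__(self, "old_probabilities", old.probabilities)
        object.__setattr__(self, "new_probabilities", new.probabilities)

    def require_both_classes(self) -> None:
        LabeledPredictions(self.outcomes, self.old_probabilities).require_both_classes()

    def swapped(self) -> "PairedPredictions":
        return PairedPredictions(self.outcomes, self.new_probabilities,
                                 self.old_probabilities)

    def old(self, reference="prevalence") -> LabeledPredictions:
        return LabeledPredictions(self.outcomes, self.old_probabilities, reference)

    def new(self, reference="prevalence") -> LabeledPredictions:
        return LabeledPredictions(self.outcomes, self.new_probabilities, reference)


@dataclass(frozen=True)
class RiskCategories:
    """Strictly increasing interior cutpoints partitioning [0, 1].

    A probability equal to a cutpoint belongs to the higher category.
    """

    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutpoints)
        if len(cuts) < 1:
            raise ValueError("need at least one cutpoint")
        if any(not 0.0 < c < 1.0 for c in cuts):
            raise ValueError(f"cutpoints must lie strictly in (0,1): {cuts}")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"cutpoints must be strictly increasing: {cuts}")
        object.__setattr__(self, "cutpoints", cuts)

    def assign(self, p: np.ndarray) -> np.ndarray:
        """Category index (0-based) of each probability."""
        return np.digitize(p, self.cutpoints, right=False)

    @classmethod
    def from_string(cls, text: str) -> "RiskCategories":
        """Parse a comma-separated cutpoint list, e.g. ``"0.1,0.2"``."""
        return cls(tuple(float(t) for t in text.split(",") if t.strip()))


def _movement_contrast(data: PairedPredictions, up: np.ndarray,
                       down: np.ndarray) -> float:
    d = data.outcomes == 1
    nd = ~d
    ev = (up[d].mean() - down[d].mean())
    ne = (up[nd].mean() - down[nd].mean())
    return float(ev - ne), float(ev), float(ne)


def nri_components(data: PairedPredictions,
                   categories: RiskCategories) -> tuple[float, float, float]:
    """(nri, event component, non-event component) for categorical NRI."""
    data.require_both_classes()
    old_cat = categories.assign(data.old_probabilities)
    new_cat = categories.assign(data.new_probabilities)
    total, ev, ne = _movement_contrast(data, new_cat > old_cat, new_cat < old_cat)
    return total, ev, ne


def nri(data: PairedPredictions, categories: RiskCategories) -> float:
    """Net reclassification improvement over explicit risk categories.

    [P(up|D=1) − P(down|D=1)] − [P(up|D=0) − P(down|D=0)] where up/down
    means the new model assigns a higher/lower category than the old.
    Ranges over [−2, 2].
    """
    return nri_components(data, categories)[0]


def cnri(data: PairedPredictions) -> float:
    """Continuous NRI: movement defined by the sign of p_new − p_old.

    An exact tie (p_new == p_old, no tolerance) counts as no movement.
    """
    data.require_both_classes()
    diff = data.new_probabilities - data.old_probabilities
    total, _, _ = _movement_contrast(data, diff > 0, diff < 0)
    return total


def idi(data: PairedPredictions) -> float:
    """Integrated discrimination improvement: change in discrimination slope.

    (mean p_new among diseased − mean p_new among non-diseased) minus the
    same contrast for the old model.
    """
    data.require_both_classes()
    d = data.outcomes == 1
    slope_new = data.new_probabilities[d].mean() - data.new_probabilities[~d].mean()
    slope_old = data.old_probabilities[d].mean() - data.old_probabilities[~d].mean()
    return float(slope_new - slope_old)


@dataclass(frozen=True)
class ComparisonReport:
    """Deltas of the absolute indices plus the relative measures."""

    old_report: PerformanceReport
    new_report: PerformanceReport
    delta_auc: float
    delta_gini: float
    delta_pietra: float
    delta_sbrier: float
    relative_pct: dict[str, float]          # NaN where baseline index is 0
    undefined_relative: tuple[str, ...]     # names flagged undefined
    cnri: float
    idi: float
    nri: float | None = None
    nri_event: float | None = None
    nri_nonevent: float | None = None

    def to_dict(self) -> dict:
        out = {
            "old": self.old_report.to_dict(),
            "new": self.new_report.to_dict(),
            "delta": {
                "auc": self.delta_auc,
                "gini": self.delta_gini,
                "pietra": self.delta_pietra,
                "sbrier": self.delta_sbrier,
            },
            "relative_pct": self.relative_pct,
            "undefined_relative": list(self.undefined_relative),
            "cnri": self.cnri,
            "idi": self.idi,
        }
        if self.nri is not None:
            out["nri"] = self.nri
            out["nri_event"] = self.nri_event
            out["nri_nonevent"] = self.nri_nonevent
        return out

    def to_tsv(self) -> str:
        """Two model rows plus an 'absolute (relative %)' improvement row."""
        measures = ("auc", "gini", "pietra", "sbrier")
        lines = ["model\t" + "\t".join(measures)]
        for name, rep in (("old", self.old_report), ("new", self.new_report)):
            lines.append(name + "\t" +
                         "\t".join(f"{getattr(rep, m):.3f}" for m in measures))
        cells = []
        for m in measures:
            delta = getattr(self, f"delta_{m}")
            rel = self.relative_pct[m]
            cells.append(f"{delta:+.3f} (undefined)" if math.isnan(rel)
                         else f"{delta:+.3f} ({rel:+.1f}%)")
        lines.append("improvement\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def compare(data: PairedPredictions,
            categories: RiskCategories | None = None,
            reference="prevalence") -> ComparisonReport:
    """Full old-vs-new comparison: index deltas, NRI (optional), cNRI, IDI."""
    old_rep = evaluate_all(data.old(reference))
    new_rep = evaluate_all(data.new(reference))
    deltas = {m: getattr(new_rep, m) - getattr(old_rep, m)
              for m in ("auc", "gini", "pietra", "sbrier")}
    relative: dict[str, float] = {}
    undefined: list[str] = []
    for m, delta in deltas.items():
        base = getattr(old_rep, m)
        if base == 0.0:
            relative[m] = math.nan
            undefined.append(m)
        else:
            relative[m] = 100.0 * delta / base
    kwargs: dict = {}
    if categories is not None:
        total, ev, ne = nri_components(data, categories)
        kwargs = {"nri": total, "nri_event": ev, "nri_nonevent": ne}
    return ComparisonReport(
        old_report=old_rep,
        new_report=new_rep,
        delta_auc=deltas["auc"],
        delta_gini=deltas["gini"],
        delta_pietra=deltas["pietra"],
        delta_sbrier=deltas["sbrier"],
        relative_pct=relative,
        undefined_relative=tuple(undefined),
        cnri=cnri(data),
        idi=idi(data),
        **kwargs,
    )


@dataclass(frozen=True)
class TransitivityAudit:
    """Result of checking a set of models for NRI/cNRI ordering cycles."""

    nri_cycles: tuple[tuple[int, int, int], ...]
    cnri_cycles: tuple[tuple[int, int, int], ...]
    absolute_orderings_transitive: bool  # always True: real-valued indices

    @property
    def has_paradox(self) -> bool:
        return bool(self.nri_cycles or self.cnri_cycles)


def _pairwise_sign_matrix(models: Sequence[np.ndarray], outcomes: np.ndarray,
                          measure) -> np.ndarray:
    k = len(models)
    s = np.zeros((k, k))
    for i, j in itertools.permutations(range(k), 2):
        s[i, j] = measure(PairedPredictions(outcomes, models[j], models[i]))
    return s


def _cycles(sign: np.ndarray) -> list[tuple[int, int, int]]:
    # triple (a,b,c) is cyclic when a beats b, b beats c, and c beats a
    k = sign.shape[0]
    out = []
    for a, b, c in itertools.combinations(range(k), 3):
        for x, y, z in ((a, b, c), (a, c, b)):
            if sign[x, y] > 0 and sign[y, z] > 0 and sign[z, x] > 0:
                out.append((x, y, z))
    return out


def transitivity_audit(models: Sequence[np.ndarray], outcomes: np.ndarray,
                       categories: RiskCategories | None = None) -> TransitivityAudit:
    """Audit ≥3 models on identical subjects for relative-measure cycles.

    For every ordered pair of models the pairwise NRI (when categories are
    given) and cNRI are computed; any triple whose win/loss signs form a
    cycle is reported.  The absolute indices assign one real number per
    model, so the orderings they induce are transitive by construction —
    the audit states this rather than searching for a counterexample.
    """
    if len(models) < 3:
        raise ValueError(f"need at least 3 models, got {len(models)}")
    nri_cycles: list = []
    if categories is not None:
        sign = _pairwise_sign_matrix(models, outcomes,
                                     lambda d: nri(d, categories))
        nri_cycles = _cycles(sign)
    cnri_sign = _pairwise_sign_matrix(models, outcomes, cnri)
    return TransitivityAudit(
        nri_cycles=tuple(nri_cycles),
        cnri_cycles=tuple(_cycles(cnri_sign)),
        absolute_orderings_transitive=True,
    )


def find_nri_paradox(
    seed: int,
    *,
    n_subjects: int = 16,
    n_models: int = 4,
    categories: RiskCategories = RiskCategories((1 / 3, 2 / 3)),
    max_tries: int = 5000,
) -> tuple[list[np.ndarray], np.ndarray, TransitivityAudit] | None:
    """Random search for a concrete NRI ordering cycle.

    Draws small synthetic cohorts (random outcomes with both classes,
    uniform random probability vectors) until ``transitivity_audit``
    reports an NRI cycle; returns (models, outcomes, audit), or ``None``
    when ``max_tries`` is exhausted.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        outcomes = rng.integers(0, 2, n_subjects).astype(float)
        if outcomes.sum() in (0, n_subjects):
            continue
        models = [rng.random(n_subjects) for _ in range(n_models)]
        audit = transitivity_audit(models, outcomes, categories)
        if audit.nri_cycles:
            return models, outcomes, audit
    return None
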
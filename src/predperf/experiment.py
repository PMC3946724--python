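"""End-to-end marker-addition experiment.

For each replicate: simulate a training cohort and a validation cohort,
fit three logistic working models —

* model I  ``B``        (baseline score only),
* model II ``B + M1``   (baseline plus the uniform-effect marker),
* model III ``B + M2``  (baseline plus the gray-zone marker),

evaluate every absolute index on the validation cohort, and aggregate
across replicates into a table of means, Monte-Carlo standard errors and
absolute/relative improvements.

Model III's default functional form includes the kernel-modulated term
``K(B)·M2`` (the analyst knows that M2's effect is concentrated in the
gray zone); a plain main-effects form is available via
``ExperimentConfig.m2_form = "linear"``.  See docs/methods.md for why the
kernel-aware form is the default.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .core_measures import (
    DegenerateSampleError,
    LabeledPredictions,
    PerformanceReport,
    evaluate_all,
)
from .simulation import CohortDataset, GeneratingModelParams, gaussian_kernel, simulate_cohort

__all__ = [
    "ModelFitError",
    "FittedLogistic",
    "ExperimentConfig",
    "Table1Result",
    "fit_logistic",
    "evaluate_models",
    "run_experiment",
    "probability_histograms",
    "plot_probability_histograms",
]

logger = logging.getLogger(__name__)

MEASURES = ("auc", "gini", "pietra", "sbrier")

# covariate vocabulary for model specifications
_KERNEL_TERM = "K(B)*M2"


class ModelFitError(RuntimeError):
    """Fit failed (separation / non-convergence); replicate should be skipped."""


def _design_matrix(cohort: CohortDataset, terms: Sequence[str],
                   kernel_width: float) -> np.ndarray:
    frame = cohort.to_frame()
    cols = []
    for term in terms:
        if term == _KERNEL_TERM:
            cols.append(gaussian_kernel(cohort.baseline_score, kernel_width)
                        * cohort.marker_m2)
        elif term in frame.columns:
            cols.append(frame[term].to_numpy(dtype=float))
        else:
            raise KeyError(f"unknown covariate term {term!r}; "
                           f"available: {list(frame.columns)} or {_KERNEL_TERM!r}")
    return np.column_stack(cols)


@dataclass(frozen=True)
class FittedLogistic:
    """Maximum-likelihood logistic model over a fixed term list."""

    terms: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    kernel_width: float

    def predict(self, cohort: CohortDataset) -> np.ndarray:
        """Predicted probabilities, strictly inside (0,1) for finite input."""
        x = _design_matrix(cohort, self.terms, self.kernel_width)
        lin = self.coefficients[0] + x @ self.coefficients[1:]
        p = expit(lin)
        return np.clip(p, np.finfo(float).tiny, np.nextafter(1.0, 0.0))


def fit_logistic(train: CohortDataset, terms: Sequence[str],
                 kernel_width: float = GeneratingModelParams().kernel_width,
                 ) -> FittedLogistic:
    """Fit logit(D) ~ terms by Newton MLE on a training cohort.

    Raises :class:`ModelFitError` on perfect separation or
    non-convergence so replicate loops can flag and skip, never silently
    use a bad fit.
    """
    d = train.outcome
    if d.sum() == 0 or d.sum() == d.size:
        raise ModelFitError("training outcome has a single class")
    x = _design_matrix(train, terms, kernel_width)
    exog = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            result = sm.Logit(d, exog).fit(method="newton", maxiter=100,
                                           tol=1e-8, disp=0,
                                           warn_convergence=False)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise ModelFitError(f"logistic fit failed: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise ModelFitError("logistic fit did not converge in 100 iterations")
    return FittedLogistic(tuple(terms), np.asarray(result.params, dtype=float),
                          kernel_width)


def evaluate_models(predictors: dict[str, FittedLogistic],
                    validation: CohortDataset,
                    reference="prevalence") -> dict[str, PerformanceReport]:
    """Apply each fitted model to a validation cohort and score it."""
    out = {}
    for name, model in predictors.items():
        data = LabeledPredictions(validation.outcome, model.predict(validation),
                                  reference=reference)
        out[name] = evaluate_all(data)
    return out


@dataclass(frozen=True)
class ExperimentConfig:
    """Replicate-level description of the marker-addition experiment."""

    n_train: int = 500
    n_validation: int = 500
    n_replicates: int = 10000
    base_seed: int = 0
    params: GeneratingModelParams = field(default_factory=GeneratingModelParams)
    m2_form: Literal["kernel", "linear"] = "kernel"
    evaluate_on: Literal["validation", "training"] = "validation"
    reference: str = "prevalence"

    def __post_init__(self) -> None:
        for name in ("n_train", "n_validation", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def model_terms(self) -> dict[str, tuple[str, ...]]:
        m2_term = _KERNEL_TERM if self.m2_form == "kernel" else "M2"
        return {"B": ("B",), "B+M1": ("B", "M1"), "B+M2": ("B", m2_term)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = GeneratingModelParams.from_dict(d["params"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        """Load from JSON or YAML (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Table1Result:
    """Aggregated experiment output: model rows × measure columns.

    ``models[name][measure]`` maps to ``(mean, mc_standard_error)``;
    ``improvements[(base, new)][measure]`` carries the mean per-replicate
    delta, its SE, the relative improvement in percent of the baseline
    mean, and the delta of aggregate means (identical in expectation).
    """

    models: dict[str, dict[str, tuple[float, float]]]
    improvements: dict[tuple[str, str], dict[str, dict[str, float]]]
    n_replicates_requested: int
    n_replicates_used: int
    skip_reasons: dict[str, int]
    config: ExperimentConfig

    def to_dict(self) -> dict:
        return {
            "models": {m: {k: {"mean": v[0], "se": v[1]}
                           for k, v in row.items()}
                       for m, row in self.models.items()},
            "improvements": {f"{a}->{b}": cells
                             for (a, b), cells in self.improvements.items()},
            "n_replicates_requested": self.n_replicates_requested,
            "n_replicates_used": self.n_replicates_used,
            "skip_reasons": dict(self.skip_reasons),
            "config": self.config.to_dict(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path | None = None) -> str:
        """Layout with model rows, then 'absolute (+relative%)' rows."""
        lines = ["model\t" + "\t".join(m.upper() for m in MEASURES)]
        for name, row in self.models.items():
            lines.append(name + "\t" + "\t".join(f"{row[m][0]:.3f}" for m in MEASURES))
        lines.append("Absolute (Relative) Improvement" + "\t" * len(MEASURES))
        for (base, new), cells in self.improvements.items():
            vals = [f"{cells[m]['absolute']:+.3f} ({cells[m]['relative_pct']:+.1f}%)"
                    for m in MEASURES]
            lines.append(f"from {base} to {new}\t" + "\t".join(vals))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _replicate_once(config: ExperimentConfig, r: int,
                    collect: list | None) -> dict[str, np.ndarray] | None:
    # one generator per cohort; replicate r uses seeds base_seed + 2r (train)
    # and base_seed + 2r + 1 (validation)
    train = simulate_cohort(config.n_train, config.params, config.base_seed + 2 * r)
    valid = simulate_cohort(config.n_validation, config.params,
                            config.base_seed + 2 * r + 1)
    eval_cohort = valid if config.evaluate_on == "validation" else train
    predictors = {
        name: fit_logistic(train, terms, config.params.kernel_width)
        for name, terms in config.model_terms.items()
    }
    reports = evaluate_models(predictors, eval_cohort, config.reference)
    if collect is not None:
        collect.append({name: (predictors[name].predict(eval_cohort),
                               eval_cohort.outcome)
                        for name in predictors})
    return {name: np.array([getattr(rep, m) for m in MEASURES])
            for name, rep in reports.items()}


def run_experiment(config: ExperimentConfig,
                   collect_probabilities: bool = False,
                   ) -> Table1Result | tuple[Table1Result, list]:
    """Run the full replicate loop and aggregate.

    Degenerate replicates (single-class cohorts, separation,
    non-convergence) are skipped and counted by reason.  Aggregation is
    the arithmetic mean of per-replicate indices; absolute improvement is
    the mean of per-replicate deltas, relative improvement is 100 × that
    over the baseline aggregate mean.
    """
    names = list(config.model_terms)
    rows: dict[str, list[np.ndarray]] = {n: [] for n in names}
    skips: Counter[str] = Counter()
    collected: list | None = [] if collect_probabilities else None
    for r in range(config.n_replicates):
        try:
            rep = _replicate_once(config, r, collected)
        except (ModelFitError, DegenerateSampleError) as exc:
            skips[type(exc).__name__] += 1
            logger.info("replicate %d skipped: %s", r, exc)
            continue
        for n in names:
            rows[n].append(rep[n])
    used = len(rows[names[0]])
    if used == 0:
        raise RuntimeError("every replicate was degenerate; nothing to aggregate")
    mats = {n: np.vstack(rows[n]) for n in names}
    models = {
        n: {m: (float(mats[n][:, i].mean()),
                float(mats[n][:, i].std(ddof=1) / np.sqrt(used)) if used > 1 else 0.0)
            for i, m in enumerate(MEASURES)}
        for n in names
    }
    improvements: dict[tuple[str, str], dict[str, dict[str, float]]] = {}
    baseline = names[0]
    for new in names[1:]:
        cells = {}
        for i, m in enumerate(MEASURES):
            deltas = mats[new][:, i] - mats[baseline][:, i]
            base_mean = models[baseline][m][0]
            cells[m] = {
                "absolute": float(deltas.mean()),
                "absolute_se": float(deltas.std(ddof=1) / np.sqrt(used)) if used > 1 else 0.0,
                "relative_pct": float(100.0 * deltas.mean() / base_mean)
                                if base_mean != 0 else float("nan"),
                "delta_of_means": float(models[new][m][0] - base_mean),
            }
        improvements[(baseline, new)] = cells
    result = Table1Result(
        models=models,
        improvements=improvements,
        n_replicates_requested=config.n_replicates,
        n_replicates_used=used,
        skip_reasons=dict(skips),
        config=config,
    )
    if collect_probabilities:
        return result, collected
    return result


def probability_histograms(pooled: dict[str, tuple[np.ndarray, np.ndarray]],
                           bins: int = 40) -> pd.DataFrame:
    """Histogram predicted probabilities per model and disease status.

    ``pooled`` maps model name → (probabilities, outcomes) pooled over
    replicates.  Returns a tidy frame with one row per (model, status,
    bin), plus the grand and class-specific probability means for the
    vertical reference bars.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    records = []
    for name, (p, d) in pooled.items():
        grand = float(p.mean())
        for status, mask in (("diseased", d == 1), ("non-diseased", d == 0)):
            counts, _ = np.histogram(p[mask], bins=edges)
            class_mean = float(p[mask].mean()) if mask.any() else float("nan")
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                records.append({"model": name, "status": status,
                                "bin_left": lo, "bin_right": hi, "count": int(c),
                                "grand_mean": grand, "class_mean": class_mean})
    return pd.DataFrame.from_records(records)


def pool_replicates(collected: list[dict[str, tuple[np.ndarray, np.ndarray]]]
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Concatenate per-replicate (p, D) pairs by model name."""
    if not collected:
        raise ValueError("no replicates collected")
    names = collected[0].keys()
    return {n: (np.concatenate([c[n][0] for c in collected]),
                np.concatenate([c[n][1] for c in collected]))
            for n in names}


def plot_probability_histograms(pooled: dict[str, tuple[np.ndarray, np.ndarray]],
                                path: str | Path, bins: int = 40) -> None:
    """Write a PNG: one panel per model, outcome classes overlaid.

    Solid vertical line at the grand mean of the predicted probabilities;
    dotted lines at the class-specific means.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(pooled), figsize=(4 * len(pooled), 3),
                             sharey=True, squeeze=False)
    edges = np.linspace(0.0, 1.0, bins + 1)
    for ax, (name, (p, d)) in zip(axes[0], pooled.items()):
        ax.hist(p[d == 0], bins=edges, alpha=0.5, label="non-diseased")
        ax.hist(p[d == 1], bins=edges, alpha=0.5, label="diseased")
        ax.axvline(p.mean(), color="k", lw=1.5)
        for mask in (d == 1, d == 0):
            if mask.any():
                ax.axvline(p[mask].mean(), color="k", lw=1, ls=":")
        ax.set_title(name)
        ax.set_xlabel("predicted probability")
    axes[0][0].set_ylabel("subjects")
    axes[0][-1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
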
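"""Generator correctness: kernel, disease model, marker marginals, scenarios."""

import numpy as np
import pytest

from predperf import (
    GeneratingModelParams,
    disease_probability,
    gaussian_kernel,
    simulate_cohort,
    simulate_supplementary_s1,
    simulate_supplementary_s2,
    solve_intercept_for_prevalence,
)
from predperf.simulation import expected_prevalence


class TestKernel:
    def test_center_and_symmetry(self):
        assert gaussian_kernel(0.0, 1.0) == 1.0
        b = np.linspace(-3, 3, 13)
        assert np.allclose(gaussian_kernel(b, 0.7), gaussian_kernel(-b, 0.7))

    def test_closed_form(self):
        assert gaussian_kernel(1.0, 1.0) == pytest.approx(np.exp(-0.5))
        assert gaussian_kernel(2.0, 2.0) == pytest.approx(np.exp(-0.5))

    def test_strictly_decreasing_in_abs_b(self):
        b = np.linspace(0, 4, 50)
        k = gaussian_kernel(b, 0.64)
        assert (np.diff(k) < 0).all()

    def test_invalid_width(self):
        with pytest.raises(ValueError, match="width"):
            gaussian_kernel(1.0, 0.0)
        with pytest.raises(ValueError, match="kernel_width"):
            GeneratingModelParams(kernel_width=-1)


class TestDiseaseModel:
    def test_reference_subject_probability(self):
        params = GeneratingModelParams()
        expected = 1 / (1 + np.exp(-params.intercept))
        assert disease_probability(0.0, 0, 0, params) == pytest.approx(expected)

    def test_m2_odds_ratio_profile(self):
        """exp(γ₂·K(b)): peak at b=0, ≈1 for |b| ≥ 3 at unit width."""
        params = GeneratingModelParams(kernel_width=1.0)

        def odds_ratio_m2(b):
            p1 = disease_probability(b, 0, 1, params)
            p0 = disease_probability(b, 0, 0, params)
            return (p1 / (1 - p1)) / (p0 / (1 - p0))

        assert odds_ratio_m2(0.0) == pytest.approx(np.exp(params.log_or_m2_peak),
                                                   rel=1e-12)
        for b in (-3.0, 3.0):
            assert odds_ratio_m2(b) == pytest.approx(
                np.exp(params.log_or_m2_peak * np.exp(-4.5)), rel=1e-12)
            assert odds_ratio_m2(b) == pytest.approx(1.0, abs=0.03)

    def test_m1_odds_ratio_uniform_in_b(self):
        params = GeneratingModelParams()

        def odds_ratio_m1(b):
            p1 = disease_probability(b, 1, 0, params)
            p0 = disease_probability(b, 0, 0, params)
            return (p1 / (1 - p1)) / (p0 / (1 - p0))

        ors = [odds_ratio_m1(b) for b in (-2.0, 0.0, 2.0)]
        assert np.allclose(ors, np.exp(params.log_or_m1))


class TestSimulateCohort:
    def test_seed_determinism(self):
        a = simulate_cohort(100, seed=42)
        b = simulate_cohort(100, seed=42)
        assert np.array_equal(a.baseline_score, b.baseline_score)
        assert np.array_equal(a.outcome, b.outcome)
        c = simulate_cohort(100, seed=43)
        assert not np.array_equal(a.baseline_score, c.baseline_score)

    def test_minimum_size(self):
        with pytest.raises(ValueError, match="n ≥ 2"):
            simulate_cohort(1)

    def test_marker_conditional_prevalences(self):
        cohort = simulate_cohort(200_000, seed=7)
        high = cohort.baseline_score > 0
        for m in (cohort.marker_m1, cohort.marker_m2):
            assert m[high].mean() == pytest.approx(0.85, abs=0.005)
            assert m[~high].mean() == pytest.approx(0.75, abs=0.005)
            # marginal by total probability: 0.5·0.85 + 0.5·0.75
            assert m.mean() == pytest.approx(0.80, abs=0.005)

    def test_prevalence_matches_mean_true_probability(self):
        cohort = simulate_cohort(100_000, seed=11)
        p = cohort.true_probability
        se = np.sqrt((p * (1 - p)).mean() / p.size)
        assert abs(cohort.outcome.mean() - p.mean()) < 3 * se

    def test_true_probabilities_calibrated_by_construction(self):
        """Binning by p_true, mean outcome per bin tracks the bin mean."""
        cohort = simulate_cohort(200_000, seed=5)
        p, d = cohort.true_probability, cohort.outcome
        bins = np.quantile(p, np.linspace(0, 1, 11))
        idx = np.clip(np.digitize(p, bins[1:-1]), 0, 9)
        for k in range(10):
            mask = idx == k
            se = np.sqrt(p[mask].mean() * (1 - p[mask].mean()) / mask.sum())
            assert abs(d[mask].mean() - p[mask].mean()) < 4 * se

    def test_frame_round_trip(self, tmp_path):
        cohort = simulate_cohort(50, seed=1)
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        import pandas as pd
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["B", "M1", "M2", "p_true", "D"]
        assert np.allclose(frame["p_true"], cohort.true_probability)


class TestPrevalenceHelpers:
    def test_quadrature_matches_monte_carlo(self):
        params = GeneratingModelParams()
        exact = expected_prevalence(params)
        mc = simulate_cohort(400_000, params, seed=3).true_probability.mean()
        assert exact == pytest.approx(mc, abs=0.003)

    def test_solve_intercept_hits_target(self):
        for target in (0.1, 0.5):
            params = solve_intercept_for_prevalence(target)
            assert expected_prevalence(params) == pytest.approx(target, abs=1e-8)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            solve_intercept_for_prevalence(1.2)


class TestSupplementaryScenarios:
    def test_s1_zero_effect_reduces_to_baseline_model(self):
        from scipy.special import expit
        params = GeneratingModelParams()
        cohort = simulate_supplementary_s1(500, params, seed=9,
                                           log_or_continuous=0.0)
        base_only = expit(params.intercept
                          + params.beta_baseline * cohort.baseline_score)
        assert np.allclose(cohort.true_probability, base_only)

    def test_s1_determinism_and_marker_shift(self):
        a = simulate_supplementary_s1(50_000, seed=4)
        b = simulate_supplementary_s1(50_000, seed=4)
        assert np.array_equal(a.extra["Z"], b.extra["Z"])
        high = a.baseline_score > 0
        assert a.extra["Z"][high].mean() - a.extra["Z"][~high].mean() == \
            pytest.approx(0.5, abs=0.05)

    def test_s1_strong_marker_improves_auc(self, rng):
        """Fitted B+Z beats fitted B on validation in ≥95% of replicates."""
        from predperf import LabeledPredictions, auc, fit_logistic
        wins = 0
        reps = 200
        for r in range(reps):
            train = simulate_supplementary_s1(500, seed=1000 + 2 * r)
            valid = simulate_supplementary_s1(500, seed=1001 + 2 * r)
            base = fit_logistic(train, ("B",))
            full = fit_logistic(train, ("B", "Z"))
            a0 = auc(LabeledPredictions(valid.outcome, base.predict(valid)))
            a1 = auc(LabeledPredictions(valid.outcome, full.predict(valid)))
            wins += a1 > a0
        assert wins / reps >= 0.95

    def test_s2_single_marker_and_score_column(self):
        cohort = simulate_supplementary_s2(100, n_weak_markers=1, seed=2)
        assert set(cohort.extra) == {"G1", "score"}
        assert np.array_equal(cohort.extra["G1"], cohort.extra["score"])
        k18 = simulate_supplementary_s2(100, n_weak_markers=18, seed=2)
        stacked = np.column_stack([k18.extra[f"G{j}"] for j in range(1, 19)])
        assert np.array_equal(stacked.sum(axis=1), k18.extra["score"])

    def test_s2_invalid_counts(self):
        with pytest.raises(ValueError):
            simulate_supplementary_s2(100, n_weak_markers=0)

    def test_s2_collective_score_beats_single_markers(self):
        """The 18-marker score model's AUC gain exceeds any single marker's
        gain in ≥90% of replicates."""
        from predperf import LabeledPredictions, auc, fit_logistic
        wins = 0
        reps = 200
        for r in range(reps):
            train = simulate_supplementary_s2(500, seed=5000 + 2 * r)
            valid = simulate_supplementary_s2(500, seed=5001 + 2 * r)
            base = fit_logistic(train, ("B",))
            score = fit_logistic(train, ("B", "score"))
            a_base = auc(LabeledPredictions(valid.outcome, base.predict(valid)))
            a_score = auc(LabeledPredictions(valid.outcome, score.predict(valid)))
            single_gains = []
            for g in ("G1", "G7", "G18"):  # spot-check single markers
                m = fit_logistic(train, ("B", g))
                single_gains.append(
                    auc(LabeledPredictions(valid.outcome, m.predict(valid))) - a_base)
            wins += (a_score - a_base) > max(single_gains)
        assert wins / reps >= 0.90


def test_null_m2_effect_makes_m2_uninformative_given_b(rng):
    """With γ₂ = 0 the fitted M2 coefficient is centered at 0."""
    import statsmodels.api as sm
    params = GeneratingModelParams(log_or_m2_peak=0.0)
    coefs = []
    for r in range(60):
        cohort = simulate_cohort(2000, params, seed=300 + r)
        x = sm.add_constant(np.column_stack([cohort.baseline_score,
                                             cohort.marker_m2]))
        coefs.append(sm.Logit(cohort.outcome, x).fit(disp=0).params[2])
    coefs = np.asarray(coefs)
    assert abs(coefs.mean()) < 3 * coefs.std(ddof=1) / np.sqrt(coefs.size)


def test_params_json_round_trip(tmp_path):
    params = GeneratingModelParams(intercept=-1.0, kernel_width=0.5)
    path = tmp_path / "params.json"
    params.to_json(path)
    assert GeneratingModelParams.from_json(path) == params
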
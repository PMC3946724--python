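# Methods

## Measures

All indices operate on `(D_i, p_i)` pairs — binary outcomes and predicted
probabilities for one model on one sample.

**Reference probability.** Gini, Pietra and sBrier standardize against the
uninformative constant-`p̄` predictor and the error-free model
(`p_i = D_i`). By default `p̄` is the observed prevalence `N₁/N`, which
makes the constant-prevalence predictor score exactly zero regardless of
calibration; `reference="mean_probability"` switches to the mean
prediction. For any in-sample logistic fit with an intercept the two
coincide; on a validation sample they differ by sampling noise. The Lorenz
curve is built from the probabilities alone, so its geometric Gini/Pietra
use the mean prediction as the normalizing mean — the geometric and
formula routes agree exactly under `reference="mean_probability"` and up
to the calibration gap otherwise.

**Ties.** AUC scores tied pairs 0.5 and is computed with midranks, which
reproduces the pairwise definition exactly. The ROC curve places one
vertex per distinct threshold, so tied probabilities form a single
diagonal jump and the trapezoidal area equals the pairwise AUC to machine
precision. Tied probabilities are likewise grouped into a single Lorenz
segment.

**Numerics.** The Gini double sum uses the sorted identity
`Σᵢⱼ|p_i−p_j| = 2 Σ_k (2k−N−1) p_(k)` (O(N log N)), with numpy's pairwise
accumulation; it is tested against the naive O(N²) loop. The maximum
Lorenz deviation is taken over vertices, which is exact for a piecewise
linear curve. A negative sBrier (model worse than the constant predictor)
is returned as-is with a logged warning — clamping would hide
miscalibration. Samples with a single outcome class raise
`DegenerateSampleError` so replicate loops can count and skip them instead
of propagating NaNs.

**Known identities** (verified by the test suite): for predictions that
are calibrated in-sample — every distinct predicted value equals the mean
outcome among subjects holding it — `Gini = 2·AUC − 1`,
`sBrier = sbrier_gain`, and the change in sBrier between two calibrated
models equals the IDI. Fitted models on validation data satisfy these only
in expectation; the tests check them at 3 Monte-Carlo standard errors
there.

**Relative measures.** NRI uses explicit risk-category cutpoints (a
probability on a cutpoint belongs to the higher category); cNRI counts any
strict change of predicted probability as movement, with exact ties —
no tolerance — counting as none, so results are deterministic. NRI is
reported as a single number with the event/non-event components exposed
for diagnostics. Because pairwise sign comparisons need not be induced by
any per-model score, NRI orderings can cycle; `find_nri_paradox` locates
concrete cyclic triples by seeded random search over small cohorts
(random search rather than explicit construction, since no canonical
counterexample is fixed in the literature). The absolute indices assign
one real number per model and therefore always order models transitively.

## Generating model

Disease follows `logit P(D=1|B,M1,M2) = α + β_B·B + γ₁·M1 + γ₂·K(B)·M2`
with `B ~ N(0,1)`, both markers Bernoulli with prevalence 0.85 when
`B > 0` and 0.75 otherwise (conditionally independent given B — no direct
M1–M2 dependence is modelled), and `K(b) = exp(−b²/(2w²))`. M1's odds
ratio `e^{γ₁}` is uniform in B; M2's conditional odds ratio
`e^{γ₂·K(b)}` peaks at B = 0 and decays to 1 away from it, concentrating
its discrimination power in the baseline model's gray zone.

**Parameter defaults.** The frozen defaults are

| parameter | value | meaning |
|---|---|---|
| α | −2.21 | intercept; implies prevalence ≈ 0.50 |
| β_B | 1.67 | OR ≈ 5.3 per SD of the baseline score |
| γ₁ | 1.46 | OR ≈ 4.3 for M1, uniform in B |
| γ₂ | 1.97 | peak OR ≈ 7.2 for M2 at B = 0 |
| w | 0.64 | kernel width (SD units of B) |

These were calibrated once, by least squares against the reference
operating characteristics the package's experiment is designed to exhibit
(baseline-model AUC ≈ 0.822, Gini ≈ 0.644, Pietra ≈ 0.485,
sBrier ≈ 0.306 at 500/500 cohorts, with marker-addition improvements
ΔAUC ≈ +0.019 / ΔsBrier ≈ +0.038 for M1 and ΔPietra ≈ +0.083 /
ΔsBrier ≈ +0.057 for M2), and then frozen. The calibrated intercept
landing almost exactly at 50% prevalence supports the prevalence-matched
design. `solve_intercept_for_prevalence` re-solves α for any other target
prevalence by root-finding on the exact quadrature of `E[p_true]` (the
integral is split at B = 0 where the marker-prevalence rule switches).

**Randomness.** One seeded `numpy` Generator per cohort. The experiment
driver gives replicate `r` the seeds `base_seed + 2r` (training) and
`base_seed + 2r + 1` (validation), so any replicate can be regenerated in
isolation and results are bit-reproducible given `(config, base_seed)`.

**Supplementary scenarios.** `simulate_supplementary_s1` replaces the
binary markers with a continuous marker `Z ~ N(0.5·1[B>0], 1)` (the mean
shift plays the role of the 85%/75% correlation rule) entering with log-OR
1.0 per SD, optionally kernel-modulated. `simulate_supplementary_s2`
emulates a genetic score: 18 independent Bernoulli(0.3) markers —
carriage independent of B, as for germline variants — each with log-OR
0.25 (OR ≈ 1.28, individually near-useless at n = 500), entering through
their centered unweighted sum. These per-marker values were chosen once so
that the score is individually weak but collectively strong at the study's
sample sizes.

## The experiment

Per replicate: simulate 500 training and 500 validation subjects, fit
three working models by maximum-likelihood logistic regression (Newton,
relative tolerance 1e-8, 100 iterations max), evaluate every index on the
validation cohort, aggregate by arithmetic mean over replicates. Absolute
improvements are means of per-replicate deltas; relative improvements are
100 × that over the baseline aggregate mean (both the mean-of-deltas and
delta-of-means are reported; they agree over a common replicate set).
Degenerate replicates — single-class cohorts, perfect separation,
non-convergence — are flagged, counted by reason, and skipped, never
imputed. Evaluation on the training sample is available via
`evaluate_on="training"` for optimism checks; validation is the default.

**Model III functional form.** The fitted gray-zone model is
`logit(D) ~ B + K(B)·M2` by default — the analyst is assumed to know that
M2's effect lives in the gray zone. This is a deliberate design choice:
with a plain main-effects fit `B + M2` the working model averages M2's
effect over B and the Pietra-vs-AUC contrast collapses
(ΔPietra/ΔAUC ≈ 1.8 instead of ≈ 3.8); the gray-zone redistribution of
predicted probabilities the experiment studies only materializes when the
working model can express it. `m2_form="linear"` switches to the
main-effects form for sensitivity analysis.

## What the generator does and does not emulate

The synthetic cohorts have an exactly logistic true risk, exactly normal
baseline score, and markers whose dependence on B is a one-step function —
so `p_true` is perfectly calibrated by construction, which is precisely
the regime where the algebraic identities above hold and what makes the
generator a sharp test harness. Real cohorts add model misspecification,
measurement error, missing data and case-mix heterogeneity, none of which
are modelled; passing tests certify the measures and the experiment
machinery, not robustness of any index to those complications.

## Problem sizes

The default test run uses up to 1000 replicates for the aggregate-table
check (Monte-Carlo SE ≈ 0.001 per cell) and 200-replicate loops for
dominance/identity checks; `scripts/acceptance.py` uses 10000 replicates.
Simulator marginal checks use n = 200,000 (binomial SE ≈ 0.001 for the
85%/75% prevalences).

## Limitations

No confidence intervals or hypothesis tests are provided for Gini, Pietra
or sBrier — inference for these indices is an open problem — and no
survival-time or bias-corrected variants of NRI/IDI are implemented.
Calibration assessment (e.g. Hosmer–Lemeshow) is out of scope: the package
measures discrimination.
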
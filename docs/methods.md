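# Methods

This note documents the models, defaults and design choices behind
`twinforge`, and what the synthetic study conditions do and do not
establish about real survey data.

## The synthetic cohort generator

The generator emulates a paired two-wave midlife health panel. Baseline
(W2) variables are drawn independently per participant:

| Variable | Domain | Distribution (defaults) |
| --- | --- | --- |
| age | biological | Normal(56.0, 12.4) years |
| sex_male | biological | Bernoulli(0.452) |
| bmi | biological | Normal(27.9, 5.7), floored at 15 kg/m² |
| height_inches / weight_lbs | biological | height Normal(66.5, 3.8); weight derived as `bmi·h²/703` |
| hypertension | biological | Bernoulli(0.303) |
| prescription_meds | biological | Bernoulli(0.05 + 0.6·p_risk) — a deliberate downstream proxy |
| physical_activity | behavioral | discretized Normal(3.5, 1.5) on a 1–6 ordinal scale |
| current/ever smoker | behavioral | Bernoulli(0.20); ever = current OR Bernoulli(0.45) |
| alcohol_drinks_week | behavioral | Normal(4.0, 3.5) floored at 0 |
| depression / anxiety / stress | psychosocial | non-negative clipped normals (0.6±1.7, 1.2±1.1, 2.5±1.0) |
| education_years, household_income | socioeconomic | Normal(7.3, 2.5) on the category scale; log-normal(median $57,500, σ=0.88) |
| interviewer_id, site, admin_noise_* | administrative | categorical / standard normal, independent of the outcome |

The follow-up outcome is Bernoulli with
`P(Y=1) = logistic(β₀ + Σ βⱼ x_j^{W2})`; the default coefficient vector
spans all four substantive domains (positive weights on age, BMI,
hypertension, smoking, alcohol, anxiety, depression; negative on
activity, education, income) and gives a Bayes AUC of ≈0.75 — the
regime where a well-specified logistic fit should essentially match the
oracle. The intercept is calibrated by 1-D root finding (Brent) on the
mean predicted risk, so the realized incidence converges to the target
(14.7% by default) as n grows. Follow-up values are baseline + a
configured mean drift + a Gaussian innovation (0.3× the cross-sectional
SD); binary conditions get explicit onset/cessation probabilities
(hypertension onset 12.3%, smoking cessation 25%). No richer dynamics
are modeled: the panel's only temporal structure is the paired record.

Missingness supports MCAR and a linear-in-quantile MAR mechanism (the
deletion probability scales with the named covariate's empirical
quantile while preserving the marginal rate); attrition drops whole
follow-up records before pairing. The missing marker is `NaN`, which is
outside every declared scale and round-trips unambiguously through
CSV/Parquet.

An optional `confounded_admin` flag adds an administrative batch code
equal to the true linear predictor plus noise — an artifact that
statistical selectors latch onto and a domain-aware relevance agent
should reject; it exists to exercise the semantic audit and is off by
default.

**What passing tests on this generator do not show:** real survey data
have correlated predictors, informative (MNAR) dropout, measurement
error and many-thousand-variable inventories. The generator certifies
the machinery (calibration, recovery, leakage-safety, determinism,
monotone sensitivity), not external validity on any real cohort.

## Ontology retrieval and the relevance agent

Ontology fixtures are JSON arrays of concepts (IRI, label, definition,
source) and subject–predicate–object triples; dangling triples are
collected, not fatal. The shipped embedder hashes character 3-grams of
the lower-cased text into a 256-dimensional vector with keyed BLAKE2
hashing, unit-normalized — deterministic per text, so identical labels
embed identically and retrieval is exactly reproducible. It is a
retrieval *contract* stand-in, not a semantic model; any
text→unit-vector embedder (e.g. a sentence-transformer adapter)
satisfies the same interface. Retrieval takes the top k = 5 concepts at
cosine ≥ 0.3 over the concatenated variable name + label (configurable),
ties broken lexicographically by IRI, with touching triples and the
fixture definition attached.

The agent prompt is a deterministic concatenation of a fixed system
instruction, variable metadata, the rendered context block, an explicit
scoring rubric and the required-JSON-schema statement. Control flow is
bounded: one invocation; on schema failure or score < 0.3, exactly one
requery with the context re-retrieved at 2k; then exclusion. Every
invocation is logged (prompt digest, raw response, parsed decision).
Backends are pluggable; the shipped stubs (a scripted queue and a
domain-rubric scorer) are explicit test harnesses and make no claim
about any particular language model's outputs. Ranking keeps
non-excluded decisions sorted by score (catalog order breaks ties) and
truncates to the top 200. Baselines: Lasso ranks by |coefficient| at the
first point of a 25-step regularization path with ≥k non-zeros; MI uses
the k-NN mutual-information estimator; both fixed at `random_state=42`.

The semantic audit classifies ranked variables by catalog tags:
administrative domain → "noise"; non-modifiable substantive variables
whose label marks them as medication/prescription checklists →
"proxy/downstream"; everything else → target-relevant.

## Cleaning, prediction and calibration

Imputation routes by missing fraction: ≤5% → mean (continuous) or mode
(ordinal/binary/categorical); above that, numeric columns use k-NN
imputation (k = 5) on z-scored complete features (nan-Euclidean
distance), while categorical columns always take the mode — a deliberate
simplification over a mixed-metric k-NN, since categorical missingness
in these panels is low and the mixed metric adds surface without a
testable benefit. Continuous features are winsorized at ±4 SD and
z-scored. All parameters are fitted once and reapplied verbatim to new
data (the scenario engine depends on this).

Prediction uses stratified 5-fold CV. Class rebalancing is SMOTE-style
interpolation to a 1:1 ratio fitted inside each training fold only:
synthetic points interpolate between a minority sample and one of its
5 minority neighbors; integer-coded coordinates copy the nearer donor.
Synthetic rows are appended after the originals so an audit can assert
that evaluation folds contain none. Note that 1:1 rebalancing
deliberately trades probability calibration for minority sensitivity —
pooled Brier/ECE of the rebalanced models reflect that shift and are
reported rather than hidden. Accuracy is thresholded at 0.5. Brier is
the mean squared probability error (multiclass: mean over classes of
the squared one-hot error); ECE uses 10 equal-width bins on the
(top-class) confidence. Attribution uses native TreeSHAP contributions
for boosted trees and seeded permutation importance otherwise.

Outcome labeling for external panels follows an OR rule over
self-report, medication use, fasting glucose ≥ 126 mg/dL and HbA1c
≥ 6.5% (standard diagnostic cut-offs; configurable); missing channels
count as negative evidence, and an all-missing record is labeled 0 with
an audit flag.

## The twin

The risk score feeding state construction is the **out-of-fold**
predicted probability of the best-AUC predictor; follow-up risks apply
the same baseline-trained predictor to follow-up features under the
stored preprocessing plan. 1-D k-means is solved exactly by dynamic
programming over contiguous partitions of the sorted risks — globally
optimal SSE and fully deterministic, which subsumes the usual
k-means++ restart scheme (the `seed` argument is recorded for
provenance). Assignment is nearest-centroid with midpoint ties going to
the lower-risk state. Centroids are frozen after fitting; a digest
check asserts they never change during simulation.

The transition model is a multiclass classifier on
`[x_W2, one-hot(S_W2)]`, reporting accuracy ± SD, macro-F1, the average
log-likelihood of the realized next state, and multiclass Brier/ECE.
The outcome model consumes `[x_W2, one-hot(S_W2), P(S_W3)]` where the
soft states are the transition model's out-of-fold predictions;
passing in-sample soft states raises a leakage error. SMOTE is off for
both stages by default (the multiclass transition targets are not
rebalanced).

Scenario semantics: multiplicative changes scale by `1 + value` (so a
0% change multiplies by exactly 1.0 and is bit-identical — this is what
makes the placebo identity exact rather than merely small); additive
reductions floor at the scale minimum (0 for non-negative continuous
scores); ordinal shifts round and clamp to the declared bounds;
propagation rules re-apply the same perturbation to derived variables
(weight → BMI at fixed height). During simulation the baseline state is
recomputed from the perturbed features with the frozen centroids, so a
perturbation propagates coherently through both stages; the placebo
identity is unaffected. "Predicted cases" counts outcome-model
probabilities ≥ 0.5 (configurable), and high→low transitions compare
hard predicted-state labels baseline vs perturbed on the same frozen
state model.

The stability protocol refits states for K = 3–5 and defines each K's
high-risk population as the union of highest-centroid clusters whose
combined size first reaches the K = 3 high-risk group size (exact
equality is generically impossible, so the rule accumulates to ≥ the
reference); pairwise Jaccard overlaps of the baseline memberships
quantify robustness to the granularity choice.

## Problem sizes and numerical choices

Test and acceptance workloads use n = 600–4,174 cohorts for end-to-end
twin builds, n = 20,000 for parameter recovery (simultaneous
Bonferroni-adjusted 95% intervals over the 10 signal coefficients, the
family-wise formalization of "every coefficient covered at 95%
confidence"), n = 50,000 for incidence-calibration and
noise-independence checks, and n = 10,000 for transition-model
closed-form sanity (copy dynamics → accuracy 1, average log-likelihood
≈ 0; label-independent balanced states → accuracy ≈ 1/3, average
log-likelihood ≈ −log 3). Probability clipping uses 1e-15 in
log-likelihoods; retrieval similarity ties break lexicographically;
k-means uses exact DP so no tolerance or restart policy is needed.

## Known limitations

- Single-step, between-wave transitions only; no multistep simulation,
  online updating, or causal-effect estimation. What-if outputs are
  model sensitivities.
- The relevance agent's shipped backends are deterministic stubs; live
  LLM behavior (and the generated-then-filtered concept explanations it
  would produce) is outside the deterministic scope — fixture
  definitions stand in for explanations.
- The generator draws predictors independently; correlated designs
  (beyond the built-in weight/BMI/height and smoking couplings, and the
  optional confounded administrative code) must be added by the caller.
- Ordinal/categorical k-NN imputation distance is simplified to
  mode-filling; MNAR mechanisms are not modeled.
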
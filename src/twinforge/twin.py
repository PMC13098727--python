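"""Risk states, transition/outcome models and the what-if engine.

The twin discretizes a continuous predicted-risk score into K ordered
states (low/medium/high for K=3) by exact 1-D k-means on baseline
(wave-2) out-of-fold risks. Centroids are frozen at baseline: follow-up
risks are assigned with the same centroids, never refit. A multiclass
transition model estimates P(S_W3 | S_W2, x_W2) and a downstream binary
outcome model estimates P(Y_W3 | S_W2, soft S_W3, x_W2), with the soft
follow-up state features cross-fitted (out-of-fold) to prevent leakage.

Scenario simulation perturbs modifiable wave-2 covariates, pushes the
perturbed cohort through the frozen, deterministic model stack, and
reports state-distribution and risk deltas. A zero-magnitude (placebo)
scenario provably changes nothing; monotonicity sweeps and the
K-stability protocol provide the robustness checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score, average_precision_score
from sklearn.model_selection import StratifiedKFold

from .catalog import VariableMetadata, catalog_by_name
from .cohort import CohortPanel
from .modeling import (
    LabeledMatrix,
    MetricsReport,
    PredictorBundle,
    PreprocessPlan,
    calibration_metrics,
    labeled_matrix_from_panel,
    make_model,
    train_predictors,
    MODEL_NAMES,
)

__all__ = [
    "RiskStateModel",
    "TransitionModel",
    "OutcomeModel",
    "ScenarioSpec",
    "Perturbation",
    "ScenarioResult",
    "DigitalTwin",
    "fit_states",
    "assign_states",
    "high_risk_union",
    "jaccard_overlap",
    "fit_transition",
    "fit_outcome",
    "build_twin",
    "apply_scenario",
    "simulate_scenario",
    "monotonicity_sweep",
    "stability_analysis",
    "load_scenario",
]

STATE_LABELS_K3 = ("low", "medium", "high")


class ScenarioError(ValueError):
    """Scenario perturbs variables outside the actionable set."""


# ---------------------------------------------------------------------------
# Risk states


@dataclass
class RiskStateModel:
    """Sorted 1-D centroids over predicted risk; frozen after fitting."""

    K: int
    centroids: np.ndarray  # strictly increasing, in [0,1]
    labels: tuple[str, ...]
    fit_seed: int
    cluster_sizes: np.ndarray  # membership at fit time, by state index
    high_risk_clusters: frozenset[int]
    reference_high_size: int

    def centroid_digest(self) -> str:
        return hashlib.sha256(self.centroids.tobytes()).hexdigest()[:16]


def _kmeans_1d_exact(x: np.ndarray, K: int) -> tuple[np.ndarray, float]:
    """Globally optimal 1-D k-means via DP over contiguous partitions.

    The optimum of 1-D k-means partitions the sorted data contiguously,
    so dynamic programming over segment boundaries yields the exact
    minimum within-cluster SSE. Returns (centroids ascending, SSE).
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg_sse(j: np.ndarray, i: int) -> np.ndarray:
        cnt = i - j + 1
        s = s1[i + 1] - s1[j]
        q = s2[i + 1] - s2[j]
        return q - s * s / cnt

    D = np.full((K, n), np.inf)
    B = np.zeros((K, n), dtype=int)
    idx0 = np.arange(n)
    D[0, :] = s2[idx0 + 1] - s1[idx0 + 1] ** 2 / (idx0 + 1)
    for k in range(1, K):
        for i in range(k, n):
            j = np.arange(k, i + 1)
            cand = D[k - 1, j - 1] + seg_sse(j, i)
            best = int(np.argmin(cand))
            D[k, i] = cand[best]
            B[k, i] = k + best
    boundaries = []
    i = n - 1
    for k in range(K - 1, 0, -1):
        j = B[k, i]
        boundaries.append(j)
        i = j - 1
    boundaries = boundaries[::-1]
    starts = [0] + boundaries
    ends = boundaries + [n]
    centroids = np.array([xs[a:b].mean() for a, b in zip(starts, ends)])
    return centroids, float(D[K - 1, n - 1])


def fit_states(risk_w2: np.ndarray, K: int = 3, seed: int = 0) -> RiskStateModel:
    """Cluster baseline predicted risks into K ordered states.

    Solved exactly (DP on the sorted risks), so the result is fully
    deterministic; ``seed`` is recorded for provenance.
    """
    risk = np.asarray(risk_w2, dtype=float)
    if K < 2:
        raise ValueError("K must be >= 2")
    if np.any((risk < 0) | (risk > 1)):
        raise ValueError("risks must lie in [0,1]")
    if len(np.unique(risk)) < K:
        raise ValueError(f"need at least {K} distinct risk values")
    centroids, _ = _kmeans_1d_exact(risk, K)
    labels = STATE_LABELS_K3 if K == 3 else tuple(f"state_{i}" for i in range(K))
    model = RiskStateModel(
        K=K,
        centroids=centroids,
        labels=labels,
        fit_seed=seed,
        cluster_sizes=np.zeros(K, dtype=int),
        high_risk_clusters=frozenset({K - 1}),
        reference_high_size=0,
    )
    assigned = assign_states(risk, model)
    model.cluster_sizes = np.bincount(assigned, minlength=K)
    model.reference_high_size = int(model.cluster_sizes[K - 1])
    return model


def assign_states(risk: np.ndarray, model: RiskStateModel) -> np.ndarray:
    """Nearest-centroid assignment; midpoint ties go to the lower state.

    Never refits centroids — wave-3 risks are scored against the frozen
    wave-2 geometry.
    """
    risk = np.asarray(risk, dtype=float)
    if np.any((risk < 0) | (risk > 1)):
        raise ValueError("risks must lie in [0,1]")
    d = np.abs(risk[:, None] - model.centroids[None, :])
    return d.argmin(axis=1)  # argmin takes the first (lower-centroid) minimum


def high_risk_union(model: RiskStateModel, reference_high_size: int) -> frozenset[int]:
    """Union-matching rule for K>3 comparability.

    Clusters are taken in descending-centroid order, accumulating until
    the combined membership reaches the K=3 high-risk group size. Always
    returns at least the top cluster.
    """
    total = int(model.cluster_sizes.sum())
    if reference_high_size > total:
        raise ValueError("reference size exceeds population")
    union: list[int] = []
    cum = 0
    for idx in range(model.K - 1, -1, -1):
        union.append(idx)
        cum += int(model.cluster_sizes[idx])
        if cum >= reference_high_size:
            break
    return frozenset(union)


def jaccard_overlap(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets overlap perfectly (1.0)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# Transition and outcome models


def _one_hot(s: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros((len(s), K))
    out[np.arange(len(s)), s] = 1.0
    return out


def _expand_proba(p: np.ndarray, classes: np.ndarray, K: int) -> np.ndarray:
    full = np.zeros((p.shape[0], K))
    full[:, classes] = p
    return full


@dataclass
class TransitionModel:
    """P(S_W3 | S_W2, x_W2): multiclass classifier over K states."""

    model: object
    model_name: str
    K: int
    classes_: np.ndarray
    metrics: dict[str, dict]
    oof_proba: np.ndarray  # (n, K) cross-fitted soft states
    n_features: int

    def predict_proba(self, x: np.ndarray, s_w2: np.ndarray) -> np.ndarray:
        feats = np.hstack([x, _one_hot(s_w2, self.K)])
        p = self.model.predict_proba(feats)
        full = _expand_proba(p, self.classes_, self.K)
        return full / full.sum(axis=1, keepdims=True)


def _cv_folds(y: np.ndarray, folds: int, seed: int):
    counts = np.bincount(y)
    min_class = counts[counts > 0].min()
    eff = min(folds, int(min_class))
    if eff < folds:
        warnings.warn(
            f"smallest state has {min_class} members; reducing folds to {eff}"
        )
    if eff < 2:
        raise ValueError("a state has fewer than 2 members; cannot cross-validate")
    return StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed)


def fit_transition(
    x_w2: np.ndarray,
    s_w2: np.ndarray,
    s_w3: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    K: int | None = None,
    models: Sequence[str] = ("gradient_boosted_trees",),
) -> TransitionModel:
    """Cross-validated multiclass state-transition model.

    Reports accuracy (mean and SD over folds), macro-F1, average
    log-likelihood of the realized next state, and multiclass
    Brier/ECE. The best model (by pooled accuracy) is refit on all data.
    """
    x_w2 = np.asarray(x_w2, dtype=float)
    s_w2 = np.asarray(s_w2, dtype=int)
    s_w3 = np.asarray(s_w3, dtype=int)
    K = K or int(max(s_w2.max(), s_w3.max())) + 1
    present = np.unique(s_w3)
    if len(present) < K:
        warnings.warn(
            f"states {sorted(set(range(K)) - set(present))} absent from wave-3 targets"
        )
    # contiguous re-encoding for the classifier
    to_local = {c: i for i, c in enumerate(present)}
    y_local = np.array([to_local[s] for s in s_w3])
    feats = np.hstack([x_w2, _one_hot(s_w2, K)])
    skf = _cv_folds(y_local, folds, seed)
    metrics: dict[str, dict] = {}
    oof: dict[str, np.ndarray] = {}
    for name in models:
        oof_p = np.zeros((len(y_local), len(present)))
        fold_acc = []
        for tr, te in skf.split(feats, y_local):
            m = make_model(name, seed)
            m.fit(feats[tr], y_local[tr])
            p = m.predict_proba(feats[te])
            oof_p[te] = p
            fold_acc.append(float(np.mean(p.argmax(axis=1) == y_local[te])))
        yhat = oof_p.argmax(axis=1)
        ll = float(np.mean(np.log(np.clip(oof_p[np.arange(len(y_local)), y_local], 1e-15, 1.0))))
        brier, ece = calibration_metrics(y_local, oof_p)
        metrics[name] = {
            "accuracy": float(np.mean(yhat == y_local)),
            "accuracy_sd": float(np.std(fold_acc, ddof=1)) if len(fold_acc) > 1 else 0.0,
            "macro_f1": float(f1_score(y_local, yhat, average="macro")),
            "avg_log_likelihood": ll,
            "brier": brier,
            "ece": ece,
        }
        oof[name] = oof_p
    best = max(models, key=lambda n: metrics[n]["accuracy"])
    final = make_model(best, seed)
    final.fit(feats, y_local)
    return TransitionModel(
        model=final,
        model_name=best,
        K=K,
        classes_=present,
        metrics=metrics,
        oof_proba=_expand_proba(oof[best], present, K),
        n_features=x_w2.shape[1],
    )


@dataclass
class OutcomeModel:
    """P(Y_W3 = 1 | S_W2, soft S_W3, x_W2)."""

    model: object
    model_name: str
    K: int
    metrics: dict[str, dict]
    oof_proba: np.ndarray
    n_features: int

    def predict_proba(
        self, x: np.ndarray, s_w2: np.ndarray, p_s_w3: np.ndarray
    ) -> np.ndarray:
        feats = np.hstack([x, _one_hot(s_w2, self.K), p_s_w3])
        return self.model.predict_proba(feats)[:, 1]


def fit_outcome(
    x_w2: np.ndarray,
    s_w2: np.ndarray,
    p_s_w3_soft: np.ndarray,
    y_w3: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    models: Sequence[str] = ("gradient_boosted_trees",),
    soft_is_crossfitted: bool = True,
) -> OutcomeModel:
    """Binary follow-up outcome model on baseline features + soft states.

    ``p_s_w3_soft`` must be out-of-fold transition predictions; passing
    in-sample soft states trips the leakage detector.
    """
    if not soft_is_crossfitted:
        raise ValueError(
            "soft wave-3 state features must be cross-fitted (out-of-fold); "
            "refusing in-sample soft states"
        )
    x_w2 = np.asarray(x_w2, dtype=float)
    s_w2 = np.asarray(s_w2, dtype=int)
    y = np.asarray(y_w3, dtype=int)
    K = p_s_w3_soft.shape[1]
    feats = np.hstack([x_w2, _one_hot(s_w2, K), p_s_w3_soft])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    metrics: dict[str, dict] = {}
    oof: dict[str, np.ndarray] = {}
    for name in models:
        p_oof = np.zeros(len(y))
        fold_auc = []
        for tr, te in skf.split(feats, y):
            m = make_model(name, seed)
            m.fit(feats[tr], y[tr])
            p = m.predict_proba(feats[te])[:, 1]
            p_oof[te] = p
            fold_auc.append(float(roc_auc_score(y[te], p)))
        brier, ece = calibration_metrics(y, p_oof)
        metrics[name] = {
            "auc": float(roc_auc_score(y, p_oof)),
            "auc_sd": float(np.std(fold_auc, ddof=1)) if len(fold_auc) > 1 else 0.0,
            "pr_auc": float(average_precision_score(y, p_oof)),
            "brier": brier,
            "ece": ece,
        }
        oof[name] = p_oof
    best = max(models, key=lambda n: metrics[n]["auc"])
    final = make_model(best, seed)
    final.fit(feats, y)
    return OutcomeModel(
        model=final,
        model_name=best,
        K=K,
        metrics=metrics,
        oof_proba=oof[best],
        n_features=x_w2.shape[1],
    )


# ---------------------------------------------------------------------------
# The assembled twin


@dataclass
class DigitalTwin:
    bundle: PredictorBundle
    report: MetricsReport
    plan: PreprocessPlan
    states: RiskStateModel
    transition: TransitionModel
    outcome: OutcomeModel
    catalog: list[VariableMetadata]
    feature_names: list[str]
    ids: np.ndarray
    risk_w2: np.ndarray
    risk_w3: np.ndarray
    s_w2: np.ndarray
    s_w3: np.ndarray
    seed: int


def build_twin(
    panel: CohortPanel,
    seed: int = 0,
    folds: int = 5,
    K: int = 3,
    predictor_models: Sequence[str] = MODEL_NAMES,
    transition_models: Sequence[str] = ("gradient_boosted_trees",),
    outcome_models: Sequence[str] = ("gradient_boosted_trees",),
    features: Sequence[str] | None = None,
) -> DigitalTwin:
    """End-to-end twin construction from a paired panel.

    The risk score feeding state construction is the out-of-fold
    predicted probability of the best-AUC predictor; wave-3 risks come
    from applying the same wave-2-trained predictor to wave-3 features
    under the stored preprocessing plan.
    """
    panel = panel.pair()
    lm, plan = labeled_matrix_from_panel(panel, features=features)
    bundle, report = train_predictors(
        lm, models=predictor_models, folds=folds, seed=seed
    )
    risk_w2 = bundle.oof_proba[bundle.best_model]
    X3 = plan.transform(panel.wave("W3").astype(float))[list(lm.X.columns)]
    risk_w3 = bundle.predict_proba(X3)
    states = fit_states(risk_w2, K=K, seed=seed)
    s_w2 = assign_states(risk_w2, states)
    s_w3 = assign_states(risk_w3, states)
    tm = fit_transition(
        lm.X.to_numpy(), s_w2, s_w3, folds=folds, seed=seed, K=K,
        models=transition_models,
    )
    om = fit_outcome(
        lm.X.to_numpy(), s_w2, tm.oof_proba, lm.y, folds=folds, seed=seed,
        models=outcome_models, soft_is_crossfitted=True,
    )
    return DigitalTwin(
        bundle=bundle,
        report=report,
        plan=plan,
        states=states,
        transition=tm,
        outcome=om,
        catalog=panel.catalog,
        feature_names=list(lm.X.columns),
        ids=lm.ids,
        risk_w2=risk_w2,
        risk_w3=risk_w3,
        s_w2=s_w2,
        s_w3=s_w3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scenarios

PERTURBATION_KINDS = ("multiplicative", "additive", "ordinal_shift", "categorical_set")


@dataclass(frozen=True)
class Perturbation:
    variable: str
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ScenarioError(f"unknown perturbation kind {self.kind!r}")


@dataclass
class ScenarioSpec:
    """Declarative what-if perturbation of modifiable wave-2 covariates."""

    name: str
    perturbations: list[Perturbation]
    propagate: list[tuple[str, str]] = field(default_factory=list)  # (source, target)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "perturbations": [dataclasses.asdict(p) for p in self.perturbations],
            "propagate": [list(pair) for pair in self.propagate],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            name=d["name"],
            perturbations=[Perturbation(**p) for p in d["perturbations"]],
            propagate=[tuple(pair) for pair in d.get("propagate", [])],
        )


def load_scenario(path: str | Path) -> ScenarioSpec:
    return ScenarioSpec.from_dict(json.loads(Path(path).read_text()))


def _builtin_scenario(name: str) -> Path:
    return Path(__file__).parent / "scenarios" / f"{name}.json"


def apply_scenario(panel: CohortPanel, scenario: ScenarioSpec) -> CohortPanel:
    """Apply perturbations to wave-2 values; untouched columns are shared.

    Every perturbed variable (including propagation targets) must be
    flagged modifiable in the catalog; ordinal shifts and multiplicative
    changes on ordinal scales clamp to the declared bounds; additive
    reductions on non-negative variables floor at zero.
    """
    by_name = catalog_by_name(panel.catalog)
    targets = [p.variable for p in scenario.perturbations] + [
        t for _, t in scenario.propagate
    ]
    missing = [v for v in targets if v not in by_name]
    if missing:
        raise ScenarioError(f"scenario names unknown variables: {missing}")
    frozen = sorted({v for v in targets if not by_name[v].modifiable})
    if frozen:
        raise ScenarioError(
            f"scenario perturbs non-modifiable variables: {frozen}"
        )
    out = panel.copy()
    w2 = out.data["wave"] == "W2"
    prop_map: dict[str, list[str]] = {}
    for src, tgt in scenario.propagate:
        prop_map.setdefault(src, []).append(tgt)

    def _apply(var: str, pert: Perturbation) -> None:
        meta = by_name[var]
        col = out.data.loc[w2, var].astype(float)
        if pert.kind == "multiplicative":
            col = col * (1.0 + pert.value)
        elif pert.kind == "additive":
            col = col + pert.value
            if pert.value < 0:
                floor = meta.scale_min if meta.scale_min is not None else 0.0
                col = col.clip(lower=floor)
        elif pert.kind == "ordinal_shift":
            col = col + pert.value
        elif pert.kind == "categorical_set":
            col = pd.Series(float(pert.value), index=col.index)
        if meta.dtype == "ordinal":
            col = np.rint(col).clip(meta.scale_min, meta.scale_max)
        elif meta.scale_min is not None or meta.scale_max is not None:
            col = col.clip(meta.scale_min, meta.scale_max)
        out.data.loc[w2, var] = col

    for pert in scenario.perturbations:
        _apply(pert.variable, pert)
        for tgt in prop_map.get(pert.variable, []):
            _apply(tgt, dataclasses.replace(pert, variable=tgt))
    return out


@dataclass
class ScenarioResult:
    scenario: str
    n: int
    state_labels: tuple[str, ...]
    baseline_state_fractions: np.ndarray
    perturbed_state_fractions: np.ndarray
    baseline_cases: int
    perturbed_cases: int
    baseline_mean_risk: float
    perturbed_mean_risk: float
    risk_delta: np.ndarray  # perturbed - baseline, per participant
    n_state_changes: int
    n_high_to_low: int
    n_reduced_risk: int
    case_threshold: float

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "n": self.n,
            "baseline_state_fractions": self.baseline_state_fractions.tolist(),
            "perturbed_state_fractions": self.perturbed_state_fractions.tolist(),
            "predicted_cases_baseline": self.baseline_cases,
            "predicted_cases_perturbed": self.perturbed_cases,
            "case_delta": self.perturbed_cases - self.baseline_cases,
            "mean_risk_baseline": self.baseline_mean_risk,
            "mean_risk_perturbed": self.perturbed_mean_risk,
            "any_state_change": self.n_state_changes,
            "high_to_low_transitions": self.n_high_to_low,
            "individuals_with_reduced_risk": self.n_reduced_risk,
            "max_abs_state_fraction_change": float(
                np.max(
                    np.abs(
                        self.perturbed_state_fractions - self.baseline_state_fractions
                    )
                )
            ),
        }


def _run_stack(twin: DigitalTwin, panel: CohortPanel) -> dict:
    """Deterministic pipeline: features -> risk -> states -> soft -> outcome."""
    w2 = panel.wave("W2")
    X = twin.plan.transform(w2.astype(float))[twin.feature_names]
    risk2 = twin.bundle.predict_proba(X)
    s2 = assign_states(risk2, twin.states)
    Xnp = X.to_numpy(dtype=float)
    soft = twin.transition.predict_proba(Xnp, s2)
    risk = twin.outcome.predict_proba(Xnp, s2, soft)
    s3hat = assign_states(risk, twin.states)
    return {"risk2": risk2, "s2": s2, "soft": soft, "risk": risk, "s3hat": s3hat}


def simulate_scenario(
    panel: CohortPanel,
    scenario: ScenarioSpec,
    twin: DigitalTwin,
    case_threshold: float = 0.5,
    run_log: list | None = None,
) -> ScenarioResult:
    """Run the twin on baseline and perturbed inputs and diff the results.

    The stack is deterministic end to end, so a placebo scenario (all
    zero magnitudes) yields exactly zero deltas everywhere.
    """
    panel = panel.pair()
    digest_before = twin.states.centroid_digest()
    base = _run_stack(twin, panel)
    perturbed_panel = apply_scenario(panel, scenario)
    pert = _run_stack(twin, perturbed_panel)
    assert twin.states.centroid_digest() == digest_before, "centroids must stay frozen"
    K = twin.states.K
    n = len(base["risk"])
    frac_base = np.bincount(base["s3hat"], minlength=K) / n
    frac_pert = np.bincount(pert["s3hat"], minlength=K) / n
    delta = pert["risk"] - base["risk"]
    high = max(twin.states.high_risk_clusters)
    result = ScenarioResult(
        scenario=scenario.name,
        n=n,
        state_labels=twin.states.labels,
        baseline_state_fractions=frac_base,
        perturbed_state_fractions=frac_pert,
        baseline_cases=int(np.sum(base["risk"] >= case_threshold)),
        perturbed_cases=int(np.sum(pert["risk"] >= case_threshold)),
        baseline_mean_risk=float(base["risk"].mean()),
        perturbed_mean_risk=float(pert["risk"].mean()),
        risk_delta=delta,
        n_state_changes=int(np.sum(base["s3hat"] != pert["s3hat"])),
        n_high_to_low=int(np.sum((base["s3hat"] == high) & (pert["s3hat"] == 0))),
        n_reduced_risk=int(np.sum(delta < 0)),
        case_threshold=case_threshold,
    )
    if run_log is not None:
        run_log.append(result.summary())
    return result


def monotonicity_sweep(
    panel: CohortPanel,
    twin: DigitalTwin,
    variable: str = "weight_lbs",
    magnitudes: Sequence[float] = (0.05, 0.10, 0.15),
    propagate: Sequence[tuple[str, str]] = (("weight_lbs", "bmi"),),
    run_log: list | None = None,
) -> dict:
    """Mean predicted risk under increasing reductions of one variable."""
    if not len(magnitudes):
        raise ValueError("magnitudes must be non-empty")
    means = []
    for mag in magnitudes:
        spec = ScenarioSpec(
            name=f"{variable}_-{mag:g}",
            perturbations=[Perturbation(variable, "multiplicative", -float(mag))],
            propagate=[p for p in propagate if p[0] == variable],
        )
        res = simulate_scenario(panel, spec, twin, run_log=run_log)
        means.append(res.perturbed_mean_risk)
    monotone = all(b <= a + 1e-12 for a, b in zip(means, means[1:]))
    return {
        "variable": variable,
        "magnitudes": list(magnitudes),
        "mean_risk": means,
        "monotone_non_increasing": monotone,
    }


@dataclass
class StabilityReport:
    K_values: list[int]
    high_sets: dict[int, frozenset]
    high_sizes: dict[int, int]
    jaccard: pd.DataFrame
    transition_accuracy: dict[int, float] | None = None


def stability_analysis(
    risk_w2: np.ndarray,
    risk_w3: np.ndarray,
    K_range: Sequence[int] = (3, 4, 5),
    seed: int = 0,
    x_w2: np.ndarray | None = None,
    folds: int = 5,
) -> StabilityReport:
    """High-risk membership stability across state granularities.

    For each K the high-risk population is the union-matched cluster
    set sized against the K=3 reference; the report gives pairwise
    Jaccard overlaps of the wave-2 high-risk memberships (and, when
    features are supplied, per-K transition accuracy).
    """
    if any(k < 2 for k in K_range):
        raise ValueError("all K must be >= 2")
    risk_w2 = np.asarray(risk_w2, dtype=float)
    ref_K = 3 if 3 in K_range else min(K_range)
    ref_model = fit_states(risk_w2, K=ref_K, seed=seed)
    ref_size = ref_model.reference_high_size
    high_sets: dict[int, frozenset] = {}
    sizes: dict[int, int] = {}
    acc: dict[int, float] = {}
    for K in K_range:
        model = fit_states(risk_w2, K=K, seed=seed)
        union = high_risk_union(model, ref_size)
        assigned = assign_states(risk_w2, model)
        members = frozenset(np.flatnonzero(np.isin(assigned, list(union))).tolist())
        high_sets[K] = members
        sizes[K] = len(members)
        if x_w2 is not None:
            s3 = assign_states(np.asarray(risk_w3, dtype=float), model)
            tm = fit_transition(
                x_w2, assigned, s3, folds=folds, seed=seed, K=K,
                models=("gradient_boosted_trees",),
            )
            acc[K] = tm.metrics["gradient_boosted_trees"]["accuracy"]
    Ks = list(K_range)
    mat = pd.DataFrame(
        [[jaccard_overlap(high_sets[a], high_sets[b]) for b in Ks] for a in Ks],
        index=Ks,
        columns=Ks,
    )
    return StabilityReport(
        K_values=Ks,
        high_sets=high_sets,
        high_sizes=sizes,
        jaccard=mat,
        transition_accuracy=acc if x_w2 is not None else None,
    )
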
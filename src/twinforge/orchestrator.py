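"""Deterministic hub-and-spoke orchestration with critic hooks.

A single controller executes the stages in dependency order (cohort ->
ontology index -> feature selection -> predictor training -> twin
construction -> scenarios), writing every artifact to disk and recording
a run manifest of configuration, content digests and timings. Stages
never talk to each other directly; all hand-offs go through the
orchestrator, and two critic checkpoints gate what propagates: relevance
decisions are validated for schema/score-band consistency, and scenarios
are screened for actionability (perturbing a non-modifiable variable —
an administrative code or a downstream medication proxy — is rejected
before any simulation runs).

Free-form replanning is out of scope by design: the bounded behaviors
(single requery, reject-and-stop) are the implemented loop.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .agents import (
    AgentLog,
    FeatureRanking,
    RelevanceDecision,
    RubricStubBackend,
    select_features,
    semantic_audit,
)
from .catalog import VariableMetadata, catalog_by_name
from .cohort import CohortSpec, generate_cohort, write_panel
from .modeling import labeled_matrix_from_panel, train_predictors
from .ontology import HashingEmbedder, build_index, load_ontology, merge_ontologies
from .twin import (
    ScenarioSpec,
    build_twin,
    load_scenario,
    simulate_scenario,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "CriticReport",
    "run_pipeline",
    "critic_check_decision",
    "critic_check_scenario",
    "write_manifest",
    "read_manifest",
    "verify_manifest",
]

STAGES = ("cohort", "index", "select", "train", "twin", "scenarios", "audit")

DIRECT_BAND = 0.7  # classification "Direct" requires score >= this
UNRELATED_BAND = 0.3  # "Unrelated" requires score < this


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """All stage parameters, every random procedure explicitly seeded."""

    seed: int | None = None
    out_dir: str = "runs/run"
    n_participants: int = 1000
    target_incidence: float = 0.147
    ontology_paths: list[str] = field(default_factory=list)
    backend: str = "stub"
    top_k: int = 200
    batch_size: int = 40
    retrieval_k: int = 5
    retrieval_threshold: float = 0.3
    folds: int = 5
    K: int = 3
    predictor_models: list[str] = field(
        default_factory=lambda: ["logistic", "random_forest", "gradient_boosted_trees"]
    )
    scenario_paths: list[str] = field(default_factory=list)
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("config must set an explicit seed")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CriticReport:
    check: str
    target: str
    verdict: str  # pass | flag | reject
    reason: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def critic_check_decision(decision: RelevanceDecision) -> CriticReport:
    """Schema/score-range validation plus score-band consistency.

    ``Direct`` requires score >= 0.7 and ``Unrelated`` requires score
    < 0.3 (declared bands); a band mismatch is a flag (triggering the
    agent's single requery path), an out-of-range score is a reject.
    """
    name = decision.variable
    if not 0.0 <= decision.relevance_score <= 1.0:
        return CriticReport(
            "decision", name, "reject",
            f"relevance_score {decision.relevance_score} outside [0,1]",
        )
    s, c = decision.relevance_score, decision.classification
    if c == "Direct" and s < DIRECT_BAND:
        return CriticReport(
            "decision", name, "flag", f"Direct requires score >= {DIRECT_BAND}, got {s}"
        )
    if c == "Unrelated" and s >= UNRELATED_BAND:
        return CriticReport(
            "decision", name, "flag", f"Unrelated requires score < {UNRELATED_BAND}, got {s}"
        )
    return CriticReport("decision", name, "pass", "schema valid, score band consistent")


def critic_check_scenario(
    scenario: ScenarioSpec, catalog: Sequence[VariableMetadata]
) -> CriticReport:
    """Actionability screen: every perturbed variable must be modifiable."""
    by_name = catalog_by_name(catalog)
    targets = [p.variable for p in scenario.perturbations] + [
        t for _, t in scenario.propagate
    ]
    unknown = sorted({v for v in targets if v not in by_name})
    if unknown:
        raise ConfigError(f"scenario {scenario.name!r} names unknown variables {unknown}")
    frozen = sorted({v for v in targets if not by_name[v].modifiable})
    if frozen:
        return CriticReport(
            "scenario",
            scenario.name,
            "reject",
            "non-actionable: non-modifiable variables " + ", ".join(frozen),
        )
    return CriticReport("scenario", scenario.name, "pass", "all perturbed variables modifiable")


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)  # name -> {digest, seconds, outputs}
    critic_reports: list[dict] = field(default_factory=list)
    tool_version: str = "twinforge 0.1.0"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    Each stage writes its artifacts under ``out_dir`` and the manifest
    records a content digest per stage; reruns with an identical config
    reproduce identical digests. A stage failure halts the run with the
    manifest of completed stages written as a resumable checkpoint.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    state: dict = {}

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest.stages[stage] = {
            "outputs": [str(p) for p in paths],
            "digests": {p.name: _digest_file(p) for p in paths},
            "seconds": round(time.time() - t0, 3),
        }

    try:
        for stage in config.stages:
            t0 = time.time()
            if stage == "cohort":
                spec = CohortSpec(
                    n_participants=config.n_participants,
                    seed=config.seed,
                    target_incidence=config.target_incidence,
                )
                panel = generate_cohort(spec)
                state["panel"] = panel
                p1, p2 = out / "panel.csv", out / "dict.json"
                write_panel(panel, p1, p2)
                record(stage, [p1, p2], t0)
            elif stage == "index":
                if config.ontology_paths:
                    onto = merge_ontologies(
                        load_ontology(p) for p in config.ontology_paths
                    )
                else:
                    onto = _builtin_mini_ontology()
                embedder = HashingEmbedder(seed=config.seed)
                state["onto"] = onto
                state["embedder"] = embedder
                state["index"] = build_index(onto.concepts, embedder)
                p = out / "index.json"
                _write_json(
                    {
                        "embedder_id": embedder.embedder_id,
                        "n_concepts": len(onto.concepts),
                        "n_triples": len(onto.triples),
                        "iris": state["index"].iris,
                    },
                    p,
                )
                record(stage, [p], t0)
            elif stage == "select":
                panel = state["panel"]
                if config.backend != "stub":
                    raise ConfigError(
                        f"backend {config.backend!r} unavailable; only 'stub' ships"
                    )
                backend = RubricStubBackend(panel.catalog)
                log = AgentLog()
                ranking = select_features(
                    panel.catalog,
                    state["index"],
                    backend,
                    state["embedder"],
                    triples=state["onto"].triples,
                    top_k=config.top_k,
                    batch_size=config.batch_size,
                    retrieval_k=config.retrieval_k,
                    retrieval_threshold=config.retrieval_threshold,
                    log=log,
                )
                reports = [critic_check_decision(d) for _, d in ranking.entries]
                manifest.critic_reports.extend(r.to_dict() for r in reports)
                kept = [
                    (name, d)
                    for (name, d), rep in zip(ranking.entries, reports)
                    if rep.verdict != "reject"
                ]
                ranking = FeatureRanking(kept, ranking.k, ranking.selection_method)
                state["ranking"] = ranking
                p1, p2 = out / "ranking.csv", out / "agent_log.jsonl"
                ranking.to_frame().to_csv(p1, index=False)
                log.write_jsonl(p2)
                record(stage, [p1, p2], t0)
            elif stage == "train":
                panel = state["panel"]
                features = (
                    state["ranking"].variables if "ranking" in state else None
                )
                lm, plan = labeled_matrix_from_panel(panel, features=features)
                bundle, report = train_predictors(
                    lm,
                    models=tuple(config.predictor_models),
                    folds=config.folds,
                    seed=config.seed,
                )
                state["features"] = features
                p = out / "metrics.json"
                _write_json(report.per_model | {"best_model": report.best_model}, p)
                record(stage, [p], t0)
            elif stage == "twin":
                panel = state["panel"]
                twin = build_twin(
                    panel,
                    seed=config.seed,
                    folds=config.folds,
                    K=config.K,
                    predictor_models=tuple(config.predictor_models),
                    features=state.get("features"),
                )
                state["twin"] = twin
                p = out / "twin.json"
                _write_json(
                    {
                        "best_predictor": twin.bundle.best_model,
                        "centroids": twin.states.centroids.tolist(),
                        "state_sizes_w2": twin.states.cluster_sizes.tolist(),
                        "transition_metrics": twin.transition.metrics,
                        "outcome_metrics": twin.outcome.metrics,
                    },
                    p,
                )
                record(stage, [p], t0)
            elif stage == "scenarios":
                panel, twin = state["panel"], state["twin"]
                paths = config.scenario_paths or [
                    str(Path(__file__).parent / "scenarios" / "scenario_weight10.json")
                ]
                written = []
                run_log: list = []
                for spath in paths:
                    scenario = load_scenario(spath)
                    report = critic_check_scenario(scenario, panel.catalog)
                    manifest.critic_reports.append(report.to_dict())
                    if report.verdict == "reject":
                        continue
                    result = simulate_scenario(panel, scenario, twin, run_log=run_log)
                    rp = out / f"scenario_{scenario.name}.json"
                    _write_json(result.summary(), rp)
                    written.append(rp)
                lp = out / "simulation_log.jsonl"
                with open(lp, "w") as fh:
                    for rec in run_log:
                        fh.write(json.dumps(rec) + "\n")
                written.append(lp)
                record(stage, written, t0)
            elif stage == "audit":
                if "ranking" in state:
                    report = semantic_audit(state["ranking"], state["panel"].catalog)
                    p = out / "audit.json"
                    _write_json(dataclasses.asdict(report), p)
                    record(stage, [p], t0)
    finally:
        write_manifest(manifest, out / "manifest.json")
    return manifest


def _builtin_mini_ontology():
    """Tiny built-in concept set used when no fixture paths are given."""
    from .ontology import Ontology, OntologyConcept, OntologyTriple

    concepts = [
        OntologyConcept("DDO:0000362", "obesity", "Excess body fat increasing metabolic risk.", "mini"),
        OntologyConcept("DDO:0000130", "body weight", "Body mass of an individual.", "mini"),
        OntologyConcept("DDO:0000127", "physical activity level", "Habitual exercise frequency.", "mini"),
        OntologyConcept("DDO:0000483", "anxiety", "Anxiety symptom construct.", "mini"),
        OntologyConcept("DDO:0000201", "chronic disease", "Long-duration condition.", "mini"),
        OntologyConcept("DM:T2D", "type 2 diabetes", "Metabolic disease with insulin resistance.", "mini"),
    ]
    triples = [
        OntologyTriple("DM:T2D", "hasRiskFactor", "DDO:0000362"),
        OntologyTriple("DDO:0000362", "influencedBy", "DDO:0000127"),
    ]
    return Ontology(concepts=concepts, triples=triples)


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    _write_json(manifest.to_dict(), Path(path))


def read_manifest(path: str | Path) -> RunManifest:
    d = json.loads(Path(path).read_text())
    return RunManifest(
        config=d["config"],
        stages=d["stages"],
        critic_reports=d.get("critic_reports", []),
        tool_version=d.get("tool_version", ""),
    )


def verify_manifest(manifest: RunManifest) -> dict[str, bool]:
    """Recompute artifact digests; True per stage when all still match."""
    ok: dict[str, bool] = {}
    for stage, info in manifest.stages.items():
        good = True
        for out_path in info["outputs"]:
            p = Path(out_path)
            if not p.exists() or _digest_file(p) != info["digests"][p.name]:
                good = False
        ok[stage] = good
    return ok
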
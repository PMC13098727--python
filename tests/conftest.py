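"""Shared fixtures: small cohorts, ontology fixtures, a prebuilt twin.

Everything is generated programmatically at test time; expensive
artifacts (the mid-size panel, the assembled twin) are session-scoped.
"""

from __future__ import annotations

import json

import numpy as np
import pytest

import twinforge as tf
from twinforge.ontology import HashingEmbedder, build_index, load_ontology
from twinforge.twin import build_twin


ONTOLOGY_FIXTURE = {
    "concepts": [
        {
            "iri": "DM:T2D",
            "label": "type 2 diabetes",
            "definition": "Metabolic disease characterized by insulin resistance.",
            "source_ontology": "mini-dmto",
        },
        {
            "iri": "DDO:0000362",
            "label": "obesity",
            "definition": "Excess body fat that increases metabolic risk.",
            "source_ontology": "mini-dmto",
        },
        {
            "iri": "DDO:0000130",
            "label": "body weight",
            "definition": "Body mass of an individual.",
            "source_ontology": "mini-dmto",
        },
        {
            "iri": "DDO:0000127",
            "label": "physical activity level",
            "definition": "Habitual frequency of exercise.",
            "source_ontology": "mini-dmto",
        },
        {
            "iri": "DDO:0000483",
            "label": "anxiety",
            "definition": "Anxiety symptom construct.",
            "source_ontology": "mini-dmto",
        },
        {
            "iri": "SCO:baseline",
            "label": "baseline demographic variable",
            "definition": "Variable describing cohort composition at entry.",
            "source_ontology": "mini-sco",
        },
    ],
    "triples": [
        {"subject": "DM:T2D", "predicate": "hasRiskFactor", "object": "DDO:0000362"},
        {"subject": "DDO:0000362", "predicate": "influencedBy", "object": "DDO:0000127"},
    ],
}


@pytest.fixture(scope="session")
def ontology_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("onto") / "mini.json"
    p.write_text(json.dumps(ONTOLOGY_FIXTURE))
    return p


@pytest.fixture(scope="session")
def ontology(ontology_path):
    return load_ontology(ontology_path)


@pytest.fixture(scope="session")
def embedder():
    return HashingEmbedder()


@pytest.fixture(scope="session")
def concept_index(ontology, embedder):
    return build_index(ontology.concepts, embedder)


@pytest.fixture(scope="session")
def small_spec():
    return tf.CohortSpec(n_participants=600, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return tf.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def midsize_panel():
    return tf.generate_cohort(tf.CohortSpec(n_participants=4000, seed=19))


@pytest.fixture(scope="session")
def small_twin(small_panel):
    """A full twin on a small cohort (logistic predictor for speed/monotonicity)."""
    return build_twin(
        small_panel,
        seed=7,
        predictor_models=("logistic", "gradient_boosted_trees"),
    )
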
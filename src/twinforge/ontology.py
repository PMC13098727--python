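"""Ontology fixtures, embeddings and concept retrieval.

Concepts (IRI, label, definition) and subject-predicate-object triples
are loaded from small JSON fixtures that mimic the shape of published
disease ontologies. Concept labels are embedded to unit vectors; for a
survey variable, the top-k concepts above a cosine-similarity threshold
are retrieved together with the triples that touch them, and rendered
into the deterministic context block injected into relevance-agent
prompts.

The shipped embedder is a seeded feature-hashing of character n-grams:
deterministic per text and dependency-free. Any object satisfying the
same contract (text -> fixed-length unit vector, deterministic) can be
substituted, e.g. a sentence-transformer adapter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .catalog import VariableMetadata

__all__ = [
    "OntologyConcept",
    "OntologyTriple",
    "Ontology",
    "EmbeddingIndex",
    "RetrievalContext",
    "HashingEmbedder",
    "load_ontology",
    "build_index",
    "retrieve_concepts",
    "format_context",
]

NO_MATCH_SENTINEL = "[no ontology matches above threshold]"


class OntologyFormatError(ValueError):
    """Malformed ontology fixture record."""


@dataclass(frozen=True)
class OntologyConcept:
    iri: str
    label: str
    definition: str = ""
    source_ontology: str = ""


@dataclass(frozen=True)
class OntologyTriple:
    subject_iri: str
    predicate: str
    object_iri: str

    def render(self, labels: dict[str, str] | None = None) -> str:
        labels = labels or {}
        s = labels.get(self.subject_iri, self.subject_iri)
        o = labels.get(self.object_iri, self.object_iri)
        return f"{s} → {self.predicate} → {o}"


@dataclass
class Ontology:
    concepts: list[OntologyConcept] = field(default_factory=list)
    triples: list[OntologyTriple] = field(default_factory=list)
    dangling: list[OntologyTriple] = field(default_factory=list)

    @property
    def labels(self) -> dict[str, str]:
        return {c.iri: c.label for c in self.concepts}


def load_ontology(path: str | Path) -> Ontology:
    """Parse a JSON fixture with ``concepts`` and ``triples`` arrays.

    Triples whose subject or object does not resolve to a loaded concept
    are collected in ``dangling`` rather than treated as fatal. An empty
    file yields an empty ontology.
    """
    text = Path(path).read_text().strip()
    if not text:
        return Ontology()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as e:  # pragma: no cover - message path
        raise OntologyFormatError(f"{path}: invalid JSON ({e})") from e
    onto = Ontology()
    seen: set[str] = set()
    for i, rec in enumerate(raw.get("concepts", [])):
        try:
            c = OntologyConcept(
                iri=rec["iri"],
                label=rec["label"],
                definition=rec.get("definition", ""),
                source_ontology=rec.get("source_ontology", ""),
            )
        except (TypeError, KeyError) as e:
            raise OntologyFormatError(f"{path}: concept record {i} malformed: {e}") from e
        if c.iri in seen:
            raise OntologyFormatError(f"{path}: concept record {i}: duplicate iri {c.iri!r}")
        seen.add(c.iri)
        onto.concepts.append(c)
    for i, rec in enumerate(raw.get("triples", [])):
        try:
            t = OntologyTriple(rec["subject"], rec["predicate"], rec["object"])
        except (TypeError, KeyError) as e:
            raise OntologyFormatError(f"{path}: triple record {i} malformed: {e}") from e
        if t.subject_iri in seen and t.object_iri in seen:
            onto.triples.append(t)
        else:
            onto.dangling.append(t)
    return onto


def merge_ontologies(ontologies: Iterable[Ontology]) -> Ontology:
    merged = Ontology()
    seen: set[str] = set()
    for o in ontologies:
        for c in o.concepts:
            if c.iri in seen:
                raise OntologyFormatError(f"duplicate iri {c.iri!r} across ontologies")
            seen.add(c.iri)
            merged.concepts.append(c)
        merged.triples.extend(o.triples)
        merged.dangling.extend(o.dangling)
    return merged


class Embedder(Protocol):
    embedder_id: str
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Character n-gram feature hashing onto the unit sphere.

    Deterministic per text (the hash is keyed, not process-salted), so
    identical texts always map to identical vectors and cosine 1.0.
    """

    def __init__(self, dim: int = 256, ngram: int = 3, seed: int = 0):
        self.dim = int(dim)
        self.ngram = int(ngram)
        self.seed = int(seed)
        self.embedder_id = f"hashing-ngram{ngram}-d{dim}-s{seed}"

    def embed(self, text: str) -> np.ndarray:
        padded = f"\x02{text.lower()}\x03"
        vec = np.zeros(self.dim)
        n = self.ngram
        key = str(self.seed).encode()
        for i in range(max(1, len(padded) - n + 1)):
            gram = padded[i : i + n].encode("utf-8")
            h = hashlib.blake2b(gram, key=key, digest_size=8).digest()
            idx = int.from_bytes(h[:4], "little") % self.dim
            sign = 1.0 if h[4] & 1 else -1.0
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            vec[0] = 1.0
            norm = 1.0
        return vec / norm


@dataclass
class EmbeddingIndex:
    embedder_id: str
    iris: list[str]
    vectors: np.ndarray  # (n_concepts, dim), rows unit-norm
    concepts: dict[str, OntologyConcept]

    def __post_init__(self) -> None:
        if len(self.iris) != self.vectors.shape[0]:
            raise ValueError("iris/vectors length mismatch")
        if len(self.iris):
            norms = np.linalg.norm(self.vectors, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("index vectors must be unit-norm")


def build_index(concepts: Sequence[OntologyConcept], embedder: Embedder) -> EmbeddingIndex:
    """One unit vector per concept label, keyed by IRI."""
    vecs = []
    for c in concepts:
        v = np.asarray(embedder.embed(c.label), dtype=float)
        if v.ndim != 1 or (vecs and v.shape != vecs[0].shape):
            raise ValueError(f"embedder returned wrong dimensionality for {c.iri!r}")
        vecs.append(v)
    matrix = np.vstack(vecs) if vecs else np.zeros((0, getattr(embedder, "dim", 0)))
    return EmbeddingIndex(
        embedder_id=embedder.embedder_id,
        iris=[c.iri for c in concepts],
        vectors=matrix,
        concepts={c.iri: c for c in concepts},
    )


@dataclass
class RetrievalMatch:
    concept: OntologyConcept
    similarity: float
    triples: list[OntologyTriple]
    explanation: str


@dataclass
class RetrievalContext:
    variable: VariableMetadata
    matches: list[RetrievalMatch]
    k: int
    threshold: float


def variable_query_text(variable: VariableMetadata, fields: str = "name+label") -> str:
    """Text embedded for retrieval; name and label concatenated by default."""
    if fields == "name":
        return variable.name
    if fields == "label":
        return variable.label
    return f"{variable.name} {variable.label}"


def retrieve_concepts(
    variable: VariableMetadata,
    index: EmbeddingIndex,
    embedder: Embedder,
    k: int = 5,
    threshold: float = 0.3,
    triples: Sequence[OntologyTriple] = (),
    query_fields: str = "name+label",
) -> RetrievalContext:
    """Top-k concepts above the cosine threshold, similarity-descending.

    Ties at equal similarity break lexicographically by IRI for
    reproducibility. An empty index yields an empty context.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [-1, 1]")
    if len(index.iris) == 0:
        return RetrievalContext(variable, [], k, threshold)
    q = np.asarray(embedder.embed(variable_query_text(variable, query_fields)), dtype=float)
    sims = index.vectors @ q
    order = sorted(
        range(len(index.iris)), key=lambda i: (-sims[i], index.iris[i])
    )
    matches: list[RetrievalMatch] = []
    for i in order:
        if sims[i] < threshold:
            continue
        iri = index.iris[i]
        concept = index.concepts[iri]
        touching = [
            t for t in triples if t.subject_iri == iri or t.object_iri == iri
        ]
        matches.append(
            RetrievalMatch(concept, float(sims[i]), touching, concept.definition)
        )
        if len(matches) == k:
            break
    return RetrievalContext(variable, matches, k, threshold)


def format_context(ctx: RetrievalContext) -> str:
    """Deterministic text rendering of a retrieval context."""
    if not ctx.matches:
        return NO_MATCH_SENTINEL
    labels = {m.concept.iri: m.concept.label for m in ctx.matches}
    lines: list[str] = []
    for m in ctx.matches:
        lines.append(f"- {m.concept.label} [{m.concept.iri}] (similarity {m.similarity:.3f})")
        for t in m.triples:
            lines.append(f"    {t.render(labels)}")
        if m.explanation:
            lines.append(f"    explanation: {m.explanation}")
    return "\n".join(lines)
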
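"""Typed knowledge graph of drugs, proteins, genes, diseases and processes.

Entities are CURIE-identified nodes; assertions are single-source interaction
records (one per nanopublication-style evidence item); edges aggregate every
assertion sharing one (subject, interaction type, object) triple and carry a
single combined probability.  Adjacency indexes support directed traversal
("who targets this entity?" / "what does it act on?") with undirected
protein-protein interaction edges visible from both endpoints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

ENTITY_TYPES = frozenset({"drug", "protein", "gene", "disease", "process"})

#: dump format marker for the JSON-lines serialisation
_DUMP_FORMAT = "rxgraph-kg"
_DUMP_VERSION = 1


class ValidationError(ValueError):
    """Raised when a record or entity violates a structural invariant."""


class MissingEntityError(KeyError):
    """Raised when an operation references an entity id not in the graph."""


@dataclass(frozen=True)
class Evidence:
    """Provenance class of one assertion.

    ``kind`` is ``"curated"`` (manually curated source database) or
    ``"experimental"`` (derived from a specific detection method, in which
    case ``method_code`` holds the PSI-MI method code, e.g. ``"MI:0018"``).
    """

    kind: str
    method_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("curated", "experimental"):
            raise ValidationError(f"unknown evidence kind {self.kind!r}")
        if self.kind == "experimental" and not self.method_code:
            raise ValidationError("experimental evidence requires a method code")
        if self.kind == "curated" and self.method_code is not None:
            raise ValidationError("curated evidence carries no method code")


@dataclass
class Entity:
    """A typed node: drug, protein, gene, disease or biological process."""

    id: str
    label: str
    entity_type: str
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entity id must be non-empty")
        if not self.label:
            raise ValidationError(f"entity {self.id}: label must be non-empty")
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(
                f"entity {self.id}: type {self.entity_type!r} not in {sorted(ENTITY_TYPES)}"
            )


@dataclass
class AssertionRecord:
    """One interaction assertion from one source, with provenance.

    The smallest unit of evidence: subject–type–object plus where it came
    from (source database, detection method or curation, publication) and
    the probability assigned to it by the evidence model.
    """

    subject_id: str
    interaction_type: str
    object_id: str
    directed: bool
    source_db: str
    evidence: Evidence
    primary_ref: str = ""
    probability: Optional[float] = None

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject_id, self.interaction_type, self.object_id)

    def validate_probability(self) -> None:
        if self.probability is None:
            raise ValidationError(f"record {self.triple}: probability not assigned")
        if not (0.0 < self.probability < 1.0):
            raise ValidationError(
                f"record {self.triple}: probability {self.probability} outside (0,1)"
            )


@dataclass
class Edge:
    """Aggregate of all assertion records sharing one triple.

    ``combined_probability`` is None while stale (records added but not yet
    recombined); the evidence module's ``recombine_edges`` fills it.
    """

    subject_id: str
    interaction_type: str
    object_id: str
    directed: bool
    records: list[AssertionRecord] = field(default_factory=list)
    combined_probability: Optional[float] = None

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject_id, self.interaction_type, self.object_id)

    def other_endpoint(self, entity_id: str) -> str:
        if entity_id == self.subject_id:
            return self.object_id
        if entity_id == self.object_id:
            return self.subject_id
        raise ValueError(f"{entity_id} is not an endpoint of {self.triple}")


class KnowledgeGraph:
    """Entities plus triple-keyed edges with incoming/outgoing indexes."""

    def __init__(self) -> None:
        self.entities: dict[str, Entity] = {}
        self.edges: dict[tuple[str, str, str], Edge] = {}
        # adjacency: entity id -> set of edge triples
        self._outgoing: dict[str, set[tuple[str, str, str]]] = {}
        self._incoming: dict[str, set[tuple[str, str, str]]] = {}
        self._id_conflicts = 0

    # ------------------------------------------------------------------ #
    # entities

    def add_entity(self, entity: Entity) -> None:
        """Register an entity; on id collision the first registration wins.

        Sources disagree on typing (a gene symbol may arrive as a protein
        from an interaction database and as a gene from a disease table);
        collisions are counted and logged rather than treated as errors.
        """
        existing = self.entities.get(entity.id)
        if existing is None:
            self.entities[entity.id] = entity
            self._outgoing.setdefault(entity.id, set())
            self._incoming.setdefault(entity.id, set())
        elif existing.entity_type != entity.entity_type:
            self._id_conflicts += 1
            logger.debug(
                "entity id %s already registered as %s; ignoring re-registration as %s",
                entity.id, existing.entity_type, entity.entity_type,
            )

    def entity(self, entity_id: str) -> Entity:
        try:
            return self.entities[entity_id]
        except KeyError:
            raise MissingEntityError(entity_id) from None

    # ------------------------------------------------------------------ #
    # assertions and edges

    def add_assertion(
        self,
        record: AssertionRecord,
        *,
        auto_register: bool = False,
        entity_types: Optional[dict[str, str]] = None,
    ) -> Edge:
        """Append a record to its triple's edge, creating the edge if new.

        The edge's combined probability is invalidated (set to None) until
        the next recombination pass.  With ``auto_register`` the endpoints
        are created on the fly using ``entity_types`` (id -> entity_type).
        """
        record.validate_probability()
        for endpoint in (record.subject_id, record.object_id):
            if endpoint not in self.entities:
                if not auto_register:
                    raise MissingEntityError(endpoint)
                etype = (entity_types or {}).get(endpoint, "protein")
                self.add_entity(Entity(id=endpoint, label=endpoint, entity_type=etype))

        key = record.triple
        edge = self.edges.get(key)
        if edge is None:
            edge = Edge(
                subject_id=record.subject_id,
                interaction_type=record.interaction_type,
                object_id=record.object_id,
                directed=record.directed,
            )
            self.edges[key] = edge
            self._index_edge(edge)
        elif edge.directed != record.directed:
            raise ValidationError(
                f"edge {key}: records disagree on directedness"
            )
        edge.records.append(record)
        edge.combined_probability = None  # stale until recombined
        return edge

    def _index_edge(self, edge: Edge) -> None:
        key = edge.triple
        self._outgoing[edge.subject_id].add(key)
        self._incoming[edge.object_id].add(key)
        if not edge.directed:
            # undirected edges are visible in both directions from both ends
            self._outgoing[edge.object_id].add(key)
            self._incoming[edge.subject_id].add(key)

    def rebuild_indexes(self) -> None:
        """Recompute adjacency from the edge set (consistency check hook)."""
        self._outgoing = {eid: set() for eid in self.entities}
        self._incoming = {eid: set() for eid in self.entities}
        for edge in self.edges.values():
            self._index_edge(edge)

    def neighbors(
        self,
        entity_id: str,
        direction: str = "both",
        entity_type_filter: Optional[str] = None,
    ) -> list[Edge]:
        """Edges touching ``entity_id`` in the given direction.

        ``incoming`` returns edges where the entity is the object (plus
        undirected edges touching it), ``outgoing`` the symmetric set,
        ``both`` their union.  ``entity_type_filter`` restricts the type of
        the far endpoint.
        """
        if entity_id not in self.entities:
            raise MissingEntityError(entity_id)
        if direction not in ("incoming", "outgoing", "both"):
            raise ValueError(f"unknown direction {direction!r}")
        keys: set[tuple[str, str, str]] = set()
        if direction in ("incoming", "both"):
            keys |= self._incoming[entity_id]
        if direction in ("outgoing", "both"):
            keys |= self._outgoing[entity_id]
        edges = [self.edges[k] for k in sorted(keys)]
        if entity_type_filter is not None:
            edges = [
                e for e in edges
                if self.entities[e.other_endpoint(entity_id)].entity_type
                == entity_type_filter
            ]
        return edges

    def iter_records(self) -> Iterator[AssertionRecord]:
        for edge in self.edges.values():
            yield from edge.records

    @property
    def n_records(self) -> int:
        return sum(len(e.records) for e in self.edges.values())

    # ------------------------------------------------------------------ #
    # JSON-lines serialisation

    def dump_jsonl(self, path, combiner_method: str = "composite_z") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in self.to_jsonl_lines(combiner_method):
                fh.write(line + "\n")

    def to_jsonl_lines(self, combiner_method: str = "composite_z") -> Iterator[str]:
        """Deterministic JSON-lines: header, sorted entities, sorted records."""
        def js(obj) -> str:
            return json.dumps(obj, sort_keys=True, separators=(",", ":"))

        yield js({
            "format": _DUMP_FORMAT,
            "version": _DUMP_VERSION,
            "combiner": combiner_method,
            "n_entities": len(self.entities),
            "n_edges": len(self.edges),
            "n_records": self.n_records,
        })
        for eid in sorted(self.entities):
            e = self.entities[eid]
            yield js({
                "kind": "entity",
                "id": e.id,
                "label": e.label,
                "entity_type": e.entity_type,
                "synonyms": sorted(e.synonyms),
            })
        records = sorted(
            self.iter_records(),
            key=lambda r: (
                r.subject_id, r.interaction_type, r.object_id,
                r.source_db, r.primary_ref, r.evidence.kind,
                r.evidence.method_code or "", r.probability,
            ),
        )
        for r in records:
            yield js({
                "kind": "assertion",
                "subject_id": r.subject_id,
                "interaction_type": r.interaction_type,
                "object_id": r.object_id,
                "directed": r.directed,
                "source_db": r.source_db,
                "evidence_kind": r.evidence.kind,
                "method_code": r.evidence.method_code,
                "primary_ref": r.primary_ref,
                "probability": r.probability,
            })

    @classmethod
    def load_jsonl(cls, path) -> tuple["KnowledgeGraph", str]:
        """Load a dump; returns (graph, combiner method recorded in header).

        Combined edge probabilities are left stale; callers recombine with
        the header's combiner to reproduce them.
        """
        graph = cls()
        combiner = "composite_z"
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            if header.get("format") != _DUMP_FORMAT:
                raise ValidationError(f"{path}: not a {_DUMP_FORMAT} dump")
            combiner = header.get("combiner", combiner)
            for line in fh:
                obj = json.loads(line)
                if obj["kind"] == "entity":
                    graph.add_entity(Entity(
                        id=obj["id"], label=obj["label"],
                        entity_type=obj["entity_type"],
                        synonyms=list(obj["synonyms"]),
                    ))
                elif obj["kind"] == "assertion":
                    graph.add_assertion(AssertionRecord(
                        subject_id=obj["subject_id"],
                        interaction_type=obj["interaction_type"],
                        object_id=obj["object_id"],
                        directed=obj["directed"],
                        source_db=obj["source_db"],
                        evidence=Evidence(obj["evidence_kind"], obj["method_code"]),
                        primary_ref=obj["primary_ref"],
                        probability=obj["probability"],
                    ))
                else:
                    raise ValidationError(f"unknown dump line kind {obj['kind']!r}")
        return graph, combiner

    # ------------------------------------------------------------------ #
    # lookup helpers

    def find_entities(self, text: str, entity_type: Optional[str] = None) -> list[Entity]:
        """Case-insensitive substring search over labels and synonyms."""
        needle = text.lower()
        out = []
        for e in self.entities.values():
            if entity_type is not None and e.entity_type != entity_type:
                continue
            names = [e.label, e.id, *e.synonyms]
            if any(needle in n.lower() for n in names):
                out.append(e)
        return sorted(out, key=lambda e: e.id)


def export_trig(graph: KnowledgeGraph, path) -> int:
    """Export assertions as TriG nanopublications (one per record).

    Each record becomes three named graphs — assertion, supporting
    (provenance: method or curation) and attribution (source database and
    primary reference).  Returns the number of nanopublications written.
    Read-back is not supported; this is an interoperability export.
    """
    from rdflib import Dataset, Literal, Namespace, RDF, URIRef

    NP = Namespace("http://example.org/nanopub/")
    SIO = Namespace("http://semanticscience.org/resource/")
    PROV = Namespace("http://www.w3.org/ns/prov#")

    def ref(curie: str) -> URIRef:
        return URIRef("http://example.org/id/" + curie.replace(":", "/"))

    ds = Dataset()
    n = 0
    for i, record in enumerate(sorted(
        graph.iter_records(), key=lambda r: (r.triple, r.source_db, r.primary_ref)
    )):
        base = NP[f"NP{i}"]
        assertion = ds.graph(URIRef(base + "_Assertion"))
        supporting = ds.graph(URIRef(base + "_Supporting"))
        attribution = ds.graph(URIRef(base + "_Attribution"))
        interaction = URIRef(base + "_Interaction")
        assertion.add((interaction, RDF.type, ref(record.interaction_type)))
        assertion.add((interaction, SIO["has-participant"], ref(record.subject_id)))
        assertion.add((interaction, SIO["has-target"], ref(record.object_id)))
        activity = URIRef(base + "_Activity")
        supporting.add((URIRef(base + "_Assertion"), PROV.wasGeneratedBy, activity))
        if record.evidence.kind == "experimental":
            supporting.add((activity, RDF.type, ref(record.evidence.method_code)))
        else:
            supporting.add((activity, RDF.type, SIO["curation"]))
        attribution.add((URIRef(base + "_Assertion"), PROV.wasQuotedFrom,
                         Literal(record.source_db)))
        if record.primary_ref:
            attribution.add((URIRef(base + "_Assertion"), PROV.hadPrimarySource,
                             Literal(record.primary_ref)))
        n += 1
    ds.serialize(destination=str(path), format="trig")
    return n
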
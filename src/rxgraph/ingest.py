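"""Readers for the tabular source formats and the evidence configuration.

Three minimal tab-separated dialects are supported, shaped after the
upstream databases they emulate:

* a PSI-MITAB-style protein-protein interaction table (columns ``id_a``,
  ``id_b``, ``method``, ``interaction_type``, ``source_db``, ``pubmed``);
* a drug-target table (``drug_id``, ``drug_name``, ``target_id``, optional
  ``action``);
* a gene-disease association table (``gene_id``, ``disease_id``,
  ``disease_label``), read once per source (OMIM-like or COSMIC-like).

Extra columns are accepted by name and ignored.  The evidence configuration
is a YAML file mapping detection-method codes to confidence levels and
naming which source databases count as manually curated; see
``docs/methods.md`` for a worked schema example.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, TYPE_CHECKING

import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .evidence import CombinerSpec

from .evidence import assign_probability
from .graph import AssertionRecord, Entity, Evidence, ValidationError

logger = logging.getLogger(__name__)

#: interaction-type strings attached to the non-PPI assertion classes
DRUG_TARGET_TYPE = "sio:targets"
GENE_DISEASE_TYPE = "sio:gene-disease-association"

DEFAULT_LEVEL_PROBABILITIES = {1: 0.8, 2: 0.95, 3: 0.99}
DEFAULT_CURATED_PROBABILITY = 0.999
DEFAULT_CURATED_SOURCES = frozenset({"drugbank", "omim", "cosmic"})


@dataclass
class EvidenceConfig:
    """Flat evidence model: curated sources plus method-code confidence levels."""

    curated_sources: frozenset[str] = DEFAULT_CURATED_SOURCES
    method_levels: dict[str, int] = field(default_factory=dict)
    level_probabilities: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_PROBABILITIES))
    curated_probability: float = DEFAULT_CURATED_PROBABILITY
    unknown_method_policy: str = "default_level_1"
    synonym_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.level_probabilities) != {1, 2, 3}:
            raise ValidationError("level_probabilities keys must be exactly {1, 2, 3}")
        for level, p in self.level_probabilities.items():
            if not (0.0 < p < 1.0):
                raise ValidationError(f"level {level} probability {p} outside (0,1)")
        if not (0.0 < self.curated_probability < 1.0):
            raise ValidationError("curated_probability outside (0,1)")
        if any(self.curated_probability <= p for p in self.level_probabilities.values()):
            raise ValidationError(
                "curated_probability must exceed every level probability")
        for code, level in self.method_levels.items():
            if level not in (1, 2, 3):
                raise ValidationError(f"method {code}: level {level} not in {{1,2,3}}")
        if self.unknown_method_policy not in ("error", "default_level_1"):
            raise ValidationError(
                f"unknown_method_policy {self.unknown_method_policy!r} invalid")

    def normalize_id(self, identifier: str) -> str:
        return self.synonym_map.get(identifier, identifier)

    def to_yaml(self, path) -> None:
        payload = {
            "curated_sources": sorted(self.curated_sources),
            "curated_probability": self.curated_probability,
            "level_probabilities": {int(k): float(v)
                                    for k, v in self.level_probabilities.items()},
            "method_levels": {str(k): int(v) for k, v in self.method_levels.items()},
            "unknown_method_policy": self.unknown_method_policy,
            "synonym_map": dict(self.synonym_map),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def load_evidence_config(path) -> EvidenceConfig:
    """Load and validate a YAML evidence configuration, filling defaults."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: evidence config must be a mapping")
    levels = dict(DEFAULT_LEVEL_PROBABILITIES)
    for k, v in (raw.get("level_probabilities") or {}).items():
        levels[int(k)] = float(v)
    return EvidenceConfig(
        curated_sources=frozenset(raw.get("curated_sources", DEFAULT_CURATED_SOURCES)),
        method_levels={str(k): int(v)
                       for k, v in (raw.get("method_levels") or {}).items()},
        level_probabilities=levels,
        curated_probability=float(
            raw.get("curated_probability", DEFAULT_CURATED_PROBABILITY)),
        unknown_method_policy=raw.get("unknown_method_policy", "default_level_1"),
        synonym_map={str(k): str(v) for k, v in (raw.get("synonym_map") or {}).items()},
    )


@dataclass
class IngestResult:
    """Records plus the entities they reference and per-file skip counts."""

    records: list[AssertionRecord]
    entities: list[Entity]
    n_rows: int
    n_skipped: int


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _evidence_for(source_db: str, method_code: str, config: EvidenceConfig) -> Evidence:
    if source_db in config.curated_sources:
        return Evidence("curated")
    return Evidence("experimental", method_code)


def read_mitab(path, config: EvidenceConfig) -> IngestResult:
    """Read a MITAB-style PPI table into undirected assertion records.

    Rows missing either interactor id are skipped and counted, as are n-ary
    records (complex expansions flagged by a ``complex:`` interactor id) —
    only binary interactions enter the graph.
    """
    df = _read_table(path, ("id_a", "id_b", "method", "interaction_type",
                            "source_db", "pubmed"))
    records, entities = [], {}
    n_skipped = 0
    for row in df.itertuples(index=False):
        id_a, id_b = row.id_a.strip(), row.id_b.strip()
        if not id_a or not id_b or id_a.startswith("complex:") or id_b.startswith("complex:"):
            n_skipped += 1
            continue
        id_a, id_b = config.normalize_id(id_a), config.normalize_id(id_b)
        record = AssertionRecord(
            subject_id=id_a,
            interaction_type=row.interaction_type.strip() or "sio:direct-interaction",
            object_id=id_b,
            directed=False,
            source_db=row.source_db.strip(),
            evidence=_evidence_for(row.source_db.strip(), row.method.strip(), config),
            primary_ref=row.pubmed.strip(),
        )
        records.append(assign_probability(record, config))
        for eid in (id_a, id_b):
            entities.setdefault(eid, Entity(eid, _local_label(eid), "protein"))
    if n_skipped:
        logger.info("%s: skipped %d rows (missing ids or n-ary records)", path, n_skipped)
    return IngestResult(records, list(entities.values()), len(df), n_skipped)


def read_drug_targets(path, config: EvidenceConfig) -> IngestResult:
    """Read a DrugBank-like drug-target table into directed curated records."""
    df = _read_table(path, ("drug_id", "drug_name", "target_id"))
    records, entities = [], {}
    n_skipped = 0
    for row in df.itertuples(index=False):
        drug_id, target_id = row.drug_id.strip(), row.target_id.strip()
        if not drug_id or not target_id:
            n_skipped += 1
            continue
        target_id = config.normalize_id(target_id)
        record = AssertionRecord(
            subject_id=drug_id,
            interaction_type=DRUG_TARGET_TYPE,
            object_id=target_id,
            directed=True,
            source_db="drugbank",
            evidence=Evidence("curated"),
        )
        records.append(assign_probability(record, config))
        entities.setdefault(drug_id, Entity(drug_id, row.drug_name.strip() or drug_id, "drug"))
        entities.setdefault(target_id, Entity(target_id, _local_label(target_id), "protein"))
    if len(df) == 0:
        logger.warning("%s: empty drug-target table", path)
    if n_skipped:
        logger.info("%s: skipped %d malformed rows", path, n_skipped)
    return IngestResult(records, list(entities.values()), len(df), n_skipped)


def read_gene_disease(path, source_db: str, config: EvidenceConfig) -> IngestResult:
    """Read an OMIM/COSMIC-like gene-disease table into directed curated records."""
    if source_db not in ("omim", "cosmic"):
        raise ValidationError(f"gene-disease source must be omim or cosmic, got {source_db!r}")
    df = _read_table(path, ("gene_id", "disease_id", "disease_label"))
    records, entities = [], {}
    n_skipped = 0
    for row in df.itertuples(index=False):
        gene_id, disease_id = row.gene_id.strip(), row.disease_id.strip()
        if not gene_id or not disease_id:
            n_skipped += 1
            continue
        gene_id = config.normalize_id(gene_id)
        record = AssertionRecord(
            subject_id=gene_id,
            interaction_type=GENE_DISEASE_TYPE,
            object_id=disease_id,
            directed=True,
            source_db=source_db,
            evidence=Evidence("curated"),
        )
        records.append(assign_probability(record, config))
        entities.setdefault(gene_id, Entity(gene_id, _local_label(gene_id), "gene"))
        entities.setdefault(
            disease_id,
            Entity(disease_id, row.disease_label.strip() or disease_id, "disease"))
    if n_skipped:
        logger.info("%s: skipped %d malformed rows", path, n_skipped)
    return IngestResult(records, list(entities.values()), len(df), n_skipped)


def _local_label(curie: str) -> str:
    """Display label from a CURIE: the part after the namespace prefix."""
    return curie.split(":", 1)[-1] if ":" in curie else curie


def build_graph(
    config: EvidenceConfig,
    mitab: Sequence = (),
    drug_targets: Sequence = (),
    omim: Sequence = (),
    cosmic: Sequence = (),
    combiner: Optional["CombinerSpec"] = None,
    deduplicate: bool = True,
):
    """Ingest source tables into a recombined knowledge graph.

    Each argument takes a sequence of file paths of the corresponding
    dialect.  Entities from all tables are registered first (so endpoint
    typing does not depend on file order beyond first-wins id collisions),
    then records are attached and every edge's combined probability is
    computed with ``combiner`` (default composite-Z).
    """
    from .evidence import CombinerSpec, recombine_edges
    from .graph import KnowledgeGraph

    results: list[IngestResult] = []
    for path in mitab:
        results.append(read_mitab(path, config))
    for path in drug_targets:
        results.append(read_drug_targets(path, config))
    for path in omim:
        results.append(read_gene_disease(path, "omim", config))
    for path in cosmic:
        results.append(read_gene_disease(path, "cosmic", config))

    graph = KnowledgeGraph()
    for result in results:
        for entity in result.entities:
            graph.add_entity(entity)
    for result in results:
        for record in result.records:
            graph.add_assertion(record)
    spec = combiner or CombinerSpec()
    recombine_edges(graph, spec, deduplicate=deduplicate)
    logger.info(
        "built graph: %d entities, %d edges, %d records",
        len(graph.entities), len(graph.edges), graph.n_records)
    return graph
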
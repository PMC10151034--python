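"""Deterministic synthetic source tables: random graphs and the melanoma benchmark.

Two generators, both writing the three tabular ingest dialects plus an
evidence configuration so the full pipeline can be exercised without any
database download:

* :func:`generate_random_kg` — seeded random drug/protein/disease networks
  with redundant multi-record edges and a ground-truth manifest recording
  every planted record's expected probability;
* :func:`generate_melanoma_benchmark` — a replica of the published melanoma
  case-study neighbourhood: 25 known drug candidates whose best paths have
  the published step counts (2 or 3) and joint probabilities that round to
  the published values (0.93 / 0.95 / 0.97 / 0.98), plus decoy drugs that
  fail the 0.93 / 3-step filter so that threshold sweeps peak at the
  published operating point.

The planted edge probabilities of the benchmark are chosen to reproduce the
published roundings; they are not claimed to equal the original knowledge
base's values, which are not recoverable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .ingest import EvidenceConfig

MELANOMA_ID = "efo:0000756"
MELANOMA_LABEL = "melanoma"

_MITAB_COLUMNS = ["id_a", "id_b", "method", "interaction_type", "source_db", "pubmed"]
_PPI_TYPE = "sio:direct-interaction"


# --------------------------------------------------------------------------- #
# melanoma benchmark

@dataclass(frozen=True)
class BenchmarkDrug:
    """One published melanoma candidate: status, path shape, printed joint p."""

    drug_id: str
    name: str
    status: str
    steps: int
    printed_joint: float  # published joint probability, 2 decimals
    target: str           # drug's protein target (pathway entry point)
    via: str | None       # disease gene reached through a PPI; None for 2-step


#: the 25 published candidates (status / steps / joint p as printed)
MELANOMA_BENCHMARK: tuple[BenchmarkDrug, ...] = (
    BenchmarkDrug("drugbank:vemurafenib", "Vemurafenib", "approved", 2, 0.98, "BRAF", None),
    BenchmarkDrug("drugbank:dabrafenib", "Dabrafenib", "phase_iii", 2, 0.98, "BRAF", None),
    BenchmarkDrug("drugbank:sorafenib", "Sorafenib", "phase_iii", 2, 0.98, "BRAF", None),
    BenchmarkDrug("drugbank:vinblastine", "Vinblastine", "phase_iii", 3, 0.93, "TUBB", "MAPK1"),
    BenchmarkDrug("drugbank:zidovudine", "Zidovudine", "phase_ii", 2, 0.98, "TERT", None),
    BenchmarkDrug("drugbank:trametinib", "Trametinib", "phase_ii", 2, 0.98, "MAP2K1", None),
    BenchmarkDrug("drugbank:regorafenib", "Regorafenib", "phase_ii", 2, 0.98, "BRAF", None),
    BenchmarkDrug("drugbank:nadroparin", "Nadroparin", "phase_ii", 3, 0.97, "SERPINC1", "MYC"),
    BenchmarkDrug("drugbank:vinorelbine", "Vinorelbine", "phase_ii", 3, 0.93, "TUBB", "MAPK1"),
    BenchmarkDrug("drugbank:irinotecan", "Irinotecan", "phase_ii", 3, 0.93, "TOP1", "CDKN2A"),
    BenchmarkDrug("drugbank:topotecan", "Topotecan", "phase_ii", 3, 0.93, "TOP1", "CDKN2A"),
    BenchmarkDrug("drugbank:sodium-stibogluconate", "Sodium stibogluconate", "phase_i",
                  3, 0.93, "PTPN6", "CDKN2A"),
    BenchmarkDrug("drugbank:ingenol-mebutate", "Ingenol mebutate", "case_study",
                  3, 0.95, "PRKCA", "BRAF"),
    BenchmarkDrug("drugbank:bosutinib", "Bosutinib", "in_vitro", 2, 0.98, "MAP2K1", None),
    BenchmarkDrug("drugbank:purvalanol", "Purvalanol", "in_vitro", 3, 0.97, "CDK2", "TP53"),
    BenchmarkDrug("drugbank:ellagic-acid", "Ellagic acid", "in_vitro", 3, 0.95, "PRKCA", "BRAF"),
    BenchmarkDrug("drugbank:albendazole", "Albendazole", "in_vitro", 3, 0.93, "TUBA1A", "CDKN2A"),
    BenchmarkDrug("drugbank:colchicine", "Colchicine", "in_vitro", 3, 0.93, "TUBB", "MAPK1"),
    BenchmarkDrug("drugbank:plerixafor", "Plerixafor", "in_vivo", 3, 0.97, "CXCR4", "CXCL12"),
    BenchmarkDrug("drugbank:vincristine", "Vincristine", "in_vivo", 3, 0.93, "TUBB", "MAPK1"),
    BenchmarkDrug("drugbank:l-methionine", "L-Methionine", "in_vivo", 3, 0.93, "MTR", "CDKN2A"),
    BenchmarkDrug("drugbank:mebendazole", "Mebendazole", "in_vivo", 3, 0.93, "TUBA1A", "CDKN2A"),
    BenchmarkDrug("drugbank:framycetin", "Framycetin", "novel", 3, 0.97, "CXCR4", "CXCL12"),
    BenchmarkDrug("drugbank:lucanthone", "Lucanthone", "novel", 3, 0.93, "TOP2A", "CDKN2A"),
    BenchmarkDrug("drugbank:podofilox", "Podofilox", "novel", 3, 0.93, "TUBB", "MAPK1"),
)

#: disease genes and the curated source asserting their melanoma link
_BENCHMARK_DISEASE_GENES = {
    "BRAF": "cosmic", "CDKN2A": "cosmic",
    "TERT": "omim", "MAP2K1": "omim", "MAPK1": "omim", "MYC": "omim",
    "TP53": "omim", "CXCL12": "omim",
}

# probability-axis decoys: reachable in 3 steps but with a weak middle edge
# (single level-1 record, joint 0.99*0.8*0.99 = 0.784), labelled novel
_PROB_DECOYS = ("amoxicillin", "lisinopril", "omeprazole",
                "metformin", "loratadine", "simvastatin")
# step-axis decoys: strong 4-step chains (excluded at <=3 steps, included at 4)
_STEP_DECOYS = ("aspirin", "ibuprofen")

#: evidence model used by the benchmark tables (user-replaceable; the level
#: values are calibrated so planted paths reproduce the published roundings)
def benchmark_evidence_config() -> EvidenceConfig:
    return EvidenceConfig(
        curated_sources=frozenset({"drugbank", "omim", "cosmic"}),
        method_levels={"MI:0018": 1, "MI:0096": 2, "MI:0114": 3},
        level_probabilities={1: 0.8, 2: 0.95, 3: 0.97},
        curated_probability=0.99,
        unknown_method_policy="error",
    )


def generate_melanoma_benchmark(outdir) -> dict[str, FsPath]:
    """Write the benchmark source tables, evidence config and hit labels.

    Returns a dict of output paths: ``mitab``, ``drug_targets``, ``omim``,
    ``cosmic``, ``evidence_config``, ``labels``, ``expected``.
    """
    outdir = FsPath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def uid(symbol: str) -> str:
        return f"uniprot:{symbol}"

    drug_rows, ppi, omim_rows, cosmic_rows, labels = [], {}, [], [], []
    ref_counter = iter(range(9000001, 9999999))

    def add_ppi(a: str, b: str, rows: list[tuple[str, str, str]]) -> None:
        """rows: (method code, source db, pubmed ref) per redundant record."""
        ppi.setdefault((a, b), rows)

    for drug in MELANOMA_BENCHMARK:
        drug_rows.append((drug.drug_id, drug.name, uid(drug.target), "inhibitor"))
        labels.append((drug.drug_id, MELANOMA_ID, drug.status))
        if drug.via is not None:
            if drug.printed_joint == 0.93:    # middle edge 0.95: one level-2 record
                rows = [("MI:0096", "biogrid", f"pubmed:{next(ref_counter)}")]
            elif drug.printed_joint == 0.95:  # middle edge 0.97: one level-3 record
                rows = [("MI:0114", "intact", f"pubmed:{next(ref_counter)}")]
            else:                             # 0.97: three level-1 records reinforce
                rows = [("MI:0018", db, f"pubmed:{next(ref_counter)}")
                        for db in ("biogrid", "intact", "dip")]
            add_ppi(uid(drug.target), uid(drug.via), rows)

    for gene, source in _BENCHMARK_DISEASE_GENES.items():
        (cosmic_rows if source == "cosmic" else omim_rows).append(
            (uid(gene), MELANOMA_ID, MELANOMA_LABEL))

    for i, slug in enumerate(_PROB_DECOYS, start=1):
        drug_id, pa, pb = f"drugbank:{slug}", uid(f"DEC{i}A"), uid(f"DEC{i}B")
        drug_rows.append((drug_id, slug.capitalize(), pa, "inhibitor"))
        add_ppi(pa, pb, [("MI:0018", "biogrid", f"pubmed:{next(ref_counter)}")])
        omim_rows.append((pb, MELANOMA_ID, MELANOMA_LABEL))
        labels.append((drug_id, MELANOMA_ID, "novel"))

    for i, slug in enumerate(_STEP_DECOYS, start=1):
        drug_id = f"drugbank:{slug}"
        p1, p2, p3 = (uid(f"SD{i}{c}") for c in "ABC")
        drug_rows.append((drug_id, slug.capitalize(), p1, "inhibitor"))
        for a, b in ((p1, p2), (p2, p3)):
            add_ppi(a, b, [("MI:0096", db, f"pubmed:{next(ref_counter)}")
                           for db in ("biogrid", "intact")])
        omim_rows.append((p3, MELANOMA_ID, MELANOMA_LABEL))
        labels.append((drug_id, MELANOMA_ID, "phase_ii"))

    paths = {
        "mitab": outdir / "ppi_mitab.tsv",
        "drug_targets": outdir / "drug_targets.tsv",
        "omim": outdir / "gene_disease_omim.tsv",
        "cosmic": outdir / "gene_disease_cosmic.tsv",
        "evidence_config": outdir / "evidence_config.yaml",
        "labels": outdir / "labels.tsv",
        "expected": outdir / "expected_candidates.csv",
    }

    mitab_rows = [
        {"id_a": a, "id_b": b, "method": method, "interaction_type": _PPI_TYPE,
         "source_db": db, "pubmed": ref}
        for (a, b), rows in sorted(ppi.items())
        for (method, db, ref) in rows
    ]
    pd.DataFrame(mitab_rows, columns=_MITAB_COLUMNS).to_csv(
        paths["mitab"], sep="\t", index=False)
    pd.DataFrame(sorted(drug_rows),
                 columns=["drug_id", "drug_name", "target_id", "action"]).to_csv(
        paths["drug_targets"], sep="\t", index=False)
    for key, rows in (("omim", omim_rows), ("cosmic", cosmic_rows)):
        pd.DataFrame(sorted(rows),
                     columns=["gene_id", "disease_id", "disease_label"]).to_csv(
            paths[key], sep="\t", index=False)
    benchmark_evidence_config().to_yaml(paths["evidence_config"])
    pd.DataFrame(sorted(labels),
                 columns=["drug_id", "disease_id", "status"]).to_csv(
        paths["labels"], sep="\t", index=False)
    pd.DataFrame(
        [{"drug_id": d.drug_id, "drug_label": d.name, "status": d.status,
          "steps": d.steps, "joint_probability_2dp": f"{d.printed_joint:.2f}"}
         for d in MELANOMA_BENCHMARK],
        columns=["drug_id", "drug_label", "status", "steps", "joint_probability_2dp"],
    ).to_csv(paths["expected"], index=False)
    return paths


# --------------------------------------------------------------------------- #
# random knowledge graphs

@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a random evidence-annotated knowledge graph.

    ``records_per_edge_mean`` is the mean multiplicity of redundant records
    per PPI edge (1 + Poisson); ``evidence_mix`` gives the proportions of
    curated / level-1 / level-2 / level-3 PPI records.
    """

    seed: int = 0
    n_drugs: int = 12
    n_proteins: int = 30
    n_diseases: int = 3
    ppi_density: float = 0.08
    records_per_edge_mean: float = 1.6
    evidence_mix: tuple[float, float, float, float] = (0.1, 0.3, 0.35, 0.25)

    def __post_init__(self) -> None:
        from .graph import ValidationError
        if min(self.n_drugs, self.n_proteins, self.n_diseases) < 1:
            raise ValidationError("entity counts must all be >= 1")
        if not (0.0 < self.ppi_density < 1.0):
            raise ValidationError("ppi_density must be in (0, 1)")
        if self.records_per_edge_mean < 1.0:
            raise ValidationError("records_per_edge_mean must be >= 1")
        if abs(sum(self.evidence_mix) - 1.0) > 1e-9 or min(self.evidence_mix) < 0:
            raise ValidationError("evidence_mix proportions must be >= 0 and sum to 1")


_LEVEL_METHODS = {1: "MI:0018", 2: "MI:0096", 3: "MI:0114"}
_EXPERIMENTAL_DBS = ("biogrid", "intact", "dip")


def random_evidence_config() -> EvidenceConfig:
    """Default evidence model for random fixtures ('hprd' is the curated PPI source)."""
    return EvidenceConfig(
        curated_sources=frozenset({"drugbank", "omim", "cosmic", "hprd"}),
        method_levels=dict((v, k) for k, v in _LEVEL_METHODS.items()),
    )


def generate_random_kg(spec: FixtureSpec, outdir) -> dict:
    """Write random source tables plus a ground-truth manifest.

    The manifest records every planted record's assigned probability (so
    downstream edge probabilities are independently recomputable) and the
    table checksums (so determinism under a repeated seed is checkable).
    Returns the manifest dict; files land in ``outdir``.
    """
    spec.__post_init__()
    outdir = FsPath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    config = random_evidence_config()

    proteins = [f"uniprot:P{i:04d}" for i in range(spec.n_proteins)]
    drugs = [f"drugbank:D{i:04d}" for i in range(spec.n_drugs)]
    diseases = [f"efo:Z{i:04d}" for i in range(spec.n_diseases)]

    manifest_records = []
    mitab_rows = []
    for i in range(spec.n_proteins):
        for j in range(i + 1, spec.n_proteins):
            if rng.random() >= spec.ppi_density:
                continue
            multiplicity = 1 + rng.poisson(spec.records_per_edge_mean - 1.0)
            for k in range(multiplicity):
                cls = rng.choice(4, p=spec.evidence_mix)
                ref = f"pubmed:{rng.integers(1_000_000, 9_999_999)}"
                if cls == 0:
                    db, method = "hprd", ""
                    prob = config.curated_probability
                else:
                    db = _EXPERIMENTAL_DBS[int(rng.integers(len(_EXPERIMENTAL_DBS)))]
                    method = _LEVEL_METHODS[int(cls)]
                    prob = config.level_probabilities[int(cls)]
                mitab_rows.append({
                    "id_a": proteins[i], "id_b": proteins[j], "method": method,
                    "interaction_type": _PPI_TYPE, "source_db": db, "pubmed": ref,
                })
                manifest_records.append({
                    "subject_id": proteins[i], "object_id": proteins[j],
                    "interaction_type": _PPI_TYPE, "source_db": db,
                    "method": method or None, "primary_ref": ref,
                    "probability": prob,
                })

    drug_rows = []
    for d, drug_id in enumerate(drugs):
        n_targets = int(rng.integers(1, 4))
        targets = rng.choice(spec.n_proteins, size=n_targets, replace=False)
        for t in sorted(int(x) for x in targets):
            drug_rows.append({
                "drug_id": drug_id, "drug_name": f"Drug {d}",
                "target_id": proteins[t], "action": "inhibitor",
            })
            manifest_records.append({
                "subject_id": drug_id, "object_id": proteins[t],
                "interaction_type": "sio:targets", "source_db": "drugbank",
                "method": None, "primary_ref": "",
                "probability": config.curated_probability,
            })

    gd_rows = []
    for z, disease_id in enumerate(diseases):
        n_genes = int(rng.integers(2, 6))
        genes = rng.choice(spec.n_proteins, size=min(n_genes, spec.n_proteins),
                           replace=False)
        for g in sorted(int(x) for x in genes):
            gd_rows.append({
                "gene_id": proteins[g], "disease_id": disease_id,
                "disease_label": f"disease {z}",
            })
            manifest_records.append({
                "subject_id": proteins[g], "object_id": disease_id,
                "interaction_type": "sio:gene-disease-association",
                "source_db": "omim", "method": None, "primary_ref": "",
                "probability": config.curated_probability,
            })

    paths = {
        "mitab": outdir / "ppi_mitab.tsv",
        "drug_targets": outdir / "drug_targets.tsv",
        "omim": outdir / "gene_disease_omim.tsv",
        "evidence_config": outdir / "evidence_config.yaml",
        "manifest": outdir / "manifest.json",
    }
    pd.DataFrame(mitab_rows, columns=_MITAB_COLUMNS).to_csv(
        paths["mitab"], sep="\t", index=False)
    pd.DataFrame(drug_rows,
                 columns=["drug_id", "drug_name", "target_id", "action"]).to_csv(
        paths["drug_targets"], sep="\t", index=False)
    pd.DataFrame(gd_rows,
                 columns=["gene_id", "disease_id", "disease_label"]).to_csv(
        paths["omim"], sep="\t", index=False)
    config.to_yaml(paths["evidence_config"])

    manifest = {
        "spec": {
            "seed": spec.seed, "n_drugs": spec.n_drugs,
            "n_proteins": spec.n_proteins, "n_diseases": spec.n_diseases,
            "ppi_density": spec.ppi_density,
            "records_per_edge_mean": spec.records_per_edge_mean,
            "evidence_mix": list(spec.evidence_mix),
        },
        "n_records": len(manifest_records),
        "records": manifest_records,
        "checksums": {name: _sha256(paths[name])
                      for name in ("mitab", "drug_targets", "omim", "evidence_config")},
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _sha256(path) -> str:
    return hashlib.sha256(FsPath(path).read_bytes()).hexdigest()
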
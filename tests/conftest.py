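"""Shared fixtures: the melanoma benchmark pipeline and toy-graph builders."""

import math

import pytest

from rxgraph.evidence import CombinerSpec, recombine_edges
from rxgraph.fixtures import benchmark_evidence_config, generate_melanoma_benchmark
from rxgraph.graph import AssertionRecord, Entity, Evidence, KnowledgeGraph
from rxgraph.ingest import build_graph


@pytest.fixture(scope="session")
def benchmark_paths(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("melanoma_benchmark")
    return generate_melanoma_benchmark(outdir)


@pytest.fixture(scope="session")
def benchmark_graph(benchmark_paths):
    return build_graph(
        benchmark_evidence_config(),
        mitab=[benchmark_paths["mitab"]],
        drug_targets=[benchmark_paths["drug_targets"]],
        omim=[benchmark_paths["omim"]],
        cosmic=[benchmark_paths["cosmic"]],
    )


@pytest.fixture
def toy_graph_factory():
    """Build a graph from (subject, type, object, directed, probability,
    subject_type, object_type) tuples; edges get their combined probability
    from a single planted record each."""

    def build(edge_specs, combiner=CombinerSpec()):
        graph = KnowledgeGraph()
        for subj, itype, obj, directed, prob, stype, otype in edge_specs:
            for eid, etype in ((subj, stype), (obj, otype)):
                if eid not in graph.entities:
                    graph.add_entity(Entity(eid, eid.split(":")[-1], etype))
            graph.add_assertion(AssertionRecord(
                subject_id=subj, interaction_type=itype, object_id=obj,
                directed=directed, source_db="toy",
                evidence=Evidence("experimental", "MI:0018"),
                primary_ref=f"ref:{subj}-{obj}", probability=prob,
            ))
        return recombine_edges(graph, combiner)

    return build


# independent normal CDF / quantile used as the combiner oracle
def normal_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def normal_quantile(p: float) -> float:
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if normal_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_composite_z(probabilities) -> float:
    return normal_cdf(sum(normal_quantile(p) for p in probabilities))
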
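"""Joint-probability expansion against a brute-force enumeration oracle."""

import numpy as np
import pytest

from rxgraph.graph import (
    AssertionRecord,
    Entity,
    Evidence,
    KnowledgeGraph,
    MissingEntityError,
    ValidationError,
)
from rxgraph.evidence import recombine_edges
from rxgraph.pathfind import (
    ExpansionQuery,
    expand,
    find_candidates,
    joint_probability,
)


class TestJointProbability:
    def test_empty_conjunction_is_one(self):
        assert joint_probability([]) == 1.0

    def test_identity_and_product(self):
        assert joint_probability([0.93]) == pytest.approx(0.93)
        assert joint_probability([0.99, 0.99]) == pytest.approx(0.9801)

    def test_values_outside_half_open_interval_rejected(self):
        for bad in (0.0, -0.1, 1.0001):
            with pytest.raises(ValidationError):
                joint_probability([bad])


# ---------------------------------------------------------------------------- #
# brute-force oracle: enumerate every simple path, filter afterwards

def enumerate_all_simple_paths(graph, seed, direction, max_len):
    """All simple paths from seed up to max_len edges, no pruning."""
    paths = []

    def walk(node, nodes, edges):
        if len(edges) == max_len:
            return
        for edge in graph.neighbors(node, direction=direction):
            nxt = edge.other_endpoint(node)
            if nxt == node or nxt in nodes:
                continue
            new_nodes, new_edges = nodes + (nxt,), edges + (edge,)
            paths.append((new_nodes, new_edges))
            walk(nxt, new_nodes, new_edges)

    walk(seed, (seed,), ())
    return paths


def oracle_expand(graph, query):
    """Post-hoc filtered enumeration: the reference for expand()."""
    out = []
    for nodes, edges in enumerate_all_simple_paths(
            graph, query.seed_entity, query.direction, query.max_steps):
        jp = 1.0
        for e in edges:
            jp *= e.combined_probability
        if jp < query.min_joint_probability:
            continue
        if (query.endpoint_type_filter is not None
                and graph.entity(nodes[-1]).entity_type != query.endpoint_type_filter):
            continue
        out.append((nodes, jp))
    return out


def random_graph(rng, n_nodes, n_edges):
    g = KnowledgeGraph()
    types = ["drug", "protein", "protein", "gene", "disease"]
    ids = []
    for i in range(n_nodes):
        eid = f"n{i}"
        g.add_entity(Entity(eid, eid, types[int(rng.integers(len(types)))]))
        ids.append(eid)
    for k in range(n_edges):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        g.add_assertion(AssertionRecord(
            subject_id=ids[a],
            interaction_type=f"t{int(rng.integers(2))}",
            object_id=ids[b],
            directed=bool((a + b) % 2),  # consistent per node pair
            source_db="toy",
            evidence=Evidence("experimental", "MI:0018"),
            primary_ref=f"pubmed:{k}",
            probability=float(rng.uniform(0.5, 0.999)),
        ))
    return recombine_edges(g)


def assert_matches_oracle(graph, query):
    got = {(p.node_sequence, round(p.joint_probability, 14)): p.joint_probability
           for p in expand(graph, query)}
    want = {(nodes, round(jp, 14)): jp for nodes, jp in oracle_expand(graph, query)}
    assert set(got) == set(want)
    for key, jp in got.items():
        assert jp == pytest.approx(want[key], abs=1e-12)


class TestExpand:
    def test_linear_drug_protein_disease_chain(self, toy_graph_factory):
        g = toy_graph_factory([
            ("drugbank:d", "sio:targets", "uniprot:p", True, 0.999, "drug", "protein"),
            ("uniprot:p", "sio:gene-disease-association", "efo:z", True, 0.999,
             "gene", "disease"),
        ])
        paths = expand(g, ExpansionQuery(seed_entity="efo:z", direction="incoming",
                                         endpoint_type_filter="drug"))
        assert len(paths) == 1
        assert paths[0].steps == 2
        assert paths[0].joint_probability == pytest.approx(0.998001)

    def test_threshold_excludes_everything_when_too_high(self, toy_graph_factory):
        g = toy_graph_factory([
            ("drugbank:d", "sio:targets", "uniprot:p", True, 0.999, "drug", "protein"),
            ("uniprot:p", "sio:gene-disease-association", "efo:z", True, 0.999,
             "gene", "disease"),
        ])
        paths = expand(g, ExpansionQuery(seed_entity="efo:z", direction="incoming",
                                         min_joint_probability=0.999,
                                         endpoint_type_filter="drug"))
        assert paths == []

    def test_directed_edges_not_traversed_against_query_direction(self, toy_graph_factory):
        g = toy_graph_factory([
            ("a", "t", "b", True, 0.9, "protein", "protein"),
        ])
        downstream = expand(g, ExpansionQuery(seed_entity="a", direction="outgoing",
                                              min_joint_probability=0.5))
        upstream = expand(g, ExpansionQuery(seed_entity="a", direction="incoming",
                                            min_joint_probability=0.5))
        assert len(downstream) == 1 and upstream == []

    def test_self_interaction_never_advances_a_path(self, toy_graph_factory):
        g = toy_graph_factory([
            ("a", "t", "a", False, 0.9, "protein", "protein"),
            ("a", "t", "b", False, 0.9, "protein", "protein"),
        ])
        paths = expand(g, ExpansionQuery(seed_entity="a", direction="both",
                                         min_joint_probability=0.5))
        assert [p.node_sequence for p in paths] == [("a", "b")]

    def test_unknown_seed_raises(self, toy_graph_factory):
        g = toy_graph_factory([("a", "t", "b", False, 0.9, "protein", "protein")])
        with pytest.raises(MissingEntityError):
            expand(g, ExpansionQuery(seed_entity="zzz"))

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n_nodes = int(rng.integers(4, 20))
            g = random_graph(rng, n_nodes, n_edges=int(rng.integers(3, 30)))
            query = ExpansionQuery(
                seed_entity="n0",
                direction=("incoming", "outgoing", "both")[int(rng.integers(3))],
                max_steps=int(rng.integers(1, 5)),
                min_joint_probability=float(rng.choice([0.3, 0.5, 0.8])),
                endpoint_type_filter="drug" if rng.random() < 0.5 else None,
            )
            assert_matches_oracle(g, query)

    def test_pruning_loses_no_path_because_extension_never_raises_probability(self):
        # anti-monotonicity spot check on a dense random graph
        rng = np.random.default_rng(11)
        g = random_graph(rng, 10, 40)
        query = ExpansionQuery(seed_entity="n0", direction="both",
                               max_steps=4, min_joint_probability=0.6)
        for path in expand(g, query):
            probs = [e.combined_probability for e in path.edge_sequence]
            for k in range(1, len(probs) + 1):
                prefix = joint_probability(probs[:k])
                assert prefix + 1e-15 >= path.joint_probability
                assert prefix >= query.min_joint_probability


class TestFindCandidates:
    @pytest.fixture
    def forked(self, toy_graph_factory):
        # one drug reachable by a 2-step (0.9801) and a 3-step (0.931) path
        return toy_graph_factory([
            ("drugbank:d", "sio:targets", "uniprot:g", True, 0.99, "drug", "protein"),
            ("drugbank:d", "sio:targets", "uniprot:p", True, 0.99, "drug", "protein"),
            ("uniprot:p", "sio:direct-interaction", "uniprot:g", False, 0.95,
             "protein", "protein"),
            ("uniprot:g", "sio:gene-disease-association", "efo:z", True, 0.99,
             "gene", "disease"),
        ])

    def test_best_path_prefers_higher_joint_probability(self, forked):
        table = find_candidates(forked, "efo:z")
        assert len(table) == 1
        c = table.candidates[0]
        assert c.steps == 2
        assert c.joint_probability == pytest.approx(0.9801)
        assert c.path_node_ids == ("drugbank:d", "uniprot:g", "efo:z")

    def test_isolated_disease_gives_empty_table(self, toy_graph_factory):
        g = toy_graph_factory([
            ("drugbank:d", "sio:targets", "uniprot:p", True, 0.99, "drug", "protein"),
        ])
        g.add_entity(Entity("efo:lonely", "lonely", "disease"))
        assert len(find_candidates(g, "efo:lonely")) == 0

    def test_non_disease_seed_rejected(self, forked):
        with pytest.raises(ValidationError):
            find_candidates(forked, "drugbank:d")

    def test_reported_candidates_respect_both_thresholds(self, benchmark_graph):
        from rxgraph.fixtures import MELANOMA_ID
        table = find_candidates(benchmark_graph, MELANOMA_ID,
                                max_steps=4, min_joint_probability=0.8)
        assert all(c.joint_probability >= 0.8 and c.steps <= 4
                   for c in table.candidates)

    def test_stricter_thresholds_never_add_candidates(self, benchmark_graph):
        from rxgraph.fixtures import MELANOMA_ID
        loose = set(find_candidates(benchmark_graph, MELANOMA_ID,
                                    min_joint_probability=0.5,
                                    max_steps=4).drug_ids())
        for p in (0.7, 0.9, 0.93, 0.95, 0.99):
            tighter = set(find_candidates(benchmark_graph, MELANOMA_ID,
                                          min_joint_probability=p,
                                          max_steps=4).drug_ids())
            assert tighter <= loose
            loose = tighter
        prev = set(find_candidates(benchmark_graph, MELANOMA_ID,
                                   max_steps=6).drug_ids())
        for steps in (5, 4, 3, 2, 1):
            smaller = set(find_candidates(benchmark_graph, MELANOMA_ID,
                                          max_steps=steps).drug_ids())
            assert smaller <= prev
            prev = smaller

    def test_csv_round_trip(self, tmp_path, forked):
        table = find_candidates(forked, "efo:z")
        path = tmp_path / "candidates.csv"
        table.to_csv(path)
        from rxgraph.pathfind import CandidateTable
        loaded = CandidateTable.from_csv(path)
        assert loaded.drug_ids() == table.drug_ids()
        assert loaded.candidates[0].joint_probability == pytest.approx(
            table.candidates[0].joint_probability, abs=1e-6)
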
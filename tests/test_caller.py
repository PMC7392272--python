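"""Chain calls: satisfaction modes, comprehensiveness, oracle equivalence."""

import itertools

import networkx as nx
import numpy as np
import pytest
from helpers import status_frame

from regenpath.caller import (
    call_catalog,
    comprehensive_call,
    node_satisfied,
)
from regenpath.expression import FormatError
from regenpath.pathway import (
    PathwayGraph,
    PathwayNode,
    load_packaged_catalog,
    load_packaged_pathway,
    pathway_from_dict,
)


def chain_graph(*node_specs, edges=None) -> PathwayGraph:
    """Linear or custom graph from (node_id, role, members) triples."""
    nodes = [
        {"node_id": nid, "label": nid, "role": role, "members": list(members)}
        for nid, role, members in node_specs
    ]
    if edges is None:
        ids = [n["node_id"] for n in nodes]
        edges = [[u, v] for u, v in zip(ids, ids[1:])]
    return pathway_from_dict(
        {"pathway_id": "toy", "name": "toy", "nodes": nodes, "edges": edges}
    )


class TestNodeSatisfied:
    def test_or_semantics_over_family_members(self):
        node = PathwayNode("MAPK1/3", "MAPK1/3", "intermediate",
                           ("MAPK1", "MAPK3"))
        st = status_frame(early=["MAPK1"])
        assert node_satisfied(node, st, "any")
        assert node_satisfied(node, st, "early")
        assert not node_satisfied(node, st, "late")

    def test_absent_members_count_as_not_upregulated(self):
        node = PathwayNode("X", "X", "effector", ("NOT_MEASURED",))
        assert not node_satisfied(node, status_frame(early=["OTHER"]), "any")

    def test_late_mode_sees_persistent_gene(self):
        node = PathwayNode("CSF1", "CSF1", "initiator", ("CSF1",))
        st = status_frame(early=["CSF1"], late=["CSF1"])
        assert node_satisfied(node, st, "late")

    def test_downregulation_never_satisfies(self):
        node = PathwayNode("CREB", "CREB", "effector", ("CREB1",))
        assert not node_satisfied(node, status_frame(down=["CREB1"]), "any")


class TestComprehensiveCall:
    def test_broken_middle_node_blocks(self):
        g = chain_graph(("A", "initiator", ["GA"]),
                        ("B", "intermediate", ["GB"]),
                        ("C", "effector", ["GC"]))
        call = comprehensive_call(g, status_frame(early=["GA", "GC"]))
        assert not call.comprehensive and call.satisfied_chains == ()

    def test_complete_chain_satisfies(self):
        g = chain_graph(("A", "initiator", ["GA"]),
                        ("B", "intermediate", ["GB"]),
                        ("C", "effector", ["GC"]))
        call = comprehensive_call(g, status_frame(early=["GA", "GB", "GC"]))
        assert call.comprehensive
        assert call.satisfied_chains == (("A", "B", "C"),)

    def test_all_unchanged_statuses_empty_call(self):
        for pid in ("mapk", "hippo", "camp", "jak_stat", "ras"):
            g = load_packaged_pathway(pid)
            call = comprehensive_call(g, status_frame())
            assert not call.comprehensive and not call.satisfied_chains

    def test_persistence_flags_follow_chain_nodes(self):
        g = chain_graph(("A", "initiator", ["GA"]),
                        ("B", "intermediate", ["GB"]),
                        ("C", "effector", ["GC"]))
        st = status_frame(early=["GA", "GB", "GC"], late=["GA"])
        call = comprehensive_call(g, st)
        assert call.initiators_persistent and not call.effectors_persistent

    def test_cycle_terminates_with_simple_paths(self):
        g = chain_graph(
            ("A", "initiator", ["GA"]), ("B", "intermediate", ["GB"]),
            ("C", "effector", ["GC"]),
            edges=[["A", "B"], ["B", "A"], ["B", "C"]],
        )
        call = comprehensive_call(g, status_frame(early=["GA", "GB", "GC"]))
        assert call.comprehensive
        assert call.satisfied_chains == (("A", "B", "C"),)

    def test_order_invariance_of_declaration(self):
        data = load_packaged_pathway("mapk").to_dict()
        shuffled = dict(data)
        shuffled["nodes"] = list(reversed(data["nodes"]))
        shuffled["edges"] = list(reversed(data["edges"]))
        st = status_frame(early=["CSF1", "GRB2", "SOS1", "KRAS", "ARAF",
                                 "MAP2K1", "MAPK1", "FOS"])
        c1 = comprehensive_call(pathway_from_dict(data), st)
        c2 = comprehensive_call(pathway_from_dict(shuffled), st)
        assert c1.comprehensive == c2.comprehensive
        assert c1.satisfied_chains == c2.satisfied_chains
        assert c1.node_status == c2.node_status


def _random_dag_and_statuses(rng: np.random.Generator):
    n = int(rng.integers(4, 11))
    ids = [f"N{i}" for i in range(n)]
    roles = ["initiator"] + ["intermediate"] * (n - 2) + ["effector"]
    # sprinkle extra initiators/effectors
    for i in range(1, n - 1):
        r = rng.random()
        if r < 0.15:
            roles[i] = "initiator"
        elif r > 0.85:
            roles[i] = "effector"
    nodes = [
        {"node_id": ids[i], "label": ids[i], "role": roles[i],
         "members": [f"g{i}a", f"g{i}b"]}
        for i in range(n)
    ]
    edges = [
        [ids[i], ids[j]]
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.35
    ]
    g = pathway_from_dict(
        {"pathway_id": "rand", "name": "rand", "nodes": nodes, "edges": edges}
    )
    up = [f"g{i}{'a' if rng.random() < 0.5 else 'b'}"
          for i in range(n) if rng.random() < 0.6]
    return g, status_frame(early=up)


def _brute_force_comprehensive(g: PathwayGraph, statuses) -> bool:
    """Independent oracle: enumerate all simple initiator-to-effector paths
    in the FULL graph and check whether any consists of satisfied nodes."""
    dig = g.to_networkx()
    for init in g.initiators():
        for eff in g.effectors():
            for path in nx.all_simple_paths(dig, init, eff):
                if all(node_satisfied(g.nodes[n], statuses, "any")
                       for n in path):
                    return True
    return False


def test_small_graph_brute_force_equivalence():
    rng = np.random.default_rng(42)
    for _ in range(60):
        g, st = _random_dag_and_statuses(rng)
        call = comprehensive_call(g, st)
        assert call.comprehensive == _brute_force_comprehensive(g, st)


def test_monotone_in_upregulated_genes():
    """Adding upregulated genes never turns a call off; removing them never
    turns it on."""
    rng = np.random.default_rng(43)
    for _ in range(30):
        g, st = _random_dag_and_statuses(rng)
        call = comprehensive_call(g, st)
        all_genes = sorted(g.all_members())
        bigger = status_frame(early=sorted(set(st.index) | set(all_genes)))
        call_big = comprehensive_call(g, bigger)
        if call.comprehensive:
            assert call_big.comprehensive
        smaller = status_frame(early=list(st.index[: len(st) // 2]))
        call_small = comprehensive_call(g, smaller)
        if not call.comprehensive:
            assert not call_small.comprehensive


def test_locality_unrelated_genes_do_not_affect_call():
    g = chain_graph(("A", "initiator", ["GA"]), ("C", "effector", ["GC"]))
    st1 = status_frame(early=["GA", "GC"])
    st2 = status_frame(early=["GA", "GC", "ELSEWHERE1", "ELSEWHERE2"])
    c1, c2 = comprehensive_call(g, st1), comprehensive_call(g, st2)
    assert c1.comprehensive == c2.comprehensive
    assert c1.satisfied_chains == c2.satisfied_chains


class TestCatalogCalls:
    def test_empty_status_table_zero_comprehensive(self):
        report = call_catalog(load_packaged_catalog(), status_frame())
        assert report.n_comprehensive == 0
        assert report.n_called == 5 and report.n_catalog == 20

    def test_not_called_entries_reported(self):
        report = call_catalog(load_packaged_catalog(), status_frame())
        assert len(report.not_called) == 15
        frame = report.to_frame()
        assert (~frame.loc[list(report.not_called), "called"]).all()
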
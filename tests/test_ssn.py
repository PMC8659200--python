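"""Sequence similarity network: dedup, edge rules, component assignment
vs a union-find oracle, threshold monotonicity, and the characterized
subgroup ii co-clustering fixture."""
import numpy as np
import pytest

from cyclomine.align import AlignmentParams
from cyclomine.models import ProteinRecord
from cyclomine.simulate import mutate_to_identity
from cyclomine.ssn import SSNGraph, SSNNode, assign_groups, build_ssn, dedupe_sequences
from oracles import union_find_components

BASE = "MSKELLRNAIGQTVKDAWDNGIKGGFLTAGQALSTVGAPFLNAVVGAIGGALTNWGLNKA"


def recs(seqs, prefix="r"):
    return [ProteinRecord(id=f"{prefix}{i}", sequence=s) for i, s in enumerate(seqs)]


class TestDedupe:
    def test_identical_sequences_collapse_with_multiplicity(self):
        nodes = dedupe_sequences(recs([BASE, BASE, BASE]))
        assert len(nodes) == 1
        assert nodes[0].multiplicity == 3
        assert nodes[0].id == "r0"  # first-seen id wins

    def test_distinct_sequences_stay_apart(self):
        nodes = dedupe_sequences(recs([BASE, BASE[1:], BASE[2:]]))
        assert [n.multiplicity for n in nodes] == [1, 1, 1]


class TestBuildSsn:
    def test_single_node_has_no_edges(self):
        g = build_ssn(dedupe_sequences(recs([BASE])))
        assert g.edges == []
        g.validate()

    def test_identical_pair_gets_one_edge_at_identity_100(self):
        g = build_ssn(dedupe_sequences(recs([BASE, BASE[:-1] + "G"])))
        assert len(g.edges) == 1
        assert g.edges[0][2] > 95.0

    def test_family_connected_at_50_edgeless_at_90(self):
        """Mutants at ~80% to a common ancestor are pairwise ~65% identical:
        one component at the 50% cutoff, fully disconnected at 90%."""
        rng = np.random.default_rng(3)
        family = [mutate_to_identity(BASE, 80.0, rng) for _ in range(5)]
        nodes = dedupe_sequences(recs(family))
        low = build_ssn(nodes, identity_threshold_pct=50.0)
        comps = assign_groups(low)
        assert len(comps) == 1 and not comps[0].is_singleton
        high = build_ssn(nodes, identity_threshold_pct=90.0)
        assert high.edges == []

    def test_outlier_at_40_percent_separates(self):
        rng = np.random.default_rng(4)
        family = [mutate_to_identity(BASE, 85.0, rng) for _ in range(4)]
        outlier = mutate_to_identity(BASE, 40.0, rng)
        nodes = dedupe_sequences(recs(family + [outlier]))
        groups = assign_groups(build_ssn(nodes))
        assert sum(1 for g in groups if not g.is_singleton) == 1
        singletons = [m for g in groups if g.is_singleton for m in g.members]
        assert singletons == ["r4"]


def synthetic_graph(rng, n_nodes, p_edge):
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    nodes = [SSNNode(id=i, sequence="M", multiplicity=1, source_ids=(i,)) for i in ids]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((ids[i], ids[j], 60.0, 100.0))
    return SSNGraph(nodes=nodes, edges=edges), ids, [(a, b) for a, b, *_ in edges]


class TestAssignGroups:
    def test_edgeless_graph_is_all_singletons(self):
        g, _, _ = synthetic_graph(np.random.default_rng(0), 5, 0.0)
        groups = assign_groups(g)
        assert len(groups) == 5
        assert all(g.is_singleton for g in groups)

    def test_ranking_by_descending_size(self):
        ids = [f"n{i}" for i in range(6)]
        nodes = [SSNNode(i, "M", 1, (i,)) for i in ids]
        edges = [("n0", "n1", 60, 100), ("n1", "n2", 60, 100), ("n2", "n3", 60, 100),
                 ("n4", "n5", 60, 100)]
        groups = assign_groups(SSNGraph(nodes=nodes, edges=edges))
        assert len(groups[0].members) == 4 and groups[0].group_id == 1
        assert len(groups[1].members) == 2 and groups[1].group_id == 2

    def test_components_match_union_find_oracle_on_random_graphs(self):
        """200 random graphs: component structure equals an independent
        union-find computation."""
        rng = np.random.default_rng(7218)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            g, ids, raw_edges = synthetic_graph(rng, n, float(rng.uniform(0, 0.2)))
            ours = sorted(g.members for g in assign_groups(g))
            assert ours == union_find_components(ids, raw_edges)

    def test_partition_conservation(self):
        g, ids, _ = synthetic_graph(np.random.default_rng(1), 30, 0.05)
        groups = assign_groups(g)
        assert sum(len(g.members) for g in groups) == len(ids)
        assert sorted(m for g in groups for m in g.members) == sorted(ids)


def test_raising_threshold_never_merges_components():
    """Components at a higher identity threshold refine those at a lower
    one: every high-threshold component sits inside one low-threshold
    component."""
    rng = np.random.default_rng(11)
    seqs = [mutate_to_identity(BASE, t, rng) for t in (95, 90, 80, 70, 60, 50)]
    nodes = dedupe_sequences(recs([BASE] + seqs))
    prev = None
    for threshold in (40.0, 55.0, 70.0, 85.0, 99.0):
        comps = [set(g.members) for g in assign_groups(
            build_ssn(nodes, identity_threshold_pct=threshold))]
        if prev is not None:
            for comp in comps:
                assert any(comp <= p for p in prev)
        prev = comps


def test_validate_rejects_self_edges_and_below_threshold_edges():
    nodes = [SSNNode("a", "M", 1, ("a",)), SSNNode("b", "M", 1, ("b",))]
    with pytest.raises(ValueError, match="self-edge"):
        SSNGraph(nodes=nodes, edges=[("a", "a", 60, 100)]).validate()
    with pytest.raises(ValueError, match="below identity"):
        SSNGraph(nodes=nodes, edges=[("a", "b", 30, 100)]).validate()


class TestCharacterizedFixture:
    def test_six_subgroup_ii_bacteriocins_co_cluster(self, seed_set):
        """The six documented subgroup ii circular bacteriocins land in a
        single connected component at the default 50% cutoff."""
        nodes = dedupe_sequences([e.record for e in seed_set.by_role("precursor")])
        groups = assign_groups(build_ssn(nodes))
        six = {"acidocin_B_precursor", "butyrovibriocin_AR10_precursor",
               "gassericin_A_precursor", "plantaricyclin_A_precursor",
               "plantacyclin_B21AG_precursor", "paracyclicin_precursor"}
        holders = [g for g in groups if six & set(g.members)]
        assert len(holders) == 1
        assert six <= set(holders[0].members)

    def test_families_do_not_merge(self, seed_set):
        nodes = dedupe_sequences([e.record for e in seed_set.by_role("precursor")])
        groups = assign_groups(build_ssn(nodes))
        by_member = {m: g.group_id for g in groups for m in g.members}
        assert by_member["amylocyclicin_precursor"] == by_member["enterocin_NKR_5_3B_precursor"]
        assert by_member["enterocin_AS_48_precursor"] == by_member["pumilarin_precursor"]
        assert by_member["amylocyclicin_precursor"] != by_member["enterocin_AS_48_precursor"]
        assert by_member["amylocyclicin_precursor"] != by_member["acidocin_B_precursor"]
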
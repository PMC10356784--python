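"""Graph construction, superpathway search, pruning, structure I/O."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from covrecon.model_io import MetabolicModel, Metabolite, Reaction, ReactionThermo, SideMetaboliteList
from covrecon.sim_network import (
    JacobianStructure,
    build_graph,
    export_interaction_sbml,
    import_interaction_sbml,
    prune_and_structure,
    shortest_paths,
    structure_compare,
    superpathway_table,
)


def make_model(reactions, mets=None):
    if mets is None:
        mets = sorted({m for r in reactions for m in r.stoichiometry})
    return MetabolicModel(metabolites=[Metabolite(id=m) for m in mets], reactions=reactions)


def enumerate_cheapest(graph, s, t):
    """Exhaustive simple-path enumeration oracle (graphs <= 8 nodes)."""
    g = graph.graph
    best = math.inf
    for path in nx.all_simple_paths(g, s, t):
        cost = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        best = min(best, cost)
    return best


class TestBuildGraph:
    def test_irreversible_bimolecular(self):
        model = make_model([Reaction("R", {"A": -1, "B": -1, "C": 1}, reversible=False)])
        g = build_graph(model, sides=None)
        assert g.weight("A", "C") == 1.0
        assert g.weight("B", "C") == 1.0
        assert g.weight("A", "B") == 1.0 and g.weight("B", "A") == 1.0   # co-substrates
        assert not g.graph.has_edge("C", "A")

    def test_reversible_default_reverse_weight(self):
        model = make_model([Reaction("R", {"A": -1, "B": 1}, reversible=True)])
        g = build_graph(model)
        assert g.weight("A", "B") == 1.0
        assert g.weight("B", "A") == 2.0

    def test_thermo_penalty_log10(self):
        model = make_model([Reaction("R", {"A": -1, "B": 1}, reversible=True)])
        thermo = {"R": ReactionThermo("R", delta_g=5000.0)}
        g = build_graph(model, thermo=thermo)
        assert g.weight("B", "A") == pytest.approx(2.0 + math.log10(5000.0))
        g2 = build_graph(model, thermo=thermo, use_thermo=False)
        assert g2.weight("B", "A") == 2.0

    def test_small_delta_g_no_penalty(self):
        model = make_model([Reaction("R", {"A": -1, "B": 1}, reversible=True)])
        g = build_graph(model, thermo={"R": ReactionThermo("R", delta_g=50.0)})
        assert g.weight("B", "A") == 2.0

    def test_side_metabolites_excluded(self):
        model = make_model([Reaction("R", {"A": -1, "atp_c": -1, "B": 1, "adp_c": 1})])
        g = build_graph(model, sides=SideMetaboliteList(ids={"atp", "adp"}))
        assert g.weight("A", "B") == 1.0
        assert "atp_c" not in g.graph

    def test_empty_side_stripped_reaction_contributes_nothing(self):
        model = make_model([Reaction("R", {"atp_c": -1, "adp_c": 1, "B": 1})])
        g = build_graph(model, sides=SideMetaboliteList(ids={"atp", "adp"}))
        assert g.graph.number_of_edges() == 0

    def test_co_product_edges_only_for_reversible(self):
        irr = make_model([Reaction("R", {"A": -1, "B": 1, "C": 1}, reversible=False)])
        g = build_graph(irr)
        assert not g.graph.has_edge("B", "C")
        rev = make_model([Reaction("R", {"A": -1, "B": 1, "C": 1}, reversible=True)])
        g = build_graph(rev)
        assert g.weight("B", "C") == 2.0 and g.weight("C", "B") == 2.0

    def test_parallel_edges_collapse_to_min_with_merged_provenance(self):
        model = make_model([
            Reaction("R1", {"A": -1, "B": 1}, reversible=False),
            Reaction("R2", {"B": -1, "A": 1}, reversible=True),
        ])
        g = build_graph(model)
        assert g.weight("A", "B") == 1.0                   # forward R1 beats reverse R2
        prov = g.graph["A"]["B"]["provenance"]
        assert {p[0] for p in prov} == {"R1", "R2"}

    def test_determinism_under_reaction_order(self):
        rxns = [
            Reaction("R1", {"A": -1, "B": 1}, reversible=True),
            Reaction("R2", {"B": -1, "C": 1}, reversible=False),
            Reaction("R3", {"A": -1, "C": -1, "D": 1}, reversible=False),
        ]
        g1 = build_graph(make_model(rxns))
        g2 = build_graph(make_model(rxns[::-1]))
        assert sorted(g1.graph.edges(data="weight")) == sorted(g2.graph.edges(data="weight"))

    def test_reverse_weight_below_one_rejected(self):
        model = make_model([Reaction("R", {"A": -1, "B": 1})])
        with pytest.raises(ValueError):
            build_graph(model, reverse_weight=0.5)


class TestShortestPaths:
    def chain(self):
        return build_graph(make_model([
            Reaction("R1", {"A": -1, "B": 1}, reversible=False),
            Reaction("R2", {"B": -1, "C": 1}, reversible=False),
        ]))

    def test_chain_cost(self):
        paths = shortest_paths(self.chain(), ["A", "C"])
        (p,) = paths
        assert (p.source, p.target, p.cost) == ("A", "C", 2.0)
        assert p.nodes == ["A", "B", "C"]

    def test_disconnected_pair_absent(self):
        paths = shortest_paths(self.chain(), ["C", "A"])
        assert [(p.source, p.target) for p in paths] == [("A", "C")]

    def test_equal_cost_tie_lexicographic(self):
        # two parallel two-step routes A->B1->Z and A->B2->Z, same cost
        g = build_graph(make_model([
            Reaction("R1", {"A": -1, "B2": 1}),
            Reaction("R2", {"B2": -1, "Z": 1}),
            Reaction("R3", {"A": -1, "B1": 1}),
            Reaction("R4", {"B1": -1, "Z": 1}),
        ]))
        (p,) = shortest_paths(g, ["A", "Z"])
        assert p.nodes == ["A", "B1", "Z"]

    def test_costs_match_exhaustive_enumeration(self, rng):
        # random weighted digraphs with <= 8 nodes
        for trial in range(10):
            g = nx.gnp_random_graph(7, 0.35, seed=int(rng.integers(1 << 30)), directed=True)
            from covrecon.sim_network import WeightedReactionGraph
            wg = WeightedReactionGraph()
            for u, v in g.edges:
                wg.add_edge(str(u), str(v), float(rng.uniform(0.5, 3.0)), ("R", "forward", "x"))
            nodes = [str(n) for n in g.nodes if str(n) in wg.graph]
            paths = shortest_paths(wg, nodes)
            found = {(p.source, p.target): p.cost for p in paths}
            for s, t in itertools.permutations(nodes, 2):
                oracle = enumerate_cheapest(wg, s, t)
                if math.isinf(oracle):
                    assert (s, t) not in found
                else:
                    assert found[(s, t)] == pytest.approx(oracle)

    def test_absent_target_kept_isolated(self):
        paths = shortest_paths(self.chain(), ["A", "C", "GHOST"])
        assert all("GHOST" not in (p.source, p.target) for p in paths)


class TestPruneAndStructure:
    def abc_paths(self, targets):
        g = build_graph(make_model([
            Reaction("R1", {"A": -1, "B": 1}),
            Reaction("R2", {"B": -1, "C": 1}),
        ]))
        return shortest_paths(g, targets)

    def test_two_step_route_kept(self):
        struct = prune_and_structure(self.abc_paths(["A", "C"]), ["A", "C"])
        assert struct.mask[1, 0]           # route A -> C sets entry (C, A)
        assert not struct.mask[0, 1]

    def test_interior_target_discarded(self):
        struct = prune_and_structure(self.abc_paths(["A", "B", "C"]), ["A", "B", "C"])
        assert not struct.mask[2, 0]       # A -> C passes through measured B
        assert struct.mask[1, 0] and struct.mask[2, 1]

    def test_cost_above_threshold_discarded(self):
        paths = self.abc_paths(["A", "C"])
        struct = prune_and_structure(paths, ["A", "C"], cost_threshold=1.5)
        assert not struct.mask[1, 0]

    def test_cost_exactly_at_threshold_kept(self):
        paths = self.abc_paths(["A", "C"])
        struct = prune_and_structure(paths, ["A", "C"], cost_threshold=2.0)
        assert struct.mask[1, 0]

    def test_diagonal_always_true(self):
        struct = prune_and_structure([], ["A", "B"])
        assert struct.mask.diagonal().all()

    def test_threshold_monotonicity(self):
        paths = self.abc_paths(["A", "B", "C"])
        for t1, t2 in [(0.5, 1.0), (1.0, 2.0), (2.0, 3.0)]:
            m1 = prune_and_structure(paths, ["A", "B", "C"], t1).mask
            m2 = prune_and_structure(paths, ["A", "B", "C"], t2).mask
            assert np.all(~m1 | m2)

    def test_adding_target_never_adds_entries_between_old_targets(self):
        g = build_graph(make_model([
            Reaction("R1", {"A": -1, "B": 1}),
            Reaction("R2", {"B": -1, "C": 1}),
            Reaction("R3", {"A": -1, "C": 1}),   # direct shortcut
        ]))
        small = prune_and_structure(shortest_paths(g, ["A", "C"]), ["A", "C"])
        big = prune_and_structure(shortest_paths(g, ["A", "B", "C"]), ["A", "B", "C"])
        # entries between A and C in the bigger run are a subset
        assert not (~small.mask[1, 0] and big.mask[2, 0])


class TestStructureIO:
    def make_structure(self):
        mask = np.array([[1, 0], [1, 1]], dtype=bool)
        return JacobianStructure(labels=["glc__D_c", "pyr_c"], mask=mask)

    def test_sbml_roundtrip_reproduces_mask(self, tmp_path):
        struct = self.make_structure()
        p = tmp_path / "net.xml"
        export_interaction_sbml(struct, p)
        back = import_interaction_sbml(p)
        assert back.labels == struct.labels
        assert np.array_equal(back.mask, struct.mask)

    def test_full_mask_counts(self, tmp_path):
        struct = JacobianStructure(labels=["a", "b"], mask=np.ones((2, 2), bool))
        p = tmp_path / "full.xml"
        export_interaction_sbml(struct, p)
        import libsbml

        doc = libsbml.readSBML(str(p))
        assert doc.getModel().getNumSpecies() == 2
        assert doc.getModel().getNumReactions() == 2
        assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0

    def test_diagonal_only_no_reactions(self, tmp_path):
        struct = JacobianStructure(labels=["a", "b"], mask=np.eye(2, dtype=bool))
        p = tmp_path / "diag.xml"
        export_interaction_sbml(struct, p)
        import libsbml

        assert libsbml.readSBML(str(p)).getModel().getNumReactions() == 0

    def test_superpathway_table_columns(self):
        g = build_graph(make_model([
            Reaction("R1", {"A": -1, "B": 1}, gene_association=["gA"]),
        ]))
        struct = prune_and_structure(shortest_paths(g, ["A", "B"]), ["A", "B"])
        model = make_model([Reaction("R1", {"A": -1, "B": 1}, gene_association=["gA"])])
        df = superpathway_table(struct, model)
        assert list(df.columns) == ["from", "to", "cost", "reactions", "genes"]
        assert df.iloc[0]["reactions"] == "R1"
        assert df.iloc[0]["genes"] == "gA"


class TestStructureCompare:
    def test_identical(self):
        s = JacobianStructure(labels=["a", "b"], mask=np.ones((2, 2), bool))
        rep = structure_compare(s, s)
        assert rep["added"] == 0 and rep["missing"] == 0 and rep["shared"] == 2

    def test_one_extra_entry(self):
        ref = JacobianStructure(labels=["a", "b"], mask=np.eye(2, dtype=bool))
        found = JacobianStructure(labels=["a", "b"],
                                  mask=np.array([[1, 1], [0, 1]], bool))
        rep = structure_compare(found, ref)
        assert rep["added"] == 1 and rep["missing"] == 0

    def test_disjoint_offdiagonals(self):
        f = np.eye(3, dtype=bool)
        f[0, 1] = f[0, 2] = True
        r = np.eye(3, dtype=bool)
        r[1, 0] = r[2, 0] = r[2, 1] = True
        rep = structure_compare(JacobianStructure(labels=list("abc"), mask=f),
                                JacobianStructure(labels=list("abc"), mask=r))
        assert (rep["added"], rep["missing"], rep["shared"]) == (2, 3, 0)

    def test_label_mismatch_rejected(self):
        a = JacobianStructure(labels=["a", "b"], mask=np.eye(2, dtype=bool))
        b = JacobianStructure(labels=["b", "a"], mask=np.eye(2, dtype=bool))
        with pytest.raises(ValueError, match="label"):
            structure_compare(a, b)
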
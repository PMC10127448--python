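import math
import random

import pytest

from degrank import (
    PruneSpec,
    UNREACHABLE,
    add_pathway,
    build_reaction_graph,
    enzyme_pathway_distances,
    lp_distance,
    prune_metabolites,
    shortest_distance,
)
from degrank.distance import _graph_reaction_ids
from degrank.synthetic_data import ToySpec, generate_toy_model

from conftest import BIG, build_model, random_toy
from _oracles import bfs_distance, pairwise_adjacency


class TestPrune:
    def test_degree_threshold_removes_hub(self):
        rxns = {"EX_S": ({"S": -1}, -10, BIG, None), "BIOMASS": ({"X5": -1}, 0, BIG, None)}
        prev = "S"
        for k in range(1, 6):  # hub participates in all five conversions
            rxns[f"r{k}"] = ({prev: -1, f"X{k}": 1, "hub": 0.0}, 0, BIG, None)
            prev = f"X{k}"
        model = build_model(rxns, "BIOMASS")
        surviving = prune_metabolites(model, PruneSpec.by_degree(3))
        assert "hub" not in surviving
        assert "X1" in surviving

    def test_explicit_list(self, chain3):
        surviving = prune_metabolites(chain3, PruneSpec.explicit(["M1_c"]))
        assert "M1_c" not in surviving and "M2_c" in surviving

    def test_missing_id_warns_not_errors(self, chain3):
        with pytest.warns(UserWarning, match="absent"):
            surviving = prune_metabolites(chain3, PruneSpec.explicit(["atp_ghost"]))
        assert surviving == set(chain3.metabolites)

    def test_exactly_one_mode(self):
        with pytest.raises(ValueError):
            PruneSpec(mode="both")
        with pytest.raises(ValueError):
            PruneSpec.by_degree(0)


class TestReactionGraph:
    def test_chain_is_path_graph(self, chain3):
        g = build_reaction_graph(chain3, set(chain3.metabolites))
        # exchanges and biomass are excluded
        assert set(g.nodes) == {"r_1", "r_2", "r_3"}
        assert set(map(frozenset, g.edges)) == {
            frozenset({"r_1", "r_2"}), frozenset({"r_2", "r_3"})
        }

    def test_pruned_metabolite_breaks_edge(self):
        model = build_model(
            {
                "EX_S": ({"S": -1}, -10, BIG, None),
                "ra": ({"S": -1, "A": 1, "atp": -0.5, "adp": 0.5}, 0, BIG, None),
                "rb": ({"A": -1, "B": 1}, 0, BIG, None),
                "rc": ({"B": -1, "X": 1, "adp": -0.5, "atp": 0.5}, 0, BIG, None),
                "BIOMASS": ({"X": -1}, 0, BIG, None),
            },
            "BIOMASS",
        )
        full = build_reaction_graph(model, set(model.metabolites))
        assert full.has_edge("ra", "rc")  # via shared ATP/ADP only
        pruned = build_reaction_graph(
            model, prune_metabolites(model, PruneSpec.explicit(["atp", "adp"]))
        )
        assert not pruned.has_edge("ra", "rc")
        # and the distance grows from 1 to the true path length 2
        assert shortest_distance(full, {"ra"}, {"rc"}) == 1
        assert shortest_distance(pruned, {"ra"}, {"rc"}) == 2

    def test_edges_match_pairwise_oracle(self):
        for seed in range(10):
            model = random_toy(seed)
            surviving = set(model.metabolites)
            g = build_reaction_graph(model, surviving)
            expected = pairwise_adjacency(model, surviving, _graph_reaction_ids(model))
            assert {tuple(sorted(e)) for e in g.edges} == expected


class TestShortestDistance:
    def test_identity_zero(self, chain3):
        g = build_reaction_graph(chain3, set(chain3.metabolites))
        assert shortest_distance(g, {"r_1"}, {"r_1"}) == 0

    def test_adjacent_is_one(self, chain3):
        g = build_reaction_graph(chain3, set(chain3.metabolites))
        assert shortest_distance(g, {"r_1"}, {"r_2"}) == 1

    def test_disconnected_unreachable(self, chain3):
        g = build_reaction_graph(chain3, set())  # prune everything: no edges
        assert math.isinf(shortest_distance(g, {"r_1"}, {"r_3"}))

    def test_unknown_id_rejected(self, chain3):
        g = build_reaction_graph(chain3, set(chain3.metabolites))
        with pytest.raises(KeyError):
            shortest_distance(g, {"nope"}, {"r_1"})


class TestLpDistance:
    def test_trivial_cases(self, chain3):
        surviving = set(chain3.metabolites)
        assert lp_distance(chain3, surviving, {"r_1"}, {"r_1"}) == 0
        assert lp_distance(chain3, surviving, {"r_1"}, {"r_2"}) == 1
        assert lp_distance(chain3, surviving, {"r_1"}, {"r_3"}) == 2

    def test_unreachable(self, chain3):
        assert math.isinf(lp_distance(chain3, set(), {"r_1"}, {"r_3"}))

    def test_equals_bfs_on_random_instances(self):
        rng = random.Random(0)
        checked = 0
        for seed in range(40):
            model = random_toy(seed, max_reactions=15)
            surviving = set(model.metabolites)
            g = build_reaction_graph(model, surviving)
            nodes = sorted(g.nodes)
            for _ in range(3):
                src = {rng.choice(nodes)}
                dst = {rng.choice(nodes)}
                expected = shortest_distance(g, src, dst)
                assert lp_distance(model, surviving, src, dst) == expected
                checked += 1
        assert checked >= 100


class TestMetricProperties:
    def _graph(self, seed):
        model = random_toy(seed)
        return model, build_reaction_graph(model, set(model.metabolites))

    def test_symmetry_and_identity(self):
        model, g = self._graph(4)
        nodes = sorted(g.nodes)
        for a in nodes:
            assert shortest_distance(g, {a}, {a}) == 0
            for b in nodes:
                assert shortest_distance(g, {a}, {b}) == shortest_distance(g, {b}, {a})

    def test_triangle_inequality(self):
        rng = random.Random(1)
        model, g = self._graph(5)
        nodes = sorted(g.nodes)
        for _ in range(30):
            a, b, c = (rng.choice(nodes) for _ in range(3))
            dab = shortest_distance(g, {a}, {b})
            dbc = shortest_distance(g, {b}, {c})
            dac = shortest_distance(g, {a}, {c})
            if not (math.isinf(dab) or math.isinf(dbc)):
                assert dac <= dab + dbc

    def test_pruning_is_monotone(self):
        # removing more metabolites can only lengthen (or disconnect) paths
        model = random_toy(6)
        mets = sorted(model.metabolites)
        g_full = build_reaction_graph(model, set(mets))
        g_less = build_reaction_graph(model, set(mets[: len(mets) // 2]))
        for a in g_full.nodes:
            for b in g_full.nodes:
                d_full = shortest_distance(g_full, {a}, {b})
                d_less = shortest_distance(g_less, {a}, {b})
                assert d_less >= d_full

    def test_relabeling_invariance(self):
        model = random_toy(7)
        relabeled = build_model(
            {
                f"zz_{rid}": (dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                              r.gpr.expression if r.gpr else None)
                for rid, r in model.reactions.items()
            },
            "zz_BIOMASS",
        )
        g1 = build_reaction_graph(model, set(model.metabolites))
        g2 = build_reaction_graph(relabeled, set(relabeled.metabolites))
        for a in g1.nodes:
            for b in g1.nodes:
                assert shortest_distance(g1, {a}, {b}) == shortest_distance(
                    g2, {f"zz_{a}"}, {f"zz_{b}"}
                )


class TestEnzymePathwayDistances:
    def test_planted_distance_recovered(self):
        for seed in (0, 1, 2):
            spec = ToySpec(seed=seed, planted_pathway_distance=3)
            model, medium, pathway, truth = generate_toy_model(spec)
            grafted = add_pathway(model, pathway)
            prune = PruneSpec.explicit(truth.currency_metabolite_ids)
            table = enzyme_pathway_distances(
                grafted,
                [(truth.planted_target_gene, [truth.planted_target_reaction])],
                pathway,
                prune,
            )
            assert table.min_distance[truth.planted_target_gene] == 3

    def test_multireaction_enzyme_aggregates_by_minimum(self, chain3):
        pathway_like = type("P", (), {"pathway_reaction_ids": ["r_3"]})()
        table = enzyme_pathway_distances(
            chain3, [("Gmulti", ["r_1", "r_2"])], pathway_like,
            PruneSpec.explicit([]),
        )
        assert table.entries[("Gmulti", "r_3")] == 1  # via r_2
        assert table.min_distance["Gmulti"] == 1

    def test_empty_reaction_set_rejected(self, chain3):
        pathway_like = type("P", (), {"pathway_reaction_ids": ["r_3"]})()
        with pytest.raises(ValueError, match="Ggone"):
            enzyme_pathway_distances(
                chain3, [("Ggone", [])], pathway_like, PruneSpec.explicit([])
            )
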
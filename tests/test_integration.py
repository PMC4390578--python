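import itertools

import numpy as np
import pytest

from mosaic import (
    CutoffTable,
    GraphNode,
    ProposalGraph,
    ProposalSet,
    SequenceRecord,
    ValidationError,
    WeightScheme,
    apply_cutoffs,
    build_graph,
    ccd_optimize,
    integrate,
    objective_of,
    search_space_size,
)


def rec(seq_id, species, method="m", residues="AWVATFD"):
    return SequenceRecord(seq_id, species, method, residues)


def node(species, method, sim, seq_id=None):
    seq_id = seq_id or f"{species}_{method}"
    return GraphNode(species, method, rec(seq_id, species, method), sim)


def graph_of(nodes, edges=None, ref_species="human"):
    return ProposalGraph(rec("ref", ref_species, "ref"), tuple(nodes), edges or {})


class TestSearchSpace:
    def test_four_methods_ten_species_exceeds_a_million(self):
        assert search_space_size(4, 10) == 1_048_576
        assert search_space_size(4, 10) >= 10**6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            search_space_size(0, 5)


class TestBuildGraph:
    def test_single_candidate_reference_only(self):
        pset = ProposalSet(
            "g1", rec("r", "human", "ref"), {("chimp", "m1"): rec("c", "chimp", "m1")}
        )
        graph = build_graph(pset)
        assert len(graph.nodes) == 1
        assert graph.nodes[0].sim_to_ref == 1.0
        assert graph.edges == {}

    def test_pairwise_weights_add_cross_species_edges(self):
        """3 species x 2 methods: 6 nodes; cross-species candidate pairs =
        C(6,2) minus 3 same-species pairs = 12 edges."""
        candidates = {
            (sp, m): rec(f"{sp}_{m}", sp, m)
            for sp in ("chimp", "gorilla", "cow")
            for m in ("m1", "m2")
        }
        pset = ProposalSet("g1", rec("r", "human", "ref"), candidates)
        graph = build_graph(pset, weights=WeightScheme.uniform_pairwise())
        assert len(graph.nodes) == 6
        assert len(graph.edges) == 12

    def test_reference_only_skips_candidate_edges(self):
        candidates = {
            (sp, "m1"): rec(f"{sp}", sp, "m1") for sp in ("chimp", "gorilla")
        }
        pset = ProposalSet("g1", rec("r", "human", "ref"), candidates)
        graph = build_graph(pset, weights=WeightScheme.reference_only())
        assert graph.edges == {}

    def test_no_candidates_is_an_error(self):
        pset = ProposalSet("g1", rec("r", "human", "ref"), {})
        with pytest.raises(ValidationError):
            build_graph(pset)

    def test_failing_scorer_drops_node_with_warning(self):
        def bad_scorer(pair):
            raise RuntimeError("boom")

        pset = ProposalSet(
            "g1", rec("r", "human", "ref"), {("chimp", "m1"): rec("c", "chimp", "m1")}
        )
        with pytest.warns(UserWarning, match="dropping"):
            graph = build_graph(pset, scorer=bad_scorer)
        assert graph.nodes == ()


class TestApplyCutoffs:
    def test_below_cutoff_removed(self):
        graph = graph_of([node("chimp", "m1", 0.80)])
        out = apply_cutoffs(graph, CutoffTable({"chimp": 0.82}))
        assert out.nodes == ()

    def test_exactly_at_cutoff_retained(self):
        graph = graph_of([node("chimp", "m1", 0.82)])
        out = apply_cutoffs(graph, CutoffTable({"chimp": 0.82}))
        assert len(out.nodes) == 1

    def test_all_above_cutoffs_unchanged(self):
        graph = graph_of([node("chimp", "m1", 0.99), node("cow", "m1", 0.95)])
        out = apply_cutoffs(graph, CutoffTable.mammal_defaults())
        assert out.nodes == graph.nodes

    def test_default_cutoff_applies_to_unlisted_species(self):
        graph = graph_of([node("cat", "m1", 0.69), node("cow", "m1", 0.71)])
        out = apply_cutoffs(graph, CutoffTable.mammal_defaults())
        assert [n.species for n in out.nodes] == ["cow"]

    def test_edges_to_removed_nodes_are_dropped(self):
        a, b = node("chimp", "m1", 0.60), node("cow", "m1", 0.95)
        graph = graph_of([a, b], {frozenset((a.key, b.key)): 0.8})
        out = apply_cutoffs(graph, CutoffTable.mammal_defaults())
        assert out.edges == {}


class TestObjective:
    def test_reference_only_sums_similarities(self):
        chosen = {"chimp": node("chimp", "m1", 0.9), "cow": node("cow", "m1", 0.8)}
        graph = graph_of(list(chosen.values()))
        obj = objective_of(chosen, graph, WeightScheme.reference_only())
        assert obj == pytest.approx(1.7)

    def test_empty_cluster_scores_zero(self):
        graph = graph_of([node("chimp", "m1", 0.9)])
        assert objective_of({}, graph, WeightScheme.reference_only()) == 0.0

    def test_uniform_pairwise_hand_sum(self):
        a, b, c = (
            node("chimp", "m1", 0.9),
            node("cow", "m1", 0.8),
            node("cat", "m1", 0.7),
        )
        edges = {
            frozenset((a.key, b.key)): 0.6,
            frozenset((a.key, c.key)): 0.5,
            frozenset((b.key, c.key)): 0.4,
        }
        graph = graph_of([a, b, c], edges)
        obj = objective_of(
            {"chimp": a, "cow": b, "cat": c}, graph, WeightScheme.uniform_pairwise()
        )
        # ref edges 0.9+0.8+0.7 plus candidate edges 0.6+0.5+0.4
        assert obj == pytest.approx(3.9)


def brute_force(graph, weights):
    by_species = graph.nodes_by_species()
    best = -np.inf
    for combo in itertools.product(*by_species.values()):
        chosen = {n.species: n for n in combo}
        best = max(best, objective_of(chosen, graph, weights))
    return best


class TestCcdOptimize:
    def test_single_method_selects_all_survivors(self):
        graph = graph_of([node("chimp", "m1", 0.9), node("cow", "m1", 0.8)])
        sol = ccd_optimize(graph, seed=0)
        assert {sp: n.method for sp, n in sol.chosen.items()} == {
            "chimp": "m1",
            "cow": "m1",
        }

    def test_reference_only_reduces_to_per_species_argmax(
        self, random_graph_factory
    ):
        """With reference-only weights the optimum is, independently per
        species, the candidate most similar to the reference."""
        for seed in range(10):
            graph = random_graph_factory(4, 3, seed=seed)
            sol = ccd_optimize(
                graph, WeightScheme.reference_only(), n_restarts=5, seed=seed
            )
            for species, nodes in graph.nodes_by_species().items():
                best_sim = max(n.sim_to_ref for n in nodes)
                assert sol.chosen[species].sim_to_ref == best_sim

    def test_matches_exhaustive_optimum_on_small_instances(
        self, random_graph_factory, brute_force_optimum
    ):
        """Best-of-20-restart CCD attains the enumeration optimum on random
        pairwise-weighted instances (<= 4 species x 3 methods)."""
        weights = WeightScheme.uniform_pairwise()
        for seed in range(25):
            graph = random_graph_factory(4, 3, seed=1000 + seed)
            sol = ccd_optimize(graph, weights, n_restarts=20, seed=seed)
            assert sol.objective == pytest.approx(brute_force_optimum(graph, weights))

    def test_objective_traces_are_monotone(self, random_graph_factory):
        weights = WeightScheme.uniform_pairwise()
        for seed in range(10):
            graph = random_graph_factory(4, 3, seed=seed)
            sol = ccd_optimize(graph, weights, n_restarts=10, seed=seed)
            for trace in sol.traces:
                assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_objective_equals_recomputation(self, random_graph_factory):
        weights = WeightScheme.uniform_pairwise()
        graph = random_graph_factory(3, 3, seed=5)
        sol = ccd_optimize(graph, weights, n_restarts=5, seed=5)
        assert sol.objective == pytest.approx(
            objective_of(sol.chosen, graph, weights)
        )

    def test_fixed_seed_reproducible(self, random_graph_factory):
        graph = random_graph_factory(4, 3, seed=3)
        weights = WeightScheme.uniform_pairwise()
        a = ccd_optimize(graph, weights, n_restarts=10, seed=42)
        b = ccd_optimize(graph, weights, n_restarts=10, seed=42)
        assert a == b

    def test_tie_break_prefers_method_priority_then_seq_id(self):
        tied = [
            node("chimp", "m2", 0.9, seq_id="zz"),
            node("chimp", "m1", 0.9, seq_id="aa"),
        ]
        sol = ccd_optimize(graph_of(tied), seed=0, method_priority=["m2", "m1"])
        assert sol.chosen["chimp"].method == "m2"
        sol = ccd_optimize(graph_of(tied), seed=0, method_priority=["m1", "m2"])
        assert sol.chosen["chimp"].method == "m1"

    def test_removing_non_optimal_node_preserves_optimum(
        self, random_graph_factory
    ):
        weights = WeightScheme.uniform_pairwise()
        graph = random_graph_factory(3, 3, seed=11)
        sol = ccd_optimize(graph, weights, n_restarts=20, seed=0)
        chosen_keys = {n.key for n in sol.chosen.values()}
        loser = next(n for n in graph.nodes if n.key not in chosen_keys)
        pruned_nodes = tuple(n for n in graph.nodes if n.key != loser.key)
        kept = {n.key for n in pruned_nodes}
        pruned = ProposalGraph(
            graph.ref_seq,
            pruned_nodes,
            {p: s for p, s in graph.edges.items() if p <= kept},
        )
        sol2 = ccd_optimize(pruned, weights, n_restarts=20, seed=0)
        assert sol2.objective == pytest.approx(sol.objective)

    def test_pooling_dominated_method_never_decreases_objective(
        self, random_graph_factory
    ):
        """Adding a method whose candidates are strictly dominated leaves the
        optimum unchanged; pooling methods can only help."""
        weights = WeightScheme.reference_only()
        graph = random_graph_factory(4, 2, seed=21)
        base = ccd_optimize(graph, weights, n_restarts=10, seed=0).objective
        extra = [
            node(sp, "worse", 0.01 * i, seq_id=f"{sp}_worse")
            for i, sp in enumerate(graph.nodes_by_species())
        ]
        pooled = ProposalGraph(
            graph.ref_seq, graph.nodes + tuple(extra), graph.edges
        )
        pooled_obj = ccd_optimize(pooled, weights, n_restarts=10, seed=0).objective
        assert pooled_obj >= base

    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValidationError):
            ccd_optimize(graph_of([]))


class TestIntegrate:
    def _pset(self):
        ref = rec("r", "human", "ref", "AWVATFDKKW")
        candidates = {
            ("chimp", "m1"): rec("c1", "chimp", "m1", "AWVATFDKKW"),
            ("chimp", "m2"): rec("c2", "chimp", "m2", "AWVRTFDKKW"),
            ("cow", "m1"): rec("w1", "cow", "m1", "AWVRTFDKKV"),
        }
        return ProposalSet("g1", ref, candidates)

    def test_selects_most_similar_per_species(self):
        result = integrate(self._pset(), cutoffs=CutoffTable.none(), seed=0)
        assert result.solution.chosen["chimp"].record.seq_id == "c1"
        assert result.solution.chosen["cow"].record.seq_id == "w1"

    def test_all_filtered_leaves_reference_only(self):
        strict = CutoffTable({}, 1.0)
        pset = ProposalSet(
            "g1",
            rec("r", "human", "ref", "AWVATFDKKW"),
            {("chimp", "m1"): rec("c", "chimp", "m1", "WWWWWFDKKW")},
        )
        result = integrate(pset, cutoffs=strict, seed=0)
        assert result.solution.chosen == {}
        assert result.solution.objective == 0.0
        assert [r.seq_id for r in result.selected_records] == ["r"]

    def test_provenance_lists_winning_methods(self):
        result = integrate(self._pset(), cutoffs=CutoffTable.none(), seed=0)
        prov = result.provenance
        assert list(prov.columns) == ["species", "method", "seq_id", "sim_to_ref"]
        assert set(prov["species"]) == {"chimp", "cow"}

    def test_fasta_output_reference_first(self, tmp_path):
        result = integrate(self._pset(), cutoffs=CutoffTable.none(), seed=0)
        out = tmp_path / "sel.fasta"
        result.write_fasta(out)
        first = out.read_text().splitlines()[0]
        assert first.startswith(">r|human")


class TestWeightScheme:
    def test_reference_only_zeroes_non_reference_pairs(self):
        w = WeightScheme.reference_only()
        assert w.weight("human", "chimp", "human") == 1.0
        assert w.weight("cow", "chimp", "human") == 0.0

    def test_same_species_weight_is_zero(self):
        assert WeightScheme.uniform_pairwise().weight("cow", "cow", "human") == 0.0

    def test_custom_weights_looked_up_unordered(self):
        w = WeightScheme.custom({frozenset(("cow", "chimp")): 0.5})
        assert w.weight("chimp", "cow", "human") == 0.5
        assert w.weight("cow", "chimp", "human") == 0.5
        assert w.weight("cow", "cat", "human") == 0.0

    def test_negative_custom_weight_rejected(self):
        with pytest.raises(ValidationError):
            WeightScheme.custom({frozenset(("a", "b")): -1.0})
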
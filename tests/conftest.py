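import numpy as np
import pytest
from hypothesis import settings

from mosaic import GraphNode, ProposalGraph, SequenceRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_record(seq_id, species, method, residues="AWVATFD"):
    return SequenceRecord(seq_id, species, method, residues)


@pytest.fixture
def random_graph_factory():
    """Factory for random proposal graphs with all candidate-candidate edges,
    usable under any weight scheme (sims drawn uniformly in [0, 1])."""

    def build(n_species, n_methods, seed, ref_species="human"):
        rng = np.random.default_rng(seed)
        ref = make_record("ref", ref_species, "reference")
        species = [f"sp{i}" for i in range(n_species)]
        methods = [f"m{j}" for j in range(n_methods)]
        nodes = []
        for sp in species:
            for meth in methods:
                rec = make_record(f"{sp}_{meth}", sp, meth)
                nodes.append(GraphNode(sp, meth, rec, float(rng.random())))
        edges = {}
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if a.species != b.species:
                    edges[frozenset((a.key, b.key))] = float(rng.random())
        return ProposalGraph(ref, tuple(nodes), edges)

    return build


@pytest.fixture(scope="session")
def five_leaf_trees():
    """All 15 unrooted binary trees on five leaves, independently of any tree
    library: each tree is uniquely the pair of disjoint leaf 2-subsets forming
    its two nontrivial splits.  Returns (newick, split_set) pairs."""
    import itertools

    leaves = ["a", "b", "c", "d", "e"]
    trees = []
    for s1, s2 in itertools.combinations(
        (frozenset(p) for p in itertools.combinations(leaves, 2)), 2
    ):
        if s1 & s2:
            continue  # overlapping 2-subsets are incompatible splits
        (x, y), (z, w) = sorted(s1), sorted(s2)
        (v,) = set(leaves) - s1 - s2
        newick = f"(({x},{y}),({z},{w}),{v});"
        trees.append((newick, {s1, s2}))
    assert len(trees) == 15
    return trees


@pytest.fixture
def brute_force_optimum():
    """Independent exhaustive-enumeration oracle for the cluster objective:
    direct arithmetic over every combination of one node per species."""
    import itertools

    def solve(graph, weights):
        ref_sp = graph.ref_species
        by_species = graph.nodes_by_species()
        best = -np.inf
        for combo in itertools.product(*by_species.values()):
            total = 0.0
            for node in combo:
                total += weights.weight(ref_sp, node.species, ref_sp) * node.sim_to_ref
            for a, b in itertools.combinations(combo, 2):
                w = weights.weight(a.species, b.species, ref_sp)
                if w:
                    total += w * graph.edges[frozenset((a.key, b.key))]
            best = max(best, total)
        return best

    return solve
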
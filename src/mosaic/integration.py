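"""Ortholog-detection integration as similarity-graph cluster optimization.

Candidate orthologs proposed by several detection methods are placed as nodes
in a graph, weighted by sequence similarity, filtered with species-specific
identity cutoffs, and reduced to at most one sequence per species by cyclic
coordinate descent (CCD) with random restarts.  With reference-only weights
the optimum is simply, per species, the candidate most similar to the
reference; with pairwise weights the optimizer trades off similarity among
all chosen sequences.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ProposalSet, SequenceRecord, write_fasta
from .similarity import AlignParams, Scorer, align_pair, percent_identity, score_value

logger = logging.getLogger(__name__)

NodeKey = tuple[str, str, str]  # (species, method, seq_id)


# ---------------------------------------------------------------------------
# Weights, cutoffs, graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightScheme:
    """Species-pair weights for the cluster objective.

    ``reference_only`` puts unit weight on pairs involving the reference
    species and zero elsewhere, so only similarity to the reference counts.
    ``uniform_pairwise`` weights every cross-species pair equally (maximizing
    the summed, hence average, pairwise similarity).  ``custom`` takes an
    explicit map of unordered species pairs to non-negative weights.
    """

    mode: str
    weights: Mapping[frozenset, float] | None = None

    _MODES = ("reference_only", "uniform_pairwise", "custom")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValidationError(f"unknown weight mode {self.mode!r}")
        if self.mode == "custom":
            if self.weights is None:
                raise ValidationError("custom mode requires an explicit weight map")
            for pair, w in self.weights.items():
                if w < 0:
                    raise ValidationError(f"negative weight {w} for pair {set(pair)}")

    @classmethod
    def reference_only(cls) -> "WeightScheme":
        return cls("reference_only")

    @classmethod
    def uniform_pairwise(cls) -> "WeightScheme":
        return cls("uniform_pairwise")

    @classmethod
    def custom(cls, weights: Mapping[frozenset, float]) -> "WeightScheme":
        return cls("custom", dict(weights))

    def weight(self, species_a: str, species_b: str, ref_species: str) -> float:
        if species_a == species_b:
            return 0.0
        if self.mode == "reference_only":
            return 1.0 if ref_species in (species_a, species_b) else 0.0
        if self.mode == "uniform_pairwise":
            return 1.0
        return self.weights.get(frozenset((species_a, species_b)), 0.0)


#: Identity cutoffs used for the ten-mammal primate-centred analysis: close
#: primates get stricter thresholds reflecting their lower expected divergence
#: from the reference; all remaining species default to 0.70.
MAMMAL_CUTOFFS: dict[str, float] = {
    "chimp": 0.82,
    "gorilla": 0.77,
    "orangutan": 0.75,
    "rhesus_macaque": 0.73,
}


@dataclass(frozen=True)
class CutoffTable:
    """Per-species minimum similarity-to-reference; candidates below their
    species cutoff are treated as putatively non-orthologous and removed.

    A candidate exactly at its cutoff is retained (the >= convention).
    """

    species_cutoffs: Mapping[str, float] = field(default_factory=dict)
    default_cutoff: float = 0.70

    def __post_init__(self) -> None:
        for sp, c in self.species_cutoffs.items():
            if not (0.0 <= c <= 1.0):
                raise ValidationError(f"cutoff {c} for {sp!r} outside [0, 1]")
        if not (0.0 <= self.default_cutoff <= 1.0):
            raise ValidationError(f"default cutoff {self.default_cutoff} outside [0, 1]")

    @classmethod
    def mammal_defaults(cls) -> "CutoffTable":
        return cls(dict(MAMMAL_CUTOFFS), 0.70)

    @classmethod
    def none(cls) -> "CutoffTable":
        """A no-op table (cutoff 0 everywhere)."""
        return cls({}, 0.0)

    def cutoff_for(self, species: str) -> float:
        return self.species_cutoffs.get(species, self.default_cutoff)


@dataclass(frozen=True)
class GraphNode:
    """One surviving candidate: its provenance plus similarity to the reference."""

    species: str
    method: str
    record: SequenceRecord
    sim_to_ref: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sim_to_ref <= 1.0):
            raise ValidationError(f"sim_to_ref {self.sim_to_ref} outside [0, 1]")

    @property
    def key(self) -> NodeKey:
        return (self.species, self.method, self.record.seq_id)


@dataclass(frozen=True)
class ProposalGraph:
    """The CCD search space: candidate nodes plus weighted similarity edges.

    Reference-candidate similarities live on the nodes (``sim_to_ref``);
    candidate-candidate edges are present only when the weight scheme gives
    their species pair nonzero weight.  Nodes of the same species are never
    connected (they compete, they do not co-occur).
    """

    ref_seq: SequenceRecord
    nodes: tuple[GraphNode, ...]
    edges: Mapping[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_key = {n.key: n for n in self.nodes}
        if len(by_key) != len(self.nodes):
            raise ValidationError("duplicate node keys in graph")
        for pair, sim in self.edges.items():
            a, b = tuple(pair)
            if a[0] == b[0]:
                raise ValidationError(f"edge between same-species nodes {a}, {b}")
            if not (0.0 <= sim <= 1.0):
                raise ValidationError(f"edge similarity {sim} outside [0, 1]")

    @property
    def ref_species(self) -> str:
        return self.ref_seq.species

    def nodes_by_species(self) -> dict[str, list[GraphNode]]:
        out: dict[str, list[GraphNode]] = {}
        for node in self.nodes:
            out.setdefault(node.species, []).append(node)
        return out

    def edge_sim(self, a: GraphNode, b: GraphNode) -> float:
        return self.edges[frozenset((a.key, b.key))]


@dataclass(frozen=True)
class ClusterSolution:
    """At most one chosen candidate per species, plus the achieved objective.

    ``traces`` holds, per restart, the objective value after initialization
    and after every accepted coordinate update; each trace is non-decreasing
    by construction.
    """

    chosen: Mapping[str, GraphNode]
    objective: float
    n_restarts_used: int
    converged: bool
    traces: tuple[tuple[float, ...], ...] = ()


def search_space_size(n_methods: int, n_species: int) -> int:
    """Upper bound on the number of integrated clusters: methods ** species."""
    if n_methods < 1 or n_species < 0:
        raise ValidationError("need n_methods >= 1 and n_species >= 0")
    return n_methods ** n_species


# ---------------------------------------------------------------------------
# Graph construction and filtering
# ---------------------------------------------------------------------------

def build_graph(
    pset: ProposalSet,
    scorer: Scorer = percent_identity,
    weights: WeightScheme | None = None,
    align_params: AlignParams | None = None,
) -> ProposalGraph:
    """Score every candidate against the reference and assemble the graph.

    Candidate-candidate edges are computed only for species pairs the weight
    scheme actually weights, which under reference-only weights skips all of
    them.  Cross-candidate similarities are symmetrized (mean of the two
    reference-denominated directions) since edge weights are unordered.
    A candidate the scorer fails on is dropped with a warning, not a crash.
    """
    if not pset.candidates:
        raise ValidationError(f"{pset.ref_gene}: no candidates to integrate")
    weights = weights or WeightScheme.reference_only()

    nodes: list[GraphNode] = []
    for (species, method), rec in pset.candidates.items():
        try:
            pair = align_pair(pset.ref_seq, rec, align_params)
            sim = score_value(scorer, pair)
        except Exception as exc:
            warnings.warn(
                f"{pset.ref_gene}: dropping candidate {rec.seq_id!r} "
                f"({species}/{method}): scoring failed: {exc}",
                stacklevel=2,
            )
            logger.warning("dropped candidate %s: %s", rec.seq_id, exc)
            continue
        nodes.append(GraphNode(species, method, rec, sim))

    edges: dict[frozenset, float] = {}
    for node_a, node_b in itertools.combinations(nodes, 2):
        if node_a.species == node_b.species:
            continue
        if weights.weight(node_a.species, node_b.species, pset.ref_seq.species) == 0.0:
            continue
        try:
            ab = score_value(
                scorer, align_pair(node_a.record, node_b.record, align_params)
            )
            ba = score_value(
                scorer, align_pair(node_b.record, node_a.record, align_params)
            )
        except Exception as exc:
            warnings.warn(
                f"{pset.ref_gene}: edge {node_a.record.seq_id}-"
                f"{node_b.record.seq_id} failed: {exc}",
                stacklevel=2,
            )
            continue
        edges[frozenset((node_a.key, node_b.key))] = (ab + ba) / 2.0

    return ProposalGraph(pset.ref_seq, tuple(nodes), edges)


def apply_cutoffs(graph: ProposalGraph, cutoffs: CutoffTable) -> ProposalGraph:
    """Remove nodes whose similarity to the reference is below their species
    cutoff (candidates at the cutoff are retained).  A species may end up with
    no surviving nodes, in which case it is simply absent downstream."""
    kept = tuple(
        n for n in graph.nodes if n.sim_to_ref >= cutoffs.cutoff_for(n.species)
    )
    kept_keys = {n.key for n in kept}
    edges = {
        pair: sim for pair, sim in graph.edges.items() if pair <= kept_keys
    }
    return ProposalGraph(graph.ref_seq, kept, edges)


# ---------------------------------------------------------------------------
# Objective and CCD optimizer
# ---------------------------------------------------------------------------

def objective_of(
    chosen: Mapping[str, GraphNode],
    graph: ProposalGraph,
    weights: WeightScheme,
) -> float:
    """Weighted sum of pairwise similarities over the chosen cluster.

    The reference sequence is always part of the cluster; species with no
    chosen node contribute nothing.
    """
    ref_sp = graph.ref_species
    total = 0.0
    for node in chosen.values():
        total += weights.weight(ref_sp, node.species, ref_sp) * node.sim_to_ref
    for node_a, node_b in itertools.combinations(chosen.values(), 2):
        w = weights.weight(node_a.species, node_b.species, ref_sp)
        if w != 0.0:
            total += w * graph.edge_sim(node_a, node_b)
    return total


def _tie_key(node: GraphNode, method_priority: Sequence[str] | None) -> tuple:
    # lower key wins: configured method priority first, then seq_id
    if method_priority and node.method in method_priority:
        rank = method_priority.index(node.method)
    else:
        rank = len(method_priority) if method_priority else 0
    return (rank, node.method, node.record.seq_id)


def _node_gain(
    node: GraphNode,
    others: Mapping[str, GraphNode],
    graph: ProposalGraph,
    weights: WeightScheme,
) -> float:
    ref_sp = graph.ref_species
    gain = weights.weight(ref_sp, node.species, ref_sp) * node.sim_to_ref
    for sp, other in others.items():
        if sp == node.species:
            continue
        w = weights.weight(node.species, other.species, ref_sp)
        if w != 0.0:
            gain += w * graph.edge_sim(node, other)
    return gain


def ccd_optimize(
    graph: ProposalGraph,
    weights: WeightScheme | None = None,
    n_restarts: int = 20,
    seed: int | None = None,
    method_priority: Sequence[str] | None = None,
) -> ClusterSolution:
    """Select at most one candidate per species by cyclic coordinate descent.

    Each restart starts from a uniformly random choice per species, then
    sweeps the species in a freshly drawn random order; each visit replaces a
    species' choice with the candidate maximizing the objective given the
    other species' current choices, accepting only strict improvements.  A
    restart terminates when a full sweep changes nothing — guaranteed, since
    the objective strictly increases on every accepted change and the state
    space is finite.  After convergence one canonicalization pass resolves
    exact ties by the configured method priority, then sequence id, so output
    is deterministic for a fixed seed.  The best solution across restarts is
    returned.
    """
    weights = weights or WeightScheme.reference_only()
    by_species = graph.nodes_by_species()
    if not by_species:
        raise ValidationError("graph has no candidate nodes")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    for sp in by_species:
        by_species[sp].sort(key=lambda n: _tie_key(n, method_priority))
    species_list = sorted(by_species)

    rng = np.random.default_rng(seed)
    best: dict[str, GraphNode] | None = None
    best_obj = -np.inf
    traces: list[tuple[float, ...]] = []

    for _ in range(n_restarts):
        chosen = {
            sp: nodes[rng.integers(len(nodes))] for sp, nodes in by_species.items()
        }
        obj = objective_of(chosen, graph, weights)
        trace = [obj]
        changed = True
        while changed:
            changed = False
            order = [species_list[i] for i in rng.permutation(len(species_list))]
            for sp in order:
                others = {s: n for s, n in chosen.items() if s != sp}
                current_gain = _node_gain(chosen[sp], others, graph, weights)
                best_node, best_gain = chosen[sp], current_gain
                for node in by_species[sp]:
                    gain = _node_gain(node, others, graph, weights)
                    if gain > best_gain:
                        best_node, best_gain = node, gain
                if best_node is not chosen[sp]:
                    assert best_gain > current_gain  # strict improvement only
                    chosen[sp] = best_node
                    obj += best_gain - current_gain
                    trace.append(obj)
                    changed = True

        # Resolve exact ties deterministically: among candidates with the same
        # gain as the converged choice, prefer the canonical tie-break winner.
        for sp in species_list:
            others = {s: n for s, n in chosen.items() if s != sp}
            current_gain = _node_gain(chosen[sp], others, graph, weights)
            for node in by_species[sp]:  # already in tie-break order
                if _node_gain(node, others, graph, weights) == current_gain:
                    chosen[sp] = node
                    break

        obj = objective_of(chosen, graph, weights)
        traces.append(tuple(trace))
        if obj > best_obj or (
            obj == best_obj
            and best is not None
            and sorted(n.key for n in chosen.values())
            < sorted(n.key for n in best.values())
        ):
            best, best_obj = dict(chosen), obj

    assert best is not None
    return ClusterSolution(
        chosen=best,
        objective=best_obj,
        n_restarts_used=n_restarts,
        converged=True,
        traces=tuple(traces),
    )


# ---------------------------------------------------------------------------
# End-to-end integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrationResult:
    """Outcome of integrating one proposal set."""

    ref_gene: str
    solution: ClusterSolution
    graph: ProposalGraph          # all scored candidates, pre-filter
    filtered_graph: ProposalGraph  # survivors of the cutoff filter

    @property
    def selected_records(self) -> list[SequenceRecord]:
        """Chosen sequences, reference first, then species-sorted."""
        out = [self.graph.ref_seq]
        for sp in sorted(self.solution.chosen):
            out.append(self.solution.chosen[sp].record)
        return out

    @property
    def provenance(self) -> pd.DataFrame:
        """Winning method and similarity per species."""
        rows = [
            (sp, node.method, node.record.seq_id, node.sim_to_ref)
            for sp, node in sorted(self.solution.chosen.items())
        ]
        return pd.DataFrame(rows, columns=["species", "method", "seq_id", "sim_to_ref"])

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.selected_records, path)

    def write_provenance(self, path: str | Path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)


def integrate(
    pset: ProposalSet,
    scorer: Scorer = percent_identity,
    weights: WeightScheme | None = None,
    cutoffs: CutoffTable | None = None,
    n_restarts: int = 20,
    seed: int | None = None,
    method_priority: Sequence[str] | None = None,
    align_params: AlignParams | None = None,
) -> IntegrationResult:
    """Build the proposal graph, filter it, and optimize the cluster.

    If every candidate is filtered out the result contains the reference
    alone, with objective 0.
    """
    weights = weights or WeightScheme.reference_only()
    cutoffs = cutoffs if cutoffs is not None else CutoffTable.mammal_defaults()
    graph = build_graph(pset, scorer, weights, align_params)
    filtered = apply_cutoffs(graph, cutoffs)
    if not filtered.nodes:
        solution = ClusterSolution(
            chosen={}, objective=0.0, n_restarts_used=0, converged=True
        )
    else:
        solution = ccd_optimize(filtered, weights, n_restarts, seed, method_priority)
    return IntegrationResult(pset.ref_gene, solution, graph, filtered)
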
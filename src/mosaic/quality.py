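"""Ortholog-quality assessment metrics.

Covers the four assessment axes used to judge integrated ortholog sets:
head-to-head percent-identity wins between methods, gene-tree/species-tree
concordance via the normalized unweighted Robinson-Foulds (RF) distance and
an AUC summary of its distribution, binary functional concordance from
protein-family annotations, and Jaccard overlap of positively selected sites.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import dendropy
from dendropy.calculate import treecompare

from .exceptions import ValidationError
from .io import AnnotationTable

#: Two methods are called apart only when their percent identities differ by
#: at least this margin (five percentage points); otherwise they are tied.
DEFAULT_WIN_MARGIN = 0.05

#: RF values at or beyond this limit carry no weight in the AUC summary.
DEFAULT_RF_LIMIT = 0.4

_EPS = 1e-12  # absorb float noise at the margin boundary


class Outcome(enum.Enum):
    A_WINS = "A_WINS"
    B_WINS = "B_WINS"
    TIE = "TIE"


class Concordance(enum.Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"
    UNDEFINED = "UNDEFINED"


def head_to_head(
    pid_a: float, pid_b: float, margin: float = DEFAULT_WIN_MARGIN
) -> Outcome:
    """Compare two percent identities; a win requires a lead of >= margin."""
    for v in (pid_a, pid_b):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"percent identity {v} outside [0, 1]")
    if pid_a - pid_b >= margin - _EPS:
        return Outcome.A_WINS
    if pid_b - pid_a >= margin - _EPS:
        return Outcome.B_WINS
    return Outcome.TIE


@dataclass(frozen=True)
class TreePair:
    """A gene tree and a species tree on overlapping leaf sets."""

    gene_tree: dendropy.Tree
    species_tree: dendropy.Tree


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None
    }


def _nontrivial_split_count(tree: dendropy.Tree) -> int:
    tree.encode_bipartitions()
    return len(
        {b.split_bitmask for b in tree.bipartition_encoding if not b.is_trivial()}
    )


def normalized_rf(
    gene_tree: dendropy.Tree, species_tree: dendropy.Tree
) -> float:
    """Normalized unweighted Robinson-Foulds distance between two trees.

    Both trees are treated as unrooted and restricted to their shared leaves
    (at least four are required).  The unweighted RF distance — the number of
    nontrivial splits present in exactly one tree — is divided by the total
    number of nontrivial splits in the two trees, yielding a value in [0, 1]
    where 0 means identical topologies.
    """
    shared = _leaf_labels(gene_tree) & _leaf_labels(species_tree)
    if len(shared) < 4:
        raise ValidationError(
            f"only {len(shared)} shared leaves; >= 4 required for RF"
        )

    tns = dendropy.TaxonNamespace()
    pruned = []
    for tree in (gene_tree, species_tree):
        clone = dendropy.Tree.get(
            data=tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=tns,
            rooting="force-unrooted",
        )
        clone.retain_taxa_with_labels(sorted(shared))
        pruned.append(clone)
    t_gene, t_species = pruned

    rf = treecompare.symmetric_difference(t_gene, t_species)
    denom = _nontrivial_split_count(t_gene) + _nontrivial_split_count(t_species)
    if denom == 0:
        # both trees are stars on the shared leaves: trivially identical
        return 0.0
    return rf / denom


def rf_cdf_auc(
    values: Iterable[float], limit: float = DEFAULT_RF_LIMIT
) -> float:
    """Area under the empirical CDF of normalized RF distances on [0, limit).

    Exact step-function integration: each value v < limit contributes
    (limit - v) / n, so smaller RF distances (better concordance) are
    up-weighted and values at or beyond the limit contribute nothing.
    The maximum is ``limit`` itself (all distances zero).
    """
    vals = list(values)
    if not vals:
        raise ValidationError("empty RF sample")
    if limit <= 0:
        raise ValidationError("limit must be positive")
    for v in vals:
        if v < 0:
            raise ValidationError(f"negative RF value {v}")
    return sum(max(0.0, limit - v) for v in vals) / len(vals)


def functional_concordance(
    annot: AnnotationTable, ref_id: str, cand_id: str
) -> Concordance:
    """Do two sequences share the same top protein-family annotation?

    UNDEFINED when either sequence lacks a top hit — absence of annotation is
    not evidence of functional divergence.
    """
    ref_fam = annot.family_of(ref_id)
    cand_fam = annot.family_of(cand_id)
    if ref_fam is None or cand_fam is None:
        return Concordance.UNDEFINED
    return Concordance.CONCORDANT if ref_fam == cand_fam else Concordance.DISCORDANT


def pss_overlap(a: Iterable[tuple[str, int]], b: Iterable[tuple[str, int]]) -> float:
    """Jaccard overlap |a ∩ b| / |a ∪ b| between two sets of (gene, site)
    positively-selected positions.  Undefined (error) when both are empty."""
    set_a, set_b = set(a), set(b)
    union = set_a | set_b
    if not union:
        raise ValidationError("overlap undefined for two empty site sets")
    return len(set_a & set_b) / len(union)
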
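# Methods

## The problem

Ortholog detection (OD) methods — reciprocal-BLAST clustering, synteny-based
aligners, translated-search tools, tree/graph hybrids — frequently disagree,
and no single method dominates across species and genome qualities. This
package integrates the proposals of an arbitrary set of OD methods: for each
reference gene it pools every candidate sequence proposed for every species,
filters implausible candidates, and selects at most one sequence per species
so that a similarity objective over the selected cluster is maximized.

## The model

For one reference gene, candidates are nodes of a graph. Node `i` carries its
species, the proposing method, and its similarity to the reference sequence;
an edge `(i, j)` between nodes of different species carries their pairwise
similarity. Given a weight `w(s, t) ≥ 0` per unordered species pair, the
objective of a selection `C` (one node per species at most, reference always
included) is

    J(C) = Σ_{i<j ∈ C ∪ {ref}}  w(species_i, species_j) · sim(i, j)

Two weight schemes are built in. *Reference-only* puts unit weight on pairs
involving the reference species and zero elsewhere; the optimum then
decomposes per species into "keep the candidate most similar to the
reference", and candidate–candidate edges are never computed. *Uniform
pairwise* weights all cross-species pairs equally, which maximizes the summed
(equivalently average) pairwise similarity of the cluster; custom weight maps
are also accepted.

### Similarity

The default scorer is reference-denominated percent identity over a global
pairwise alignment: columns where the reference carries a gap are ignored; a
candidate gap opposite a reference residue is a mismatch; the score is
matches over reference sites considered. The canonical example —

    ref   A W V A - T F D
    cand  - W V R Y T F D

— scores 5/7 (≈ 71%): seven reference sites, mismatches at columns 1 (gap)
and 4 (A vs R), the reference-gap column ignored. The measure is asymmetric
by design; the pipeline always denominates in the configured reference
species. Any user callable mapping an aligned pair to [0, 1] can replace it
through the scorer registry. For candidate–candidate edges (only needed
under pairwise weights) the asymmetric score is symmetrized as the mean of
the two directions, since edges are unordered.

Pairwise alignment is global with BLOSUM62 and affine gap scoring (first gap
position −11, each extension −1, end gaps penalized like internal ones) —
standard protein-search parameters, configurable via `AlignParams`. Among
co-optimal alignments the aligner's first enumeration is used, which is
deterministic for fixed inputs and parameters; tests assert score-optimality
against exhaustive enumeration rather than one particular traceback.

### Filtering

Before optimization, candidates whose similarity to the reference falls below
a per-species cutoff are removed as putatively non-orthologous (gene loss,
annotation errors, highly diverged paralogs). The shipped default table is
primate-centred — chimp 0.82, gorilla 0.77, orangutan 0.75, rhesus macaque
0.73, all other species 0.70 — and fully overridable. A candidate exactly at
its cutoff is **retained** (≥ convention); the boundary is documented and
tested because only the strict-side rule ("below") is conventional. A species
whose candidates are all filtered is simply absent from the cluster: since
similarities are non-negative, including a surviving candidate can never
lower the objective, so absence is never offered as an optimizer move when
nodes exist.

### Optimization

With `m` methods and `s` species the selection space holds up to `m^s`
clusters (4 methods × 10 species ⇒ 1,048,576), so exhaustive search is
infeasible at proteome scale. The optimizer is cyclic coordinate descent
(CCD): start from a uniformly random candidate per species, then sweep the
species in a freshly drawn random order, replacing each species' choice with
the candidate that maximizes the objective given the others' current
choices. Only strict improvements are accepted, so the objective strictly
increases on every change and termination is guaranteed on the finite state
space — asserted, not timed out. Because CCD can stop in local optima under
pairwise weights, the whole procedure restarts from new random points
(default 20 restarts, configurable) and keeps the best solution.

Determinism: all randomness flows from one seeded generator; after
convergence a single canonicalization pass resolves exact ties by a
configured method-priority list, then lexicographic sequence id; equal-
objective solutions across restarts prefer the lexicographically smallest
selection. Fixed seed ⇒ bit-identical output.

Under reference-only weights CCD converges in one sweep to the per-species
argmax, which is also how the property tests cross-check it; under uniform
pairwise weights, best-of-20-restarts is verified to attain the
exhaustive-enumeration optimum on instances small enough to enumerate.

## Quality metrics

* **Head-to-head wins** — method A beats method B on an ortholog when its
  percent identity is at least five percentage points higher (margin
  configurable); anything closer is a tie. The margin comparison tolerates
  1e-12 of float noise so that a lead of exactly 0.05 counts as a win.
* **Tree concordance** — normalized unweighted Robinson–Foulds distance:
  both trees are treated as unrooted, pruned to their shared leaves (≥ 4
  required), and the count of nontrivial splits present in exactly one tree
  is divided by the total nontrivial split count of both. Trivial
  (single-leaf) splits are not counted. Distributions are summarized by the
  area under the empirical CDF on [0, 0.4): each distance `v < 0.4`
  contributes `(0.4 − v)/n`, which up-weights small distances; values at or
  beyond the limit contribute nothing, and the maximum is 0.4 itself. Two
  shared-leaf star trees (denominator zero) are defined as distance 0.
* **Functional concordance** — binary agreement of top protein-family
  annotations; undefined when either sequence lacks a top hit, since absence
  of annotation is not evidence of divergence.
* **PSS overlap** — Jaccard index |A∩B|/|A∪B| over sets of (gene, site)
  positively selected positions; undefined (error) when both sets are empty.

## Selection-analysis post-filters

These operate on externally computed tables (sitewise dN/dS with
confidences, codon-model fits); the likelihood machinery itself is out of
scope.

* **Confidence masking** keeps MSA columns aligned with confidence ≥ 0.95
  (threshold configurable) and maps kept columns to 1-based ungapped
  reference coordinates; kept columns where the reference is gapped have no
  reference coordinate.
* **PSS calling** includes a site iff it is flagged positively selected,
  its confidence is ≥ 0.95, and (when a mask is supplied) it maps to a kept
  column. Raising either threshold can only shrink the called set.
* **dN/dS outlier exclusion** drops genes with ω > 3, guarding averages
  against rare fits that place extreme selection on a handful of sites.
* **AIC model selection** minimizes 2k − 2 lnL; ties prefer fewer
  parameters, then model name, so the choice is order-independent.
* **Species matching** restricts two alignments to their shared species for
  like-for-like evolutionary comparisons.

All keep/drop boundaries are inclusive on the keep side (keep at confidence
= 0.95, keep at ω = 3.0, keep at identity = cutoff), stated explicitly
because only one side of each rule is conventional.

## Synthetic families

The simulator exists to make every pipeline stage testable without any
genomic download. For one gene it draws a uniformly random reference protein
(default 150 residues), then per species a *true ortholog* by i.i.d.
per-site substitution at that species' divergence (substituted residues drawn
uniformly from the 19 alternatives) and a *decoy paralog* generated the same
way at divergence + 0.15, emulating an in-paralog that duplicated and
diverged further. Each of four mock methods independently reports the true
ortholog, the decoy (probability 0.3), or nothing (probability 0.2). The
default species panel mirrors a primate-centred mammalian study: chimp 0.01,
gorilla 0.02, orangutan 0.03, rhesus macaque 0.05, marmoset 0.08, bushbaby
0.12, cat 0.15, cow 0.16, horse 0.17 expected substitutions per site versus
the human reference — chosen so that expected identities sit above the
default cutoffs while spanning the panel's divergence range.

Recovery is scored over eligible slots: (gene, species) pairs where at least
one method proposed the true ortholog and it survived the cutoffs; the rate
is the fraction of those slots where integration selected it. Note that
eligible slots include uncontested ones (no method proposed the decoy), so
with statistically identical decoys the rate sits above 1/2; the fair-coin
symmetry only appears when conditioning on slots where both sequences
compete, which is how the tests probe it.

What the simulator deliberately omits: indels (alignments of simulated pairs
are gapless, so the alignment path is exercised by separate unit tests, not
by recovery experiments), site-rate heterogeneity, realistic substitution
preferences (no BLOSUM-like bias), and correlated errors between methods.
Passing recovery tests therefore demonstrate the selection machinery under
clean signal-to-noise separation, not performance on real proteomes.

## Problem sizes in the test suite

Optimizer-vs-enumeration checks run on 100 random instances of up to
4 species × 3 methods (≤ 81 clusters each, enumerable exactly). Tree-metric
checks enumerate all 105 pairs of the 15 unrooted binary 5-leaf topologies
against direct split arithmetic. The recovery experiment uses 200 simulated
families over the nine-species panel (~5,000 pairwise alignments), which
completes in well under a minute on one CPU.

## Known limitations

* Percent identity is a weak similarity measure for distant homologs; the
  scorer registry accepts substitution-matrix or profile-based alternatives,
  but none is shipped beyond percent identity.
* The sum-form objective never benefits from dropping a surviving candidate;
  a normalized (per-pair averaged) objective could, and is not implemented.
* Gene loss, duplication histories, horizontal transfer and incomplete
  lineage sorting are not modelled; the cutoff filter is the only guard
  against non-orthologous candidates.
* RF concordance on single genes can reflect true gene-tree/species-tree
  discordance rather than OD error; it is meaningful in aggregate.
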
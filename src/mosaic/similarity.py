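"""Pairwise alignment and similarity scoring against a reference sequence.

The default similarity measure is reference-denominated percent identity:
the fraction of reference residues whose aligned partner is the identical
residue.  Columns where the reference carries a gap (a deletion in the
reference, or an insertion in the other lineage) are ignored; a gap in the
candidate opposite a reference residue counts as a mismatch.  The measure is
therefore asymmetric — it is always denominated in the reference sequence.

Any callable mapping an :class:`AlignedPair` to a score in [0, 1] can be used
in its place; scorers are looked up by name through a small registry
(``"perID"`` is the default entry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .exceptions import NoScorableSitesError, ValidationError
from .io import MsaWithConfidence, SequenceRecord

GAP = "-"


@dataclass(frozen=True)
class AlignedPair:
    """A reference sequence globally aligned to one candidate."""

    ref_aln: str
    cand_aln: str

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.cand_aln):
            raise ValidationError(
                f"aligned lengths differ: {len(self.ref_aln)} vs {len(self.cand_aln)}"
            )
        if not self.ref_aln:
            raise ValidationError("empty alignment")
        for i, (r, c) in enumerate(zip(self.ref_aln, self.cand_aln)):
            if r == GAP and c == GAP:
                raise ValidationError(f"gap-vs-gap column at position {i + 1}")


@dataclass(frozen=True)
class SimilarityScore:
    """A similarity in [0, 1] plus the number of reference residues scored."""

    value: float
    n_ref_sites: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValidationError(f"similarity {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment parameters: substitution matrix plus affine gaps.

    ``open_gap`` is the score of the first gap position and ``extend_gap`` of
    each subsequent one, so a gap of length L scores
    ``open_gap + (L - 1) * extend_gap``.  End gaps are penalized like internal
    ones.  Defaults follow common protein-search practice (BLOSUM62, -11/-1).
    """

    matrix: str = "BLOSUM62"
    open_gap: float = -11.0
    extend_gap: float = -1.0


def percent_identity(pair: AlignedPair) -> SimilarityScore:
    """Reference-denominated percent identity of an aligned pair.

    Ignores columns where the reference has a gap; a candidate gap opposite a
    reference residue is a mismatch.  Raises
    :class:`~mosaic.exceptions.NoScorableSitesError` when the reference
    contributes no residues.
    """
    matches = 0
    n_sites = 0
    for r, c in zip(pair.ref_aln, pair.cand_aln):
        if r == GAP:
            continue
        n_sites += 1
        if r == c:
            matches += 1
    if n_sites == 0:
        raise NoScorableSitesError("reference contributes no residues")
    return SimilarityScore(matches / n_sites, n_sites)


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.open_gap
    aligner.extend_gap_score = params.extend_gap
    return aligner


def align_pair(
    ref: SequenceRecord,
    cand: SequenceRecord,
    params: AlignParams | None = None,
) -> AlignedPair:
    """Globally align a candidate to the reference sequence.

    The alignment is score-optimal under ``params``.  Among co-optimal
    alignments the first one in the aligner's deterministic enumeration order
    is taken, so results are reproducible for fixed parameters.
    """
    if not ref.residues or not cand.residues:
        raise ValidationError("cannot align empty sequences")
    params = params or AlignParams()
    alignment = _make_aligner(params).align(ref.residues, cand.residues)[0]
    return AlignedPair(str(alignment[0]), str(alignment[1]))


def msa_percent_identity(
    msa: MsaWithConfidence, ref_species: str, other_species: str
) -> SimilarityScore:
    """Percent identity between two rows of an existing MSA.

    Applies the same column rule as :func:`percent_identity` to the rows as
    already aligned in the MSA — no pairwise realignment is performed, so the
    value reflects the quality of the joint alignment itself.
    """
    for sp in (ref_species, other_species):
        if sp not in msa.rows:
            raise ValidationError(f"species {sp!r} not present in MSA")
    ref_row = msa.rows[ref_species]
    cand_row = msa.rows[other_species]
    matches = 0
    n_sites = 0
    for r, c in zip(ref_row, cand_row):
        if r == GAP:
            continue
        n_sites += 1
        if r == c:
            matches += 1
    if n_sites == 0:
        raise NoScorableSitesError(f"row {ref_species!r} is all gaps")
    return SimilarityScore(matches / n_sites, n_sites)


# ---------------------------------------------------------------------------
# Scorer registry
# ---------------------------------------------------------------------------

Scorer = Callable[[AlignedPair], Union[SimilarityScore, float]]

_SCORERS: dict[str, Scorer] = {"perID": percent_identity}


def register_scorer(name: str, fn: Scorer) -> None:
    """Register a user-defined scorer (any ``AlignedPair -> [0, 1]`` callable)."""
    _SCORERS[name] = fn


def get_scorer(name: str) -> Scorer:
    try:
        return _SCORERS[name]
    except KeyError:
        raise KeyError(
            f"unknown scorer {name!r}; registered: {sorted(_SCORERS)}"
        ) from None


def score_value(scorer: Scorer, pair: AlignedPair) -> float:
    """Apply a scorer and coerce its result to a validated float in [0, 1]."""
    result = scorer(pair)
    value = float(result)
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"scorer returned {value}, outside [0, 1]")
    return value
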
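"""Readers and writers for the external formats the toolkit touches.

All parsers validate strictly and raise :class:`~mosaic.exceptions.ParseError`
or :class:`~mosaic.exceptions.ValidationError` rather than silently repairing
malformed input.  Write-then-read round-trips the in-memory objects exactly.

Conventions
-----------
* FASTA headers are pipe-delimited: ``>seq_id|species|method``.
* Proposal tables are TSV with columns ``ref_gene, species, method, seq_id``.
* Alignment-confidence sidecars hold one value per line, one line per MSA
  column (``#`` comments and blank lines ignored).
* MSA columns and site indices are 1-based; site indices count ungapped
  residues of the reference row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .exceptions import ParseError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

_PROPOSAL_COLUMNS = ["ref_gene", "species", "method", "seq_id"]
_SITE_COLUMNS = ["gene", "site", "omega", "confidence", "positively_selected"]


@dataclass(frozen=True)
class SequenceRecord:
    """One candidate (or reference) protein sequence.

    Residues are one-letter amino-acid codes (the 20 standard residues plus
    ``X`` for ambiguity); gap characters are forbidden — gaps only exist in
    alignments, never in sequence records.
    """

    seq_id: str
    species: str
    method: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"{self.seq_id}: empty residue string")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"{self.seq_id}: illegal residue character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProposalSet:
    """All candidate orthologs proposed for one reference gene.

    ``candidates`` is keyed by ``(species, method)``; the reference species
    never appears among the keys.
    """

    ref_gene: str
    ref_seq: SequenceRecord
    candidates: Mapping[tuple[str, str], SequenceRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for species, method in self.candidates:
            if species == self.ref_seq.species:
                raise ValidationError(
                    f"{self.ref_gene}: reference species {species!r} listed "
                    f"as a candidate (method {method!r})"
                )

    @property
    def species(self) -> list[str]:
        """Candidate species, in first-appearance order."""
        seen: dict[str, None] = {}
        for sp, _ in self.candidates:
            seen.setdefault(sp)
        return list(seen)

    @property
    def methods(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, m in self.candidates:
            seen.setdefault(m)
        return list(seen)


@dataclass(frozen=True)
class MsaWithConfidence:
    """A multiple sequence alignment plus per-column confidence values.

    ``rows`` maps species label to the aligned string (residues and ``-``);
    ``col_conf`` holds one confidence in [0, 1] per column.
    """

    rows: Mapping[str, str]
    col_conf: tuple[float, ...]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValidationError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.rows and lengths and next(iter(lengths)) != len(self.col_conf):
            raise ValidationError(
                f"confidence length {len(self.col_conf)} != alignment "
                f"length {next(iter(lengths))}"
            )
        for c in self.col_conf:
            if not (0.0 <= c <= 1.0) or math.isnan(c):
                raise ValidationError(f"confidence {c} outside [0, 1]")

    @property
    def n_columns(self) -> int:
        return len(self.col_conf)


@dataclass(frozen=True)
class AnnotationTable:
    """Top protein-family hit per sequence; sequences without a hit are absent."""

    entries: Mapping[str, str]

    def family_of(self, seq_id: str) -> str | None:
        return self.entries.get(seq_id)


@dataclass(frozen=True)
class SiteRow:
    """Per-site selection estimate for one reference residue."""

    gene: str
    site: int
    omega: float
    confidence: float
    positively_selected: bool

    def __post_init__(self) -> None:
        if self.site < 1:
            raise ValidationError(f"{self.gene}: site index {self.site} < 1")
        if self.omega < 0:
            raise ValidationError(f"{self.gene}:{self.site}: omega {self.omega} < 0")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"{self.gene}:{self.site}: confidence {self.confidence} outside [0, 1]"
            )


@dataclass(frozen=True)
class SiteTable:
    """Site-level selection estimates, one row per (gene, site)."""

    rows: tuple[SiteRow, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for row in self.rows:
            key = (row.gene, row.site)
            if key in seen:
                raise ValidationError(f"duplicate site row {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a pipe-dialect FASTA file (``>seq_id|species|method``).

    Returns records in file order, residues uppercased.  Raises
    :class:`ParseError` for a malformed header (naming the line) and
    :class:`ValidationError` for illegal residues or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen_ids: set[str] = set()
    header: tuple[int, str] | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        lineno, text = header
        fields = text.split("|")
        if len(fields) != 3 or not all(f.strip() for f in fields):
            raise ParseError(
                f"{path}:{lineno}: header '>{text}' is not 'seq_id|species|method'"
            )
        seq_id, species, method = (f.strip() for f in fields)
        if seq_id in seen_ids:
            raise ValidationError(f"{path}: duplicate sequence id {seq_id!r}")
        seen_ids.add(seq_id)
        records.append(
            SequenceRecord(seq_id, species, method, "".join(chunks).upper())
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = (lineno, line[1:].strip())
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before header")
                chunks.append(line)
        _flush()
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}|{rec.species}|{rec.method}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# Proposal tables
# ---------------------------------------------------------------------------

def read_proposals(
    tsv_path: str | Path,
    fasta_paths: Sequence[str | Path],
    reference_species: str,
) -> list[ProposalSet]:
    """Read a normalized proposal table plus the FASTA sources it references.

    The table has columns ``ref_gene, species, method, seq_id`` exactly.  Rows
    are grouped by ``ref_gene``; the reference sequence is the single row whose
    species equals ``reference_species``.  Every ``seq_id`` must resolve in the
    FASTA sources.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if list(df.columns) != _PROPOSAL_COLUMNS:
        raise ParseError(
            f"{tsv_path}: expected columns {_PROPOSAL_COLUMNS}, got {list(df.columns)}"
        )

    index: dict[str, SequenceRecord] = {}
    for fp in fasta_paths:
        for rec in read_fasta(fp):
            prev = index.get(rec.seq_id)
            if prev is not None and prev.residues != rec.residues:
                raise ValidationError(
                    f"sequence id {rec.seq_id!r} appears in multiple FASTA "
                    "sources with different residues"
                )
            index[rec.seq_id] = rec

    missing = sorted(set(df["seq_id"]) - set(index))
    if missing:
        raise ValidationError(f"{tsv_path}: unresolvable seq_id(s): {missing}")

    psets: list[ProposalSet] = []
    for gene, sub in df.groupby("ref_gene", sort=False):
        ref_rows = sub[sub["species"] == reference_species]
        if len(ref_rows) == 0:
            raise ValidationError(f"{gene}: no row for reference species {reference_species!r}")
        if len(ref_rows) > 1:
            raise ValidationError(f"{gene}: multiple rows for reference species")
        ref_row = ref_rows.iloc[0]
        src = index[ref_row["seq_id"]]
        ref_seq = SequenceRecord(
            src.seq_id, reference_species, ref_row["method"], src.residues
        )
        candidates: dict[tuple[str, str], SequenceRecord] = {}
        for _, row in sub[sub["species"] != reference_species].iterrows():
            key = (row["species"], row["method"])
            if key in candidates:
                raise ValidationError(f"{gene}: duplicate proposal for {key}")
            src = index[row["seq_id"]]
            candidates[key] = SequenceRecord(
                src.seq_id, row["species"], row["method"], src.residues
            )
        psets.append(ProposalSet(str(gene), ref_seq, candidates))
    return psets


def write_proposals(psets: Sequence[ProposalSet], tsv_path: str | Path) -> None:
    rows = []
    for pset in psets:
        ref = pset.ref_seq
        rows.append((pset.ref_gene, ref.species, ref.method, ref.seq_id))
        for (species, method), rec in pset.candidates.items():
            rows.append((pset.ref_gene, species, method, rec.seq_id))
    pd.DataFrame(rows, columns=_PROPOSAL_COLUMNS).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MSA + confidence sidecar
# ---------------------------------------------------------------------------

def read_msa_with_confidence(
    aln_path: str | Path, conf_path: str | Path
) -> MsaWithConfidence:
    """Read an aligned FASTA (headers = species labels) plus a confidence
    sidecar with one value per alignment column."""
    rows: dict[str, str] = {}
    species = None
    chunks: list[str] = []
    with open(aln_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if species is not None:
                    rows[species] = "".join(chunks)
                species = line[1:].split("|")[0].strip()
                if not species:
                    raise ParseError(f"{aln_path}:{lineno}: empty species label")
                if species in rows:
                    raise ValidationError(f"{aln_path}: duplicate species {species!r}")
                chunks = []
            else:
                if species is None:
                    raise ParseError(f"{aln_path}:{lineno}: data before header")
                chunks.append(line.upper())
        if species is not None:
            rows[species] = "".join(chunks)

    conf: list[float] = []
    with open(conf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                conf.append(float(line))
            except ValueError as exc:
                raise ParseError(f"{conf_path}:{lineno}: not a number: {line!r}") from exc
    return MsaWithConfidence(rows, tuple(conf))


def write_msa_with_confidence(
    msa: MsaWithConfidence, aln_path: str | Path, conf_path: str | Path
) -> None:
    with open(aln_path, "w") as fh:
        for species, aligned in msa.rows.items():
            fh.write(f">{species}\n{aligned}\n")
    with open(conf_path, "w") as fh:
        for c in msa.col_conf:
            fh.write(f"{c:.6g}\n")


# ---------------------------------------------------------------------------
# Trees, site tables, annotations
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read one Newick tree; leaf labels are species names and must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises assorted error types
        if "duplicate" in str(exc).lower():
            raise ValidationError(f"{path}: duplicate leaf labels: {exc}") from exc
        raise ParseError(f"{path}: not parseable as Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"{path}: duplicate leaf label(s) {dup}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_site_table(path: str | Path) -> SiteTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    rows = tuple(
        SiteRow(
            gene=str(r.gene),
            site=int(r.site),
            omega=float(r.omega),
            confidence=float(r.confidence),
            positively_selected=_parse_bool(r.positively_selected),
        )
        for r in df.itertuples()
    )
    return SiteTable(rows)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.gene, r.site, r.omega, r.confidence, str(r.positively_selected).lower())
            for r in table
        ],
        columns=_SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ParseError(f"not a boolean: {value!r}")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a TSV of ``seq_id, family``; blank family means no top hit."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("seq_id", "family"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column(s) ['{col}']")
    entries: dict[str, str] = {}
    seen: set[str] = set()
    for r in df.itertuples():
        if r.seq_id in seen:
            raise ValidationError(f"{path}: duplicate seq_id {r.seq_id!r}")
        seen.add(r.seq_id)
        if r.family.strip():
            entries[r.seq_id] = r.family.strip()
    return AnnotationTable(entries)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.entries.items()), columns=["seq_id", "family"]
    ).to_csv(path, sep="\t", index=False)
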
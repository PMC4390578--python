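"""Post-processing around site- and gene-level selection estimates.

These are the filtering and model-selection rules applied to externally
computed evolutionary estimates (sitewise dN/dS tables, codon-model fits):
masking poorly aligned MSA columns, calling positively selected sites (PSS)
at a confidence threshold, excluding implausible dN/dS outliers, and AIC
model selection.  The likelihood fitting itself is out of scope — only its
tabulated outputs are consumed.

Boundary conventions are inclusive on the keep side throughout: a column at
exactly the confidence threshold is kept, a site at exactly the PSS
confidence threshold is called, and a gene at exactly the dN/dS cap is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .exceptions import ValidationError
from .io import MsaWithConfidence, SiteTable

#: Columns aligned to less than this confidence are masked.
DEFAULT_CONF_THRESHOLD = 0.95

#: dN/dS estimates greater than this cap are treated as outliers.
DEFAULT_DNDS_CAP = 3.0


@dataclass(frozen=True)
class ModelFit:
    """One fitted evolutionary model: its log-likelihood and parameter count."""

    model_name: str
    log_likelihood: float
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"{self.model_name}: k must be >= 1, got {self.k}")

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.log_likelihood


@dataclass(frozen=True)
class GeneDnds:
    """Gene-level dN/dS estimate."""

    gene: str
    omega: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValidationError(f"{self.gene}: omega {self.omega} < 0")


@dataclass(frozen=True)
class MaskResult:
    """Outcome of confidence masking: kept MSA columns (1-based) and their
    mapping to ungapped reference sites."""

    kept_columns: frozenset[int]
    ref_site_map: Mapping[int, int]  # kept column -> 1-based ungapped ref site

    @property
    def kept_ref_sites(self) -> frozenset[int]:
        return frozenset(self.ref_site_map.values())


def mask_low_confidence(
    msa: MsaWithConfidence,
    ref_species: str,
    threshold: float = DEFAULT_CONF_THRESHOLD,
) -> MaskResult:
    """Keep columns aligned with confidence >= threshold.

    Returns the kept column indices (1-based) together with the induced map
    from kept columns to 1-based ungapped reference coordinates (columns where
    the reference row has a gap appear in ``kept_columns`` but not in the site
    map — they have no reference coordinate).
    """
    if ref_species not in msa.rows:
        raise ValidationError(f"reference species {ref_species!r} not in MSA")
    ref_row = msa.rows[ref_species]
    kept: set[int] = set()
    site_map: dict[int, int] = {}
    ref_site = 0
    for col0, (res, conf) in enumerate(zip(ref_row, msa.col_conf)):
        col = col0 + 1
        has_residue = res != "-"
        if has_residue:
            ref_site += 1
        if conf >= threshold:
            kept.add(col)
            if has_residue:
                site_map[col] = ref_site
    return MaskResult(frozenset(kept), site_map)


def call_pss(
    table: SiteTable,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    kept_sites: Mapping[str, Iterable[int]] | Iterable[int] | None = None,
) -> set[tuple[str, int]]:
    """Call positively selected sites from a sitewise selection table.

    A (gene, site) pair is called iff the row is flagged positively selected,
    its confidence is >= ``conf_threshold``, and — when an alignment mask is
    supplied — the site maps to a confidently aligned column.  ``kept_sites``
    may be a per-gene mapping of kept reference sites, a single site set
    applied to every gene, or None for no alignment mask.
    """
    per_gene: Mapping[str, set[int]] | None
    flat: set[int] | None
    if kept_sites is None:
        per_gene = flat = None
    elif isinstance(kept_sites, Mapping):
        per_gene = {g: set(s) for g, s in kept_sites.items()}
        flat = None
    else:
        per_gene = None
        flat = set(kept_sites)

    called: set[tuple[str, int]] = set()
    for row in table:
        if not row.positively_selected or row.confidence < conf_threshold:
            continue
        if per_gene is not None and row.site not in per_gene.get(row.gene, set()):
            continue
        if flat is not None and row.site not in flat:
            continue
        called.add((row.gene, row.site))
    return called


def exclude_dnds_outliers(
    values: Sequence[GeneDnds], cap: float = DEFAULT_DNDS_CAP
) -> list[GeneDnds]:
    """Drop genes with dN/dS greater than the cap; values at the cap are kept.

    Guards summaries against rare fits where selection over a handful of
    sites inflates the gene-wide average.
    """
    return [v for v in values if v.omega <= cap]


def aic_select(fits: Sequence[ModelFit]) -> ModelFit:
    """Return the fit minimizing AIC = 2k - 2 lnL.

    Ties prefer the model with fewer parameters; an exact tie on both is
    broken by model name so the choice is independent of input order.
    """
    if not fits:
        raise ValidationError("no model fits to select from")
    return min(fits, key=lambda f: (f.aic, f.k, f.model_name))


def matched_species(
    msa_a: MsaWithConfidence, msa_b: MsaWithConfidence
) -> tuple[MsaWithConfidence, MsaWithConfidence]:
    """Restrict two alignments to their shared species.

    Used for like-for-like evolutionary comparisons where differing species
    composition would otherwise confound rate estimates.  Rows are subset;
    columns (and their confidences) are left untouched.
    """
    shared = set(msa_a.rows) & set(msa_b.rows)
    if not shared:
        raise ValidationError("alignments share no species")
    sub_a = MsaWithConfidence(
        {sp: s for sp, s in msa_a.rows.items() if sp in shared}, msa_a.col_conf
    )
    sub_b = MsaWithConfidence(
        {sp: s for sp, s in msa_b.rows.items() if sp in shared}, msa_b.col_conf
    )
    return sub_a, sub_b
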
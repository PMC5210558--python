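"""Curation-import pipelines: phospho-site filtering, histone-table
conversion, and pathway-participant mapping with coverage statistics.

Three workflows that feed externally curated or text-mined PTM evidence
into proteoform terms:

* :func:`iptmnet_filter` — keep only single-site phosphorylation evidence
  corroborated by at least two sources, whose abstracts do not muddy the
  single-site reading, and which is not already curated.
* :func:`histome_convert` — turn rows of (accession, modification type,
  residue, position, PMID) into unreviewed term stanzas, one per distinct
  canonical proteoform, merging evidence for duplicate sites.
* :func:`reactome_map` — normalize pathway-participant descriptors into
  canonical notation and map them against an existing term index by exact
  string match, reporting per-pathway coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .config import ModTypeLookup, UnmappedModificationType, load_mod_type_lookup
from .converters import (
    FeatureLookupError,
    FeatureTable,
    ReactomeDescriptor,
    from_feature_id,
    from_reactome,
)
from .notation import (
    ModBlock,
    ModSite,
    ProteoformRecord,
    SeqBlock,
    canonical_string,
    canonicalize,
)
from .term_factory import TermFactory, TermStanza

__all__ = [
    "PtmEvidenceRow",
    "FilterResult",
    "RejectReason",
    "iptmnet_filter",
    "HistomeRow",
    "HistomeResult",
    "histome_convert",
    "ExternalParticipant",
    "MappingResult",
    "reactome_map",
    "coverage_report",
    "CoverageSummary",
]


# ---------------------------------------------------------------------------
# single-site phosphorylation filter

@dataclass(frozen=True)
class PtmEvidenceRow:
    """One substrate-site evidence row in the integrated-PTM-table shape.

    ``abstract_flags`` come from upstream text mining: whether the source
    abstract mentions additional modification sites, or PTM types other
    than phosphorylation (e.g. acetylation) — either disqualifies the row
    from the automated single-site workflow.
    """

    accession: str
    residue: str
    position: int
    ptm_type: str
    sources: frozenset[str]
    pmids: tuple[str, ...] = ()
    isoform: Optional[int] = None
    mentions_multiple_sites: bool = False
    mentions_other_ptm_types: bool = False

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.sources:
            raise ValueError("row must cite >= 1 source")
        object.__setattr__(self, "sources", frozenset(self.sources))
        object.__setattr__(self, "pmids", tuple(self.pmids))

    def record(self, lookup: ModTypeLookup) -> ProteoformRecord:
        """Canonical single-site record asserted by this row."""
        mod_id = lookup.mod_id(self.ptm_type, self.residue)
        return canonicalize(
            ProteoformRecord(
                SeqBlock(self.accession, isoform=self.isoform),
                (ModBlock((ModSite(self.residue, self.position),), mod_id),),
            )
        )


#: Reject reasons, checked in this priority order so that they partition
#: the removed rows.
class RejectReason:
    NOT_PHOSPHORYLATION = "not-phosphorylation"
    SINGLE_SOURCE = "single-source"
    ABSTRACT_FLAGGED = "abstract-flagged"
    ALREADY_CURATED = "already-curated"

    ALL = (NOT_PHOSPHORYLATION, SINGLE_SOURCE, ABSTRACT_FLAGGED, ALREADY_CURATED)


@dataclass(frozen=True)
class FilterResult:
    survivors: tuple[PtmEvidenceRow, ...]
    rejected: tuple[tuple[PtmEvidenceRow, str], ...]  # (row, reason)


def iptmnet_filter(
    rows: Sequence[PtmEvidenceRow],
    curated: Iterable[str],
    lookup: Optional[ModTypeLookup] = None,
) -> FilterResult:
    """Select rows eligible for automated single-site phosphoform creation.

    A row survives iff its PTM type is phosphorylation, it is described by
    at least two distinct sources, neither abstract flag is set, and its
    canonical single-site record is not already among the ``curated``
    canonical strings.  Output order is input order (stable); the filter
    is idempotent.
    """
    lookup = lookup or load_mod_type_lookup()
    curated = set(curated)
    survivors: list[PtmEvidenceRow] = []
    rejected: list[tuple[PtmEvidenceRow, str]] = []
    for row in rows:
        if row.ptm_type.lower() != "phosphorylation":
            rejected.append((row, RejectReason.NOT_PHOSPHORYLATION))
        elif len(row.sources) < 2:
            rejected.append((row, RejectReason.SINGLE_SOURCE))
        elif row.mentions_multiple_sites or row.mentions_other_ptm_types:
            rejected.append((row, RejectReason.ABSTRACT_FLAGGED))
        elif canonical_string(row.record(lookup)) in curated:
            rejected.append((row, RejectReason.ALREADY_CURATED))
        else:
            survivors.append(row)
    return FilterResult(tuple(survivors), tuple(rejected))


# ---------------------------------------------------------------------------
# histone-modification table conversion

@dataclass(frozen=True)
class HistomeRow:
    """Minimum information for one histone-modification term: accession
    (+ isoform if known), modification type, modified residue, position,
    and a PubMed evidence reference."""

    accession: str
    mod_type: str
    residue: str
    position: int
    pmid: str
    isoform: Optional[int] = None


@dataclass(frozen=True)
class HistomeResult:
    stanzas: tuple[TermStanza, ...]
    rejected: tuple[tuple[HistomeRow, str], ...]  # (row, reason message)


def histome_convert(
    rows: Sequence[HistomeRow],
    lookup: Optional[ModTypeLookup] = None,
    factory: Optional[TermFactory] = None,
) -> HistomeResult:
    """One unreviewed stanza per distinct canonical record among the rows.

    Each stanza asserts at least one modification with a known position on
    the molecule.  Rows for the same site with different PMIDs merge into
    one stanza carrying all evidence xrefs.  Rows whose modification type
    has no PSI-MOD mapping are rejected with a report, never silently
    dropped.
    """
    lookup = lookup or load_mod_type_lookup()
    factory = factory or TermFactory()
    rejected: list[tuple[HistomeRow, str]] = []
    by_record: dict[str, tuple[ProteoformRecord, list[str]]] = {}
    for row in rows:
        for name, value in (
            ("accession", row.accession), ("mod_type", row.mod_type),
            ("residue", row.residue), ("pmid", row.pmid),
        ):
            if not value:
                rejected.append((row, f"missing {name}"))
                break
        else:
            try:
                mod_id = lookup.mod_id(row.mod_type, row.residue)
            except UnmappedModificationType as exc:
                rejected.append((row, str(exc)))
                continue
            try:
                rec = canonicalize(
                    ProteoformRecord(
                        SeqBlock(row.accession, isoform=row.isoform),
                        (ModBlock((ModSite(row.residue, row.position),), mod_id),),
                    )
                )
            except ValueError as exc:
                rejected.append((row, str(exc)))
                continue
            key = canonical_string(rec)
            _, pmids = by_record.setdefault(key, (rec, []))
            if row.pmid not in pmids:
                pmids.append(row.pmid)
    stanzas = tuple(
        factory.make_proteoform_term(rec, evidence=pmids, source="HIstome")
        for rec, pmids in by_record.values()
    )
    return HistomeResult(stanzas, tuple(rejected))


# ---------------------------------------------------------------------------
# pathway-participant mapping

@dataclass(frozen=True)
class ExternalParticipant:
    """One pathway participant to normalize: either a Reactome-style
    descriptor or a feature-identifier token, tagged with its pathway."""

    pathway_id: str
    external_id: str
    descriptor: Union[ReactomeDescriptor, str]


@dataclass(frozen=True)
class MappingPair:
    external_id: str
    pathway_id: str
    canonical: Optional[str]  # None when normalization failed
    pro_id: Optional[str]     # None when unmatched
    status: str               # "mapped" | "unmapped" | "unresolved"


@dataclass(frozen=True)
class MappingResult:
    pairs: tuple[MappingPair, ...]
    coverage: Mapping[str, float]            # pathway -> mapped/total
    totals: Mapping[str, tuple[int, int]]    # pathway -> (mapped, total)

    def unmatched(self) -> list[MappingPair]:
        return [p for p in self.pairs if p.status != "mapped"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.external_id, p.pathway_id, p.canonical, p.pro_id, p.status)
             for p in self.pairs],
            columns=["external_id", "pathway_id", "canonical", "pro_id", "status"],
        )


def reactome_map(
    externals: Sequence[ExternalParticipant],
    pro_terms: Mapping[str, str],
    table: Optional[FeatureTable] = None,
) -> MappingResult:
    """Map external participants onto existing terms by exact string match.

    Each participant is normalized to its canonical notation string via
    the converters, then looked up in ``pro_terms`` (canonical string ->
    term id).  Unmatched participants are listed for term creation;
    unresolvable feature identifiers are reported, not fatal.  Coverage
    per pathway is mapped/total, exactly.
    """
    pairs: list[MappingPair] = []
    for ext in externals:
        canonical: Optional[str] = None
        try:
            if isinstance(ext.descriptor, ReactomeDescriptor):
                rec = from_reactome(ext.descriptor)
            else:
                if table is None:
                    raise FeatureLookupError("no feature table supplied")
                rec = from_feature_id(ext.descriptor, table)
            canonical = canonical_string(rec)
        except (FeatureLookupError, ValueError):
            pairs.append(
                MappingPair(ext.external_id, ext.pathway_id, None, None, "unresolved")
            )
            continue
        pro_id = pro_terms.get(canonical)
        status = "mapped" if pro_id is not None else "unmapped"
        pairs.append(
            MappingPair(ext.external_id, ext.pathway_id, canonical, pro_id, status)
        )

    totals: dict[str, tuple[int, int]] = {}
    for p in pairs:
        mapped, total = totals.get(p.pathway_id, (0, 0))
        totals[p.pathway_id] = (mapped + (p.status == "mapped"), total + 1)
    coverage = {pw: m / t for pw, (m, t) in totals.items()}
    return MappingResult(tuple(pairs), coverage, totals)


@dataclass(frozen=True)
class CoverageSummary:
    n_pathways: int
    n_full: int            # pathways at 100% coverage
    n_at_threshold: int    # pathways at >= threshold coverage
    threshold: float
    table: pd.DataFrame    # pathway_id, mapped, total, fraction
    warnings: tuple[str, ...] = ()


def coverage_report(result: MappingResult, threshold: float = 0.7) -> CoverageSummary:
    """Count pathways at full and at >= ``threshold`` coverage.

    Empty pathways (zero participants) cannot occur in a
    :class:`MappingResult` built by :func:`reactome_map`, but are excluded
    with a warning if present in hand-built input.
    """
    warnings = []
    rows = []
    n_full = n_at = 0
    for pw in sorted(result.totals):
        mapped, total = result.totals[pw]
        if total == 0:
            warnings.append(f"pathway {pw} has no participants; excluded")
            continue
        frac = mapped / total
        rows.append((pw, mapped, total, frac))
        n_full += frac == 1.0
        n_at += frac >= threshold
    table = pd.DataFrame(rows, columns=["pathway_id", "mapped", "total", "fraction"])
    return CoverageSummary(len(rows), n_full, n_at, threshold, table, tuple(warnings))
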
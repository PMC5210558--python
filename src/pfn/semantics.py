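"""Equality, subsumption, specificity levels and light-weight classification.

Proteoform classes form a specificity hierarchy: an accession alone names
every product of a gene in an organism (*organism-gene level*); adding an
isoform narrows to one transcript's product (*organism-sequence level*);
adding a subsequence range and/or modification blocks narrows to a
processed or modified form (*organism-modification level*).

Modification semantics are "at least these sites": a record asserts that
the named sites are modified and stays silent about other positions, so a
record with fewer asserted sites is the more general class.  Range
subsumption requires *equality* of ranges, not containment — a deliberate
under-approximation (nested cleavage products are not inferred to be
related).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import networkx as nx

from .notation import (
    ProteoformRecord,
    canonical_string,
    canonicalize,
    strip_isoform,
    strip_mods,
    strip_range,
)

__all__ = [
    "LevelLabel",
    "equals",
    "subsumes",
    "assign_level",
    "infer_parents",
    "InferenceResult",
    "build_hierarchy",
    "DEFAULT_PHOSPHO_MOD_IDS",
]

#: PSI-MOD ids for phosphorylated Ser / Thr / Tyr residues, plus the
#: residue-agnostic "phosphorylated residue" parent.  Overridable via config.
DEFAULT_PHOSPHO_MOD_IDS = frozenset({"MOD:00046", "MOD:00047", "MOD:00048", "MOD:00696"})


class LevelLabel(str, Enum):
    """Taxon-specific specificity tier of a proteoform class."""

    ORGANISM_GENE = "organism-gene"
    ORGANISM_SEQUENCE = "organism-sequence"
    ORGANISM_MODIFICATION = "organism-modification"


def equals(a: ProteoformRecord, b: ProteoformRecord) -> bool:
    """True iff the two records have identical canonical serializations."""
    return canonical_string(a) == canonical_string(b)


def subsumes(general: ProteoformRecord, specific: ProteoformRecord) -> bool:
    """Is-a test: does ``general`` describe a class containing ``specific``?

    Requires the same accession.  ``general`` subsumes ``specific`` iff
    each of its constraints (isoform, range, site set) is either absent or
    satisfied by ``specific``: isoform unset or equal, range unset or
    equal, and the (position, mod_id) site set a subset of the specific
    record's.  Reflexive; a partial order on canonical records.
    """
    if general.seq.accession != specific.seq.accession:
        return False
    if general.seq.isoform is not None and general.seq.isoform != specific.seq.isoform:
        return False
    if general.seq.range is not None and general.seq.range != specific.seq.range:
        return False
    return general.site_set() <= specific.site_set()


def assign_level(rec: ProteoformRecord) -> LevelLabel:
    """Specificity tier as a total function of the populated fields.

    Accession only -> gene level; accession + isoform only -> sequence
    level; any range or modification block -> modification level (a bare
    cleavage product, e.g. after signal-peptide removal, already counts).
    """
    if rec.seq.range is not None or rec.mods:
        return LevelLabel.ORGANISM_MODIFICATION
    if rec.seq.isoform is not None:
        return LevelLabel.ORGANISM_SEQUENCE
    return LevelLabel.ORGANISM_GENE


@dataclass(frozen=True)
class InferenceResult:
    """Output of :func:`infer_parents`.

    ``parents``: strict generalizations, most specific first.
    ``categories``: cross-cutting class labels (e.g. ``"phosphoprotein"``).
    ``inconsistencies``: contradictions between asserted and implied class.
    """

    parents: tuple[ProteoformRecord, ...]
    categories: tuple[str, ...] = ()
    inconsistencies: tuple[str, ...] = ()


def infer_parents(
    rec: ProteoformRecord,
    phospho_mod_ids: Iterable[str] = DEFAULT_PHOSPHO_MOD_IDS,
    asserted_non_phospho: bool = False,
) -> InferenceResult:
    """Generalization chain plus toy phosphoprotein classification.

    Parents are obtained by nested stripping — modifications first, then
    the subsequence range, then the isoform.  The nesting is forced by the
    coordinate system: range and site positions are relative to the stated
    isoform, so the isoform cannot be dropped while coordinates remain.

    A record carrying any modification block whose PSI-MOD id is in
    ``phospho_mod_ids`` is additionally classified as a ``"phosphoprotein"``.
    If the record is simultaneously asserted to lack phosphorylation
    (``asserted_non_phospho``), the contradiction is reported as an
    inconsistency rather than silently resolved.
    """
    rec = canonicalize(rec)
    chain: list[ProteoformRecord] = []
    cur = rec
    if cur.mods:
        cur = strip_mods(cur)
        chain.append(cur)
    if cur.seq.range is not None:
        cur = strip_range(cur)
        chain.append(cur)
    if cur.seq.isoform is not None:
        cur = strip_isoform(cur)
        chain.append(cur)

    phospho_ids = frozenset(phospho_mod_ids)
    is_phospho = any(b.mod_id in phospho_ids for b in rec.mods)
    categories = ("phosphoprotein",) if is_phospho else ()
    inconsistencies: tuple[str, ...] = ()
    if asserted_non_phospho and is_phospho:
        inconsistencies = (
            "record asserted to lack phosphorylation but carries a "
            "phosphorylation site",
        )
    return InferenceResult(tuple(chain), categories, inconsistencies)


def build_hierarchy(
    records: Sequence[ProteoformRecord],
) -> tuple[list[tuple[str, str]], list[str]]:
    """Parent-child edges of the subsumption hierarchy.

    Returns ``(edges, warnings)`` where each edge is
    ``(child_canonical, parent_canonical)`` and the edge set is the
    transitive reduction of the strict-subsumption DAG over the distinct
    canonical records.  Duplicate records are collapsed with a warning.
    """
    warnings: list[str] = []
    by_key: dict[str, ProteoformRecord] = {}
    for rec in records:
        key = canonical_string(rec)
        if key in by_key:
            warnings.append(f"duplicate record collapsed: {key}")
        else:
            by_key[key] = canonicalize(rec)

    g = nx.DiGraph()
    g.add_nodes_from(by_key)
    keys = sorted(by_key)
    for child in keys:
        for parent in keys:
            if child != parent and subsumes(by_key[parent], by_key[child]):
                g.add_edge(child, parent)
    reduced = nx.transitive_reduction(g)
    edges = sorted(reduced.edges())
    return edges, warnings
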
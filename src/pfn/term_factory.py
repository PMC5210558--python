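"""OBO term-stanza generation for proteoform classes.

Two kinds of terms are produced:

* *Dynamic* gene/sequence-level terms whose identifier reuses the
  UniProtKB accession (addressable as ``PR_<accession>``) and whose
  definition instantiates the template
  ``"a protein that is a translation product of <gene> in <organism>."``
  verbatim.  These are transient: they are never persisted to a term
  store, only rendered on demand.
* *Pipeline* modification-level terms minted with fresh nine-digit ids
  from a configurable counter, flagged ``unreviewed`` and carrying the
  canonical notation string in their comment plus at least one evidence
  cross-reference.

Identifiers come in two spellings that differ only in the separator:
``PR:xxxxxxxxx`` in the OBO representation and ``PR_xxxxxxxxx`` in the
OWL/PURL representation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .notation import ACCESSION_RE, ProteoformRecord, canonical_string, canonicalize
from .semantics import LevelLabel, assign_level, infer_parents

__all__ = [
    "TermStanza",
    "TermFactory",
    "GENE_LEVEL_TEMPLATE",
    "obo_to_owl_id",
    "owl_to_obo_id",
    "make_gene_level_term",
    "write_obo",
    "read_obo",
]

GENE_LEVEL_TEMPLATE = "a protein that is a translation product of {gene} in {organism}."

_OBO_ID_RE = re.compile(r"PR:(\d{9}|[A-Z][A-Z0-9]{5,9})")
_OWL_ID_RE = re.compile(r"PR_(\d{9}|[A-Z][A-Z0-9]{5,9})")


def obo_to_owl_id(obo_id: str) -> str:
    """``PR:000004855`` -> ``PR_000004855`` (and accession-reusing ids alike)."""
    if not _OBO_ID_RE.fullmatch(obo_id):
        raise ValueError(f"not an OBO-form PR id: {obo_id!r}")
    return "PR_" + obo_id[3:]


def owl_to_obo_id(owl_id: str) -> str:
    if not _OWL_ID_RE.fullmatch(owl_id):
        raise ValueError(f"not an OWL-form PR id: {owl_id!r}")
    return "PR:" + owl_id[3:]


@dataclass(frozen=True)
class TermStanza:
    """One OBO ``[Term]`` block.

    ``xrefs`` are prefixed identifiers (``UniProtKB:…``, ``PMID:…``,
    ``MOD:…``); ``status`` is ``"reviewed"`` or ``"unreviewed"``; an
    unreviewed stanza must cite at least one evidence xref.
    """

    id: str
    name: str
    definition: str
    parents: tuple[str, ...] = ()
    xrefs: tuple[str, ...] = ()
    comment: Optional[str] = None
    status: str = "reviewed"
    transient: bool = False

    def __post_init__(self):
        if not _OBO_ID_RE.fullmatch(self.id):
            raise ValueError(f"bad term id {self.id!r}")
        if self.status not in ("reviewed", "unreviewed"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "unreviewed" and not any(
            x.startswith("PMID:") for x in self.xrefs
        ):
            raise ValueError("unreviewed term requires >= 1 evidence (PMID) xref")
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "xrefs", tuple(self.xrefs))

    @property
    def owl_id(self) -> str:
        return obo_to_owl_id(self.id)


def make_gene_level_term(
    accession: str, gene_symbol: str, organism: str
) -> TermStanza:
    """Dynamically generated gene-level term reusing the UniProtKB accession.

    The definition instantiates :data:`GENE_LEVEL_TEMPLATE` verbatim, which
    makes distinct (gene, organism) pairs yield distinct definitions.
    """
    if not accession or not ACCESSION_RE.fullmatch(accession):
        raise ValueError(f"malformed accession {accession!r}")
    if not gene_symbol or not organism:
        raise ValueError("gene symbol and organism must be non-empty")
    return TermStanza(
        id=f"PR:{accession}",
        name=f"{gene_symbol} ({organism})",
        definition=GENE_LEVEL_TEMPLATE.format(gene=gene_symbol, organism=organism),
        xrefs=(f"UniProtKB:{accession}",),
        comment=f"Category={LevelLabel.ORGANISM_GENE.value}.",
        status="reviewed",
        transient=True,
    )


class TermFactory:
    """Mints proteoform term stanzas with deterministic nine-digit ids.

    Ids are assigned from ``counter_start`` upward, in first-seen order of
    the distinct canonical records; asking twice for the same record
    returns the same id within one factory's lifetime.  Input ids are
    never reused.
    """

    def __init__(self, counter_start: int = 900000000):
        if not (0 < counter_start < 10**9):
            raise ValueError("counter start must be a positive nine-digit number")
        self._next = counter_start
        self._ids: dict[str, str] = {}

    def id_for(self, rec: ProteoformRecord) -> str:
        key = canonical_string(rec)
        if key not in self._ids:
            if self._next >= 10**9:
                raise OverflowError("nine-digit id space exhausted")
            self._ids[key] = f"PR:{self._next:09d}"
            self._next += 1
        return self._ids[key]

    def make_proteoform_term(
        self,
        rec: ProteoformRecord,
        evidence: Sequence[str],
        source: str,
        name: Optional[str] = None,
    ) -> TermStanza:
        """Unreviewed modification-level stanza for a pipeline-imported record.

        The comment embeds the canonical notation string; the parent is the
        nearest generalization from the inference chain (or none for a
        gene-level record); evidence PMIDs become xrefs.
        """
        rec = canonicalize(rec)
        if not evidence:
            raise ValueError("pipeline-sourced (unreviewed) term requires evidence")
        notation = canonical_string(rec)
        chain = infer_parents(rec).parents
        parents: tuple[str, ...] = ()
        if chain:
            parent = chain[0]
            if assign_level(parent) == LevelLabel.ORGANISM_GENE:
                parents = (f"PR:{parent.seq.accession}",)
            else:
                parents = (self.id_for(parent),)
        xrefs = tuple(f"PMID:{p}" if not str(p).startswith("PMID:") else str(p)
                      for p in evidence)
        xrefs += (f"UniProtKB:{rec.seq.accession}",)
        return TermStanza(
            id=self.id_for(rec),
            name=name or f"{rec.seq.accession} proteoform",
            definition=f"A proteoform of UniProtKB:{rec.seq.accession} "
            f"defined by the standardized representation.",
            parents=parents,
            xrefs=xrefs,
            comment=f"Category={assign_level(rec).value}. "
            f"Proteoform notation: {notation}. Source: {source}.",
            status="unreviewed",
        )


# ---------------------------------------------------------------------------
# OBO 1.4 flat-file serialization

_HEADER = [
    "format-version: 1.4",
    "ontology: pr",
    'subsetdef: unreviewed "pipeline-generated term awaiting expert curation"',
]


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def write_obo(stanzas: Iterable[TermStanza]) -> str:
    """Serialize stanzas as an OBO 1.4 document (sorted by id, one
    ``[Term]`` block each).  Duplicate ids are an error."""
    stanzas = sorted(stanzas, key=lambda s: s.id)
    ids = [s.id for s in stanzas]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate term ids: {dup}")
    lines = list(_HEADER)
    for s in stanzas:
        lines.append("")
        lines.append("[Term]")
        lines.append(f"id: {s.id}")
        lines.append(f"name: {s.name}")
        xref_part = ", ".join(s.xrefs)
        lines.append(f'def: "{_escape(s.definition)}" [{xref_part}]')
        if s.comment:
            lines.append(f"comment: {s.comment}")
        if s.status == "unreviewed":
            lines.append("subset: unreviewed")
        for p in s.parents:
            lines.append(f"is_a: {p}")
    return "\n".join(lines) + "\n"


def read_obo(text: str) -> list[TermStanza]:
    """Parse an OBO document written by :func:`write_obo` back to stanzas.

    Only the tags this package emits are understood; unknown tags raise.
    """
    stanzas: list[TermStanza] = []
    cur: Optional[dict] = None

    def flush():
        if cur is None:
            return
        stanzas.append(
            TermStanza(
                id=cur["id"],
                name=cur.get("name", ""),
                definition=cur.get("definition", ""),
                parents=tuple(cur.get("parents", [])),
                xrefs=tuple(cur.get("xrefs", [])),
                comment=cur.get("comment"),
                status=cur.get("status", "reviewed"),
            )
        )

    in_header = True
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line == "[Term]":
            flush()
            cur = {}
            in_header = False
            continue
        if in_header:
            continue
        tag, _, value = line.partition(": ")
        if cur is None:
            raise ValueError(f"tag outside stanza: {line!r}")
        if tag == "id":
            cur["id"] = value
        elif tag == "name":
            cur["name"] = value
        elif tag == "def":
            m = re.fullmatch(r'"(.*)" \[(.*)\]', value, re.DOTALL)
            if m is None:
                raise ValueError(f"malformed def line: {line!r}")
            cur["definition"] = _unescape(m.group(1))
            cur["xrefs"] = [x.strip() for x in m.group(2).split(",") if x.strip()]
        elif tag == "comment":
            cur["comment"] = value
        elif tag == "subset":
            if value == "unreviewed":
                cur["status"] = "unreviewed"
        elif tag == "is_a":
            cur.setdefault("parents", []).append(value)
        else:
            raise ValueError(f"unsupported OBO tag {tag!r}")
    flush()
    return stanzas
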
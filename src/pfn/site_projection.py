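"""Cross-species projection of modification sites through a multiple
sequence alignment.

Given an MSA of orthologous proteoform sequences and modification sites
on one reference sequence, each site is carried along its alignment
column to every other sequence and classified:

* ``conserved-modifiable`` — the aligned residue belongs to the
  modification's residue-compatibility set (for phosphorylation:
  Ser/Thr/Tyr), so the modification could be conserved there;
* ``not-amenable`` — the aligned residue cannot chemically carry the
  modification (a Ser phospho-site aligned to a Leu, say), so the event
  is not conserved;
* ``gap`` — the column is a gap in the target sequence.

Alignments are consumed, not computed: any pre-computed aligned FASTA
(e.g. from MUSCLE or MAFFT) works.  Coordinates are 1-based on both the
ungapped sequences and the alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import AlignIO

from .config import DEFAULT_PHOSPHO_COMPAT, load_compat_sets
from .notation import AA1_TO_AA3, AA3_TO_AA1, ModSite

__all__ = [
    "AlignedSet",
    "SiteProjection",
    "SiteClass",
    "project_sites",
]

GAP_CHARS = frozenset("-.")


class SiteClass:
    CONSERVED = "conserved-modifiable"
    NOT_AMENABLE = "not-amenable"
    GAP = "gap"


class AlignedSet:
    """A gapped multiple alignment with per-sequence coordinate maps.

    Each sequence gets two mutually inverse maps between its 1-based
    ungapped residue positions and the 1-based alignment columns holding
    them; gap columns have no ungapped counterpart.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if len(sequences) < 2:
            raise ValueError("an alignment needs >= 2 sequences")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal gapped length")
        self.ids: tuple[str, ...] = tuple(sequences)
        self.gapped: dict[str, str] = {k: str(v).upper() for k, v in sequences.items()}
        self.width = lengths.pop()
        self._to_col: dict[str, dict[int, int]] = {}
        self._to_pos: dict[str, dict[int, int]] = {}
        for sid, seq in self.gapped.items():
            to_col, to_pos = {}, {}
            pos = 0
            for col, ch in enumerate(seq, start=1):
                if ch not in GAP_CHARS:
                    pos += 1
                    to_col[pos] = col
                    to_pos[col] = pos
            self._to_col[sid] = to_col
            self._to_pos[sid] = to_pos

    @classmethod
    def from_fasta(cls, path) -> "AlignedSet":
        aln = AlignIO.read(path, "fasta")
        return cls({rec.id: str(rec.seq) for rec in aln})

    def ungapped(self, seq_id: str) -> str:
        return "".join(c for c in self.gapped[seq_id] if c not in GAP_CHARS)

    def ungapped_length(self, seq_id: str) -> int:
        return len(self._to_col[seq_id])

    def ungapped_to_column(self, seq_id: str, position: int) -> int:
        """Alignment column (1-based) holding residue ``position`` of
        ``seq_id``; inverse of :meth:`column_to_ungapped`."""
        try:
            return self._to_col[seq_id][position]
        except KeyError:
            raise IndexError(
                f"position {position} out of range for {seq_id} "
                f"(ungapped length {self.ungapped_length(seq_id)})"
            ) from None

    def column_to_ungapped(self, seq_id: str, column: int) -> Optional[int]:
        """Ungapped position of ``seq_id`` at alignment ``column``, or
        ``None`` when the column is a gap in that sequence."""
        if not (1 <= column <= self.width):
            raise IndexError(f"column {column} out of range 1..{self.width}")
        return self._to_pos[seq_id].get(column)

    def residue_at(self, seq_id: str, column: int) -> str:
        return self.gapped[seq_id][column - 1]


@dataclass(frozen=True)
class SiteProjection:
    """Classification of one reference site in one target sequence."""

    ref_site: ModSite
    mod_id: str
    column: int
    target_id: str
    target_residue: Optional[str]   # three-letter code; None on gap
    target_position: Optional[int]  # ungapped position; None on gap
    site_class: str


def project_sites(
    aln: AlignedSet,
    ref_id: str,
    sites: Sequence[tuple[ModSite, str]],
    compat: Optional[Mapping[str, frozenset[str]]] = None,
) -> list[SiteProjection]:
    """Project reference modification sites onto every other sequence.

    ``sites`` pairs each :class:`~pfn.notation.ModSite` (coordinates on
    the *ungapped* reference) with its PSI-MOD id; ``compat`` maps the
    mod id to the residues amenable to it (defaulting to the packaged
    compatibility sets, with Ser/Thr/Tyr as the phospho fallback).  The
    reference residue must match the site's stated residue code — a
    mismatch means inconsistent input data and raises.
    """
    if ref_id not in aln.gapped:
        raise KeyError(f"reference {ref_id!r} not in alignment")
    if compat is None:
        compat = load_compat_sets()
    out: list[SiteProjection] = []
    for site, mod_id in sites:
        col = aln.ungapped_to_column(ref_id, site.position)
        ref_res = aln.residue_at(ref_id, col)
        if AA1_TO_AA3.get(ref_res) != site.residue:
            raise ValueError(
                f"reference {ref_id} has {ref_res!r} at position "
                f"{site.position}, record asserts {site.residue}"
            )
        allowed = compat.get(mod_id, DEFAULT_PHOSPHO_COMPAT)
        for sid in aln.ids:
            if sid == ref_id:
                continue
            pos = aln.column_to_ungapped(sid, col)
            if pos is None:
                out.append(
                    SiteProjection(site, mod_id, col, sid, None, None, SiteClass.GAP)
                )
                continue
            res1 = aln.residue_at(sid, col)
            res3 = AA1_TO_AA3.get(res1, res1)
            cls = (
                SiteClass.CONSERVED if res3 in allowed else SiteClass.NOT_AMENABLE
            )
            out.append(SiteProjection(site, mod_id, col, sid, res3, pos, cls))
    return out


def projections_to_tsv_rows(projections: Iterable[SiteProjection]) -> list[tuple]:
    """Rows for the TSV export: ref_site, target_id, target_pos,
    target_residue, class."""
    return [
        (str(p.ref_site), p.mod_id, p.target_id,
         "" if p.target_position is None else p.target_position,
         p.target_residue or "-", p.site_class)
        for p in projections
    ]
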
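"""Parsing, canonicalization and serialization of the standardized proteoform notation.

A proteoform string names the precise molecular form of a protein: a
*sequence block* (UniProtKB accession, optional isoform number, optional
residue range for cleavage products) followed by zero or more *modification
blocks*, each grouping the sites that carry one PSI-MOD modification type::

    P00001-2, 1-100, Ser-10/Ser-20, MOD:00046|Thr-30, MOD:00047

Grammar (canonical surface form uses ``", "`` after commas, bare ``|`` and
``/``; the parser tolerates arbitrary spacing around separators)::

    record    := seq_block (", " mod_block ("|" mod_block)*)?
    seq_block := ACC ("-" INT)? (", " INT "-" INT)?
    mod_block := SITE ("/" SITE)* ", " MODID
    SITE      := AA3 "-" INT
    MODID     := "MOD:" DIGIT{5}

Coordinates are 1-based and ranges inclusive (UniProtKB convention).  When
an isoform is given, range and site positions are relative to the full
length of that isoform; otherwise to the representative sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "AA3_CODES",
    "ModSite",
    "ModBlock",
    "SeqBlock",
    "ProteoformRecord",
    "NotationSyntaxError",
    "NotationSemanticError",
    "Finding",
    "parse",
    "canonicalize",
    "serialize",
    "validate",
    "is_canonical",
]

#: The 20 standard three-letter amino-acid codes (Title case).
AA3_CODES = frozenset(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile "
    "Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)

#: One-letter -> three-letter residue code map.
AA1_TO_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}

# UniProtKB accession shape (release-current regex, both 6- and 10-char forms).
ACCESSION_RE = re.compile(
    r"[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}"
)

MODID_RE = re.compile(r"MOD:\d{5}")


class NotationSyntaxError(ValueError):
    """Malformed notation text; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class NotationSemanticError(ValueError):
    """Structurally parseable but semantically invalid record."""


@dataclass(frozen=True, order=True)
class ModSite:
    """One modified residue: three-letter code + 1-based position."""

    residue: str
    position: int

    def __post_init__(self):
        res = self.residue.capitalize()
        if res != self.residue:
            object.__setattr__(self, "residue", res)
        if res not in AA3_CODES:
            raise NotationSemanticError(f"unknown residue code {self.residue!r}")
        if self.position < 1:
            raise NotationSemanticError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.residue}-{self.position}"


@dataclass(frozen=True)
class ModBlock:
    """A group of sites sharing one PSI-MOD modification type."""

    sites: tuple[ModSite, ...]
    mod_id: str

    def __post_init__(self):
        if not self.sites:
            raise NotationSemanticError("modification block must have >= 1 site")
        object.__setattr__(self, "sites", tuple(self.sites))
        if not MODID_RE.fullmatch(self.mod_id):
            raise NotationSemanticError(f"bad PSI-MOD identifier {self.mod_id!r}")
        positions = [s.position for s in self.sites]
        if len(set(positions)) != len(positions):
            raise NotationSemanticError(
                f"duplicate site position within block {self.mod_id}"
            )

    @property
    def min_position(self) -> int:
        return min(s.position for s in self.sites)

    def __str__(self) -> str:
        return "/".join(str(s) for s in self.sites) + f", {self.mod_id}"


@dataclass(frozen=True)
class SeqBlock:
    """Accession + optional isoform number + optional inclusive residue range."""

    accession: str
    isoform: Optional[int] = None
    range: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if not ACCESSION_RE.fullmatch(self.accession):
            raise NotationSemanticError(
                f"accession {self.accession!r} is not UniProtKB-shaped"
            )
        if self.isoform is not None and self.isoform < 1:
            raise NotationSemanticError(f"isoform must be >= 1, got {self.isoform}")
        if self.range is not None:
            start, end = self.range
            if not (1 <= start <= end):
                raise NotationSemanticError(f"bad range {start}-{end}")
            object.__setattr__(self, "range", (int(start), int(end)))

    def __str__(self) -> str:
        s = self.accession
        if self.isoform is not None:
            s += f"-{self.isoform}"
        if self.range is not None:
            s += f", {self.range[0]}-{self.range[1]}"
        return s


@dataclass(frozen=True)
class ProteoformRecord:
    """A sequence block plus an ordered list of modification blocks."""

    seq: SeqBlock
    mods: tuple[ModBlock, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mods", tuple(self.mods))

    def check_sites_in_range(self) -> None:
        """Raise if any site falls outside the declared range (parse-time
        semantic check; :func:`validate` reports the same as a finding)."""
        if self.seq.range is None:
            return
        start, end = self.seq.range
        for block in self.mods:
            for site in block.sites:
                if not (start <= site.position <= end):
                    raise NotationSemanticError(
                        f"site {site} outside declared range {start}-{end}"
                    )

    def site_set(self) -> frozenset[tuple[int, str]]:
        """All (position, mod_id) pairs asserted by this record."""
        return frozenset(
            (s.position, b.mod_id) for b in self.mods for s in b.sites
        )


# ---------------------------------------------------------------------------
# parsing

_WS = re.compile(r"\s*")


class _Cursor:
    """Tokenizing cursor with offset-carrying errors."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self):
        self.pos = _WS.match(self.text, self.pos).end()

    def eof(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, literal: str, what: str):
        self.skip_ws()
        if not self.text.startswith(literal, self.pos):
            raise NotationSyntaxError(f"expected {what}", self.pos)
        self.pos += len(literal)

    def take(self, pattern: re.Pattern, what: str) -> str:
        self.skip_ws()
        m = pattern.match(self.text, self.pos)
        if m is None:
            raise NotationSyntaxError(f"expected {what}", self.pos)
        self.pos = m.end()
        return m.group()


_INT = re.compile(r"\d+")
_AA3 = re.compile(r"[A-Za-z]{3}")
_ACC_TOKEN = re.compile(r"[A-Z][A-Z0-9]{5,9}")


def _parse_site(cur: _Cursor) -> ModSite:
    at = cur.pos
    aa = cur.take(_AA3, "three-letter residue code")
    if aa.capitalize() not in AA3_CODES:
        raise NotationSyntaxError(f"unknown residue code {aa!r}", at)
    cur.expect("-", "'-' between residue and position")
    pos = int(cur.take(_INT, "residue position"))
    if pos < 1:
        raise NotationSyntaxError("position must be >= 1", at)
    return ModSite(aa.capitalize(), pos)


def _parse_mod_block(cur: _Cursor) -> ModBlock:
    at = cur.pos
    sites = [_parse_site(cur)]
    while cur.peek() == "/":
        cur.expect("/", "'/'")
        sites.append(_parse_site(cur))
    cur.expect(",", "',' before PSI-MOD identifier")
    mod_at = cur.pos
    mod_id = cur.take(re.compile(r"MOD:\d{5}"), "PSI-MOD identifier (MOD:nnnnn)")
    try:
        return ModBlock(tuple(sites), mod_id)
    except NotationSemanticError as exc:
        raise NotationSyntaxError(str(exc), at) from exc


def parse(text: str) -> ProteoformRecord:
    """Parse a notation string into a :class:`ProteoformRecord`.

    The raw parse preserves the input order of blocks and sites; use
    :func:`canonicalize` to obtain the normal form.  Malformed input raises
    :class:`NotationSyntaxError` with a character offset; a site falling
    outside a declared range raises :class:`NotationSemanticError`.
    """
    if not text or not text.strip():
        raise NotationSyntaxError("empty notation string", 0)
    cur = _Cursor(text)

    acc_at = cur.pos
    acc = cur.take(_ACC_TOKEN, "UniProtKB accession")
    if not ACCESSION_RE.fullmatch(acc):
        raise NotationSyntaxError(f"{acc!r} is not a UniProtKB accession", acc_at)
    isoform = None
    if cur.peek() == "-":
        cur.expect("-", "'-'")
        iso_at = cur.pos
        isoform = int(cur.take(_INT, "isoform number"))
        if isoform < 1:
            raise NotationSyntaxError("isoform must be >= 1", iso_at)

    range_: Optional[tuple[int, int]] = None
    blocks: list[ModBlock] = []
    if cur.peek() == ",":
        cur.expect(",", "','")
        # Either a range (digits) or the first modification block (letters).
        if cur.peek().isdigit():
            at = cur.pos
            start = int(cur.take(_INT, "range start"))
            cur.expect("-", "'-' in range")
            end = int(cur.take(_INT, "range end"))
            if not (1 <= start <= end):
                raise NotationSyntaxError(f"bad range {start}-{end}", at)
            range_ = (start, end)
            if cur.peek() == ",":
                cur.expect(",", "','")
                blocks.append(_parse_mod_block(cur))
        else:
            blocks.append(_parse_mod_block(cur))
        while cur.peek() == "|":
            cur.expect("|", "'|'")
            blocks.append(_parse_mod_block(cur))

    if not cur.eof():
        raise NotationSyntaxError("unexpected trailing text", cur.pos)

    rec = ProteoformRecord(SeqBlock(acc, isoform, range_), tuple(blocks))
    rec.check_sites_in_range()
    return rec


# ---------------------------------------------------------------------------
# canonical form

def canonicalize(rec: ProteoformRecord) -> ProteoformRecord:
    """Rewrite ``rec`` into its unique normal form.

    Blocks sharing a PSI-MOD id are merged (sites unioned); within each
    block sites are sorted by ascending position; blocks are ordered by the
    position of the modified residue nearest the N terminus, with the
    PSI-MOD id as a lexicographic tie-break.  Idempotent.

    Raises :class:`NotationSemanticError` if the same (position, mod_id)
    site is asserted twice.
    """
    by_mod: dict[str, dict[int, ModSite]] = {}
    for block in rec.mods:
        bucket = by_mod.setdefault(block.mod_id, {})
        for site in block.sites:
            prev = bucket.get(site.position)
            if prev is not None:
                raise NotationSemanticError(
                    f"site position {site.position} asserted twice for {block.mod_id}"
                )
            bucket[site.position] = site
    blocks = [
        ModBlock(tuple(sorted(bucket.values(), key=lambda s: s.position)), mod_id)
        for mod_id, bucket in by_mod.items()
    ]
    blocks.sort(key=lambda b: (b.min_position, b.mod_id))
    return ProteoformRecord(rec.seq, tuple(blocks))


def is_canonical(rec: ProteoformRecord) -> bool:
    try:
        return canonicalize(rec) == rec
    except NotationSemanticError:
        return False


def serialize(rec: ProteoformRecord) -> str:
    """Render a canonical record as its notation string.

    Only canonical records serialize; this keeps ``parse(serialize(r)) == r``
    and makes the string a usable equality key.
    """
    if not is_canonical(rec):
        raise NotationSemanticError("serialize() requires a canonical record")
    out = str(rec.seq)
    if rec.mods:
        out += ", " + "|".join(str(b) for b in rec.mods)
    return out


def canonical_string(rec: ProteoformRecord) -> str:
    """Shorthand for ``serialize(canonicalize(rec))``."""
    return serialize(canonicalize(rec))


# ---------------------------------------------------------------------------
# validation findings

@dataclass(frozen=True)
class Finding:
    """A validation finding; ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    code: str
    message: str


def validate(
    rec: ProteoformRecord, sequence: Optional[str] = None
) -> list[Finding]:
    """Check a record against its own constraints and, optionally, a
    reference residue sequence (one-letter codes, isoform/representative
    coordinates as appropriate for the record).

    Findings are returned, never raised.
    """
    findings: list[Finding] = []
    rng = rec.seq.range
    for block in rec.mods:
        for site in block.sites:
            if rng is not None and not (rng[0] <= site.position <= rng[1]):
                findings.append(
                    Finding(
                        "error",
                        "site-outside-range",
                        f"site {site} outside subsequence {rng[0]}-{rng[1]}",
                    )
                )
    if sequence is not None:
        seq = sequence.strip().upper()
        if rng is not None and rng[1] > len(seq):
            findings.append(
                Finding(
                    "error",
                    "range-beyond-sequence",
                    f"range end {rng[1]} beyond sequence length {len(seq)}",
                )
            )
        for block in rec.mods:
            for site in block.sites:
                if site.position > len(seq):
                    findings.append(
                        Finding(
                            "error",
                            "site-beyond-sequence",
                            f"site {site} beyond sequence length {len(seq)}",
                        )
                    )
                    continue
                letter = seq[site.position - 1]
                expected = AA3_TO_AA1[site.residue]
                if letter != expected:
                    findings.append(
                        Finding(
                            "error",
                            "residue-mismatch",
                            f"sequence has {letter} at {site.position}, "
                            f"record asserts {site.residue}",
                        )
                    )
    return findings


def strip_mods(rec: ProteoformRecord) -> ProteoformRecord:
    """The subsequence-only generalization (modification blocks removed)."""
    return ProteoformRecord(rec.seq, ())


def strip_range(rec: ProteoformRecord) -> ProteoformRecord:
    """Drop the subsequence range (mods must already be absent)."""
    if rec.mods:
        raise NotationSemanticError("cannot drop range while sites remain")
    return ProteoformRecord(replace(rec.seq, range=None), ())


def strip_isoform(rec: ProteoformRecord) -> ProteoformRecord:
    """Drop the isoform indicator (range/mods must already be absent:
    their coordinates are isoform-relative)."""
    if rec.mods or rec.seq.range is not None:
        raise NotationSemanticError(
            "cannot drop isoform while isoform-relative coordinates remain"
        )
    return ProteoformRecord(replace(rec.seq, isoform=None), ())
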
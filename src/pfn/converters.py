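"""Normalize external proteoform descriptors into the standard notation.

Two descriptor dialects are supported:

* Reactome-style: a gene-symbol label with an optional parenthesized
  residue range, plus the UniProtKB accession it refers to — e.g. the p25
  cleavage product ``CDK5R1(99-307)`` / ``Q15078``.
* UniProtKB feature-identifier style (as used by the IntAct Complex
  Portal): ``<accession>-PRO_<10 digits>``, resolved to a residue range
  through a feature table of processed chains/peptides.

Both converge on the same canonical record when they describe the same
chain, which is what makes cross-resource identity checks possible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .notation import (
    NotationSemanticError,
    NotationSyntaxError,
    ProteoformRecord,
    SeqBlock,
    canonicalize,
)

__all__ = [
    "ReactomeDescriptor",
    "FeatureTable",
    "FeatureLookupError",
    "from_reactome",
    "from_feature_id",
    "parse_reactome_label",
]

_LABEL_RE = re.compile(
    r"""(?P<symbol>[A-Za-z0-9_.:-]+?)
        (?:\(\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*\))?$""",
    re.VERBOSE,
)
_ISOFORM_SUFFIX_RE = re.compile(r"-(\d+)$")
_FEATURE_ID_RE = re.compile(r"PRO_\d{10}$")


@dataclass(frozen=True)
class ReactomeDescriptor:
    """Gene-symbol label (optionally ``SYMBOL(start-end)``) + accession."""

    label: str
    accession: str


class FeatureLookupError(KeyError):
    """Feature identifier not present in the feature table."""


class FeatureTable:
    """Mapping (accession, feature_id) -> residue range of a processed chain.

    Thin wrapper over a DataFrame with columns
    ``accession, feature_id, start, end`` (the shape of a UniProtKB
    chain/peptide feature export).
    """

    COLUMNS = ("accession", "feature_id", "start", "end")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["start"] = frame["start"].astype(int)
        frame["end"] = frame["end"].astype(int)
        if (frame["start"] < 1).any() or (frame["start"] > frame["end"]).any():
            raise ValueError("feature table contains an invalid range")
        dup = frame.duplicated(subset=["accession", "feature_id"])
        if dup.any():
            raise ValueError("feature_id must be unique per accession")
        if not frame["feature_id"].map(lambda f: bool(_FEATURE_ID_RE.fullmatch(f))).all():
            raise ValueError("feature ids must look like PRO_<10 digits>")
        self.frame = frame
        self._index = {
            (row.accession, row.feature_id): (row.start, row.end)
            for row in frame.itertuples()
        }

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def lookup(self, accession: str, feature_id: str) -> tuple[int, int]:
        try:
            return self._index[(accession, feature_id)]
        except KeyError:
            raise FeatureLookupError(
                f"no feature {feature_id} for accession {accession}"
            ) from None

    def __len__(self) -> int:
        return len(self.frame)


def parse_reactome_label(label: str) -> tuple[str, Optional[tuple[int, int]]]:
    """Split ``SYMBOL(start-end)`` into (symbol, range); range may be absent."""
    m = _LABEL_RE.fullmatch(label.strip())
    if m is None:
        raise NotationSyntaxError(f"malformed descriptor label {label!r}", 0)
    if m.group("start") is None:
        return m.group("symbol"), None
    start, end = int(m.group("start")), int(m.group("end"))
    if start > end:
        raise NotationSemanticError(f"bad range {start}-{end} in label {label!r}")
    return m.group("symbol"), (start, end)


def from_reactome(desc: ReactomeDescriptor) -> ProteoformRecord:
    """Convert a Reactome-style descriptor to a (mod-free) canonical record.

    The parenthesized coordinates on the label become the subsequence
    range; an ``-<n>`` suffix on the accession is taken as an isoform
    indicator.
    """
    _, range_ = parse_reactome_label(desc.label)
    accession, isoform = _split_isoform(desc.accession)
    return canonicalize(
        ProteoformRecord(SeqBlock(accession, isoform=isoform, range=range_))
    )


def _split_isoform(token: str) -> tuple[str, Optional[int]]:
    m = _ISOFORM_SUFFIX_RE.search(token)
    if m:
        return token[: m.start()], int(m.group(1))
    return token, None


def from_feature_id(
    token: str, table: FeatureTable
) -> ProteoformRecord:
    """Resolve an ``<accession>-PRO_<10 digits>`` token to a ranged record.

    The dash after an accession is ambiguous between an isoform number and
    a feature reference; it is disambiguated by the suffix shape: digits
    mean an isoform, ``PRO_…`` means a feature lookup.  A plain isoform
    token is accepted and returns an isoform-level record (no range).
    Modification information is never introduced: the result always has
    zero modification blocks.
    """
    token = token.strip()
    acc, sep, suffix = token.partition("-")
    if not sep:
        return canonicalize(ProteoformRecord(SeqBlock(acc)))
    if _FEATURE_ID_RE.fullmatch(suffix):
        start, end = table.lookup(acc, suffix)
        return canonicalize(
            ProteoformRecord(SeqBlock(acc, range=(start, end)))
        )
    if suffix.isdigit():
        return canonicalize(
            ProteoformRecord(SeqBlock(acc, isoform=int(suffix)))
        )
    raise NotationSyntaxError(
        f"suffix {suffix!r} is neither an isoform number nor a PRO_ feature id",
        len(acc) + 1,
    )
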
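"""Configurable lookup tables: PTM-type -> PSI-MOD id, category sets,
residue-compatibility sets.

Defaults ship as an editable TSV (``data/mod_types.tsv``) keyed by
(ptm_type, residue); a ``*`` residue row is the fallback for a type.
Category membership (e.g. which PSI-MOD ids count as phosphorylation for
the phosphoprotein rule) and per-modification residue compatibility (which
residues can chemically carry a modification) are plain YAML files with
the same override mechanism.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

__all__ = [
    "ModTypeLookup",
    "UnmappedModificationType",
    "load_mod_type_lookup",
    "load_compat_sets",
    "DEFAULT_PHOSPHO_COMPAT",
]

#: Residues chemically amenable to phosphorylation (three-letter codes).
DEFAULT_PHOSPHO_COMPAT = frozenset({"Ser", "Thr", "Tyr"})


class UnmappedModificationType(KeyError):
    """PTM-type label with no PSI-MOD mapping in the lookup table."""


class ModTypeLookup:
    """(ptm_type label, residue) -> PSI-MOD id, with a ``*`` fallback row."""

    def __init__(self, frame: pd.DataFrame):
        required = {"ptm_type", "residue", "mod_id"}
        if not required <= set(frame.columns):
            raise ValueError(f"lookup table needs columns {sorted(required)}")
        self._map: dict[tuple[str, str], str] = {}
        for row in frame.itertuples():
            self._map[(row.ptm_type.lower(), row.residue)] = row.mod_id

    def mod_id(self, ptm_type: str, residue: str) -> str:
        key = ptm_type.lower()
        hit = self._map.get((key, residue)) or self._map.get((key, "*"))
        if hit is None:
            raise UnmappedModificationType(
                f"no PSI-MOD mapping for {ptm_type!r} on {residue}"
            )
        return hit

    def knows(self, ptm_type: str, residue: str) -> bool:
        try:
            self.mod_id(ptm_type, residue)
            return True
        except UnmappedModificationType:
            return False


def load_mod_type_lookup(path=None) -> ModTypeLookup:
    """Load the PTM-type lookup; ``path=None`` uses the packaged defaults."""
    if path is None:
        ref = resources.files("pfn.data").joinpath("mod_types.tsv")
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    return ModTypeLookup(frame)


def load_compat_sets(path=None) -> dict[str, frozenset[str]]:
    """PSI-MOD id -> set of residues amenable to that modification."""
    if path is None:
        ref = resources.files("pfn.data").joinpath("compat.yaml")
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {mod: frozenset(residues) for mod, residues in raw.items()}
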
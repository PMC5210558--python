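"""Seeded synthetic-data generation for every module in the package.

Each generator is fully deterministic under its spec's seed and emits its
own ground truth alongside the data: the canonical form of each record is
recomputed here by explicit brute-force sorting (independent of the
parser/canonicalizer under test), pipeline rows carry planted
accept/reject labels, and alignments carry a planted per-site
conservation table.  Ground truth is written to a ``truth/`` sidecar
directory that the code under test never reads.

The defaults mirror the study conditions the package is exercised under:
1000-record notation batches, a phospho-filter table with 82 planted
survivors, a 500-row histone table with 468 distinct proteoforms, and
pathway sets with a planted 60% mappable fraction.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .converters import FeatureTable, ReactomeDescriptor
from .notation import (
    AA3_CODES,
    AA3_TO_AA1,
    ModBlock,
    ModSite,
    ProteoformRecord,
    SeqBlock,
)
from .pipelines import ExternalParticipant, HistomeRow, PtmEvidenceRow, RejectReason
from .site_projection import AlignedSet, SiteClass

__all__ = [
    "FixtureSpec",
    "GeneratedRecord",
    "gen_records",
    "IptmnetFixture",
    "gen_iptmnet_table",
    "HistomeFixture",
    "gen_histome_table",
    "PathwayFixture",
    "gen_pathway_set",
    "AlignmentFixture",
    "gen_alignment",
    "write_fixture_dir",
]

_RESIDUES = sorted(AA3_CODES)
_MOD_POOL = [f"MOD:{n:05d}" for n in
             (46, 47, 48, 64, 85, 126, 134, 599, 696, 1148)]


@dataclass(frozen=True)
class FixtureSpec:
    """Counts and planted parameters for one deterministic fixture set."""

    seed: int = 0
    n_records: int = 1000
    # phospho-filter table: survivors + rejects per reason
    n_pass: int = 82
    n_reject: dict = field(default_factory=lambda: {
        RejectReason.NOT_PHOSPHORYLATION: 25,
        RejectReason.SINGLE_SOURCE: 25,
        RejectReason.ABSTRACT_FLAGGED: 25,
        RejectReason.ALREADY_CURATED: 25,
    })
    # histone table
    n_histome_rows: int = 500
    n_histome_distinct: int = 468
    # pathway mapping
    n_pathways: int = 10
    participants_per_pathway: int = 20
    fraction_mappable: float = 0.60
    # alignment
    n_sequences: int = 4
    aln_length: int = 80
    n_sites: int = 6


def _rand_accession(rng: random.Random) -> str:
    """A UniProtKB-shaped six-character accession."""
    u = string.ascii_uppercase
    a = string.ascii_uppercase + string.digits
    return (rng.choice("OPQ") + rng.choice(string.digits)
            + "".join(rng.choice(a) for _ in range(3)) + rng.choice(string.digits))


# ---------------------------------------------------------------------------
# notation records

@dataclass(frozen=True)
class GeneratedRecord:
    """A raw (possibly shuffled, possibly split-block) record plus the
    canonical string computed by brute force at generation time."""

    record: ProteoformRecord
    canonical: str


def _brute_force_canonical(seq: SeqBlock,
                           sites: Sequence[tuple[str, int, str]]) -> str:
    """Canonical string from first principles: group (residue, pos, mod)
    triples by mod id, sort sites by position, sort groups by
    (min position, mod id), then join with the notation separators."""
    groups: dict[str, list[tuple[int, str]]] = {}
    for residue, pos, mod in sites:
        groups.setdefault(mod, []).append((pos, residue))
    rendered = []
    for mod, ps in groups.items():
        ps = sorted(set(ps))
        rendered.append((ps[0][0], mod,
                         "/".join(f"{r}-{p}" for p, r in ps) + f", {mod}"))
    rendered.sort(key=lambda t: (t[0], t[1]))
    head = seq.accession
    if seq.isoform is not None:
        head += f"-{seq.isoform}"
    if seq.range is not None:
        head += f", {seq.range[0]}-{seq.range[1]}"
    if rendered:
        head += ", " + "|".join(r[2] for r in rendered)
    return head


def _random_record(rng: random.Random) -> tuple[ProteoformRecord, str]:
    acc = _rand_accession(rng)
    isoform = rng.randint(1, 4) if rng.random() < 0.3 else None
    range_ = None
    lo, hi = 1, 600
    if rng.random() < 0.4:
        start = rng.randint(1, 300)
        end = rng.randint(start, start + 400)
        range_, lo, hi = (start, end), start, end
    n_blocks = rng.randint(0, 4)
    mods = rng.sample(_MOD_POOL, k=n_blocks)
    triples: list[tuple[str, int, str]] = []
    positions_by_mod: dict[str, set[int]] = {}
    for mod in mods:
        n_sites = rng.randint(1, 3)
        used = positions_by_mod.setdefault(mod, set())
        for _ in range(n_sites):
            for _attempt in range(50):
                pos = rng.randint(lo, hi)
                if pos not in used:
                    used.add(pos)
                    triples.append((rng.choice(_RESIDUES), pos, mod))
                    break
    canonical = _brute_force_canonical(SeqBlock(acc, isoform, range_), triples)

    # Raw record: sometimes split one mod's sites into two blocks, shuffle
    # block order and within-block site order, so canonicalization has
    # real work to do.
    blocks: list[ModBlock] = []
    for mod in mods:
        mod_triples = [t for t in triples if t[2] == mod]
        rng.shuffle(mod_triples)
        if len(mod_triples) > 1 and rng.random() < 0.3:
            cut = rng.randint(1, len(mod_triples) - 1)
            parts = [mod_triples[:cut], mod_triples[cut:]]
        else:
            parts = [mod_triples]
        for part in parts:
            blocks.append(
                ModBlock(tuple(ModSite(r, p) for r, p, _ in part), mod)
            )
    rng.shuffle(blocks)
    return ProteoformRecord(SeqBlock(acc, isoform, range_), tuple(blocks)), canonical


def gen_records(spec: FixtureSpec) -> list[GeneratedRecord]:
    """Deterministic batch of valid records with brute-force canonical
    strings; every record passes the notation validators."""
    rng = random.Random(spec.seed)
    return [GeneratedRecord(*_random_record(rng)) for _ in range(spec.n_records)]


# ---------------------------------------------------------------------------
# phospho-filter table

@dataclass(frozen=True)
class IptmnetFixture:
    rows: tuple[PtmEvidenceRow, ...]
    labels: tuple[str, ...]        # per-row: "pass" or a RejectReason value
    curated: frozenset[str]        # canonical strings already curated


_PHOSPHO_RESIDUE_MOD = {"Ser": "MOD:00046", "Thr": "MOD:00047", "Tyr": "MOD:00048"}


def gen_iptmnet_table(spec: FixtureSpec) -> IptmnetFixture:
    """Evidence table with planted per-row accept/reject ground truth.

    Every row gets a unique (accession, position) so the categories cannot
    interact; rows planted ``already-curated`` have their canonical
    single-site record included in the emitted curated set.
    """
    rng = random.Random(spec.seed + 1)
    rows: list[PtmEvidenceRow] = []
    labels: list[str] = []
    curated: set[str] = set()
    counter = 0

    def new_site() -> tuple[str, str, int]:
        nonlocal counter
        counter += 1
        return _rand_accession(rng), rng.choice(["Ser", "Thr", "Tyr"]), counter

    def sources(n: int) -> frozenset[str]:
        pool = ["PhosphoSitePlus", "PSP", "HPRD", "Signor", "RLIMS-P", "neXtProt"]
        return frozenset(rng.sample(pool, k=n))

    for _ in range(spec.n_pass):
        acc, res, pos = new_site()
        rows.append(PtmEvidenceRow(acc, res, pos, "phosphorylation",
                                   sources(rng.randint(2, 4)),
                                   pmids=(str(rng.randint(10**6, 10**7)),)))
        labels.append("pass")
    for _ in range(spec.n_reject.get(RejectReason.NOT_PHOSPHORYLATION, 0)):
        acc, _, pos = new_site()
        rows.append(PtmEvidenceRow(acc, "Lys", pos, "acetylation",
                                   sources(rng.randint(2, 3))))
        labels.append(RejectReason.NOT_PHOSPHORYLATION)
    for _ in range(spec.n_reject.get(RejectReason.SINGLE_SOURCE, 0)):
        acc, res, pos = new_site()
        rows.append(PtmEvidenceRow(acc, res, pos, "phosphorylation", sources(1)))
        labels.append(RejectReason.SINGLE_SOURCE)
    for _ in range(spec.n_reject.get(RejectReason.ABSTRACT_FLAGGED, 0)):
        acc, res, pos = new_site()
        multi = rng.random() < 0.5
        rows.append(PtmEvidenceRow(acc, res, pos, "phosphorylation",
                                   sources(2),
                                   mentions_multiple_sites=multi,
                                   mentions_other_ptm_types=not multi))
        labels.append(RejectReason.ABSTRACT_FLAGGED)
    for _ in range(spec.n_reject.get(RejectReason.ALREADY_CURATED, 0)):
        acc, res, pos = new_site()
        rows.append(PtmEvidenceRow(acc, res, pos, "phosphorylation", sources(2)))
        labels.append(RejectReason.ALREADY_CURATED)
        curated.add(f"{acc}, {res}-{pos}, {_PHOSPHO_RESIDUE_MOD[res]}")

    order = list(range(len(rows)))
    rng.shuffle(order)
    return IptmnetFixture(tuple(rows[i] for i in order),
                          tuple(labels[i] for i in order),
                          frozenset(curated))


# ---------------------------------------------------------------------------
# histone table

@dataclass(frozen=True)
class HistomeFixture:
    rows: tuple[HistomeRow, ...]
    n_distinct: int


_HISTOME_MODS = [("acetylation", "Lys"), ("phosphorylation", "Ser"),
                 ("phosphorylation", "Thr"), ("methylation", "Lys"),
                 ("methylation", "Arg"), ("ubiquitination", "Lys")]


def gen_histome_table(spec: FixtureSpec) -> HistomeFixture:
    """Histone-style rows with a planted number of distinct proteoforms;
    the surplus rows duplicate earlier sites with fresh PMIDs."""
    if spec.n_histome_distinct > spec.n_histome_rows:
        raise ValueError("distinct count cannot exceed row count")
    rng = random.Random(spec.seed + 2)
    accessions = [_rand_accession(rng) for _ in range(8)]  # a histone-sized gene set
    seen: set[tuple] = set()
    distinct: list[HistomeRow] = []
    while len(distinct) < spec.n_histome_distinct:
        acc = rng.choice(accessions)
        mod_type, residue = rng.choice(_HISTOME_MODS)
        pos = rng.randint(1, 300)
        iso = rng.randint(1, 2) if rng.random() < 0.2 else None
        key = (acc, iso, mod_type, residue, pos)
        if key in seen:
            continue
        seen.add(key)
        distinct.append(HistomeRow(acc, mod_type, residue, pos,
                                   str(rng.randint(10**6, 10**7)), iso))
    rows = list(distinct)
    for _ in range(spec.n_histome_rows - spec.n_histome_distinct):
        base = rng.choice(distinct)
        rows.append(HistomeRow(base.accession, base.mod_type, base.residue,
                               base.position, str(rng.randint(10**6, 10**7)),
                               base.isoform))
    rng.shuffle(rows)
    return HistomeFixture(tuple(rows), spec.n_histome_distinct)


# ---------------------------------------------------------------------------
# pathway mapping

@dataclass(frozen=True)
class PathwayFixture:
    externals: tuple[ExternalParticipant, ...]
    pro_terms: dict          # canonical string -> PR id
    feature_table: FeatureTable
    fraction_mappable: float


def gen_pathway_set(spec: FixtureSpec) -> PathwayFixture:
    """Pathways whose participants are Reactome-style descriptors or
    feature-id tokens; exactly ``fraction_mappable`` of each pathway's
    participants have their canonical form planted in the term index."""
    rng = random.Random(spec.seed + 3)
    n_map = round(spec.participants_per_pathway * spec.fraction_mappable)
    externals: list[ExternalParticipant] = []
    pro_terms: dict[str, str] = {}
    feature_rows = []
    term_no = 40000000
    used_acc: set[str] = set()

    def fresh_accession() -> str:
        # unique per fixture so an unmapped participant can never collide
        # with a planted canonical string
        while True:
            acc = _rand_accession(rng)
            if acc not in used_acc:
                used_acc.add(acc)
                return acc

    for p in range(spec.n_pathways):
        pw = f"R-HSA-{100000 + p}"
        for j in range(spec.participants_per_pathway):
            acc = fresh_accession()
            ext_id = f"{pw}.{j}"
            style = rng.random()
            if style < 0.5:
                start = rng.randint(1, 200)
                end = start + rng.randint(10, 400)
                symbol = "GENE" + str(rng.randint(1, 999))
                desc = ReactomeDescriptor(f"{symbol}({start}-{end})", acc)
                canonical = f"{acc}, {start}-{end}"
            elif style < 0.75:
                start = rng.randint(1, 200)
                end = start + rng.randint(10, 400)
                fid = f"PRO_{rng.randint(0, 10**10 - 1):010d}"
                feature_rows.append((acc, fid, start, end))
                desc = f"{acc}-{fid}"
                canonical = f"{acc}, {start}-{end}"
            else:
                desc = ReactomeDescriptor("GENE" + str(rng.randint(1, 999)), acc)
                canonical = acc
            externals.append(ExternalParticipant(pw, ext_id, desc))
            if j < n_map:
                term_no += 1
                pro_terms[canonical] = f"PR:{term_no:09d}"
    table = FeatureTable(pd.DataFrame(
        feature_rows, columns=["accession", "feature_id", "start", "end"]))
    return PathwayFixture(tuple(externals), pro_terms, table,
                          n_map / spec.participants_per_pathway)


# ---------------------------------------------------------------------------
# alignment with planted conservation

@dataclass(frozen=True)
class AlignmentFixture:
    alignment: AlignedSet
    ref_id: str
    sites: tuple[tuple[ModSite, str], ...]
    # truth rows: (site index, target id, class, target ungapped pos or None)
    truth: tuple[tuple[int, str, str, Optional[int]], ...]


_NOT_AMENABLE = ["Leu", "Ile", "Val", "Phe", "Gly", "Ala", "Pro"]


def gen_alignment(spec: FixtureSpec) -> AlignmentFixture:
    """Alignment built column-by-column with planted site classifications.

    At each planted site column the reference carries a phosphorylatable
    residue and every target is planted as conserved-modifiable,
    not-amenable (an aliphatic residue) or gap; elsewhere columns get
    random residues with a small gap rate (never a gap in the reference at
    a site column).
    """
    rng = random.Random(spec.seed + 4)
    ids = ["ref"] + [f"sp{i}" for i in range(1, spec.n_sequences)]
    site_cols = sorted(rng.sample(range(1, spec.aln_length + 1), k=spec.n_sites))
    plan: dict[int, dict[str, str]] = {}  # col -> target id -> class
    for col in site_cols:
        plan[col] = {
            sid: rng.choice(
                [SiteClass.CONSERVED, SiteClass.NOT_AMENABLE, SiteClass.GAP]
            )
            for sid in ids[1:]
        }

    aa1 = sorted(AA3_TO_AA1.values())
    columns: dict[str, list[str]] = {sid: [] for sid in ids}
    for col in range(1, spec.aln_length + 1):
        if col in plan:
            ref_res = rng.choice(["Ser", "Thr", "Tyr"])
            columns["ref"].append(AA3_TO_AA1[ref_res])
            for sid in ids[1:]:
                cls = plan[col][sid]
                if cls == SiteClass.GAP:
                    columns[sid].append("-")
                elif cls == SiteClass.CONSERVED:
                    columns[sid].append(
                        AA3_TO_AA1[rng.choice(["Ser", "Thr", "Tyr"])])
                else:
                    columns[sid].append(AA3_TO_AA1[rng.choice(_NOT_AMENABLE)])
        else:
            for sid in ids:
                if sid != "ref" and rng.random() < 0.08:
                    columns[sid].append("-")
                else:
                    columns[sid].append(rng.choice(aa1))

    aln = AlignedSet({sid: "".join(chars) for sid, chars in columns.items()})

    sites: list[tuple[ModSite, str]] = []
    truth: list[tuple[int, str, str, Optional[int]]] = []
    for i, col in enumerate(site_cols):
        ref_pos = sum(1 for c in range(col) if columns["ref"][c] != "-")
        ref_res3 = {v: k for k, v in AA3_TO_AA1.items()}[columns["ref"][col - 1]]
        mod = _PHOSPHO_RESIDUE_MOD[ref_res3]
        sites.append((ModSite(ref_res3, ref_pos), mod))
        for sid in ids[1:]:
            cls = plan[col][sid]
            if cls == SiteClass.GAP:
                truth.append((i, sid, cls, None))
            else:
                tpos = sum(1 for c in range(col) if columns[sid][c] != "-")
                truth.append((i, sid, cls, tpos))
    return AlignmentFixture(aln, "ref", tuple(sites), tuple(truth))


# ---------------------------------------------------------------------------
# on-disk fixture sets

def write_fixture_dir(spec: FixtureSpec, out_dir) -> None:
    """Write a complete fixture set: data files at the top level, planted
    ground truth under ``truth/`` (consumed only by tests)."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)

    recs = gen_records(spec)
    (out / "records.txt").write_text(
        "".join(f"{g.canonical}\n" for g in recs))
    (out / "truth" / "records_canonical.tsv").write_text(
        "".join(f"{i}\t{g.canonical}\n" for i, g in enumerate(recs)))

    ipt = gen_iptmnet_table(spec)
    with open(out / "iptmnet.tsv", "w") as fh:
        fh.write("accession\tresidue\tposition\tptm_type\tsources\tpmids\t"
                 "mentions_multiple_sites\tmentions_other_ptm_types\n")
        for r in ipt.rows:
            fh.write(f"{r.accession}\t{r.residue}\t{r.position}\t{r.ptm_type}\t"
                     f"{';'.join(sorted(r.sources))}\t{';'.join(r.pmids)}\t"
                     f"{int(r.mentions_multiple_sites)}\t"
                     f"{int(r.mentions_other_ptm_types)}\n")
    (out / "curated.txt").write_text(
        "".join(f"{c}\n" for c in sorted(ipt.curated)))
    (out / "truth" / "iptmnet_labels.tsv").write_text(
        "".join(f"{i}\t{lab}\n" for i, lab in enumerate(ipt.labels)))

    his = gen_histome_table(spec)
    with open(out / "histome.tsv", "w") as fh:
        fh.write("accession\tisoform\tmod_type\tresidue\tposition\tpmid\n")
        for r in his.rows:
            fh.write(f"{r.accession}\t{r.isoform or ''}\t{r.mod_type}\t"
                     f"{r.residue}\t{r.position}\t{r.pmid}\n")
    (out / "truth" / "histome_distinct.txt").write_text(f"{his.n_distinct}\n")

    alf = gen_alignment(spec)
    with open(out / "alignment.fasta", "w") as fh:
        for sid in alf.alignment.ids:
            fh.write(f">{sid}\n{alf.alignment.gapped[sid]}\n")
    with open(out / "sites.tsv", "w") as fh:
        fh.write("residue\tposition\tmod_id\n")
        for site, mod in alf.sites:
            fh.write(f"{site.residue}\t{site.position}\t{mod}\n")
    with open(out / "truth" / "conservation.tsv", "w") as fh:
        fh.write("site_index\ttarget_id\tclass\ttarget_position\n")
        for i, sid, cls, pos in alf.truth:
            fh.write(f"{i}\t{sid}\t{cls}\t{'' if pos is None else pos}\n")
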
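"""Equality, subsumption, level assignment, classification, hierarchy."""

import itertools
import random

import pytest

from pfn.converters import ReactomeDescriptor, from_feature_id, from_reactome
from pfn.fixtures import FixtureSpec, gen_records
from pfn.notation import (
    ModBlock,
    ModSite,
    ProteoformRecord,
    SeqBlock,
    canonical_string,
    canonicalize,
    parse,
)
from pfn.semantics import (
    DEFAULT_PHOSPHO_MOD_IDS,
    LevelLabel,
    assign_level,
    build_hierarchy,
    equals,
    infer_parents,
    subsumes,
)


def _constraint_set(rec: ProteoformRecord) -> frozenset:
    """Brute-force oracle: a record as an explicit set of constraints;
    subsumption is then plain subset inclusion."""
    rec = canonicalize(rec)
    cons = {("acc", rec.seq.accession)}
    if rec.seq.isoform is not None:
        cons.add(("iso", rec.seq.isoform))
    if rec.seq.range is not None:
        cons.add(("range", rec.seq.range))
    for b in rec.mods:
        for s in b.sites:
            cons.add(("site", s.position, b.mod_id))
    return frozenset(cons)


def _drop_variants(rec: ProteoformRecord):
    """Oracle for the generalization chain: nested field removal.

    Coordinates are isoform-relative, so generality only increases along
    nested drops: mods first, then range, then isoform.
    """
    rec = canonicalize(rec)
    out = []
    seq = rec.seq
    for variant in (
        ProteoformRecord(seq, ()),
        ProteoformRecord(SeqBlock(seq.accession, seq.isoform, None), ()),
        ProteoformRecord(SeqBlock(seq.accession, None, None), ()),
    ):
        if not equals(variant, rec) and (not out or not equals(variant, out[-1])):
            out.append(variant)
    return out


class TestEquals:
    def test_p25_routes_are_equal(self, p25_feature_table):
        a = from_reactome(ReactomeDescriptor("CDK5R1(99-307)", "Q15078"))
        b = from_feature_id("Q15078-PRO_0000004795", p25_feature_table)
        assert equals(a, b)

    def test_block_input_order_is_irrelevant(self):
        a = parse("P00001, Ser-10, MOD:00046|Thr-30, MOD:00047")
        b = parse("P00001, Thr-30, MOD:00047|Ser-10, MOD:00046")
        assert equals(a, b)

    def test_agrees_with_field_set_oracle_on_seeded_pairs(self, small_batch):
        """500 seeded pairs: equals() iff identical constraint sets."""
        rng = random.Random(41)
        recs = [g.record for g in small_batch]
        for _ in range(500):
            a, b = rng.choice(recs), rng.choice(recs)
            if rng.random() < 0.3:
                b = a  # force some equal pairs
            assert equals(a, b) == (_constraint_set(a) == _constraint_set(b))


class TestSubsumes:
    def test_missing_subsequence_is_broader(self):
        assert subsumes(parse("Q15078"), parse("Q15078, 99-307"))
        assert not subsumes(parse("Q15078, 99-307"), parse("Q15078"))

    def test_subsequence_only_class_subsumes_phosphoform(self):
        general = parse("Q15078, 99-307")
        specific = parse("Q15078, 99-307, Ser-159, MOD:00046")
        assert subsumes(general, specific)
        assert not subsumes(specific, general)

    def test_range_subsumption_requires_equality_not_containment(self):
        assert not subsumes(parse("Q15078, 99-307"), parse("Q15078, 100-200"))

    def test_different_accessions_never_subsume(self):
        assert not subsumes(parse("P00001"), parse("Q15078, 99-307"))

    def test_matches_constraint_subset_oracle(self, small_batch):
        """300 seeded records (+ dropped-field variants): subsumes() is
        exactly constraint-set inclusion."""
        rng = random.Random(43)
        pool = []
        for g in small_batch:
            pool.append(canonicalize(g.record))
            for v in _drop_variants(g.record):
                if rng.random() < 0.3:
                    pool.append(v)
        rng.shuffle(pool)
        pairs = [(rng.choice(pool), rng.choice(pool)) for _ in range(1500)]
        # make sure related pairs are well represented
        for g in small_batch[:100]:
            rec = canonicalize(g.record)
            for v in _drop_variants(rec):
                pairs.append((v, rec))
        for a, b in pairs:
            assert subsumes(a, b) == (_constraint_set(a) <= _constraint_set(b))

    def test_partial_order_properties(self, small_batch):
        recs = [canonicalize(g.record) for g in small_batch[:60]]
        recs += list(itertools.chain.from_iterable(
            _drop_variants(r) for r in recs[:20]))
        for a in recs:
            assert subsumes(a, a)  # reflexive
        for a, b in itertools.permutations(recs[:40], 2):
            if subsumes(a, b) and subsumes(b, a):  # antisymmetric
                assert canonical_string(a) == canonical_string(b)
        rng = random.Random(47)
        for _ in range(2000):  # transitive (sampled)
            a, b, c = (rng.choice(recs) for _ in range(3))
            if subsumes(a, b) and subsumes(b, c):
                assert subsumes(a, c)

    def test_equals_iff_mutual_subsumption(self, small_batch):
        rng = random.Random(53)
        recs = [g.record for g in small_batch]
        for _ in range(300):
            a, b = rng.choice(recs), rng.choice(recs)
            assert equals(a, b) == (subsumes(a, b) and subsumes(b, a))


class TestAssignLevel:
    @pytest.mark.parametrize(
        "text,level",
        [
            ("Q15078", LevelLabel.ORGANISM_GENE),
            ("Q15078-2", LevelLabel.ORGANISM_SEQUENCE),
            ("Q15078, 99-307", LevelLabel.ORGANISM_MODIFICATION),
            ("Q15078-2, 99-307", LevelLabel.ORGANISM_MODIFICATION),
            ("Q15078, Ser-159, MOD:00046", LevelLabel.ORGANISM_MODIFICATION),
        ],
    )
    def test_level_is_total_function_of_populated_fields(self, text, level):
        assert assign_level(parse(text)) == level

    def test_monotone_along_subsumption(self, small_batch):
        order = {LevelLabel.ORGANISM_GENE: 0, LevelLabel.ORGANISM_SEQUENCE: 1,
                 LevelLabel.ORGANISM_MODIFICATION: 2}
        for g in small_batch[:150]:
            rec = canonicalize(g.record)
            chain = [rec] + _drop_variants(rec)
            levels = [order[assign_level(r)] for r in chain]
            assert levels == sorted(levels, reverse=True)


class TestInferParents:
    def test_phospho_block_yields_phosphoprotein(self):
        rec = parse("Q15078, 99-307, Ser-159, MOD:00046")
        result = infer_parents(rec)
        assert "phosphoprotein" in result.categories

    def test_unmodified_record_has_chain_only(self):
        result = infer_parents(parse("Q15078-2, 99-307"))
        assert result.categories == ()
        assert [canonical_string(p) for p in result.parents] == [
            "Q15078-2", "Q15078"]

    def test_non_phospho_modification_is_not_phosphoprotein(self):
        rec = parse("P00001, Lys-9, MOD:00064")
        assert infer_parents(rec).categories == ()

    def test_asserted_non_phospho_with_phospho_block_is_inconsistent(self):
        rec = parse("P00001, Ser-10, MOD:00046")
        result = infer_parents(rec, asserted_non_phospho=True)
        assert result.inconsistencies
        assert "phosphoprotein" in result.categories

    def test_phospho_set_is_configuration(self):
        rec = parse("P00001, Ser-10, MOD:00046")
        assert infer_parents(rec, phospho_mod_ids={"MOD:99999"}).categories == ()

    def test_chain_matches_brute_force_generalizations(self, small_batch):
        """200 seeded records: parents equal the nested-drop enumeration,
        most specific first, with the record itself excluded."""
        for g in small_batch[:200]:
            expected = [canonical_string(v) for v in _drop_variants(g.record)]
            got = [canonical_string(p) for p in infer_parents(g.record).parents]
            assert got == expected


class TestBuildHierarchy:
    def test_three_node_chain(self):
        recs = [parse("Q15078"), parse("Q15078, 99-307"),
                parse("Q15078, 99-307, Ser-159, MOD:00046")]
        edges, warnings = build_hierarchy(recs)
        assert warnings == []
        assert sorted(edges) == [
            ("Q15078, 99-307", "Q15078"),
            ("Q15078, 99-307, Ser-159, MOD:00046", "Q15078, 99-307"),
        ]

    def test_sibling_phosphoforms_branch(self):
        recs = [parse("Q15078-2"),
                parse("Q15078-2, Ser-10, MOD:00046"),
                parse("Q15078-2, Thr-20, MOD:00047")]
        edges, _ = build_hierarchy(recs)
        parents = [p for _, p in edges]
        assert parents == ["Q15078-2", "Q15078-2"]

    def test_duplicates_collapse_with_warning(self):
        recs = [parse("Q15078"), parse("Q15078")]
        edges, warnings = build_hierarchy(recs)
        assert edges == []
        assert len(warnings) == 1

    def test_matches_brute_force_transitive_reduction(self):
        """Random 50-record sets: edges equal the reduction computed
        directly from the full subsumption matrix."""
        for seed in (61, 67, 71):
            batch = gen_records(FixtureSpec(seed=seed, n_records=25))
            pool = []
            for g in batch:
                rec = canonicalize(g.record)
                pool.append(rec)
                pool.extend(_drop_variants(rec))
            seen, recs = set(), []
            for r in pool:
                key = canonical_string(r)
                if key not in seen:
                    seen.add(key)
                    recs.append(r)
            recs = recs[:50]
            edges, _ = build_hierarchy(recs)

            strict = {
                (canonical_string(a), canonical_string(b))
                for a in recs for b in recs
                if canonical_string(a) != canonical_string(b)
                and subsumes(b, a)  # b general, a specific: edge a -> b
            }
            expected = {
                (child, parent)
                for child, parent in strict
                if not any((child, mid) in strict and (mid, parent) in strict
                           for mid in {c for c, _ in strict} | {p for _, p in strict})
            }
            assert set(edges) == expected

    def test_acyclic(self, small_batch):
        import networkx as nx
        recs = [canonicalize(g.record) for g in small_batch[:40]]
        edges, _ = build_hierarchy(recs)
        g = nx.DiGraph(edges)
        assert nx.is_directed_acyclic_graph(g)
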
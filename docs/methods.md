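# Methods

## The notation and its grammar

The package fixes an exact token grammar for the standardized proteoform
representation:

```
record    := seq_block (", " mod_block ("|" mod_block)*)?
seq_block := ACC ("-" INT)? (", " INT "-" INT)?
mod_block := SITE ("/" SITE)* ", " MODID
SITE      := AA3 "-" INT          # e.g. Thr-608
MODID     := "MOD:" DIGIT{5}      # PSI-MOD identifier
```

`ACC` must match the UniProtKB accession pattern (both six- and
ten-character forms). Coordinates are 1-based with inclusive ranges, the
UniProtKB convention. When an isoform number is present, range and site
positions are read relative to that isoform's full-length sequence;
otherwise relative to the representative sequence. Three-letter residue
codes are normalized to Title case; the residue set is the 20 standard
amino acids.

The canonical surface form uses `", "` after commas and bare `|` and `/`
separators; the parser tolerates arbitrary whitespace around all
separators, since source databases vary. Parsing is total: every input
either yields a record or a syntax error carrying the character offset —
there is no silent truncation. A site outside the declared range is a
semantic (not syntax) error at parse time and a reported finding in
`validate`.

After an accession, a dash is ambiguous between an isoform number and a
UniProtKB feature identifier. The converters resolve it by suffix shape:
all digits ⇒ isoform, `PRO_` + 10 digits ⇒ feature lookup. The notation
grammar itself only admits the isoform reading; feature identifiers are
an external dialect that must be resolved through a feature table before
a record exists.

### Canonical form

Canonicalization (a) merges blocks sharing a PSI-MOD id — "grouped by
type of modification" implies one block per type — with the same
(position, type) site asserted twice being a validation error;
(b) sorts sites ascending by position within each block; (c) orders
blocks by the position of the modified residue nearest the N terminus.
When two blocks share their minimum position, the PSI-MOD id breaks the
tie lexicographically; any total order would do, this one is stable and
reproducible. Canonicalization is idempotent and permutation-invariant,
and `serialize` only accepts canonical records, so the canonical string
is a sound equality key.

## Subsumption semantics

A record is read as a conjunction of constraints: the accession, an
optional isoform, an optional exact range, and a set of
(position, PSI-MOD id) sites. Modification semantics are **"at least
these sites"**: a record asserts that the listed sites are modified and
says nothing about other positions. Consequently fewer asserted sites ⇒
a more general class, and `subsumes(general, specific)` is exactly
constraint-set inclusion (isoform unset or equal, range unset or equal,
site set a subset). This is stated prominently because the prose
convention it formalizes is usually left implicit.

Range subsumption requires *equality*, not containment. Nested cleavage
products (residues 1-100 vs 20-80) are not inferred to be related: the
containment reading asserts biology the data model does not state, so
the safe under-approximation was chosen.

Specificity levels are a total function of the populated fields:
accession only ⇒ organism-gene; accession + isoform only ⇒
organism-sequence; any range or modification block ⇒
organism-modification (a bare cleavage product already counts — e.g.
when the only distinction is a removed signal peptide).

`infer_parents` returns the nested generalization chain: strip
modifications, then the range, then the isoform. The nesting is forced
by the coordinate system — positions are isoform-relative, so a variant
that drops the isoform while keeping coordinates would silently change
their meaning; only drops that remove the coordinates first are sound.
On top of the chain a deliberately simple classification rule is
implemented: any block whose PSI-MOD id is in the configured
phosphorylation set (shipped default: the phospho-Ser/Thr/Tyr ids plus
the residue-agnostic phosphorylated-residue id) marks the record a
*phosphoprotein*; a record simultaneously asserted to lack
phosphorylation is reported inconsistent rather than resolved. The
category id set is configuration, not code.

`build_hierarchy` computes the strict-subsumption DAG over distinct
canonical records (duplicates collapse with a warning) and returns its
transitive reduction (networkx). Because distinct canonical records
cannot mutually subsume, the graph is acyclic by construction.

## Term generation

Terms come in two flavours. *Dynamic* gene/sequence-level terms reuse
the UniProtKB accession as their identifier (`PR:E1BE92` in OBO form,
`PR_E1BE92` in OWL form — the two spellings differ only in the
separator) and instantiate the definition template
`"a protein that is a translation product of <gene> in <organism>."`
verbatim. They are marked transient and never persisted to a term store.
*Pipeline* terms get fresh nine-digit ids from a configurable counter
(default start 900000000, far above curated id ranges, never reusing
input ids), deterministic within a factory's lifetime: the same
canonical record always receives the same id. Pipeline terms are flagged
`unreviewed` and must carry at least one PMID evidence cross-reference;
the canonical notation string is embedded in the stanza comment (the
flat-file format offers no dedicated tag for it; a comment keeps it
both human-readable and machine-recoverable).

The OBO 1.4 writer emits a fixed header plus sorted `[Term]` blocks and
the reader inverts it exactly, so a stanza set round-trips
order-normalized. The `unreviewed` flag is carried as a `subset` tag
declared in the header. obonet is used in the test suite as an
independent reader of the emitted documents.

## Pipelines

**Single-site phosphorylation filter.** A row survives iff: its PTM type
is phosphorylation; it is described by ≥ 2 distinct source names
("multiple sources", with a curated database and a text-mining hit both
counting); neither abstract-level flag is set (mentions of additional
modification sites, or of PTM types other than phosphorylation, e.g.
acetylation — these flags are inputs produced by upstream text mining,
not recomputed here); and its canonical single-site record is not
already curated. Rejections carry one reason each, assigned in a fixed
priority order (type, sources, abstract flags, curated) so the reasons
partition the removed set; the filter is stable and idempotent.

**Histone-modification conversion.** Rows of (accession + optional
isoform, modification type, residue, position, PMID) become one
unreviewed stanza per distinct canonical record, merging PMIDs for
repeated sites. The modification-type → PSI-MOD lookup is an editable
TSV keyed by (type, residue) with a `*` fallback row; unmapped types are
rejected with a report, never silently dropped.

**Pathway mapping.** Participants (either descriptor dialect) are
normalized through the converters and matched against an existing
canonical-string → term-id index by exact string equality. Unresolvable
feature identifiers are reported, not fatal. Coverage per pathway is
mapped/total exactly; the report counts pathways at 100% and at a
threshold (default 70%).

## Site projection

Alignments are consumed, not computed: any pre-computed aligned FASTA
(MUSCLE, MAFFT, …) is accepted, removing the external-binary dependency.
Per sequence, mutually inverse maps between 1-based ungapped positions
and 1-based alignment columns are built once. Each reference site is
carried along its column to every other sequence and classified:
*conserved-modifiable* when the aligned residue is in the modification's
residue-compatibility set, *not-amenable* otherwise, *gap* when the
target has no residue in the column. The default phospho compatibility
set is {Ser, Thr, Tyr}, matching the usual highlighting of potentially
phosphorylatable aligned residues; per-modification sets are
configuration (`compat.yaml`), with the phospho set as fallback for
unknown ids, and identical-residue-only logic can be had by supplying
singleton sets. A reference residue that contradicts the site's stated
residue code raises: that is inconsistent input data, not a projection
result.

## Synthetic data

The generator exists so every module is exercised offline with planted
ground truth computed independently of the code under test:

* **Records** (default 1000 per batch): random UniProtKB-shaped
  accessions; isoform present with probability 0.3 (1–4); range present
  with probability 0.4 (start ≤ 300, width ≤ 400); 0–4 modification
  blocks of 1–3 sites drawn from a ten-id PSI-MOD pool. The canonical
  string is computed at generation time by explicit brute-force
  grouping/sorting, and the emitted raw record is shuffled (and one
  block sometimes split in two) so canonicalization has real work to do.
* **Evidence table**: 82 planted survivors plus 25 rows per reject
  reason, each row with a unique (accession, position) so categories
  cannot interact; curated-category rows contribute their canonical
  string to the emitted curated set.
* **Histone table**: 500 rows over 468 planted distinct proteoforms on
  a histone-sized gene set; the surplus rows duplicate earlier sites
  with fresh PMIDs.
* **Pathways**: 10 pathways × 20 participants, a planted 60% of each
  pathway's participants present in the term index; accessions are
  unique per fixture so an unmapped participant can never collide with a
  planted string.
* **Alignments**: 4 sequences × 80 columns with 6 planted site columns;
  at each one the reference carries a phospho-acceptor residue and every
  target is planted conserved / not-amenable (aliphatic residue) / gap;
  elsewhere an 8% gap rate in non-reference rows.

All generators are byte-deterministic under the spec's seed. On disk,
planted truth goes to a `truth/` sidecar directory that the code under
test never reads. The generator emulates the *shape* of curated PTM
resources, not their content: accessions are fictitious, sequences are
i.i.d. residues with no evolutionary model, and abstract-level flags are
sampled rather than text-mined — so passing tests demonstrate the
correctness of the normalization, filtering, counting and projection
logic, not agreement with any real database release. Corpus-scale counts
reported for real resources depend on those resources' versions and are
out of scope.

## Numerical and degenerate-input choices

Everything is exact integer/string computation; there are no tolerances.
Ties in block ordering break on PSI-MOD id; hierarchy edges and OBO
stanzas are emitted sorted for reproducibility. Degenerate inputs:
empty notation strings are syntax errors; an empty stanza set serializes
to a header-only document; an empty record list yields an empty edge
list; pathways with zero participants are excluded from coverage
summaries with a warning.

## Known limitations

* Glycan structures, sequence variants, cross-links and modification
  ambiguity/localization scores are out of scope.
* Range subsumption by containment is deliberately not inferred (see
  above).
* The feature table is a local fixture; live UniProtKB lookup is left as
  an integration hook.
* OWL/RDF output and description-logic reasoning over a full ontology
  release are not implemented; `infer_parents` covers only the
  single-record generalization chain and the phosphoprotein rule.
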
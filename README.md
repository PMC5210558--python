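# pfn — standardized proteoform notation

A library and command-line tool for working with a standardized textual
representation of **proteoforms** — the precise molecular forms of a
protein that arise from alternative splicing, chain cleavage and
post-translational modification (PTM) of one gene's product.

Different resources describe the same proteoform in different ways. A
pathway database may write the p25 cleavage product of CDK5 regulatory
subunit 1 as `CDK5R1(99-307)` with coordinates on the UniProtKB sequence
`Q15078`, while an interaction database refers to the same entity through
the UniProtKB feature identifier `Q15078-PRO_0000004795`. Comparing,
mapping or importing such entries requires normalizing them all into one
canonical form. That is what this package does.

## The representation

A proteoform is written as a *sequence block* followed by optional
*modification blocks*:

```
ACCESSION[-ISOFORM][, START-END][, SITE[/SITE...], MOD:nnnnn[|...]]
```

* the sequence block is a UniProtKB accession, an optional isoform number
  after a dash, and an optional inclusive residue range (for cleavage
  products such as a chain left after signal-peptide removal);
* each modification block lists one or more sites (`Thr-608` style:
  three-letter residue code + 1-based position, slashes between multiple
  sites) followed by the PSI-MOD identifier of the modification type;
* blocks are ordered by the modified residue nearest the N terminus and
  grouped by modification type, separated by pipes;
* when an isoform is stated, all coordinates are relative to that
  isoform's full-length sequence.

Only the accession is required. Omitting the range makes the class more
general (any isoform / species-level product); a range without
modification blocks names a class defined by the subsequence alone.
Example of a full record:

```
P00001-2, 1-100, Ser-10/Ser-20, MOD:00046|Thr-30, MOD:00047
```

On top of the grammar the package provides:

* **canonicalization** — merging blocks of one modification type,
  sorting sites and blocks, producing a unique normal form usable as an
  equality key;
* **converters** for the two external descriptor dialects above;
* **semantics** — equality, subsumption (fewer constraints ⇒ more
  general class), specificity levels (organism-gene / organism-sequence /
  organism-modification), a generalization chain with a simple
  "phosphorylated serine ⇒ phosphoprotein" classification rule, and
  subsumption hierarchies (transitive reduction);
* an **OBO term factory** — dynamic gene-level terms whose identifier
  reuses the UniProtKB accession (`PR:E1BE92` / `PR_E1BE92`), and
  unreviewed modification-level terms minted from import pipelines;
* three **import pipelines** — a single-site phosphorylation evidence
  filter, a histone-modification table converter, and a
  pathway-participant mapper with per-pathway coverage statistics;
* **cross-species site projection** — carrying modification sites
  through a multiple sequence alignment and classifying each aligned
  position as conserved-modifiable, not amenable, or gap;
* a deterministic **synthetic-data generator** so everything is testable
  offline.

## Worked example

The p25 form of CDK5R1 from both external spellings:

```
$ pfn convert --style reactome --label "CDK5R1(99-307)" --accession Q15078
Q15078, 99-307

$ cat features.tsv
accession	feature_id	start	end
Q15078	PRO_0000004795	99	307

$ pfn convert --style feature --token Q15078-PRO_0000004795 --feature-table features.tsv
Q15078, 99-307
```

Both normalize to `Q15078, 99-307`: accession `Q15078`, residues 99-307,
no modification blocks — so the two database entries denote the same
proteoform class. Canonicalization at work:

```
$ pfn canon "P00001, Thr-30, MOD:00047|Ser-10, MOD:00046"
P00001, Ser-10, MOD:00046|Thr-30, MOD:00047
```

The block carrying Ser-10 (the modified residue nearest the N terminus)
moves first. In Python:

```python
from pfn import ReactomeDescriptor, from_reactome, serialize, assign_level
rec = from_reactome(ReactomeDescriptor("CDK5R1(99-307)", "Q15078"))
print(serialize(rec))          # Q15078, 99-307
print(assign_level(rec).value) # organism-modification
```

See `pfn --help` for the remaining subcommands (`validate`, `term`,
`pipeline`, `hierarchy`, `project`, `fixtures`).

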
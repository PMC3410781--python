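# nrseq

A non-redundant, multi-source annotated sequence database keyed by MD5
checksums, with tools to translate identifiers between annotation
namespaces and to map BLAST/BLAT tabular results onto functions, organisms
and functional hierarchies — without recomputing any search.

## The problem

Similarity searching dominates the cost of metagenome analysis, and most of
that cost is spent re-searching the *same* proteins because each reference
database (UniProt-like, KEGG-like, SEED-like, COG-like collections) ships
its own copy under its own identifiers. If every distinct residue string is
stored exactly once under a universal key, one search serves every
annotation source at once.

`nrseq` uses the 32-character hexadecimal MD5 digest of the normalized
residue string as that key:

```
md5 = MD5( uppercase(strip_whitespace(residues)) )      # one trailing '*'
                                                        # stripped (protein)
```

Sequence data and metadata separate cleanly. The sequence set is a single
FASTA file whose headers are md5s and nothing else; each annotation source
("namespace") contributes only tables linking md5s to its native IDs,
function strings, organisms/taxids and hierarchy paths. Adding a namespace
appends metadata only — the sequence set never grows for known sequences.
Identifier translation between namespaces is then a pure join through
shared sequence identity: `from_id -> md5 -> to_id`.

## Worked example

Generate two overlapping 10-sequence sources and build a store:

```python
from nrseq.fixtures import generate_sources
truth = generate_sources("sources", n_sources=2, seqs_per_source=10,
                         overlap_fraction=0.2, seed=7)
```

```sh
$ nrseq build -config build.yaml -out store
INFO nrseq: SRC01: 10 sequences, 10 annotation rows, 0 skipped
INFO nrseq: SRC02: 10 sequences, 10 annotation rows, 0 skipped
INFO nrseq: store: 18 sequences from 2 sources -> store
```

18 = 2 x 10 − 2: the two sources share two sequences, each stored once.
`store/statistics.tsv` reports per-source totals and the elements each
source contributes that no other source has:

```
source  n_ids  unique_added_ids  percent_ids  n_sequences  unique_added_sequences  percent_sequences ...
SRC01   10     10                50.0         10           8                       44.4
SRC02   10     10                50.0         10           8                       44.4
TOTAL   20                                    18
```

Resolve an md5 in any loaded namespace (single-dash flags work too):

```sh
$ nrseq query -store store -md5 6911eb369096ef2369e82bb1d366b06f \
              -option md52overview -source SRC02
6911eb369096ef2369e82bb1d366b06f  SRC02_00007  hypothetical protein family 000  Escherichia coli
```

The same sequence carries a different identifier and annotation in SRC01 —
that is the translation mechanism: same md5, different namespaces.

Map a tabular similarity file (12-column BLAST `-m 8` / `outfmt 6`, subject
field = md5) onto hierarchy categories, counting each read once per
category reached by its best hit:

```sh
$ nrseq sims -store store -sims hits.m8 -source SRC01 --summarize 1
Cellular Processes and Signaling  4
Information Storage and Processing  1
Metabolism  5
# source=SRC01  level=1  queries=17  assigned=10  unassigned=7
```

The footer is the accounting identity: assigned + unassigned = total
queries (here 7 reads hit sequences that are unannotated in SRC01, are
decoys, or lack a hierarchy).

The same operations are available as library calls
(`nrseq.md5s2sets4source`, `nrseq.translate_ids`, `nrseq.annotate_sims`,
...), built for bulk use: resolving 100,000 md5s against a 10,000-sequence
store takes well under a second.

## Layout

- `nrseq.checksum` — normalization + MD5 fingerprinting (the identity rule)
- `nrseq.ingest` — FASTA/TSV source bundles to md5-keyed form
- `nrseq.store` — merge, canonical dumps, load, statistics
- `nrseq.query` — md5/ID resolution and namespace translation
- `nrseq.sims` — similarity-file parsing, filtering, annotation, summaries
- `nrseq.fixtures` — synthetic source generator with ground-truth ledger
- `nrseq.cli` — `nrseq build | query | sims`

See `docs/methods.md` for the model, parameter choices and limitations.
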
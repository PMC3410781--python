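# Methods

## The model

A non-redundant sequence store treats the residue string itself as the
primary entity and every database identifier as metadata about it. The
universal key is the MD5 digest of the normalized residue string, rendered
as 32 lowercase hexadecimal characters. Two records from any sources are
the same sequence exactly when their normalized strings are byte-identical;
MD5 collisions are astronomically unlikely at realistic database sizes and
are treated as identity — but a same-md5/different-residues event during a
merge is *fatal* (`ResidueMismatch`), never silently resolved, because it
can only mean an implementation bug or a genuine collision, and both must
surface.

### Normalization contract

Fingerprints must be invariant to the formatting differences that FASTA
dumps actually exhibit, and to nothing else:

1. all whitespace removed;
2. letters uppercased;
3. for proteins, exactly one trailing `*` (stop) stripped if present.

After these steps only A–Z may remain. `-` gaps and internal stops are
rejected per record (the record is skipped with a logged reason, the build
continues): a gapped string is an alignment artifact, not a sequence.
Ambiguity codes (X, B, Z, J) and extended amino acids (U, O) pass, being
letters. The digest input is one ASCII byte per residue, making digests
bit-exact across implementations. Other fingerprinting pipelines may choose
a different normalization (e.g. keep case); digests here can differ from
theirs for edge-case records — the contract above is this package's
published identity rule.

## Store semantics

- **Merge** is a union keyed by md5. First writer wins for the residue
  string (all writers agree by construction); annotation rows are a
  deduplicated set union. Re-adding an already-known sequence set under a
  new namespace therefore grows only the metadata — the scaling property
  the design exists for.
- **Identity-only rows.** A sequence with no annotation row still enters
  the store with a (md5, source, native_id) record carrying no function or
  organism: presence in a source is itself metadata. Absent values are
  `None`, never `""`, so "no annotation" and "annotation is the empty
  string" stay distinct.
- **Hierarchies** attach to (source, native_id), not to md5s directly:
  membership in a COG-style category is a property of the source's
  identifier, reachable from an md5 via the ID table. They are flat ordered
  paths (1–5 levels, most general first); no DAG semantics.
- **Canonical dumps.** All tables are written deduplicated, sorted
  lexicographically on all columns, unquoted UTF-8 TSV with LF endings; the
  nr FASTA is sorted by md5 and wrapped at 80 columns. Builds are therefore
  byte-reproducible and order-insensitive: permuting source order changes
  no output byte. A `MANIFEST.tsv` lists (file, row count, file-md5).
- **Round trip.** The dump splits annotation records into independent link
  tables (`md52id`, `md52func`, `md52org`), which forgets how functions and
  organisms were grouped into rows. `load_store` re-pairs them when
  unambiguous (one function + one organism per (md5, source)) and otherwise
  attaches values to the lexicographically smallest native id. Equivalence
  after a round trip is defined — and tested — as byte-identical canonical
  re-dumps, not record-set equality.
- **Statistics.** Per source: distinct native IDs, md5s, function strings,
  organism strings; `unique_added_X` = elements present in no other source.
  String matching is exact and case-sensitive (counts are of unique
  representations). The percent column is `unique_added / global distinct
  total`, a convention this package defines explicitly since "percent of
  the database" is otherwise ambiguous.

## Query semantics

Translation runs strictly through shared sequence identity
(`from_id -> md5 -> to_id`), never through function-string matching.
Unknown md5s and native ids yield empty results — in bulk pipelines absence
is data; only an unknown namespace raises, since that is always a caller
bug. Lookups are hash-index joins built once per store (rebuilt after
`add_source`), sized so that ~10^5 resolutions complete in well under a
second on one CPU.

## Similarity mapping

Input is the standard 12-column tabular alignment format; the subject field
must be an md5. Coordinates are carried verbatim (1-based inclusive) —
this module is a join, not an alignment editor. Filtering thresholds
(max e-value, min %identity, min alignment length) default to pass-through;
no cutoff is imposed silently. Best-hit reduction keeps the maximal bit
score, breaking ties by minimal e-value then smallest subject md5, so the
result is deterministic and permutation-invariant.

Category summaries count **distinct queries (reads), not hits**: a query
whose best hit reaches k categories at the chosen level adds 1 to each of
the k. The accounting identity

```
(queries in >= 1 category) + unassigned == total queries
```

is computed and emitted with every summary, so the deliberate double
counting stays auditable. Summaries require best-hit-reduced input; a
duplicate query id is an error rather than a silent double count.

## Synthetic sources

The generator emulates the *structure* of a multi-source build, not
biology:

- residues uniform over the 20 standard amino acids (or ACGT), lengths
  uniform in [30, 300] — chance duplicates are effectively impossible, so
  every duplicate is planted and the expected distinct count is arithmetic
  (`shared + n_sources * unique`), recorded in a ledger at construction
  time along with every native_id↔md5 pair;
- a shared pool of `ceil(overlap_fraction * seqs_per_source)` sequences
  appears in every source under different native ids;
- each identifier independently carries a (function, organism, taxid) row
  with probability 0.8, chosen so a realistic tail of records stays
  identity-only and the unassigned paths of the summary code are always
  exercised; functions are drawn from a pool of ~n/3 strings to create
  within- and cross-source duplication, organisms from five fixed taxa;
- annotated identifiers get one two-level hierarchy path whose top level is
  a function-determined category.

What passing tests on these fixtures shows: the dedup, merge, translation
and accounting machinery is exact. What they do not show: behavior on real
dump formats (vendor parsers are out of scope by design — the generic
FASTA + 4-column TSV dialect is the integration point), real amino-acid
composition, or real hit-score distributions.

A separate brute-force oracle recounts distinct sequences by direct
string-set construction with no hashing, restating the normalization rules
inline, so the md5-keyed pipeline is checked against an independent path.

## Numerical and degenerate-case choices

- Empty store: `write_nr_fasta` refuses rather than writing a headerless
  file.
- A FASTA record whose residues vanish after normalization is skipped, as
  is an annotation row whose native id has no sequence
  (`orphan_annotation`); both are reported, neither aborts a build.
- A native id reused for two distinct sequences within one source is
  accepted: `id2md5` returns both md5s and annotation rows join to both.
- Best-hit ties and all output orderings are resolved lexicographically so
  every artifact is deterministic.
- Sources of different molecule types cannot share a store
  (`MixedMoltype`); protein and nucleotide collections are built
  separately.

## Problem sizes

The test suite and acceptance script run on generated fixtures from
2×10 up to 10×1000 sequences (dedup equivalence across 20 seeded
conditions spanning overlap 0–1), a 10,000-sequence store for the
100,000-lookup bulk check, and ~900-hit similarity files with up to 100%
decoy subjects. These sizes exercise every code path while keeping a full
run in seconds; the data structures are plain dict/set indexes whose cost
is linear in rows, so nothing changes qualitatively at database scale
except memory residency.

## Known limitations

- Metadata lives in memory; tens of millions of rows would need the dump
  tables loaded into an embedded relational store instead. The tabular dump
  is the portable contract for exactly that reason.
- No vendor dump parsers, no download automation, no hosted service, no
  LCA taxonomic binning, no HSP merging, and the package never runs
  BLAST/BLAT — it consumes their tabular output.
- MD5 is used as an identity fingerprint, not for security; that is the
  point of the design, not an oversight.
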
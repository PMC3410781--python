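"""The merged non-redundant store: one sequence per md5, all metadata rows.

Merging is metadata-append-only: once a residue string is present under its
md5, adding further sources only grows the annotation tables. This is what
makes the approach scale — a new namespace costs its metadata, never a copy
of the sequence set.

Persistence is a contract, not an engine: the store dumps to a canonical set
of sorted, unquoted TSV tables plus a reduced-header nr FASTA, and loads
back from them. Canonical ordering (lexicographic on all columns) makes
releases byte-reproducible and diff-able; two builds from the same inputs in
any source order produce identical files.

Files written by :func:`save_store` / :func:`dump_tables`:

* ``nr.fasta``       — one record per md5, header is the md5 and nothing
  else, residues wrapped at 80 columns, records sorted by md5;
* ``md52id.tsv``     — md5, source, native_id;
* ``md52func.tsv``   — md5, source, function;
* ``md52org.tsv``    — md5, source, organism, taxid (taxid cell may be empty);
* ``hierarchy.tsv``  — source, native_id, level1..level5 (padded);
* ``sources.tsv``    — name, moltype;
* ``MANIFEST.tsv``   — filename, row_count, md5-of-file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .checksum import md5_hex
from .errors import (
    DuplicateSourceName,
    EmptyStore,
    IntegrityError,
    MalformedId,
    MissingFile,
    MixedMoltype,
    ResidueMismatch,
    ValidationError,
)
from .ingest import parse_fasta
from .model import (
    AnnotationRecord,
    HierarchyRecord,
    Md5Id,
    Moltype,
    NormalizedSequence,
    SourceBundle,
    SourceStatsRow,
    StoreStats,
)

NR_FASTA = "nr.fasta"
TABLE_FILES = ("md52id.tsv", "md52func.tsv", "md52org.tsv", "hierarchy.tsv",
               "sources.tsv")
MANIFEST_FILE = "MANIFEST.tsv"
_WRAP = 80


@dataclass
class _Index:
    """Lookup structures for bulk identifier resolution."""

    ann_by_md5: dict[Md5Id, dict[str, set[AnnotationRecord]]]
    md5_by_id: dict[tuple[str, str], set[Md5Id]]
    hier_by_id: dict[tuple[str, str], list[tuple[str, ...]]]


@dataclass
class NrStore:
    """Sequences keyed by md5 plus the deduplicated metadata tables."""

    sequences: dict[Md5Id, NormalizedSequence]
    annotations: set[AnnotationRecord]
    hierarchies: set[HierarchyRecord]
    sources: dict[str, Moltype]
    _index: Optional[_Index] = field(default=None, repr=False, compare=False)

    @property
    def moltype(self) -> Moltype:
        return next(iter(self.sources.values()))

    def index(self) -> _Index:
        """Build (once) and return the query index; invalidated by add_source."""
        if self._index is None:
            ann_by_md5: dict[Md5Id, dict[str, set[AnnotationRecord]]] = {}
            md5_by_id: dict[tuple[str, str], set[Md5Id]] = {}
            for ann in self.annotations:
                ann_by_md5.setdefault(ann.md5, {}).setdefault(ann.source, set()).add(ann)
                md5_by_id.setdefault((ann.source, ann.native_id), set()).add(ann.md5)
            hier_by_id: dict[tuple[str, str], list[tuple[str, ...]]] = {}
            for rec in self.hierarchies:
                hier_by_id.setdefault((rec.source, rec.native_id), []).append(rec.levels)
            for paths in hier_by_id.values():
                paths.sort()
            self._index = _Index(ann_by_md5, md5_by_id, hier_by_id)
        return self._index


def _check_bundle_against(store: NrStore, bundle: SourceBundle) -> None:
    if bundle.spec.name in store.sources:
        raise DuplicateSourceName(f"source {bundle.spec.name!r} already merged")
    if bundle.spec.moltype != store.moltype:
        raise MixedMoltype(
            f"source {bundle.spec.name!r} is {bundle.spec.moltype}, "
            f"store is {store.moltype}")


def merge_sources(bundles: Sequence[SourceBundle]) -> NrStore:
    """Merge converted bundles into one non-redundant store.

    The sequence map is the union keyed by md5 (first writer wins; residues
    are identical by construction — a mismatch is fatal). The annotation set
    is the deduplicated union across sources.
    """
    if not bundles:
        raise ValidationError("merge_sources requires at least one bundle")
    first = bundles[0]
    store = NrStore(sequences=dict(first.sequences),
                    annotations=set(first.annotations),
                    hierarchies=set(first.hierarchies),
                    sources={first.spec.name: first.spec.moltype})
    for bundle in bundles[1:]:
        add_source(store, bundle)
    return store


def add_source(store: NrStore, bundle: SourceBundle) -> NrStore:
    """Append one source: metadata always grows, sequences only if new.

    Existing sequence entries are never rewritten; a same-md5 residue
    disagreement raises :class:`ResidueMismatch` (hash collision or
    normalization bug — both must surface).
    """
    _check_bundle_against(store, bundle)
    for md5, seq in bundle.sequences.items():
        existing = store.sequences.get(md5)
        if existing is None:
            store.sequences[md5] = seq
        elif existing.residues != seq.residues:
            raise ResidueMismatch(
                f"md5 {md5} maps to different residue strings "
                f"(store source vs {bundle.spec.name!r})")
    store.annotations.update(bundle.annotations)
    store.hierarchies.update(bundle.hierarchies)
    store.sources[bundle.spec.name] = bundle.spec.moltype
    store._index = None
    return store


def write_nr_fasta(store: NrStore, path: str | os.PathLike) -> int:
    """Write the reduced-header nr FASTA; returns the record count.

    One record per md5, header ``>`` + md5 and nothing else, sorted by md5,
    residues wrapped at 80 columns, LF endings.
    """
    if not store.sequences:
        raise EmptyStore("refusing to write an empty store")
    count = 0
    with open(path, "w", encoding="ascii", newline="\n") as out:
        for md5 in sorted(store.sequences):
            residues = store.sequences[md5].residues
            out.write(f">{md5}\n")
            for i in range(0, len(residues), _WRAP):
                out.write(residues[i:i + _WRAP] + "\n")
            count += 1
    return count


def _write_tsv(path: Path, rows: Iterable[tuple[str, ...]]) -> int:
    """Sorted, deduplicated, unquoted TSV; returns the row count."""
    unique = sorted(set(rows))
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        for row in unique:
            out.write("\t".join(row) + "\n")
    return len(unique)


def dump_tables(store: NrStore, directory: str | os.PathLike) -> list[tuple[str, int, str]]:
    """Write the canonical metadata tables and the manifest.

    Rows are deduplicated and sorted lexicographically by all columns. A row
    appears in md52func.tsv / md52org.tsv only when the value is present
    (absent is not the empty string). The manifest lists (filename,
    row_count, md5-of-file) for every table, plus the nr FASTA when it is
    present in the directory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    tables: dict[str, list[tuple[str, ...]]] = {name: [] for name in TABLE_FILES}
    for ann in store.annotations:
        tables["md52id.tsv"].append((ann.md5, ann.source, ann.native_id))
        if ann.function is not None:
            tables["md52func.tsv"].append((ann.md5, ann.source, ann.function))
        if ann.organism is not None:
            taxid = "" if ann.taxid is None else str(ann.taxid)
            tables["md52org.tsv"].append((ann.md5, ann.source, ann.organism, taxid))
    for rec in store.hierarchies:
        levels = rec.levels + ("",) * (5 - len(rec.levels))
        tables["hierarchy.tsv"].append((rec.source, rec.native_id) + levels)
    for name, moltype in store.sources.items():
        tables["sources.tsv"].append((name, moltype))

    manifest: list[tuple[str, int, str]] = []
    for name in TABLE_FILES:
        n = _write_tsv(directory / name, tables[name])
        manifest.append((name, n, md5_hex((directory / name).read_bytes())))

    fasta = directory / NR_FASTA
    if fasta.exists():
        n_records = sum(1 for line in fasta.open(encoding="ascii")
                        if line.startswith(">"))
        manifest.append((NR_FASTA, n_records, md5_hex(fasta.read_bytes())))

    manifest.sort()
    with open(directory / MANIFEST_FILE, "w", encoding="utf-8", newline="\n") as out:
        for name, n, digest in manifest:
            out.write(f"{name}\t{n}\t{digest}\n")
    return manifest


def save_store(store: NrStore, directory: str | os.PathLike) -> list[tuple[str, int, str]]:
    """Write nr FASTA + tables + manifest into one directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_nr_fasta(store, directory / NR_FASTA)
    return dump_tables(store, directory)


def _table_md5(cell: str, filename: str) -> Md5Id:
    try:
        return Md5Id(cell)
    except MalformedId:
        raise IntegrityError(f"{filename}: corrupt md5 {cell!r}") from None


def load_store(directory: str | os.PathLike) -> NrStore:
    """Load a store from a complete dump directory.

    ``load(dump(S))`` reproduces a store whose canonical dump is
    byte-identical to the original's. Referential integrity is enforced: any
    table md5 absent from the FASTA, or any FASTA record without an ID row,
    raises :class:`IntegrityError` naming the md5.
    """
    directory = Path(directory)
    for name in (NR_FASTA,) + TABLE_FILES:
        if not (directory / name).exists():
            raise MissingFile(f"missing {name} in {directory}")

    sources: dict[str, Moltype] = {}
    for line in (directory / "sources.tsv").read_text(encoding="utf-8").splitlines():
        name, moltype = line.split("\t")
        if moltype not in ("protein", "nucleotide"):
            raise IntegrityError(f"sources.tsv: bad moltype {moltype!r}")
        sources[name] = moltype  # type: ignore[assignment]
    if not sources:
        raise IntegrityError("sources.tsv is empty")
    moltypes = set(sources.values())
    if len(moltypes) > 1:
        raise IntegrityError("sources.tsv mixes molecule types")
    moltype = moltypes.pop()

    sequences: dict[Md5Id, NormalizedSequence] = {}
    with open(directory / NR_FASTA, encoding="ascii") as handle:
        for record in parse_fasta(handle):
            md5 = _table_md5(record.native_id, NR_FASTA)
            sequences[md5] = NormalizedSequence(residues=record.residues,
                                                moltype=moltype)

    # Per (md5, source): the dump stores native ids, functions and organisms
    # as independent link tables, so records are rebuilt as identity rows
    # plus value rows on a representative native id — the canonical re-dump
    # is identical either way.
    ids: dict[tuple[Md5Id, str], set[str]] = {}
    for line in (directory / "md52id.tsv").read_text(encoding="utf-8").splitlines():
        md5_text, source, native_id = line.split("\t")
        md5 = _table_md5(md5_text, "md52id.tsv")
        if md5 not in sequences:
            raise IntegrityError(f"md52id.tsv: md5 {md5} absent from {NR_FASTA}")
        if source not in sources:
            raise IntegrityError(f"md52id.tsv: unknown source {source!r}")
        ids.setdefault((md5, source), set()).add(native_id)

    for md5 in sequences:
        if not any(key[0] == md5 for key in ids):
            raise IntegrityError(f"{NR_FASTA}: md5 {md5} has no ID row")

    rep = {key: min(native_ids) for key, native_ids in ids.items()}

    functions: dict[tuple[Md5Id, str], list[str]] = {}
    for line in (directory / "md52func.tsv").read_text(encoding="utf-8").splitlines():
        md5_text, source, function = line.split("\t")
        md5 = _table_md5(md5_text, "md52func.tsv")
        if md5 not in sequences:
            raise IntegrityError(f"md52func.tsv: md5 {md5} absent from {NR_FASTA}")
        if (md5, source) not in rep:
            raise IntegrityError(f"md52func.tsv: ({md5}, {source}) has no ID row")
        functions.setdefault((md5, source), []).append(function)

    organisms: dict[tuple[Md5Id, str], list[tuple[str, Optional[int]]]] = {}
    for line in (directory / "md52org.tsv").read_text(encoding="utf-8").splitlines():
        md5_text, source, organism, taxid_text = line.split("\t")
        md5 = _table_md5(md5_text, "md52org.tsv")
        if md5 not in sequences:
            raise IntegrityError(f"md52org.tsv: md5 {md5} absent from {NR_FASTA}")
        if (md5, source) not in rep:
            raise IntegrityError(f"md52org.tsv: ({md5}, {source}) has no ID row")
        taxid = int(taxid_text) if taxid_text else None
        organisms.setdefault((md5, source), []).append((organism, taxid))

    annotations: set[AnnotationRecord] = set()
    for key, native_ids in ids.items():
        md5, source = key
        funcs = functions.get(key, [])
        orgs = organisms.get(key, [])
        if len(funcs) == 1 and len(orgs) == 1:
            # unambiguous pairing: rebuild one combined record
            annotations.add(AnnotationRecord(
                md5=md5, source=source, native_id=rep[key],
                function=funcs[0], organism=orgs[0][0], taxid=orgs[0][1]))
        else:
            for function in funcs:
                annotations.add(AnnotationRecord(
                    md5=md5, source=source, native_id=rep[key],
                    function=function))
            for organism, taxid in orgs:
                annotations.add(AnnotationRecord(
                    md5=md5, source=source, native_id=rep[key],
                    organism=organism, taxid=taxid))
        # identity rows cover the remaining native ids of this (md5, source)
        for native_id in native_ids:
            if native_id != rep[key] or (not funcs and not orgs):
                annotations.add(AnnotationRecord(md5=md5, source=source,
                                                 native_id=native_id))

    hierarchies: set[HierarchyRecord] = set()
    for line in (directory / "hierarchy.tsv").read_text(encoding="utf-8").splitlines():
        cells = line.split("\t")
        source, native_id, levels = cells[0], cells[1], cells[2:]
        while levels and levels[-1] == "":
            levels.pop()
        hierarchies.add(HierarchyRecord(source=source, native_id=native_id,
                                        levels=tuple(levels)))

    return NrStore(sequences=sequences, annotations=annotations,
                   hierarchies=hierarchies, sources=sources)


def compute_statistics(store: NrStore) -> StoreStats:
    """Per-source totals and unique-added counts, plus global distinct totals.

    For each source the distinct native IDs, sequences (md5s), function
    strings and organism strings are counted; ``unique_added`` is the subset
    occurring in no other source. Matching is exact and case-sensitive —
    counts are of unique representations, with no fuzzy merging.
    """
    kinds = ("ids", "sequences", "functions", "organisms")
    per_source: dict[str, dict[str, set]] = {
        name: {k: set() for k in kinds} for name in store.sources}
    for ann in store.annotations:
        sets = per_source[ann.source]
        sets["ids"].add(ann.native_id)
        sets["sequences"].add(ann.md5)
        if ann.function is not None:
            sets["functions"].add(ann.function)
        if ann.organism is not None:
            sets["organisms"].add(ann.organism)

    totals = {k: set().union(*(per_source[s][k] for s in per_source))
              for k in kinds}

    rows = []
    for name in store.sources:
        sets = per_source[name]
        others = {k: set().union(*(per_source[o][k] for o in per_source if o != name))
                  if len(per_source) > 1 else set() for k in kinds}
        rows.append(SourceStatsRow(
            source=name,
            n_ids=len(sets["ids"]),
            n_sequences=len(sets["sequences"]),
            n_functions=len(sets["functions"]),
            n_organisms=len(sets["organisms"]),
            unique_added_ids=len(sets["ids"] - others["ids"]),
            unique_added_sequences=len(sets["sequences"] - others["sequences"]),
            unique_added_functions=len(sets["functions"] - others["functions"]),
            unique_added_organisms=len(sets["organisms"] - others["organisms"]),
        ))
    rows.sort(key=lambda r: r.source)
    return StoreStats(per_source=tuple(rows),
                      total_ids=len(totals["ids"]),
                      total_sequences=len(totals["sequences"]),
                      total_functions=len(totals["functions"]),
                      total_organisms=len(totals["organisms"]))
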
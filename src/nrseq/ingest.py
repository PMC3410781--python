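"""Convert one source bundle (FASTA + annotation tables) to md5-keyed form.

This is the "convert" step of the build: every FASTA record is normalized
and fingerprinted, sequences are deduplicated within the source, and the
tabular metadata is joined on the source-native identifier. Per-record
failures (bad residues, annotation rows for unknown identifiers) are logged
and collected in the bundle's ``skipped`` list rather than aborting the
batch — real source dumps are dirty and the build must complete.

Input dialects (the documented integration points):

* FASTA — any line wrapping, blank lines between records tolerated; the
  identifier is the header token up to the first whitespace.
* Annotation table — UTF-8 TSV, four columns ``native_id, function,
  organism, taxid``; an optional header row is recognized by its first cell
  being literally ``native_id``; empty cell means absent.
* Hierarchy table — UTF-8 TSV, ``native_id`` followed by 1-5 level cells,
  most general first; trailing empty cells are trimmed.

No adapters for vendor dump formats (GenBank flat files, KEGG KO dumps, SEED
exports) ship; sources are expected in the generic dialects above.
"""

from __future__ import annotations

import csv
import logging
from itertools import chain
from typing import IO, Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .checksum import compute_md5_id, normalize_sequence
from .errors import (
    BadTaxid,
    EmptyHierarchy,
    EmptySequence,
    IllegalCharacter,
    MalformedFasta,
    MalformedRow,
    SourceEmpty,
)
from .model import (
    AnnotationRecord,
    HierarchyRecord,
    Md5Id,
    NormalizedSequence,
    RawSequenceRecord,
    SourceBundle,
    SourceSpec,
)

logger = logging.getLogger(__name__)

AnnotationRow = tuple[str, Optional[str], Optional[int], Optional[int]]


def parse_fasta(stream: Iterable[str]) -> Iterator[RawSequenceRecord]:
    """Yield one record per ``>`` header.

    Raises :class:`MalformedFasta` on sequence data before the first header
    or on an empty header token.
    """
    lines = iter(stream)
    first = None
    for line in lines:
        if line.strip():
            first = line
            break
    if first is None:
        return
    if not first.lstrip().startswith(">"):
        raise MalformedFasta("sequence data before first '>' header")
    for title, residues in SimpleFastaParser(chain([first.lstrip()], lines)):
        parts = title.split(None, 1)
        if not parts:
            raise MalformedFasta("empty FASTA header token")
        native_id = parts[0]
        description = parts[1] if len(parts) == 2 else ""
        yield RawSequenceRecord(native_id=native_id, description=description,
                                residues=residues)


def _tsv_rows(stream: Iterable[str]) -> Iterator[tuple[int, list[str]]]:
    """(line number, cells) for nonblank lines; no quoting, literal tabs split."""
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        yield lineno, line.split("\t")


def parse_annotation_table(stream: Iterable[str], spec: SourceSpec
                           ) -> Iterator[tuple[str, Optional[str], Optional[str], Optional[int]]]:
    """Yield (native_id, function, organism, taxid) tuples.

    Empty cells become ``None``; taxid must parse as a positive integer when
    present.
    """
    for lineno, cells in _tsv_rows(stream):
        if lineno == 1 and cells and cells[0] == "native_id":
            continue
        if len(cells) != 4:
            raise MalformedRow(
                f"{spec.name}: line {lineno}: expected 4 columns, got {len(cells)}")
        native_id, function, organism, taxid_text = (c if c != "" else None for c in cells)
        if native_id is None:
            raise MalformedRow(f"{spec.name}: line {lineno}: empty native_id")
        taxid: Optional[int] = None
        if taxid_text is not None:
            try:
                taxid = int(taxid_text)
            except ValueError:
                raise BadTaxid(
                    f"{spec.name}: line {lineno}: taxid {taxid_text!r} is not an integer"
                ) from None
            if taxid <= 0:
                raise BadTaxid(f"{spec.name}: line {lineno}: taxid {taxid} is not positive")
        yield native_id, function, organism, taxid


def parse_hierarchy_table(stream: Iterable[str], spec: SourceSpec
                          ) -> Iterator[HierarchyRecord]:
    """Yield hierarchy paths: native_id then 1-5 level cells, general first."""
    for lineno, cells in _tsv_rows(stream):
        if lineno == 1 and cells and cells[0] == "native_id":
            continue
        native_id, levels = cells[0], cells[1:]
        if native_id == "":
            raise MalformedRow(f"{spec.name}: line {lineno}: empty native_id")
        while levels and levels[-1] == "":
            levels.pop()
        if not levels:
            raise EmptyHierarchy(f"{spec.name}: line {lineno}: no hierarchy levels")
        if "" in levels:
            raise MalformedRow(f"{spec.name}: line {lineno}: empty internal level cell")
        if len(levels) > 5:
            raise MalformedRow(
                f"{spec.name}: line {lineno}: {len(levels)} levels exceed the maximum of 5")
        yield HierarchyRecord(source=spec.name, native_id=native_id,
                              levels=tuple(levels))


def convert_source(spec: SourceSpec) -> SourceBundle:
    """Parse, normalize and fingerprint one source.

    Every FASTA record that survives normalization enters the sequence map;
    distinct native identifiers sharing a residue string share one md5.
    Annotation rows are joined on native_id; FASTA records without any
    annotation row yield an identity-only record (presence in a source is
    itself metadata). Rows whose native_id has no FASTA record are skipped
    with reason ``orphan_annotation``.
    """
    sequences: dict[Md5Id, NormalizedSequence] = {}
    id2md5s: dict[str, list[Md5Id]] = {}
    skipped: list[tuple[str, str]] = []

    with open(spec.fasta_path, encoding="utf-8") as handle:
        for record in parse_fasta(handle):
            try:
                seq = normalize_sequence(record.residues, spec.moltype)
            except (EmptySequence, IllegalCharacter) as exc:
                skipped.append((record.native_id, str(exc)))
                continue
            md5 = compute_md5_id(seq)
            sequences.setdefault(md5, seq)
            bucket = id2md5s.setdefault(record.native_id, [])
            if md5 not in bucket:
                bucket.append(md5)

    if not sequences:
        raise SourceEmpty(f"{spec.name}: no sequences survived conversion")

    annotations: list[AnnotationRecord] = []
    annotated_ids: set[str] = set()
    if spec.annotation_path is not None:
        with open(spec.annotation_path, encoding="utf-8") as handle:
            for native_id, function, organism, taxid in parse_annotation_table(handle, spec):
                md5s = id2md5s.get(native_id)
                if md5s is None:
                    skipped.append((native_id, "orphan_annotation"))
                    continue
                annotated_ids.add(native_id)
                for md5 in md5s:
                    annotations.append(AnnotationRecord(
                        md5=md5, source=spec.name, native_id=native_id,
                        function=function, organism=organism, taxid=taxid))

    for native_id, md5s in id2md5s.items():
        if native_id not in annotated_ids:
            for md5 in md5s:
                annotations.append(AnnotationRecord(
                    md5=md5, source=spec.name, native_id=native_id))

    hierarchies: list[HierarchyRecord] = []
    if spec.hierarchy_path is not None:
        with open(spec.hierarchy_path, encoding="utf-8") as handle:
            hierarchies.extend(parse_hierarchy_table(handle, spec))

    if skipped:
        logger.info("%s: skipped %d record(s) during conversion", spec.name, len(skipped))
    return SourceBundle(spec=spec, sequences=sequences, annotations=annotations,
                        hierarchies=hierarchies, skipped=skipped)
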
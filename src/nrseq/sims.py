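"""Map similarity-search results onto annotation namespaces.

A BLAST or BLAT run against the nr FASTA produces 12-column tabular output
(query, subject, %identity, alignment length, mismatches, gap openings,
query start/end, subject start/end, e-value, bit score) whose subject field
is an md5. Because the subject is a universal sequence key, one search can
be re-interpreted in every loaded namespace without recomputation: this
module parses, filters, best-hit-reduces, annotates and summarizes such
files. Running the aligner itself is out of scope — the contribution is the
mapping, not the search.

Read-abundance semantics: a summary counts distinct queries (reads), not
hits. A query whose best hit reaches k hierarchy categories adds 1 to each
of the k; the accounting identity

    (queries appearing in >= 1 category) + n_unassigned == total queries

always holds and is reported alongside the table so double counting stays
auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from .checksum import validate_md5_id
from .errors import MalformedSimLine, NotBestHitReduced, UnknownSource, ValidationError
from .model import AnnotatedHit, SimHit
from .query import _check_source, id2hierarchy
from .store import NrStore


def parse_m8(stream: Iterable[str]) -> Iterator[SimHit]:
    """Yield one :class:`SimHit` per data line of a tabular similarity file.

    Lines beginning ``#`` and blank lines are skipped. The subject field is
    validated as an md5 (:class:`~nrseq.errors.MalformedId` otherwise);
    e-values accept scientific notation.
    """
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise MalformedSimLine(
                f"line {lineno}: expected 12 tab-separated fields, got {len(fields)}")
        try:
            yield SimHit(
                query_id=fields[0],
                subject_md5=validate_md5_id(fields[1]),
                pct_identity=float(fields[2]),
                aln_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_openings=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                e_value=float(fields[10]),
                bit_score=float(fields[11]),
            )
        except ValidationError:
            raise
        except ValueError as exc:
            raise MalformedSimLine(f"line {lineno}: {exc}") from None


def filter_hits(hits: Iterable[SimHit], max_evalue: float = math.inf,
                min_identity: float = 0.0, min_length: int = 0
                ) -> Iterator[SimHit]:
    """Keep hits passing all thresholds; the defaults pass everything."""
    if max_evalue < 0 or min_identity < 0 or min_length < 0:
        raise ValidationError("filter thresholds must be nonnegative")
    for hit in hits:
        if (hit.e_value <= max_evalue and hit.pct_identity >= min_identity
                and hit.aln_length >= min_length):
            yield hit


def best_hit_per_query(hits: Iterable[SimHit]) -> Iterator[SimHit]:
    """One hit per query: maximal bit score, ties by minimal e-value, then
    lexicographically smallest subject md5. Output is sorted by query id, so
    the result is invariant to input permutation."""
    best: dict[str, SimHit] = {}
    for hit in hits:
        rank = (-hit.bit_score, hit.e_value, hit.subject_md5)
        current = best.get(hit.query_id)
        if current is None or rank < (-current.bit_score, current.e_value,
                                      current.subject_md5):
            best[hit.query_id] = hit
    for query_id in sorted(best):
        yield best[query_id]


def annotate_sims(store: NrStore, hits: Iterable[SimHit], source: str
                  ) -> Iterator[AnnotatedHit]:
    """Join each hit with its subject's records in the chosen namespace.

    Conservative: every input hit yields exactly one :class:`AnnotatedHit`,
    in input order; a subject with no record in the source yields an empty
    annotation set.
    """
    _check_source(store, source)
    index = store.index()
    for hit in hits:
        anns = index.ann_by_md5.get(hit.subject_md5, {}).get(source, set())
        yield AnnotatedHit(hit=hit, source=source, annotations=frozenset(anns))


@dataclass(frozen=True)
class CategorySummary:
    """Read abundance per hierarchy category, with the accounting identity."""

    source: str
    level: int
    counts: tuple[tuple[str, int], ...]  # (category, n_queries), sorted
    n_queries: int
    n_assigned: int       # queries reaching >= 1 category
    n_unassigned: int

    def __post_init__(self) -> None:
        assert self.n_assigned + self.n_unassigned == self.n_queries


def summarize_by_category(store: NrStore, annotated: Iterable[AnnotatedHit],
                          source: str, level: int = 1) -> CategorySummary:
    """Read abundance per hierarchy category at the given depth.

    Requires best-hit-reduced input (one hit per query); a duplicate query id
    raises :class:`NotBestHitReduced`. Each query counts once per distinct
    category its annotations reach at level ``level``; queries with no
    annotation, or whose identifiers lack a path that deep, count as
    unassigned.
    """
    _check_source(store, source)
    if level < 1:
        raise ValidationError("level must be >= 1")
    seen: set[str] = set()
    counts: dict[str, int] = {}
    n_assigned = 0
    n_unassigned = 0
    for row in annotated:
        query_id = row.hit.query_id
        if query_id in seen:
            raise NotBestHitReduced(f"duplicate query id {query_id!r}")
        seen.add(query_id)
        categories: set[str] = set()
        for ann in row.annotations:
            for path in id2hierarchy(store, ann.native_id, source):
                if len(path) >= level:
                    categories.add(path[level - 1])
        if categories:
            n_assigned += 1
            for cat in categories:
                counts[cat] = counts.get(cat, 0) + 1
        else:
            n_unassigned += 1
    return CategorySummary(source=source, level=level,
                           counts=tuple(sorted(counts.items())),
                           n_queries=len(seen), n_assigned=n_assigned,
                           n_unassigned=n_unassigned)


def format_annotated_tsv(rows: Iterable[AnnotatedHit]) -> Iterator[str]:
    """Annotated hits as TSV lines: the 12 m8 columns + source, native_id,
    function, organism. One line per hit; multiple annotations are joined
    with '; ' in sorted order so the row count equals the hit count. A final
    '#' footer carries the accounting."""
    n_hits = n_annotated = 0
    for row in rows:
        h = row.hit
        anns = sorted(row.annotations,
                      key=lambda a: (a.native_id, a.function or "", a.organism or ""))
        join = lambda vals: "; ".join(dict.fromkeys(v for v in vals if v is not None))
        yield "\t".join(str(x) for x in (
            h.query_id, h.subject_md5, h.pct_identity, h.aln_length,
            h.mismatches, h.gap_openings, h.q_start, h.q_end, h.s_start,
            h.s_end, h.e_value, h.bit_score, row.source,
            join(a.native_id for a in anns), join(a.function for a in anns),
            join(a.organism for a in anns)))
        n_hits += 1
        n_annotated += bool(row.annotations)
    yield (f"# hits={n_hits}\tannotated={n_annotated}\t"
           f"unannotated={n_hits - n_annotated}")


def format_summary_tsv(summary: CategorySummary) -> Iterator[str]:
    """Category summary as TSV lines plus the accounting footer."""
    for category, n in summary.counts:
        yield f"{category}\t{n}"
    yield (f"# source={summary.source}\tlevel={summary.level}\t"
           f"queries={summary.n_queries}\tassigned={summary.n_assigned}\t"
           f"unassigned={summary.n_unassigned}")
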
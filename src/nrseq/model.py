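"""Domain types shared by every module.

The data model mirrors the schema of an MD5-keyed non-redundant sequence
database: one canonical residue string per 32-hex-character MD5 identifier,
with any number of per-source metadata rows (native identifiers, function
strings, organism names, taxonomy IDs, functional-hierarchy paths) attached
to that key. Sequence data and metadata are deliberately separate: adding a
new annotation source appends metadata rows only.

All types validate their invariants at construction time and raise
:class:`~nrseq.errors.ValidationError` subclasses on violation. Missing
function/organism values are represented as ``None``, never as the empty
string, so "no annotation" and "annotation is ''" stay distinguishable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Literal, Optional

from .errors import MalformedId, ValidationError

Moltype = Literal["protein", "nucleotide"]
MOLTYPES = ("protein", "nucleotide")

_HEX = set(string.hexdigits.lower())
_UPPER = set(string.ascii_uppercase)


class Md5Id(str):
    """A 32-character lowercase hexadecimal MD5 fingerprint.

    The universal sequence key. Uppercase hex input is accepted and
    canonicalized to lowercase; anything else is rejected.
    """

    __slots__ = ()

    def __new__(cls, value: str) -> "Md5Id":
        if not isinstance(value, str):
            raise MalformedId(f"MD5 ID must be a string, got {type(value).__name__}")
        text = value.lower()
        if len(text) != 32:
            raise MalformedId(f"MD5 ID must have 32 characters, got {len(text)}: {value!r}")
        if not set(text) <= _HEX:
            bad = next(c for c in text if c not in _HEX)
            raise MalformedId(f"MD5 ID contains non-hexadecimal character {bad!r}: {value!r}")
        return super().__new__(cls, text)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _check_moltype(moltype: str) -> None:
    _require(moltype in MOLTYPES, f"moltype must be one of {MOLTYPES}, got {moltype!r}")


def _check_opt_str(value: Optional[str], name: str) -> None:
    if value is not None:
        _require(isinstance(value, str) and value != "",
                 f"{name} must be None or a nonempty string, got {value!r}")


@dataclass(frozen=True)
class RawSequenceRecord:
    """One FASTA record exactly as read: identifier, description, residues."""

    native_id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        _require(self.native_id != "", "native_id must be nonempty")


@dataclass(frozen=True)
class NormalizedSequence:
    """A residue string after normalization: uppercase, A-Z only, nonempty."""

    residues: str
    moltype: Moltype

    def __post_init__(self) -> None:
        _check_moltype(self.moltype)
        _require(len(self.residues) >= 1, "normalized sequence must be nonempty")
        _require(set(self.residues) <= _UPPER,
                 "normalized residues must contain only A-Z")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NrSequenceEntry:
    """One non-redundant sequence: the fingerprint plus its residue string."""

    md5: Md5Id
    sequence: NormalizedSequence

    def __post_init__(self) -> None:
        # import here: checksum is the digest authority, model must not cycle
        from .checksum import compute_md5_id

        _require(self.md5 == compute_md5_id(self.sequence),
                 f"md5 {self.md5} does not match the sequence checksum")


@dataclass(frozen=True)
class AnnotationRecord:
    """One (md5, source, native id, function, organism, taxid) fact row.

    A row with ``function is None and organism is None`` is an identity-only
    record: it states that the source contains the sequence, nothing more.
    """

    md5: Md5Id
    source: str
    native_id: str
    function: Optional[str] = None
    organism: Optional[str] = None
    taxid: Optional[int] = None

    def __post_init__(self) -> None:
        _require(isinstance(self.md5, Md5Id), "md5 must be an Md5Id")
        _require(self.source != "", "source must be nonempty")
        _require(self.native_id != "", "native_id must be nonempty")
        _check_opt_str(self.function, "function")
        _check_opt_str(self.organism, "organism")
        if self.taxid is not None:
            _require(isinstance(self.taxid, int) and not isinstance(self.taxid, bool)
                     and self.taxid > 0,
                     f"taxid must be a positive integer, got {self.taxid!r}")


@dataclass(frozen=True)
class HierarchyRecord:
    """An ordered functional-hierarchy path attached to a source identifier.

    Keyed by (source, native_id): hierarchy membership is a property of the
    source's identifier (e.g. a COG), reachable from an md5 via the ID table.
    Paths are flat ordered label lists, most general first, 1-5 levels.
    """

    source: str
    native_id: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        _require(self.source != "", "source must be nonempty")
        _require(self.native_id != "", "native_id must be nonempty")
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        _require(1 <= len(levels) <= 5,
                 f"hierarchy must have 1-5 levels, got {len(levels)}")
        _require(all(isinstance(x, str) and x != "" for x in levels),
                 "hierarchy levels must be nonempty strings")


@dataclass(frozen=True)
class SourceSpec:
    """Where one source bundle lives on disk and what it contains."""

    name: str
    moltype: Moltype
    fasta_path: str
    annotation_path: Optional[str] = None
    hierarchy_path: Optional[str] = None

    def __post_init__(self) -> None:
        _require(self.name != "", "source name must be nonempty")
        _require("\t" not in self.name and "\n" not in self.name,
                 "source name must not contain tab or newline")
        _check_moltype(self.moltype)


@dataclass(frozen=True)
class SimHit:
    """One 12-field tabular similarity line (BLAST -m 8 / outfmt 6).

    Coordinates are carried verbatim in the aligner's convention (1-based,
    inclusive) and never renormalized.
    """

    query_id: str
    subject_md5: Md5Id
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        _require(isinstance(self.subject_md5, Md5Id), "subject_md5 must be an Md5Id")
        _require(0.0 <= self.pct_identity <= 100.0,
                 f"pct_identity must be in [0, 100], got {self.pct_identity}")
        _require(self.aln_length >= 1, "aln_length must be positive")
        _require(self.mismatches >= 0, "mismatches must be nonnegative")
        _require(self.gap_openings >= 0, "gap_openings must be nonnegative")
        for name in ("q_start", "q_end", "s_start", "s_end"):
            _require(getattr(self, name) >= 1, f"{name} must be >= 1")
        _require(self.e_value >= 0.0, "e_value must be nonnegative")


@dataclass(frozen=True)
class AnnotatedHit:
    """A similarity hit joined with its subject's records in one namespace.

    The annotation set may be empty: a hit whose subject carries no record in
    the requested source is retained and flagged unannotated, never dropped.
    """

    hit: SimHit
    source: str
    annotations: frozenset[AnnotationRecord]

    def __post_init__(self) -> None:
        object.__setattr__(self, "annotations", frozenset(self.annotations))
        for ann in self.annotations:
            _require(ann.md5 == self.hit.subject_md5,
                     "annotation md5 does not match the hit subject")
            _require(ann.source == self.source,
                     "annotation source does not match the requested source")


@dataclass(frozen=True)
class SourceStatsRow:
    """Per-source totals and unique-added counts.

    ``unique_added_X`` counts elements present in this source and in no other
    loaded source; string comparison for functions and organisms is exact and
    case-sensitive (counts are of unique representations).
    """

    source: str
    n_ids: int
    n_sequences: int
    n_functions: int
    n_organisms: int
    unique_added_ids: int
    unique_added_sequences: int
    unique_added_functions: int
    unique_added_organisms: int

    def __post_init__(self) -> None:
        for kind in ("ids", "sequences", "functions", "organisms"):
            total = getattr(self, f"n_{kind}")
            unique = getattr(self, f"unique_added_{kind}")
            _require(0 <= unique <= total,
                     f"unique_added_{kind}={unique} outside [0, n_{kind}={total}]")


@dataclass(frozen=True)
class StoreStats:
    """Figure-of-merit statistics for a merged store.

    Global totals are the sizes of the distinct unions across sources;
    percent_X = unique_added_X / global total of X (one decimal), our stated
    convention for the denominator.
    """

    per_source: tuple[SourceStatsRow, ...]
    total_ids: int
    total_sequences: int
    total_functions: int
    total_organisms: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_source", tuple(self.per_source))
        _require(self.total_sequences <= sum(r.n_sequences for r in self.per_source),
                 "global distinct sequences exceed the per-source sum")

    def percent(self, row: SourceStatsRow, kind: str) -> float:
        """unique_added share of the global total, rounded to one decimal."""
        total = getattr(self, f"total_{kind}")
        if total == 0:
            return 0.0
        return round(100.0 * getattr(row, f"unique_added_{kind}") / total, 1)


@dataclass
class SourceBundle:
    """One source after conversion to the md5-keyed internal form."""

    spec: SourceSpec
    sequences: dict[Md5Id, NormalizedSequence]
    annotations: list[AnnotationRecord]
    hierarchies: list[HierarchyRecord] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            _require(ann.md5 in self.sequences,
                     f"annotation references md5 {ann.md5} absent from bundle")
            _require(ann.source == self.spec.name,
                     f"annotation source {ann.source!r} != bundle {self.spec.name!r}")
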
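"""Identifier resolution and namespace translation.

Everything here rides on sequence identity: two native identifiers from
different annotation sources refer to the same protein exactly when they
attach to the same md5. Translation between namespaces is therefore a
composition of two index lookups (native id -> md5 -> native ids of the
other source), never a function-string match.

Unknown md5s and native ids yield empty results — absence is data, and
batch pipelines must not abort on one miss. Only an unknown *source* is an
error, since a typo'd namespace is always a caller bug.

All operations are backed by in-memory hash indexes built once per store,
so bulk calls with hundreds of thousands of identifiers resolve in seconds.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .checksum import validate_md5_id
from .errors import UnknownSource
from .model import Md5Id
from .store import NrStore

_NONE_LAST = ((0, ""),)


def _key(value: Optional[str]):
    return (1, "") if value is None else (0, value)


def _row_key(row: tuple) -> tuple:
    return tuple(_key(cell) for cell in row)


def _check_source(store: NrStore, source: str) -> None:
    if source not in store.sources:
        raise UnknownSource(f"unknown source {source!r}; loaded: "
                            + ", ".join(sorted(store.sources)))


def md52ids(store: NrStore, md5s: Iterable[str], source: Optional[str] = None
            ) -> list[tuple[Md5Id, str, str]]:
    """All (md5, source, native_id) rows for the given md5s.

    Filtered by ``source`` when given; md5s absent from the store contribute
    zero rows.
    """
    if source is not None:
        _check_source(store, source)
    index = store.index()
    rows: set[tuple[Md5Id, str, str]] = set()
    for text in md5s:
        md5 = validate_md5_id(text)
        by_source = index.ann_by_md5.get(md5)
        if not by_source:
            continue
        for src, anns in by_source.items():
            if source is not None and src != source:
                continue
            for ann in anns:
                rows.add((md5, src, ann.native_id))
    return sorted(rows)


def md52overview(store: NrStore, md5: str, source: str
                 ) -> list[tuple[Md5Id, str, Optional[str], Optional[str]]]:
    """Deduplicated (md5, native_id, function, organism) rows in one source."""
    _check_source(store, source)
    key = validate_md5_id(md5)
    anns = store.index().ann_by_md5.get(key, {}).get(source, set())
    rows = {(key, a.native_id, a.function, a.organism) for a in anns}
    return sorted(rows, key=_row_key)


def md5s2sets4source(store: NrStore, md5s: Iterable[str], source: str
                     ) -> dict[Md5Id, set[tuple[str, Optional[str], Optional[str]]]]:
    """Batch overview: md5 -> set of (native_id, function, organism).

    Keys are exactly the input md5s with at least one row in the source.
    Designed for bulk inputs (hundreds of thousands of md5s in one call).
    """
    _check_source(store, source)
    index = store.index()
    out: dict[Md5Id, set[tuple[str, Optional[str], Optional[str]]]] = {}
    for text in md5s:
        md5 = validate_md5_id(text)
        if md5 in out:
            continue
        anns = index.ann_by_md5.get(md5, {}).get(source)
        if anns:
            out[md5] = {(a.native_id, a.function, a.organism) for a in anns}
    return out


def id2md5(store: NrStore, native_id: str, source: str) -> list[Md5Id]:
    """All md5s bearing this native id in this source (normally one)."""
    _check_source(store, source)
    return sorted(store.index().md5_by_id.get((source, native_id), set()))


def translate_ids(store: NrStore, native_ids: Iterable[str], from_source: str,
                  to_source: str
                  ) -> list[tuple[str, Optional[Md5Id], Optional[str], Optional[str]]]:
    """Namespace translation via shared sequence identity.

    Every (from_id, md5, to_id, to_function) path through a shared md5.
    from_ids that resolve to no md5, or whose md5s carry no row in the target
    source, contribute a row with an absent to_id.
    """
    _check_source(store, from_source)
    _check_source(store, to_source)
    index = store.index()
    rows: set[tuple[str, Optional[Md5Id], Optional[str], Optional[str]]] = set()
    for from_id in native_ids:
        md5s = index.md5_by_id.get((from_source, from_id), set())
        if not md5s:
            rows.add((from_id, None, None, None))
            continue
        for md5 in md5s:
            targets = index.ann_by_md5.get(md5, {}).get(to_source)
            if not targets:
                rows.add((from_id, md5, None, None))
                continue
            for ann in targets:
                rows.add((from_id, md5, ann.native_id, ann.function))
    return sorted(rows, key=_row_key)


def id2hierarchy(store: NrStore, native_id: str, source: str
                 ) -> list[tuple[str, ...]]:
    """Hierarchy paths registered for (source, native_id); sorted, may be empty."""
    _check_source(store, source)
    return list(store.index().hier_by_id.get((source, native_id), []))
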
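"""Sequence normalization and MD5 fingerprinting.

This is the identity function of the whole system: two sequence records are
the same protein (or transcript) exactly when their normalized residue
strings share an MD5 digest. The published normalization contract is:

1. remove all whitespace,
2. uppercase,
3. for proteins, strip exactly one trailing ``*`` (stop) if present.

After that only A-Z may remain; anything else (notably ``-`` alignment gaps
and internal stops) is rejected rather than silently removed — a gapped
sequence is an alignment artifact, not a protein. The digest input encoding
is fixed to one ASCII byte per residue character so fingerprints are
bit-exact across implementations. Ambiguity codes (X, B, Z, J) and the
extended amino acids U and O are accepted since they fall in A-Z.

Other databases that fingerprint sequences may normalize differently (e.g.
keep case, or strip stops elsewhere); digests computed here can differ from
theirs for such edge-case records.
"""

from __future__ import annotations

import hashlib

from .errors import EmptySequence, IllegalCharacter
from .model import Md5Id, Moltype, NormalizedSequence, _check_moltype, _UPPER


def md5_hex(data: bytes | str) -> str:
    """Lowercase hex MD5 digest of raw bytes (str is encoded as ASCII)."""
    if isinstance(data, str):
        data = data.encode("ascii")
    return hashlib.md5(data).hexdigest()


def normalize_sequence(raw: str, moltype: Moltype) -> NormalizedSequence:
    """Canonicalize a raw residue string for fingerprinting.

    Raises
    ------
    EmptySequence
        if nothing remains after normalization.
    IllegalCharacter
        if any non-A-Z character remains; reports the first offender and its
        1-based position in the normalized string.
    """
    _check_moltype(moltype)
    text = "".join(raw.split()).upper()
    if moltype == "protein" and text.endswith("*"):
        text = text[:-1]
    if not text:
        raise EmptySequence("sequence is empty after normalization")
    for pos, char in enumerate(text, start=1):
        if char not in _UPPER:
            raise IllegalCharacter(char, pos)
    return NormalizedSequence(residues=text, moltype=moltype)


def compute_md5_id(seq: NormalizedSequence) -> Md5Id:
    """The 32-hex-character MD5 fingerprint of a normalized sequence."""
    return Md5Id(md5_hex(seq.residues))


def validate_md5_id(text: str) -> Md5Id:
    """Canonical lowercase Md5Id from 32 hex characters of any case.

    Raises :class:`~nrseq.errors.MalformedId` on wrong length or non-hex
    characters.
    """
    return Md5Id(text)
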
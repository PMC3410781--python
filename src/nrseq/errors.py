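"""Typed exception hierarchy.

Every error raised by this package derives from :class:`NrseqError`, so
callers (notably the CLI) can map failure classes onto exit codes without
string matching.
"""


class NrseqError(Exception):
    """Base class for all package errors."""


class ValidationError(NrseqError, ValueError):
    """A domain type was constructed with a violated invariant."""


# -- checksum / identifiers -------------------------------------------------

class MalformedId(ValidationError):
    """Text is not a 32-character hexadecimal MD5 identifier."""


class EmptySequence(ValidationError):
    """Normalization left zero residues."""


class IllegalCharacter(ValidationError):
    """A non A-Z character survived normalization."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based, in the normalized string
        super().__init__(f"illegal character {char!r} at position {position}")


# -- parsing ----------------------------------------------------------------

class MalformedFasta(NrseqError):
    """FASTA stream violates the format (data before header, empty header)."""


class MalformedRow(NrseqError):
    """A tabular row has the wrong shape; message carries the line number."""


class BadTaxid(MalformedRow):
    """Taxonomy ID cell is not a positive integer."""


class EmptyHierarchy(MalformedRow):
    """A hierarchy row carries no level cells."""


class MalformedSimLine(NrseqError):
    """A similarity (m8) line does not have 12 parseable fields."""


# -- ingest / store ---------------------------------------------------------

class SourceEmpty(NrseqError):
    """No sequence of a source bundle survived conversion."""


class MixedMoltype(NrseqError):
    """Bundles of different molecule types cannot share a store."""


class DuplicateSourceName(NrseqError):
    """A source name is already present in the store."""


class ResidueMismatch(NrseqError):
    """Same MD5, different residues: hash collision or normalization bug.

    Always fatal; never silently resolved.
    """


class EmptyStore(NrseqError):
    """Refusing to write a store with zero sequences."""


class MissingFile(NrseqError):
    """A required dump file is absent."""


class IntegrityError(NrseqError):
    """A dump table references an MD5 absent from the sequence FASTA."""


# -- query / sims -----------------------------------------------------------

class UnknownSource(NrseqError):
    """The requested annotation namespace is not loaded."""


class NotBestHitReduced(NrseqError):
    """Category summarization requires one hit per query."""
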
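"""Synthetic source bundles with known ground truth.

Real multi-source protein collections are tens of gigabytes and live behind
FTP sites; every operation in this package is instead exercised on generated
bundles whose exact expected properties are recorded at construction time.
The generator emulates the *structure* of a multi-source build — several
namespaces annotating overlapping sequence sets under source-local
identifiers, with a controllable fraction of identity-only records — not
sequence evolution: residues are drawn uniformly over the 20 standard amino
acids (so chance duplicates are effectively impossible and every duplicate
is planted), with lengths uniform in [30, 300] to exercise FASTA wrapping.

A :class:`GroundTruth` ledger records, by construction rather than by
running the pipeline, the global distinct-sequence count, the per-source
unique-added counts, every native_id <-> md5 pair, which identifiers carry
annotations, and their hierarchy paths. :func:`naive_dedup_oracle`
additionally recounts distinct sequences by brute-force string-set
construction with no hashing, as an independent check on the md5-keyed
merge.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .checksum import compute_md5_id
from .errors import ValidationError
from .model import Md5Id, Moltype, NormalizedSequence, SourceSpec

_AMINO = "ACDEFGHIKLMNPQRSTVWY"
_NUCS = "ACGT"
_CATEGORIES = (
    "Metabolism",
    "Information Storage and Processing",
    "Cellular Processes and Signaling",
    "Poorly Characterized",
)
_ORGANISMS = (
    ("Escherichia coli", 562),
    ("Bacillus subtilis", 1423),
    ("Pseudomonas aeruginosa", 287),
    ("Methanococcus maripaludis", 39152),
    ("Synechocystis sp.", 1143),
)


@dataclass
class GroundTruth:
    """Construction-time expectations for one generated fixture set."""

    specs: list[SourceSpec]
    moltype: Moltype
    seed: int
    distinct_sequences: int
    shared_md5s: set[Md5Id]
    # source -> native_id -> md5
    md5_of: dict[str, dict[str, Md5Id]]
    unique_added_sequences: dict[str, int]
    # source -> native_id -> (function, organism, taxid) or None (identity-only)
    annotation_of: dict[str, dict[str, Optional[tuple[str, str, int]]]]
    # source -> native_id -> hierarchy path (annotated ids only)
    hierarchy_of: dict[str, dict[str, tuple[str, ...]]]

    def all_md5s(self) -> set[Md5Id]:
        return {m for ids in self.md5_of.values() for m in ids.values()}


def _random_residues(rng: random.Random, moltype: Moltype, taken: set[str]) -> str:
    alphabet = _AMINO if moltype == "protein" else _NUCS
    while True:
        n = rng.randint(30, 300)
        residues = "".join(rng.choice(alphabet) for _ in range(n))
        if residues not in taken:
            taken.add(residues)
            return residues


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as out:
        for native_id, residues in records:
            out.write(f">{native_id}\n")
            for i in range(0, len(residues), 60):
                out.write(residues[i:i + 60] + "\n")


def generate_sources(out_dir: str | Path, n_sources: int = 2,
                     seqs_per_source: int = 10, overlap_fraction: float = 0.2,
                     moltype: Moltype = "protein", seed: int = 0,
                     annotated_fraction: float = 0.8) -> GroundTruth:
    """Write ``n_sources`` complete source directories under ``out_dir``.

    A shared pool of ``ceil(overlap_fraction * seqs_per_source)`` sequences
    appears in every source under different native identifiers; the rest are
    source-unique. Each identifier independently carries a (function,
    organism, taxid) annotation row with probability ``annotated_fraction``
    (default 0.8 — real sources leave a tail of records identity-only);
    annotated identifiers also get one two-level hierarchy path. Fully
    reproducible from the seed.
    """
    if n_sources < 1 or seqs_per_source < 1:
        raise ValidationError("n_sources and seqs_per_source must be >= 1")
    if not 0.0 <= overlap_fraction <= 1.0 or not 0.0 <= annotated_fraction <= 1.0:
        raise ValidationError("fractions must be in [0, 1]")

    out_dir = Path(out_dir)
    rng = random.Random(seed)
    n_shared = min(seqs_per_source, math.ceil(overlap_fraction * seqs_per_source))
    n_unique = seqs_per_source - n_shared

    taken: set[str] = set()
    shared = [_random_residues(rng, moltype, taken) for _ in range(n_shared)]
    shared_md5s = {compute_md5_id(NormalizedSequence(s, moltype)) for s in shared}

    n_functions = max(3, seqs_per_source // 3)
    functions = [f"hypothetical protein family {i:03d}" for i in range(n_functions)]

    specs: list[SourceSpec] = []
    md5_of: dict[str, dict[str, Md5Id]] = {}
    annotation_of: dict[str, dict[str, Optional[tuple[str, str, int]]]] = {}
    hierarchy_of: dict[str, dict[str, tuple[str, ...]]] = {}

    for s in range(n_sources):
        name = f"SRC{s + 1:02d}"
        src_dir = out_dir / name
        src_dir.mkdir(parents=True, exist_ok=True)
        residues_list = shared + [_random_residues(rng, moltype, taken)
                                  for _ in range(n_unique)]
        rng.shuffle(residues_list)
        records = [(f"{name}_{j:05d}", res) for j, res in enumerate(residues_list)]
        _write_fasta(src_dir / "sequences.fasta", records)

        md5_of[name] = {nid: compute_md5_id(NormalizedSequence(res, moltype))
                        for nid, res in records}
        annotation_of[name] = {}
        hierarchy_of[name] = {}
        ann_lines = ["native_id\tfunction\torganism\ttaxid"]
        hier_lines = ["native_id\tlevel1\tlevel2"]
        for nid, _res in records:
            if rng.random() < annotated_fraction:
                f_idx = rng.randrange(n_functions)
                function = functions[f_idx]
                organism, taxid = _ORGANISMS[rng.randrange(len(_ORGANISMS))]
                annotation_of[name][nid] = (function, organism, taxid)
                ann_lines.append(f"{nid}\t{function}\t{organism}\t{taxid}")
                path = (_CATEGORIES[f_idx % len(_CATEGORIES)], function)
                hierarchy_of[name][nid] = path
                hier_lines.append(nid + "\t" + "\t".join(path))
            else:
                annotation_of[name][nid] = None
        (src_dir / "annotations.tsv").write_text("\n".join(ann_lines) + "\n",
                                                 encoding="utf-8")
        (src_dir / "hierarchy.tsv").write_text("\n".join(hier_lines) + "\n",
                                               encoding="utf-8")
        specs.append(SourceSpec(
            name=name, moltype=moltype,
            fasta_path=str(src_dir / "sequences.fasta"),
            annotation_path=str(src_dir / "annotations.tsv"),
            hierarchy_path=str(src_dir / "hierarchy.tsv")))

    distinct = n_shared + n_sources * n_unique
    unique_added = {spec.name: (seqs_per_source if n_sources == 1 else n_unique)
                    for spec in specs}
    return GroundTruth(specs=specs, moltype=moltype, seed=seed,
                       distinct_sequences=distinct, shared_md5s=shared_md5s,
                       md5_of=md5_of, unique_added_sequences=unique_added,
                       annotation_of=annotation_of, hierarchy_of=hierarchy_of)


@dataclass
class SimsTruth:
    """Expectations for one generated similarity file."""

    path: Path
    # query -> list of (subject_md5, bit_score, is_decoy), best first
    hits_of: dict[str, list[tuple[Md5Id, float, bool]]]
    decoy_md5s: set[Md5Id]

    @property
    def n_hits(self) -> int:
        return sum(len(v) for v in self.hits_of.values())

    def best_subject(self, query: str) -> Md5Id:
        return self.hits_of[query][0][0]

    def expected_summary(self, truth: GroundTruth, source: str, level: int
                         ) -> tuple[dict[str, int], int]:
        """(category -> n_queries, n_unassigned) from the ledgers alone.

        Walks the ground-truth dictionaries directly — no store, no index —
        so it is an independent oracle for the pipeline's summary.
        """
        md52nids: dict[Md5Id, list[str]] = {}
        for nid, md5 in truth.md5_of[source].items():
            md52nids.setdefault(md5, []).append(nid)
        counts: dict[str, int] = {}
        unassigned = 0
        for query in self.hits_of:
            best = self.best_subject(query)
            cats = set()
            for nid in md52nids.get(best, []):
                path = truth.hierarchy_of[source].get(nid)
                if path is not None and len(path) >= level:
                    cats.add(path[level - 1])
            if cats:
                for c in cats:
                    counts[c] = counts.get(c, 0) + 1
            else:
                unassigned += 1
        return counts, unassigned


def generate_sims(truth: GroundTruth, path: str | Path, n_queries: int = 50,
                  hit_rate: float = 1.0, decoy_fraction: float = 0.0,
                  seed: int = 0) -> SimsTruth:
    """Write a 12-column tabular similarity file against the fixture md5s.

    Each query independently receives 1-3 hits with probability ``hit_rate``;
    a ``decoy_fraction`` of subjects are random md5s absent from the store
    (hits that must survive annotation with empty sets). Bit scores within a
    query are strictly decreasing, so the expected best hit is unambiguous.
    """
    if n_queries < 0 or not 0.0 <= hit_rate <= 1.0 or not 0.0 <= decoy_fraction <= 1.0:
        raise ValidationError("bad sims generator parameters")
    rng = random.Random(seed)
    real_set = truth.all_md5s()
    real_md5s = sorted(real_set)
    path = Path(path)
    hits_of: dict[str, list[tuple[Md5Id, float, bool]]] = {}
    decoys: set[Md5Id] = set()
    with open(path, "w", encoding="ascii", newline="\n") as out:
        out.write("# synthetic tabular similarity fixture\n")
        for q in range(n_queries):
            query = f"read{q:06d}"
            if rng.random() >= hit_rate:
                continue
            n_hits = rng.randint(1, 3)
            bit = rng.uniform(150.0, 300.0)
            rows = []
            for _ in range(n_hits):
                is_decoy = rng.random() < decoy_fraction
                if is_decoy:
                    subject = Md5Id(f"{rng.getrandbits(128):032x}")
                    while subject in real_set:
                        subject = Md5Id(f"{rng.getrandbits(128):032x}")
                    decoys.add(subject)
                else:
                    subject = real_md5s[rng.randrange(len(real_md5s))]
                length = rng.randint(30, 200)
                ident = round(rng.uniform(60.0, 100.0), 1)
                mism = rng.randint(0, 10)
                evalue = 10.0 ** -rng.randint(5, 60)
                out.write("\t".join(map(str, (
                    query, subject, ident, length, mism, 0, 1, length,
                    1, length, evalue, round(bit, 1)))) + "\n")
                rows.append((subject, round(bit, 1), is_decoy))
                bit -= rng.uniform(1.0, 20.0)
            hits_of[query] = rows
    return SimsTruth(path=path, hits_of=hits_of, decoy_md5s=decoys)


def naive_dedup_oracle(source_dirs: list[str | Path],
                       moltype: Moltype = "protein") -> int:
    """Distinct-sequence count by direct string-set construction, no hashing.

    Re-states the normalization rules inline (whitespace out, uppercase, one
    trailing stop off, reject non-letters) so the count is independent of the
    checksum machinery it checks. Test oracle only.
    """
    distinct: set[str] = set()
    for src_dir in source_dirs:
        fasta = Path(src_dir) / "sequences.fasta"
        residues = None
        chunks: list[list[str]] = []
        with open(fasta, encoding="ascii") as handle:
            for line in handle:
                if line.startswith(">"):
                    chunks.append([])
                elif chunks:
                    chunks[-1].append(line.strip())
        for parts in chunks:
            residues = "".join("".join(parts).split()).upper()
            if moltype == "protein" and residues.endswith("*"):
                residues = residues[:-1]
            if residues and all("A" <= c <= "Z" for c in residues):
                distinct.add(residues)
    return len(distinct)
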
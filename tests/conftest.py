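"""Shared builders: hand-countable in-memory bundles and a generated store."""

from __future__ import annotations

import pytest

from nrseq.checksum import compute_md5_id, normalize_sequence
from nrseq.fixtures import generate_sources
from nrseq.ingest import convert_source
from nrseq.model import (
    AnnotationRecord,
    HierarchyRecord,
    SourceBundle,
    SourceSpec,
)
from nrseq.store import merge_sources


def md5_of(residues: str, moltype: str = "protein"):
    return compute_md5_id(normalize_sequence(residues, moltype))


def make_bundle(name, seqs, anns=None, hiers=None, moltype="protein"):
    """Build a SourceBundle directly from dicts, no files.

    seqs: native_id -> residue string; anns: native_id -> list of
    (function, organism, taxid) rows (ids absent from anns get an
    identity-only record); hiers: native_id -> list of level tuples.
    """
    anns = anns or {}
    sequences, id2md5 = {}, {}
    for nid, res in seqs.items():
        norm = normalize_sequence(res, moltype)
        md5 = compute_md5_id(norm)
        sequences[md5] = norm
        id2md5[nid] = md5
    annotations = []
    for nid in seqs:
        rows = anns.get(nid)
        if not rows:
            annotations.append(AnnotationRecord(md5=id2md5[nid], source=name,
                                                native_id=nid))
        else:
            for function, organism, taxid in rows:
                annotations.append(AnnotationRecord(
                    md5=id2md5[nid], source=name, native_id=nid,
                    function=function, organism=organism, taxid=taxid))
    hierarchies = [HierarchyRecord(source=name, native_id=nid, levels=tuple(path))
                   for nid, paths in (hiers or {}).items() for path in paths]
    spec = SourceSpec(name=name, moltype=moltype, fasta_path=f"<memory:{name}>")
    return SourceBundle(spec=spec, sequences=sequences, annotations=annotations,
                        hierarchies=hierarchies)


@pytest.fixture
def bundle_a():
    return make_bundle(
        "A",
        {"a1": "MKL", "a2": "VVW"},
        anns={"a1": [("kinase", "E. coli", 562),
                     ("phosphatase", "E. coli", 562)]},
        hiers={"a1": [("Metabolism", "Amino acid transport")]},
    )


@pytest.fixture
def bundle_b():
    return make_bundle(
        "B",
        {"b7": "MKL", "b2": "GGH"},
        anns={"b7": [("Kinase", "Escherichia coli", 562)],
              "b2": [("transporter", None, None)]},
        hiers={"b7": [("Metabolism", "Kinases")]},
    )


@pytest.fixture
def tiny_store(bundle_a, bundle_b):
    """Two hand-built sources sharing the 'MKL' sequence."""
    return merge_sources([bundle_a, bundle_b])


@pytest.fixture(scope="session")
def gen_fixture(tmp_path_factory):
    """Generated 2-source/10-each/overlap-0.2 fixture: (truth, bundles, store)."""
    root = tmp_path_factory.mktemp("gen")
    truth = generate_sources(root, n_sources=2, seqs_per_source=10,
                             overlap_fraction=0.2, seed=7)
    bundles = [convert_source(spec) for spec in truth.specs]
    return truth, bundles, merge_sources(bundles)
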
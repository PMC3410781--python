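"""Merging, persistence and statistics of the non-redundant store."""

import itertools

import pytest

from nrseq.errors import (
    DuplicateSourceName,
    EmptyStore,
    IntegrityError,
    MissingFile,
    MixedMoltype,
    ResidueMismatch,
)
from nrseq.model import NormalizedSequence
from nrseq.store import (
    add_source,
    compute_statistics,
    dump_tables,
    load_store,
    merge_sources,
    save_store,
    write_nr_fasta,
    NR_FASTA,
    TABLE_FILES,
)

from conftest import make_bundle, md5_of


def _dir_bytes(directory):
    return {p.name: p.read_bytes() for p in sorted(directory.iterdir())}


class TestMerge:
    def test_union_keyed_by_md5(self, tiny_store):
        # A={MKL,VVW}, B={MKL,GGH} -> 3 distinct sequences
        assert len(tiny_store.sequences) == 3
        shared = md5_of("MKL")
        rows = {(a.source, a.native_id) for a in tiny_store.annotations
                if a.md5 == shared}
        assert rows == {("A", "a1"), ("B", "b7")}

    def test_metadata_only_growth(self, bundle_a, bundle_b):
        store = merge_sources([bundle_a, bundle_b])
        n_seqs, n_anns = len(store.sequences), len(store.annotations)
        renamed = make_bundle("A2", {"x1": "MKL", "x2": "VVW"},
                              anns={"x1": [("kinase", "E. coli", 562),
                                           ("phosphatase", "E. coli", 562)]})
        add_source(store, renamed)
        assert len(store.sequences) == n_seqs
        assert len(store.annotations) == n_anns + 3

    def test_disjoint_source_grows_sequences(self, bundle_a):
        store = merge_sources([bundle_a])
        add_source(store, make_bundle("C", {"c1": "AAAA", "c2": "CCCC"}))
        assert len(store.sequences) == 4

    def test_duplicate_source_name(self, bundle_a):
        store = merge_sources([bundle_a])
        with pytest.raises(DuplicateSourceName):
            add_source(store, make_bundle("A", {"z": "WWW"}))

    def test_mixed_moltype(self, bundle_a):
        nuc = make_bundle("N", {"n1": "ACGT"}, moltype="nucleotide")
        with pytest.raises(MixedMoltype):
            merge_sources([bundle_a, nuc])

    def test_residue_mismatch_is_fatal(self, bundle_a):
        store = merge_sources([bundle_a])
        forged = make_bundle("F", {"f1": "QQQQ"})
        md5 = next(iter(forged.sequences))
        forged.sequences[md5] = NormalizedSequence("RRRR", "protein")
        forged.sequences[md5_of("MKL")] = NormalizedSequence("SSSS", "protein")
        with pytest.raises(ResidueMismatch):
            add_source(store, forged)


class TestNrFasta:
    def test_headers_sorted_md5_only(self, tiny_store, tmp_path):
        path = tmp_path / "nr.fasta"
        assert write_nr_fasta(tiny_store, path) == 3
        lines = path.read_text().splitlines()
        headers = [l[1:] for l in lines if l.startswith(">")]
        assert headers == sorted(headers)
        assert all(len(h) == 32 and set(h) <= set("0123456789abcdef")
                   for h in headers)

    def test_wrap_at_80(self, tmp_path):
        store = merge_sources([make_bundle("W", {"w1": "A" * 100})])
        write_nr_fasta(store, tmp_path / "nr.fasta")
        lines = (tmp_path / "nr.fasta").read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [80, 20]

    def test_empty_store_refused(self, bundle_a, tmp_path):
        store = merge_sources([bundle_a])
        store.sequences.clear()
        with pytest.raises(EmptyStore):
            write_nr_fasta(store, tmp_path / "nr.fasta")

    def test_record_count_equals_store_size(self, gen_fixture, tmp_path):
        _t, _b, store = gen_fixture
        assert write_nr_fasta(store, tmp_path / "nr.fasta") == len(store.sequences)


class TestDumpLoad:
    def test_absent_values_emit_no_rows(self, tiny_store, tmp_path):
        dump_tables(tiny_store, tmp_path)
        org = (tmp_path / "md52org.tsv").read_text()
        assert "transporter" not in org  # b2 has function but organism=None
        func = (tmp_path / "md52func.tsv").read_text()
        assert "transporter" in func

    def test_manifest_counts_match_lines(self, tiny_store, tmp_path):
        manifest = save_store(tiny_store, tmp_path)
        for name, count, _digest in manifest:
            text = (tmp_path / name).read_text()
            if name == NR_FASTA:
                assert sum(l.startswith(">") for l in text.splitlines()) == count
            else:
                assert len(text.splitlines()) == count

    def test_merge_order_insensitive_byte_identical(self, bundle_a, bundle_b,
                                                    tmp_path):
        dirs = []
        for i, order in enumerate(itertools.permutations([bundle_a, bundle_b])):
            out = tmp_path / f"order{i}"
            save_store(merge_sources(list(order)), out)
            dirs.append(_dir_bytes(out))
        assert dirs[0] == dirs[1]

    def test_round_trip_identical_dumps(self, gen_fixture, tmp_path):
        _t, _b, store = gen_fixture
        save_store(store, tmp_path / "d1")
        reloaded = load_store(tmp_path / "d1")
        save_store(reloaded, tmp_path / "d2")
        assert _dir_bytes(tmp_path / "d1") == _dir_bytes(tmp_path / "d2")

    def test_missing_file(self, tiny_store, tmp_path):
        save_store(tiny_store, tmp_path)
        (tmp_path / "md52id.tsv").unlink()
        with pytest.raises(MissingFile):
            load_store(tmp_path)

    def test_corrupt_md5_named_in_error(self, tiny_store, tmp_path):
        save_store(tiny_store, tmp_path)
        table = tmp_path / "md52id.tsv"
        lines = table.read_text().splitlines()
        bad = "0" * 32
        lines[0] = bad + lines[0][32:]
        table.write_text("\n".join(lines) + "\n")
        with pytest.raises(IntegrityError, match=bad):
            load_store(tmp_path)


class TestStatistics:
    def test_hand_counted_two_sources(self, tiny_store):
        stats = compute_statistics(tiny_store)
        by = {r.source: r for r in stats.per_source}
        assert stats.total_sequences == 3
        assert by["A"].n_sequences == 2 and by["A"].unique_added_sequences == 1
        assert by["B"].n_sequences == 2 and by["B"].unique_added_sequences == 1
        # 'kinase' vs 'Kinase' are distinct representations (case-sensitive)
        assert stats.total_functions == 4
        assert by["A"].unique_added_functions == 2

    def test_single_source_everything_unique(self, bundle_a):
        stats = compute_statistics(merge_sources([bundle_a]))
        row = stats.per_source[0]
        for kind in ("ids", "sequences", "functions", "organisms"):
            assert getattr(row, f"unique_added_{kind}") == getattr(row, f"n_{kind}")

    def test_percent_convention(self, tiny_store):
        stats = compute_statistics(tiny_store)
        row = {r.source: r for r in stats.per_source}["A"]
        assert stats.percent(row, "sequences") == round(100.0 * 1 / 3, 1)

    def test_unique_added_sum_bounded(self, gen_fixture):
        _t, _b, store = gen_fixture
        stats = compute_statistics(store)
        assert sum(r.unique_added_sequences for r in stats.per_source) \
            <= stats.total_sequences
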
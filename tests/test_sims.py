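"""Similarity-file parsing, best-hit reduction, annotation, summaries."""

import io
import random

import pytest

from nrseq.errors import MalformedId, MalformedSimLine, NotBestHitReduced
from nrseq.fixtures import generate_sims
from nrseq.model import Md5Id, SimHit
from nrseq.sims import (
    annotate_sims,
    best_hit_per_query,
    filter_hits,
    format_annotated_tsv,
    format_summary_tsv,
    parse_m8,
    summarize_by_category,
)

from conftest import md5_of

MKL = md5_of("MKL")
LINE = ("q1\t068792e95e38032059ba7d9c26c1be78\t98.5\t120\t2\t0\t1\t120\t5"
        "\t124\t1e-50\t230\n")


def _hit(query="q1", subject=MKL, bit=230.0, evalue=1e-50):
    return SimHit(query_id=query, subject_md5=Md5Id(subject), pct_identity=98.5,
                  aln_length=120, mismatches=2, gap_openings=0, q_start=1,
                  q_end=120, s_start=5, s_end=124, e_value=evalue,
                  bit_score=bit)


class TestParseM8:
    def test_field_mapping(self):
        (hit,) = parse_m8(io.StringIO(LINE))
        assert hit.subject_md5 == "068792e95e38032059ba7d9c26c1be78"
        assert hit.pct_identity == 98.5
        assert hit.e_value == 1e-50
        assert hit.s_end == 124

    def test_comments_and_blanks_skipped(self):
        hits = list(parse_m8(io.StringIO("# BLASTP 2.2\n\n" + LINE)))
        assert len(hits) == 1

    def test_wrong_field_count_names_line(self):
        with pytest.raises(MalformedSimLine, match="line 2"):
            list(parse_m8(io.StringIO("# c\n" + LINE.rsplit("\t", 1)[0] + "\n")))

    def test_non_md5_subject(self):
        with pytest.raises(MalformedId):
            list(parse_m8(io.StringIO(LINE.replace(
                "068792e95e38032059ba7d9c26c1be78", "gi|12345"))))


class TestFilter:
    def test_defaults_pass_everything(self):
        hits = [_hit(), _hit(query="q2", evalue=10.0)]
        assert list(filter_hits(iter(hits))) == hits

    def test_evalue_cut(self):
        hits = [_hit(evalue=1e-50), _hit(query="q2", evalue=1e-3)]
        kept = list(filter_hits(iter(hits), max_evalue=1e-5))
        assert [h.query_id for h in kept] == ["q1"]

    def test_length_boundary_inclusive(self):
        assert list(filter_hits(iter([_hit()]), min_length=120)) == [_hit()]
        assert list(filter_hits(iter([_hit()]), min_length=121)) == []


class TestBestHit:
    def test_max_bit_score_wins(self):
        kept = list(best_hit_per_query([_hit(bit=180.0), _hit(bit=230.0)]))
        assert len(kept) == 1 and kept[0].bit_score == 230.0

    def test_tie_breaks_to_smaller_md5(self):
        a, b = sorted([MKL, md5_of("VVW")])
        kept = list(best_hit_per_query([_hit(subject=b), _hit(subject=a)]))
        assert kept[0].subject_md5 == a

    def test_permutation_invariant_unique_queries(self):
        rng = random.Random(11)
        hits = [_hit(query=f"q{i % 5}", subject=MKL,
                     bit=200.0 + i, evalue=10.0 ** -i) for i in range(15)]
        ref = list(best_hit_per_query(hits))
        assert len({h.query_id for h in ref}) == len(ref) == 5
        for _ in range(3):
            rng.shuffle(hits)
            assert list(best_hit_per_query(hits)) == ref

    def test_empty(self):
        assert list(best_hit_per_query([])) == []


class TestAnnotate:
    def test_conservation_and_order(self, tiny_store):
        hits = [_hit("q1", MKL), _hit("q2", "0" * 32), _hit("q3", md5_of("GGH"))]
        rows = list(annotate_sims(tiny_store, hits, "A"))
        assert [r.hit.query_id for r in rows] == ["q1", "q2", "q3"]
        assert len(rows[0].annotations) == 2
        assert rows[1].annotations == frozenset()  # decoy subject
        assert rows[2].annotations == frozenset()  # present, but not in A

    def test_tsv_row_count_equals_hit_count(self, tiny_store):
        hits = [_hit("q1", MKL), _hit("q2", "0" * 32)]
        lines = list(format_annotated_tsv(annotate_sims(tiny_store, hits, "A")))
        data = [l for l in lines if not l.startswith("#")]
        assert len(data) == 2
        assert "kinase; phosphatase" in data[0]
        assert lines[-1].startswith("# hits=2")


class TestSummarize:
    def test_hand_counted(self, tiny_store):
        hits = [_hit("q1", MKL), _hit("q2", MKL),
                _hit("q3", md5_of("VVW")), _hit("q4", "0" * 32)]
        annotated = annotate_sims(tiny_store, hits, "A")
        summary = summarize_by_category(tiny_store, annotated, "A", level=1)
        assert dict(summary.counts) == {"Metabolism": 2}
        assert summary.n_unassigned == 2  # a2 has no hierarchy; decoy unannotated
        assert summary.n_assigned + summary.n_unassigned == summary.n_queries == 4

    def test_multi_category_query_counts_once_per_category(self, bundle_a):
        from nrseq.model import HierarchyRecord
        from nrseq.store import merge_sources
        bundle_a.hierarchies.append(
            HierarchyRecord("A", "a1", ("Signaling", "Kinases")))
        store = merge_sources([bundle_a])
        summary = summarize_by_category(
            store, annotate_sims(store, [_hit("q1", MKL)], "A"), "A", level=1)
        assert dict(summary.counts) == {"Metabolism": 1, "Signaling": 1}
        assert summary.n_assigned == 1

    def test_level_beyond_paths_all_unassigned(self, tiny_store):
        summary = summarize_by_category(
            tiny_store, annotate_sims(tiny_store, [_hit("q1", MKL)], "A"),
            "A", level=3)
        assert summary.counts == () and summary.n_unassigned == 1

    def test_duplicate_query_rejected(self, tiny_store):
        annotated = annotate_sims(tiny_store, [_hit("q1"), _hit("q1")], "A")
        with pytest.raises(NotBestHitReduced):
            summarize_by_category(tiny_store, annotated, "A")

    def test_footer_accounting(self, tiny_store):
        summary = summarize_by_category(
            tiny_store, annotate_sims(tiny_store, [_hit("q1", MKL)], "A"), "A")
        footer = list(format_summary_tsv(summary))[-1]
        assert "queries=1" in footer and "assigned=1" in footer


class TestAgainstGeneratedTruth:
    def test_summary_matches_ledger_oracle(self, gen_fixture, tmp_path):
        truth, _b, store = gen_fixture
        sims_truth = generate_sims(truth, tmp_path / "hits.m8", n_queries=40,
                                   hit_rate=0.9, decoy_fraction=0.25, seed=5)
        with open(sims_truth.path) as handle:
            hits = list(parse_m8(handle))
        assert len(hits) == sims_truth.n_hits
        best = list(best_hit_per_query(hits))
        for source in truth.md5_of:
            annotated = annotate_sims(store, best, source)
            summary = summarize_by_category(store, annotated, source, level=1)
            exp_counts, exp_unassigned = sims_truth.expected_summary(
                truth, source, 1)
            assert dict(summary.counts) == exp_counts
            assert summary.n_unassigned == exp_unassigned
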
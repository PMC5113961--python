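"""Detection of core contigs in other metagenomes and group summaries."""

import numpy as np
import pandas as pd
import pytest

from corecazyome.coreset import CoreSet
from corecazyome.coverage import ContigCoverage, CoverageMatrix, is_present
from corecazyome.sharing import (
    SharingRecord,
    shared_by_alignment,
    shared_by_coverage,
    summarize_groups,
)

BLAST_COLS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
              "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def make_core(ids):
    return CoreSet(frozenset(ids), 5, 100, ("s1", "s2"))


def hits_df(rows):
    full = []
    for q, pident, length, evalue, bitscore in rows:
        full.append((q, "t", pident, length, 0, 0, 1, length, 1, length, evalue, bitscore))
    return pd.DataFrame(full, columns=BLAST_COLS)


class TestSharedByCoverage:
    def build_matrix(self, entries, samples):
        mat = CoverageMatrix(samples)
        for cid, sid, cov, length in entries:
            mat.add(sid, ContigCoverage(cid, cov, length))
        return mat

    def test_self_comparison_returns_full_core(self):
        samples = ["s1", "s2"]
        entries = [(f"c{i}", s, 8, 150) for i in range(5) for s in samples]
        mat = self.build_matrix(entries, samples)
        rec = shared_by_coverage(make_core([f"c{i}" for i in range(5)]), mat)
        assert rec.n_shared == 5

    def test_all_zero_target(self):
        mat = CoverageMatrix(["s1"])
        rec = shared_by_coverage(make_core(["c1", "c2"]), mat)
        assert rec.n_shared == 0

    def test_empty_core_warns_and_returns_zero(self, caplog):
        mat = CoverageMatrix(["s1"])
        with caplog.at_level("WARNING"):
            rec = shared_by_coverage(CoreSet(frozenset(), 5, 100, ("s1",)), mat)
        assert rec.n_shared == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        samples = ["t1", "t2", "t3"]
        core_ids = [f"c{i}" for i in range(200)]
        mat = CoverageMatrix(samples)
        for cid in core_ids:
            for s in samples:
                if rng.random() < 0.4:
                    continue
                cov = int(rng.integers(0, 10))
                length = int(rng.integers(0, 200)) if cov else 0
                if cov > 0:
                    length = max(length, 1)
                mat.add(s, ContigCoverage(cid, cov, length))
        for min_samples in (1, 2, 3):
            rec = shared_by_coverage(make_core(core_ids), mat, min_samples=min_samples)
            expected = sum(
                1
                for cid in core_ids
                if sum(is_present(mat.get(cid, s), 5, 100) for s in samples)
                >= min_samples
            )
            assert rec.n_shared == expected


class TestSharedByAlignment:
    def test_empty_hits(self):
        rec = shared_by_alignment(make_core(["c1"]), hits_df([]))
        assert rec.n_shared == 0

    def test_threshold_gate(self):
        core = make_core(["c1"])
        assert shared_by_alignment(core, hits_df([("c1", 90, 100, 1e-4, 50)])).n_shared == 0
        assert shared_by_alignment(core, hits_df([("c1", 90, 100, 1e-6, 50)])).n_shared == 1

    @pytest.mark.parametrize(
        "pident,length,evalue,expected",
        [
            (70.0, 70, 1e-5, 1),  # all three at the boundary pass
            (69.9, 70, 1e-5, 0),
            (70.0, 69, 1e-5, 0),
            (70.0, 70, 2e-5, 0),
        ],
    )
    def test_boundaries(self, pident, length, evalue, expected):
        rec = shared_by_alignment(make_core(["c1"]), hits_df([("c1", pident, length, evalue, 50)]))
        assert rec.n_shared == expected

    def test_non_core_queries_ignored(self, caplog):
        with caplog.at_level("WARNING"):
            rec = shared_by_alignment(
                make_core(["c1"]), hits_df([("cX", 90, 100, 1e-9, 50)])
            )
        assert rec.n_shared == 0
        assert "non-core" in caplog.text

    def test_matches_brute_force(self):
        rng = np.random.default_rng(14)
        core_ids = [f"c{i}" for i in range(200)]
        rows = [
            (
                f"c{rng.integers(200)}",
                float(rng.uniform(40, 100)),
                int(rng.integers(20, 200)),
                float(10.0 ** rng.uniform(-20, -2)),
                float(rng.uniform(30, 200)),
            )
            for _ in range(1000)
        ]
        rec = shared_by_alignment(make_core(core_ids), hits_df(rows))
        expected = len(
            {
                q
                for q, pident, length, evalue, _ in rows
                if evalue <= 1e-5 and length >= 70 and pident >= 70.0
            }
        )
        assert rec.n_shared == expected

    def test_antitone_in_thresholds(self):
        rng = np.random.default_rng(15)
        core_ids = [f"c{i}" for i in range(80)]
        rows = [
            (
                f"c{rng.integers(80)}",
                float(rng.uniform(40, 100)),
                int(rng.integers(20, 200)),
                float(10.0 ** rng.uniform(-20, -2)),
                50.0,
            )
            for _ in range(400)
        ]
        core, hits = make_core(core_ids), hits_df(rows)
        base = shared_by_alignment(core, hits).n_shared
        assert shared_by_alignment(core, hits, max_evalue=1e-7).n_shared <= base
        assert shared_by_alignment(core, hits, min_length=100).n_shared <= base
        assert shared_by_alignment(core, hits, min_pident=90.0).n_shared <= base

    def test_best_hit_only_mode(self):
        core = make_core(["c1"])
        # the best-scoring hit fails the identity gate; a weaker hit passes
        rows = pd.DataFrame(
            [
                ("c1", "t", 50.0, 100, 0, 0, 1, 100, 1, 100, 1e-9, 200.0),
                ("c1", "t", 90.0, 100, 0, 0, 1, 100, 1, 100, 1e-9, 100.0),
            ],
            columns=BLAST_COLS,
        )
        assert shared_by_alignment(core, rows).n_shared == 1
        assert shared_by_alignment(core, rows, best_hit_only=True).n_shared == 0


class TestSummarizeGroups:
    def rec(self, group, n, mid="m"):
        return SharingRecord(mid, group, n, "coverage")

    def test_zero_variance(self):
        out = summarize_groups([self.rec("g", 40, "a"), self.rec("g", 40, "b")])
        row = out.iloc[0]
        assert (row["mean"], row["se"]) == (40.0, 0.0)

    def test_singleton_group_reports_missing(self):
        out = summarize_groups([self.rec("tundra", 78)])
        row = out.iloc[0]
        assert row["mean"] == 78.0
        assert np.isnan(row["se"]) and np.isnan(row["sd"])

    def test_closed_form_two_member_group(self):
        out = summarize_groups([self.rec("g", 300, "a"), self.rec("g", 510, "b")])
        row = out.iloc[0]
        sd = np.std([300, 510], ddof=1)
        assert row["mean"] == 405.0
        assert row["se"] == pytest.approx(sd / np.sqrt(2))
        assert row["se"] == pytest.approx(105.0)

    def test_record_order_invariance(self):
        recs = [self.rec("g1", 10, "a"), self.rec("g2", 5, "b"), self.rec("g1", 30, "c")]
        a = summarize_groups(recs)
        b = summarize_groups(list(reversed(recs)))
        pd.testing.assert_frame_equal(a, b)
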
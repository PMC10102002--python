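import pytest

from tdmdscreen.hybrid_caller import (
    HybridRecord,
    aggregate_hybrids,
    build_kmer_index,
    call_hybrids,
    extend_target_3prime,
    map_fragment,
    split_chimera,
)
from tdmdscreen.io_formats import MiRNA, Transcript
from tdmdscreen.preprocess import CleanRead
from tdmdscreen.screen import DEFAULT_CONFIG


def _random_rna(rng, n):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


@pytest.fixture
def mirna(rng):
    return MiRNA("mir-x", _random_rna(rng, 22))


@pytest.fixture
def transcripts(rng):
    return [
        Transcript(f"tx-{i}", f"g{i}", _random_rna(rng, 300), cds_end=150)
        for i in range(5)
    ]


class TestKmerIndex:
    def test_all_positions_indexed(self):
        t = Transcript("t", "g", "ACGUACGUACGUACGUACGU", cds_end=0)  # 20 nt
        idx = build_kmer_index([t], k=12)
        assert sum(len(idx.hits(t.sequence[i : i + 12])) for i in range(9)) >= 9

    def test_absent_kmer_gives_no_hits(self):
        idx = build_kmer_index([Transcript("t", "g", "A" * 50, cds_end=0)], k=12)
        assert idx.hits("ACGUACGUACGU") == []

    def test_short_transcript_skipped_with_warning(self):
        idx = build_kmer_index([Transcript("t", "g", "ACGUA" * 4, cds_end=0)], k=30)
        assert idx.skipped == ["t"]


class TestSplitChimera:
    def test_mirna_first(self, mirna, rng):
        frag = _random_rna(rng, 30)
        split = split_chimera(mirna.sequence + frag, [mirna])
        assert split is not None
        assert split.order == "mirna_first"
        assert split.mirna_span == (0, 22)
        assert split.fragment == frag

    def test_mirna_last(self, mirna, rng):
        frag = _random_rna(rng, 30)
        split = split_chimera(frag + mirna.sequence, [mirna])
        assert split.order == "mirna_last"
        assert split.fragment == frag

    def test_no_match_returns_none(self, mirna, rng):
        assert split_chimera(_random_rna(rng, 60), [mirna]) is None

    def test_short_fragment_returns_none(self, mirna, rng):
        read = mirna.sequence + _random_rna(rng, 11)
        assert split_chimera(read, [mirna]) is None

    def test_longest_match_wins(self, rng):
        seq = _random_rna(rng, 22)
        m_long = MiRNA("b-long", seq)
        m_short = MiRNA("a-short", seq[:20] + "A" * 0 + seq[20:22])  # identical
        # identical sequences: tie broken lexicographically by id
        split = split_chimera(seq + _random_rna(rng, 30), [m_long, m_short])
        assert split.mirna_id == "a-short"


class TestMapFragment:
    def test_exact_hit_located(self, transcripts):
        frag = transcripts[2].sequence[100:130]
        idx = build_kmer_index(transcripts)
        assert map_fragment(frag, idx) == [("tx-2", 100, 130)]

    def test_multi_transcript_hits_all_reported(self, rng):
        shared = _random_rna(rng, 30)
        ts = [
            Transcript("a", "a", _random_rna(rng, 50) + shared + _random_rna(rng, 50), cds_end=0),
            Transcript("b", "b", _random_rna(rng, 80) + shared, cds_end=0),
        ]
        idx = build_kmer_index(ts)
        assert map_fragment(shared, idx) == [("a", 50, 80), ("b", 80, 110)]

    def test_one_mismatch_gives_no_hit(self, transcripts):
        frag = list(transcripts[0].sequence[50:80])
        frag[15] = {"A": "C"}.get(frag[15], "A")
        idx = build_kmer_index(transcripts)
        assert map_fragment("".join(frag), idx) == []


class TestExtension:
    @pytest.mark.parametrize(
        "hit,tlen,expect",
        [((100, 130), 1000, (100, 155)), ((100, 990), 1000, (100, 1000)),
         ((100, 1000), 1000, (100, 1000))],
    )
    def test_25nt_clamped_extension(self, hit, tlen, expect):
        assert extend_target_3prime(hit, tlen) == expect


def _rec(mirna, tx, start, end, n, lib):
    return HybridRecord(mirna, tx, start, end, n, lib)


class TestAggregate:
    COND = {"c1": "control", "ko1": "ko"}
    TOTALS = {"c1": 1_000_000, "ko1": 1_000_000}

    def test_nearby_sites_merged_with_summed_counts(self):
        recs = [_rec("m", "t", 100, 155, 3, "ko1"), _rec("m", "t", 104, 160, 2, "ko1")]
        (s,) = aggregate_hybrids(recs, self.COND, self.TOTALS)
        assert (s.site_start, s.site_end) == (100, 160)
        assert s.counts == {"ko1": 5}

    def test_distant_sites_stay_separate(self):
        recs = [_rec("m", "t", 100, 130, 1, "ko1"), _rec("m", "t", 400, 430, 1, "ko1")]
        assert len(aggregate_hybrids(recs, self.COND, self.TOTALS)) == 2

    def test_rpm_formula(self):
        recs = [_rec("m", "t", 0, 30, 240, "ko1")]
        (s,) = aggregate_hybrids(recs, self.COND, {"c1": 2_000_000, "ko1": 2_000_000})
        assert s.ko_rpm == pytest.approx(120.0)

    def test_fold_change_with_pseudocount(self):
        recs = [
            _rec("m", "t", 0, 30, 120, "ko1"),
            _rec("m", "t", 0, 30, 20, "c1"),
        ]
        (s,) = aggregate_hybrids(recs, self.COND, self.TOTALS)
        assert s.fold_change == pytest.approx((120 + 0.1) / (20 + 0.1))

    def test_zero_control_flagged_infinite(self):
        recs = [_rec("m", "t", 0, 30, 500, "ko1")]
        (s,) = aggregate_hybrids(recs, self.COND, self.TOTALS)
        assert s.infinite_fold
        assert s.fold_change > DEFAULT_CONFIG.fold_min

    def test_unmapped_library_is_an_error(self):
        with pytest.raises(ValueError, match="condition map"):
            aggregate_hybrids([_rec("m", "t", 0, 30, 1, "zz")], self.COND, self.TOTALS)

    def test_order_independence(self, rng):
        recs = [
            _rec("m", "t", int(s), int(s) + 30, int(n), lib)
            for s, n, lib in zip(
                rng.integers(0, 500, 30), rng.integers(1, 9, 30),
                ["c1", "ko1"] * 15,
            )
        ]
        a = aggregate_hybrids(recs, self.COND, self.TOTALS)
        b = aggregate_hybrids(list(reversed(recs)), self.COND, self.TOTALS)
        assert a == b


def test_planted_chimeras_fully_recovered(rng):
    """Every exact-fragment chimera is split and mapped (recall 1.0)."""
    mirnas = [MiRNA(f"m{i}", _random_rna(rng, 22)) for i in range(5)]
    transcripts = [
        Transcript(f"t{i}", f"g{i}", _random_rna(rng, 400), cds_end=200)
        for i in range(5)
    ]
    idx = build_kmer_index(transcripts)
    reads, expected = [], set()
    for k in range(60):
        m = mirnas[k % 5]
        t = transcripts[(k * 2) % 5]
        start = 40 + 5 * k % 300
        frag = t.sequence[start : start + 30]
        insert = m.sequence + frag if k % 2 else frag + m.sequence
        reads.append(CleanRead(insert, "AAAA", "CCCC"))
        expected.add((m.id, t.id))
    records, stats = call_hybrids(reads, mirnas, idx, "lib1")
    assert stats["hybrid"] == len(reads)
    assert {(r.mirna_id, r.transcript_id) for r in records} == expected
    assert sum(r.read_count for r in records) == len(reads)
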
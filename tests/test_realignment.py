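import numpy as np
import pytest

from hlaloh.hla_alleles import HlaAllele, MismatchSite
from hlaloh.realignment import (
    AlleleAlignment,
    ReadRecord,
    align_reads_to_allele,
    best_allele_assignment,
    compute_coverage,
    extract_candidate_reads,
    filter_alignments,
    site_coverage_unique,
)
from hlaloh.synthetic_data import SimConfig, make_homolog_pair, simulate_sample_reads
from conftest import write_tiny_bam
from oracles import edit_distance_events, stab_coverage

REGION_START = 29_909_037 - 1  # 0-based


def _pair(name, pos, seq="ACGT" * 25):
    return [(name, 1, pos, seq, pos + 200), (name, 2, pos + 200, seq, pos)]


class TestExtractCandidateReads:
    def test_region_pairs_extracted_others_ignored(self, tmp_path):
        records = []
        for i in range(10):
            records += _pair(f"in_{i}", REGION_START + 10 * i)
        for i in range(5):
            records += _pair(f"out_{i}", 1_000_000 + 10 * i)
        bam = write_tiny_bam(tmp_path / "t.bam", records)
        reads = extract_candidate_reads(bam)
        assert len(reads) == 20
        assert all(r.name.startswith("in_") for r in reads)

    def test_unpaired_survivor_removed(self, tmp_path):
        records = _pair("ok", REGION_START + 5)
        # mate-unmapped singleton inside the region
        records.append(("widow", 1, REGION_START + 7, "ACGT" * 25, None))
        bam = write_tiny_bam(tmp_path / "t.bam", records)
        reads = extract_candidate_reads(bam)
        assert sorted({r.name for r in reads}) == ["ok"]

    def test_empty_overlap_returns_empty(self, tmp_path):
        bam = write_tiny_bam(tmp_path / "t.bam", _pair("far", 5_000_000))
        assert extract_candidate_reads(bam) == []

    def test_unindexed_file_rejected(self, tmp_path):
        bam = write_tiny_bam(tmp_path / "t.bam", [])
        (tmp_path / "t.bam.bai").unlink()
        with pytest.raises(ValueError, match="index"):
            extract_candidate_reads(bam)


class TestAlignReadsToAllele:
    def test_exact_substring_zero_events(self, small_allele):
        read = ReadRecord("r", 1, small_allele.sequence[100:150])
        (aln,) = align_reads_to_allele([read], small_allele)
        assert (aln.start, aln.subs, aln.ins_events, aln.del_events) == (101, 0, 0, 0)
        assert aln.score == 50

    def test_single_substitution_counted(self, small_allele):
        seq = list(small_allele.sequence[100:150])
        seq[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[20]]
        (aln,) = align_reads_to_allele([ReadRecord("r", 1, "".join(seq))], small_allele)
        assert (aln.subs, aln.ins_events, aln.del_events) == (1, 0, 0)

    def test_contiguous_deletion_is_one_event(self, small_allele):
        ref = small_allele.sequence[100:150]
        read = ref[:20] + ref[23:]  # 3-base deletion
        (aln,) = align_reads_to_allele([ReadRecord("r", 1, read)], small_allele)
        assert (aln.subs, aln.ins_events, aln.del_events) == (0, 0, 1)
        assert edit_distance_events(read, small_allele.sequence) == (0, 0, 1)

    def test_event_counts_match_dp_oracle(self, small_allele, rng):
        for _ in range(10):
            start = int(rng.integers(0, 340))
            seq = list(small_allele.sequence[start:start + 60])
            k = int(rng.integers(0, 2))
            for p in rng.choice(60, size=k, replace=False):
                seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
            read = "".join(seq)
            (aln,) = align_reads_to_allele([ReadRecord("r", 1, read)], small_allele)
            assert (aln.subs, aln.ins_events, aln.del_events) == \
                edit_distance_events(read, small_allele.sequence)

    def test_unalignable_read_absent(self, small_allele):
        junk = "A" * 50
        assert align_reads_to_allele([ReadRecord("r", 1, junk)], small_allele) == []


def _aln(name, mate, allele, start, subs=0, ins=0, dels=0, length=50):
    return AlleleAlignment(
        read=ReadRecord(name, mate, "A" * length),
        allele=allele, start=start, subs=subs, ins_events=ins, del_events=dels,
        ref_bases="A" * length, score=float(length - 2 * subs),
    )


class TestFilterAlignments:
    def test_two_events_discarded_one_kept(self):
        best = {("a", 1): "h1", ("b", 1): "h1"}
        kept = filter_alignments([_aln("a", 1, "h1", 1, subs=2),
                                  _aln("b", 1, "h1", 1, subs=1)], best)
        assert [a.read.name for a in kept] == ["b"]

    def test_mixed_event_budget_is_total(self):
        best = {("a", 1): "h1"}
        assert filter_alignments([_aln("a", 1, "h1", 1, subs=1, dels=1)], best) == []

    def test_mate_on_other_allele_discards_both(self):
        best = {("p", 1): "h1", ("p", 2): "h2"}
        kept1 = filter_alignments([_aln("p", 1, "h1", 1)], best)
        kept2 = filter_alignments([_aln("p", 2, "h2", 1)], best)
        assert kept1 == [] and kept2 == []

    def test_mate_tie_does_not_discard(self):
        best = {("p", 1): "h1", ("p", 2): None}
        assert len(filter_alignments([_aln("p", 1, "h1", 1)], best)) == 1

    def test_read_best_elsewhere_removed_from_this_allele(self):
        best = {("a", 1): "h2"}
        assert filter_alignments([_aln("a", 1, "h1", 1)], best) == []


class TestBestAlleleAssignment:
    def test_tie_marks_none(self):
        per = {"h1": [_aln("a", 1, "h1", 1)], "h2": [_aln("a", 1, "h2", 1)]}
        assert best_allele_assignment(per) == {("a", 1): None}

    def test_strict_best_wins(self):
        per = {"h1": [_aln("a", 1, "h1", 1, subs=0)],
               "h2": [_aln("a", 1, "h2", 1, subs=1)]}
        assert best_allele_assignment(per) == {("a", 1): "h1"}


class TestComputeCoverage:
    def test_full_length_reads_uniform_depth(self):
        allele = HlaAllele("h1", "ACGT" * 25)
        alns = [_aln(f"r{i}", 1, "h1", 1, length=100) for i in range(10)]
        track = compute_coverage(alns, allele, "tumor")
        assert np.all(track.depth == 10)
        assert track.n_unique_reads == 10

    def test_no_alignments_zero_track(self):
        allele = HlaAllele("h1", "ACGT" * 25)
        track = compute_coverage([], allele, "tumor")
        assert np.all(track.depth == 0) and track.n_unique_reads == 0

    def test_staggered_reads_match_stab_oracle(self, rng):
        allele = HlaAllele("h1", "ACGT" * 50)
        starts = rng.integers(1, 151, size=40)
        alns = [_aln(f"r{i}", 1, "h1", int(s)) for i, s in enumerate(starts)]
        track = compute_coverage(alns, allele, "g")
        expected = stab_coverage([(int(s), int(s) + 49) for s in starts], 200)
        assert np.array_equal(track.depth, expected)


class TestSiteCoverageUnique:
    SITES = [MismatchSite("A", 10, 10, "A", "C"), MismatchSite("A", 30, 30, "A", "C")]

    def test_read_spanning_two_sites_counts_once(self):
        alns = [_aln("r", 1, "h1", 1, length=50)]
        cov = site_coverage_unique(alns, self.SITES, [10, 30])
        assert cov.depth.sum() == 1

    def test_disjoint_reads_equal_plain_depth(self):
        alns = [_aln("a", 1, "h1", 5, length=10), _aln("b", 1, "h1", 25, length=10)]
        cov = site_coverage_unique(alns, self.SITES, [10, 30])
        assert list(cov.depth) == [1, 1]

    def test_total_never_exceeds_read_count(self, rng):
        sites = [MismatchSite("A", int(p), int(p), "A", "C")
                 for p in sorted(rng.choice(np.arange(5, 195), size=8, replace=False))]
        alns = [_aln(f"r{i}", 1, "h1", int(s), length=40)
                for i, s in enumerate(rng.integers(1, 160, size=30))]
        cov = site_coverage_unique(alns, sites, [s.pos1 for s in sites])
        assert cov.depth.sum() <= 30
        plain = stab_coverage([(a.start, a.end) for a in alns], 200)
        for s, d in zip(sites, cov.depth):
            assert d <= plain[s.pos1 - 1]

    def test_deleted_base_carries_no_site_evidence(self):
        aln = AlleleAlignment(
            read=ReadRecord("r", 1, "A" * 47), allele="h1", start=1,
            subs=0, ins_events=0, del_events=1,
            ref_bases="A" * 9 + "-" + "A" * 40, score=44.0,
        )
        cov = site_coverage_unique([aln], self.SITES, [10, 30])
        assert list(cov.depth) == [0, 1]


class TestSimulatedReadsRoundTrip:
    def test_error_free_reads_pass_filters_onto_source_allele(self):
        cfg = SimConfig(seed=5, gene_length=600, n_substitutions=12,
                        germline_depth=20.0)
        a1, a2, _ = make_homolog_pair(cfg)
        reads = simulate_sample_reads((a1, a2), cfg, "germline")
        per = {a.name: align_reads_to_allele(reads, a) for a in (a1, a2)}
        best = best_allele_assignment(per)
        for allele_name, alns in per.items():
            kept = filter_alignments(alns, best)
            assert all(a.n_events <= 1 for a in kept)
            for a in kept:
                src = "h1" if "_h1_" in a.read.name else "h2"
                own = {a1.name: "h1", a2.name: "h2"}[allele_name]
                # a uniquely assigned read always maps to its source allele
                if best[a.read.key] == allele_name:
                    assert src == own
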
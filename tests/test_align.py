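"""Alignment contract: exactness against an independent DP oracle, strand
symmetry of mapping, coordinate coverage, and region extraction rules."""

import numpy as np
import pytest

from deqseq.align import (AlignmentResult, Scoring, align_pair,
                          coverage_filter, extract_region, ops_score,
                          orient_and_map, oriented_seq, query_interval)
from deqseq.qc import ReadRecord, revcomp
from deqseq.simulate import SimConfig, SimTruth, render_fragment, simulate_reads


def oracle_affine_score(q, r, mode, sc):
    """Independent plain-loop Gotoh DP (no vectorisation, no traceback)."""
    NEG = float("-inf")
    m, n = len(q), len(r)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    for j in range(1, n + 1):
        H[0][j] = 0.0 if mode == "semiglobal" else sc.gap_open + sc.gap_extend * j
        if mode == "global":
            E[0][j] = H[0][j]
    for i in range(1, m + 1):
        H[i][0] = F[i][0] = sc.gap_open + sc.gap_extend * i
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + sc.gap_open, E[i][j - 1]) + sc.gap_extend
            F[i][j] = max(H[i - 1][j] + sc.gap_open, F[i - 1][j]) + sc.gap_extend
            s = sc.match if q[i - 1] == r[j - 1] else sc.mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return max(H[m]) if mode == "semiglobal" else H[m][n]


def enumerate_alignments_score(q, r, sc):
    """Exhaustive enumeration of every global alignment (tiny inputs only),
    scoring gap runs as open + len*extend; validates the DP oracle itself."""
    best = float("-inf")

    def go(i, j, score, last):
        nonlocal best
        if i == len(q) and j == len(r):
            best = max(best, score)
            return
        if i < len(q) and j < len(r):
            s = sc.match if q[i] == r[j] else sc.mismatch
            go(i + 1, j + 1, score + s, "M")
        if i < len(q):
            opened = 0 if last == "I" else sc.gap_open
            go(i + 1, j, score + opened + sc.gap_extend, "I")
        if j < len(r):
            opened = 0 if last == "D" else sc.gap_open
            go(i, j + 1, score + opened + sc.gap_extend, "D")

    go(0, 0, 0.0, "")
    return best


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestAlignPair:
    def test_identity_alignment(self):
        res = align_pair("ACGTACGT", "ACGTACGT", "global")
        assert res.identity == 1.0 and res.ops == "=" * 8
        assert res.score == 8 * Scoring().match

    def test_single_substitution_identity(self, rng):
        ref = random_seq(rng, 100)
        q = ref[:50] + ("A" if ref[50] != "A" else "C") + ref[51:]
        res = align_pair(q, ref, "global")
        assert res.identity == pytest.approx(0.99)

    def test_enumeration_validates_oracle(self, rng):
        sc = Scoring()
        for _ in range(30):
            q = random_seq(rng, int(rng.integers(1, 6)))
            r = random_seq(rng, int(rng.integers(1, 6)))
            assert oracle_affine_score(q, r, "global", sc) == pytest.approx(
                enumerate_alignments_score(q, r, sc))

    def test_matches_dp_oracle_on_1000_random_pairs(self, rng):
        scorings = [Scoring(), Scoring(1, -1, -2, -1), Scoring(2, -3, 0, -2)]
        for trial in range(1000):
            sc = scorings[trial % len(scorings)]
            mode = ("global", "semiglobal")[trial % 2]
            q = random_seq(rng, int(rng.integers(1, 13)))
            r = random_seq(rng, int(rng.integers(1, 13)))
            res = align_pair(q, r, mode, sc)
            assert res.score == pytest.approx(oracle_affine_score(q, r, mode, sc))
            # traceback must rescore to the optimum
            assert ops_score(res.ops, sc) == pytest.approx(res.score)


def noiseless_reads(layout, n=4, seed=0, flip=0.0):
    tids = tuple(t.target_id for t in layout.targets)
    cfg = SimConfig(n_variants=1, reads_per_variant=n, gene_mutation_rate=0.0,
                    umi_length=layout.umi_length, sub_rate=0, ins_rate=0,
                    del_rate=0, strand_flip_prob=flip, seed=seed,
                    rate_ranges={t: (0.0, 0.0) for t in tids})
    from deqseq.simulate import make_library

    truths = make_library(cfg, layout.region(layout.gene_span),
                          target_ids=tuple(t.target_id for t in layout.targets))
    reads, truths, _ = simulate_reads(truths, layout, cfg)
    return reads, truths


class TestOrientAndMap:
    def test_noiseless_forward_read_is_exact(self, toy_layout):
        reads, _ = noiseless_reads(toy_layout)
        aln = orient_and_map(reads[0], toy_layout)
        assert aln.orientation == "+"
        # only the 20 N columns of the barcode region mismatch
        assert aln.ops.count("X") == 20 and "I" not in aln.ops and "D" not in aln.ops

    def test_strand_symmetry(self, toy_layout):
        reads, _ = noiseless_reads(toy_layout)
        read = reads[0]
        rc = ReadRecord(read.read_id, revcomp(read.seq), read.qual[::-1])
        fwd, rev = orient_and_map(read, toy_layout), orient_and_map(rc, toy_layout)
        assert rev.orientation == "-"
        assert fwd.identity == rev.identity
        assert (fwd.ref_start, fwd.ref_end) == (rev.ref_start, rev.ref_end)
        assert oriented_seq(rc, rev) == read.seq

    def test_noisy_reads_orient_correctly(self, toy_layout):
        cfg = SimConfig(n_variants=1, reads_per_variant=300, sub_rate=0.05,
                        ins_rate=0.01, del_rate=0.01, umi_length=20, seed=3)
        from deqseq.simulate import make_library

        truths = make_library(cfg, toy_layout.region(toy_layout.gene_span),
                              target_ids=("bt", "lox"))
        reads, truths, _ = simulate_reads(truths, toy_layout, cfg)
        alns = [orient_and_map(read, toy_layout) for read in reads]
        # ~7 % channel error plus the 20 always-mismatching N columns of the
        # barcode region on a ~190 nt fragment: every read still maps well
        # above the 0.60 floor
        assert all(a is not None for a in alns)
        idents = sorted(a.identity for a in alns)
        assert idents[0] > 0.60
        assert idents[len(idents) // 2] > 0.75

    def test_garbage_read_is_unmapped(self, toy_layout, rng):
        junk = ReadRecord("junk", random_seq(rng, 200),
                          np.full(200, 20, dtype=np.int16))
        assert orient_and_map(junk, toy_layout) is None


class TestCoverageAndExtraction:
    def test_coverage_filter_boundaries(self, toy_layout):
        g0 = toy_layout.gene_span[0]
        u1 = toy_layout.umi_span[1]
        full = AlignmentResult("q", "toy", "+", 0, len(toy_layout.ref_seq), "", 0)
        assert coverage_filter(full, toy_layout)
        inside_gene = AlignmentResult("q", "toy", "+", g0 + 10, len(toy_layout.ref_seq), "", 0)
        assert not coverage_filter(inside_gene, toy_layout)
        short_end = AlignmentResult("q", "toy", "+", 0, u1 - 1, "", 0)
        assert not coverage_filter(short_end, toy_layout)

    def test_noiseless_extraction_is_exact_for_every_span(self, toy_layout):
        reads, truths = noiseless_reads(toy_layout)
        read, truth = reads[0], truths[0]
        aln = orient_and_map(read, toy_layout)
        assert extract_region(read.seq, aln, toy_layout.umi_span) == truth.umi
        assert extract_region(read.seq, aln, toy_layout.gene_span) == truth.gene_seq
        t = toy_layout.targets[0]
        assert extract_region(read.seq, aln, t.span) == t.unedited_allele

    def test_deletion_and_insertion_inside_umi_change_length(self, toy_layout):
        reads, _ = noiseless_reads(toy_layout)
        seq = reads[0].seq
        u0, u1 = toy_layout.umi_span
        # the noiseless read is coordinate-identical to the reference
        del_read = ReadRecord("d", seq[: u0 + 5] + seq[u0 + 6:],
                              np.full(len(seq) - 1, 20, dtype=np.int16))
        aln = orient_and_map(del_read, toy_layout)
        assert len(extract_region(del_read.seq, aln, toy_layout.umi_span)) == u1 - u0 - 1
        ins_read = ReadRecord("i", seq[: u0 + 5] + "A" + seq[u0 + 5:],
                              np.full(len(seq) + 1, 20, dtype=np.int16))
        aln = orient_and_map(ins_read, toy_layout)
        assert len(extract_region(ins_read.seq, aln, toy_layout.umi_span)) == u1 - u0 + 1

    def test_boundary_insertions_belong_to_the_left_region(self):
        # constructed alignment: 4 matches, insertion, 4 matches on ref "AAAATTTT"
        aln = AlignmentResult("q", "r", "+", 0, 8, "====I====", 0)
        seq = "AAAAGTTTT"
        # insertion sits at ref position 4: left region [0,4) includes it...
        assert extract_region(seq, aln, (0, 4)) == "AAAAG"
        # ...and the right region [4,8) excludes it
        assert extract_region(seq, aln, (4, 8)) == "TTTT"
        assert query_interval(aln, (4, 8)) == (5, 9)

    def test_uncovered_span_raises(self):
        aln = AlignmentResult("q", "r", "+", 2, 6, "====", 0)
        with pytest.raises(ValueError):
            extract_region("ACGT", aln, (0, 6))


def test_fragment_rendering_roundtrip_through_mapping(toy_layout):
    """An edited fragment maps cleanly and classifies by coordinates."""
    truth = SimTruth("v0", toy_layout.region(toy_layout.gene_span), "A" * 20,
                     {"bt": 0.0, "lox": 0.0})
    frag = render_fragment(truth, toy_layout, {"bt": False, "lox": True})
    read = ReadRecord("r", frag, np.full(len(frag), 20, dtype=np.int16))
    aln = orient_and_map(read, toy_layout)
    assert aln is not None and coverage_filter(aln, toy_layout)
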
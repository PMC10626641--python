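"""Synthetic screen generator: library statistics, fragment rendering,
the error channel, and full determinism."""

import numpy as np
import pytest

from deqseq.align import edlib_global
from deqseq.simulate import (SimConfig, make_library, render_fragment,
                             simulate_reads, truth_table)


@pytest.fixture(scope="module")
def layout():
    from deqseq.simulate import example_layout

    return example_layout(seed=3, gene_len=600)


@pytest.fixture(scope="module")
def excision_layout():
    from deqseq.simulate import example_layout

    return example_layout(seed=3, gene_len=600, excision=True)


def target_ids(layout):
    return tuple(t.target_id for t in layout.targets)


class TestMakeLibrary:
    def test_zero_mutation_rate_reproduces_reference(self, layout):
        cfg = SimConfig(n_variants=5, gene_mutation_rate=0.0, seed=1)
        gene = layout.region(layout.gene_span)
        truths = make_library(cfg, gene, target_ids=target_ids(layout))
        assert all(t.gene_seq == gene for t in truths)

    def test_seeded_runs_are_identical(self, layout):
        cfg = SimConfig(n_variants=8, seed=13)
        gene = layout.region(layout.gene_span)
        a = make_library(cfg, gene, target_ids=target_ids(layout))
        b = make_library(cfg, gene, target_ids=target_ids(layout))
        assert [(t.gene_seq, t.umi, t.rates) for t in a] == \
               [(t.gene_seq, t.umi, t.rates) for t in b]

    def test_umis_are_unique_and_right_length(self, layout):
        cfg = SimConfig(n_variants=200, seed=2)
        truths = make_library(cfg, layout.region(layout.gene_span),
                              target_ids=target_ids(layout))
        umis = [t.umi for t in truths]
        assert len(set(umis)) == len(umis)
        assert all(len(u) == 50 for u in umis)

    def test_substitution_rate_matches_binomial_expectation(self):
        # 1000 variants x 1000 bases at rate 0.005
        rng = np.random.default_rng(0)
        gene = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
        cfg = SimConfig(n_variants=1000, gene_mutation_rate=0.005, seed=4)
        truths = make_library(cfg, gene)
        n_sub = sum(sum(a != b for a, b in zip(t.gene_seq, gene)) for t in truths)
        n_total = 1000 * 1000
        sd = np.sqrt(n_total * 0.005 * 0.995)
        assert abs(n_sub - n_total * 0.005) <= 3 * sd

    def test_controls_are_exact_copies(self, layout):
        gene = layout.region(layout.gene_span)
        control = gene[:-1] + ("A" if gene[-1] != "A" else "C")
        cfg = SimConfig(n_variants=6, n_controls=2, seed=5)
        truths = make_library(cfg, gene, control_ref=control,
                              target_ids=target_ids(layout))
        assert [t.gene_seq for t in truths[:2]] == [control, control]
        assert all(t.is_control for t in truths[:2])
        assert not any(t.is_control for t in truths[2:])


class TestRenderFragment:
    def test_all_unedited_equals_reference_with_substituted_regions(self, layout):
        cfg = SimConfig(n_variants=1, gene_mutation_rate=0.0, seed=1)
        truth = make_library(cfg, layout.region(layout.gene_span),
                             target_ids=target_ids(layout))[0]
        frag = render_fragment(truth, layout,
                               {t: False for t in target_ids(layout)})
        u0, u1 = layout.umi_span
        expected = layout.ref_seq[:u0] + truth.umi + layout.ref_seq[u1:]
        assert frag == expected

    def test_excision_shortens_fragment_by_741(self, excision_layout):
        cfg = SimConfig(n_variants=1, seed=1)
        truth = make_library(cfg, excision_layout.region(excision_layout.gene_span),
                             target_ids=("lox",))[0]
        unedited = render_fragment(truth, excision_layout, {"lox": False})
        recombined = render_fragment(truth, excision_layout, {"lox": True})
        assert len(unedited) - len(recombined) == 741

    def test_base_edit_changes_only_expected_adenines(self, layout):
        cfg = SimConfig(n_variants=1, seed=1)
        truth = make_library(cfg, layout.region(layout.gene_span),
                             target_ids=target_ids(layout))[0]
        tid = target_ids(layout)[0]
        outcomes = {t: False for t in target_ids(layout)}
        unedited = render_fragment(truth, layout, outcomes)
        outcomes[tid] = True
        edited = render_fragment(truth, layout, outcomes)
        assert len(edited) == len(unedited)
        site = layout.target(tid)
        ws, we = site.window_span
        diffs = [i for i, (a, b) in enumerate(zip(unedited, edited)) if a != b]
        expected_pos = [ws + o for o in (1, 2) if site.unedited_window[o] == "A"]
        assert diffs == expected_pos
        assert all(unedited[i] == "A" and edited[i] == "G" for i in diffs)

    def test_unknown_target_raises(self, layout):
        cfg = SimConfig(n_variants=1, seed=1)
        truth = make_library(cfg, layout.region(layout.gene_span),
                             target_ids=target_ids(layout))[0]
        with pytest.raises(KeyError):
            render_fragment(truth, layout, {"nope": False})


class TestSimulateReads:
    def test_noiseless_channel_is_identity(self, layout):
        cfg = SimConfig(n_variants=3, reads_per_variant=5, sub_rate=0,
                        ins_rate=0, del_rate=0, strand_flip_prob=0,
                        rate_ranges={t: (0.0, 0.0) for t in target_ids(layout)},
                        seed=6)
        truths = make_library(cfg, layout.region(layout.gene_span),
                              target_ids=target_ids(layout))
        reads, truths, _ = simulate_reads(truths, layout, cfg)
        frags = {t.variant_id: render_fragment(t, layout,
                 {x: False for x in target_ids(layout)}) for t in truths}
        for r in reads:
            vid = r.read_id.rsplit("_r", 1)[0]
            assert r.seq == frags[vid]

    def test_seeded_fastq_is_reproducible(self, layout):
        cfg = SimConfig(n_variants=4, reads_per_variant=10, seed=9)
        gene = layout.region(layout.gene_span)
        out = []
        for _ in range(2):
            truths = make_library(cfg, gene, target_ids=target_ids(layout))
            reads, truths, rt = simulate_reads(truths, layout, cfg)
            out.append(([(r.read_id, r.seq, r.qual.tolist()) for r in reads],
                        truth_table(truths).to_csv(sep="\t"), rt.to_csv(sep="\t")))
        assert out[0] == out[1]

    def test_error_rate_matches_channel_setting(self, layout):
        cfg = SimConfig(n_variants=1, reads_per_variant=100, sub_rate=0.05,
                        ins_rate=0, del_rate=0, strand_flip_prob=0,
                        gene_mutation_rate=0.0,
                        rate_ranges={t: (0.0, 0.0) for t in target_ids(layout)},
                        seed=10)
        truths = make_library(cfg, layout.region(layout.gene_span),
                              target_ids=target_ids(layout))
        reads, truths, _ = simulate_reads(truths, layout, cfg)
        frag = render_fragment(truths[0], layout,
                               {t: False for t in target_ids(layout)})
        # with indels off, reads are positionally comparable to the fragment
        mism = sum(sum(a != b for a, b in zip(r.seq, frag)) for r in reads)
        total = len(frag) * len(reads)
        assert all(len(r.seq) == len(frag) for r in reads)
        sd = np.sqrt(total * 0.05 * 0.95)
        assert abs(mism - 0.05 * total) <= 3 * sd
        # and the alignment view agrees closely (gapped paths may explain a
        # few substitutions more cheaply)
        ops, _ = edlib_global(reads[0].seq, frag)
        assert abs(ops.count("X") - sum(a != b for a, b in zip(reads[0].seq, frag))) <= 3

    def test_realized_fractions_converge_to_true_rates(self, layout):
        tids = target_ids(layout)
        cfg = SimConfig(n_variants=1, reads_per_variant=10000, sub_rate=0,
                        ins_rate=0, del_rate=0,
                        rate_ranges={tids[0]: (0.37, 0.37),
                                     tids[1]: (0.9, 0.9), tids[2]: (0.05, 0.05)},
                        seed=11)
        truths = make_library(cfg, layout.region(layout.gene_span), target_ids=tids)
        _, truths, _ = simulate_reads(truths, layout, cfg)
        t = truths[0]
        for tid in tids:
            p = t.rates[tid]
            frac = t.realized_edited[tid] / t.realized_reads
            sd = np.sqrt(p * (1 - p) / 10000)
            assert abs(frac - p) <= 3 * max(sd, 1e-6)

    def test_strand_flip_produces_both_orientations(self, layout):
        cfg = SimConfig(n_variants=1, reads_per_variant=60, sub_rate=0,
                        ins_rate=0, del_rate=0, strand_flip_prob=0.5,
                        gene_mutation_rate=0.0,
                        rate_ranges={t: (0.0, 0.0) for t in target_ids(layout)},
                        seed=12)
        truths = make_library(cfg, layout.region(layout.gene_span),
                              target_ids=target_ids(layout))
        reads, truths, _ = simulate_reads(truths, layout, cfg)
        frag = render_fragment(truths[0], layout,
                               {t: False for t in target_ids(layout)})
        n_fwd = sum(r.seq == frag for r in reads)
        assert 10 <= n_fwd <= 50  # ~Binomial(60, 0.5)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(sub_rate=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_variants=0)
    with pytest.raises(ValueError):
        SimConfig(n_controls=5, n_variants=3)
    with pytest.raises(ValueError):
        SimConfig(rate_ranges={"t": (0.8, 0.2)})
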
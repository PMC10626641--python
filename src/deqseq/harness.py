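"""Standard simulation studies: generate a synthetic screen, run the full
pipeline on it, and score recovery against the truth table.

These are the package's benchmark conditions.  The base-editing study uses
100 variants x 80 reads on a ~2.9 kb fragment with three 4-base editing
windows and a 4 % / 2 % / 2 % substitution/insertion/deletion channel; the
excision study uses one recombination target with the 741 bp excision on a
~3.1 kb fragment at 7 % total error.  Problem sizes are chosen so each
study runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import (RecoveryMetrics, evaluate_screen,
                       recombination_label_accuracy)
from .pipeline import RunConfig, ScreenResult, run_screen
from .simulate import (SimConfig, SimTruth, example_layout, make_library,
                       random_substitutions, simulate_reads)


@dataclass
class StudyResult:
    result: ScreenResult
    truths: list[SimTruth]
    read_truth: pd.DataFrame
    metrics: RecoveryMetrics


def _run(layout, cfg: SimConfig, run_cfg: RunConfig,
         truths: list[SimTruth] | None = None) -> StudyResult:
    gene = layout.region(layout.gene_span)
    if truths is None:
        truths = make_library(cfg, gene,
                              target_ids=tuple(t.target_id for t in layout.targets))
    reads, truths, read_truth = simulate_reads(truths, layout, cfg)
    result = run_screen(run_cfg, reads, log=None)
    return StudyResult(result=result, truths=truths, read_truth=read_truth,
                       metrics=evaluate_screen(result, truths))


def base_edit_study(seed: int, n_variants: int = 100, reads_per_variant: int = 80,
                    n_controls: int = 10) -> StudyResult:
    """Three base-editing targets, true rates uniform on [0, 1]."""
    layout = example_layout(seed=seed, gene_len=2600)
    cfg = SimConfig(n_variants=n_variants, reads_per_variant=reads_per_variant,
                    n_controls=n_controls, sub_rate=0.04, ins_rate=0.02,
                    del_rate=0.02, seed=seed)
    run_cfg = RunConfig(layout=layout, min_length=2500, min_mean_q=10.0)
    return _run(layout, cfg, run_cfg)


def excision_study(seed: int, n_variants: int = 60, reads_per_variant: int = 80,
                   n_controls: int = 6) -> StudyResult:
    """One excision target (741 bp), 7 % total read error."""
    layout = example_layout(seed=seed, gene_len=2100, excision=True)
    cfg = SimConfig(n_variants=n_variants, reads_per_variant=reads_per_variant,
                    n_controls=n_controls, sub_rate=0.03, ins_rate=0.02,
                    del_rate=0.02, seed=seed)
    # recombined fragments are 741 bp shorter, so the length filter sits
    # below the recombined length
    run_cfg = RunConfig(layout=layout, min_length=1800, min_mean_q=10.0)
    return _run(layout, cfg, run_cfg)


def excision_label_accuracy(study: StudyResult) -> tuple[float, int]:
    return recombination_label_accuracy(study.result, study.read_truth, "lox")


def control_discrimination_study(
    seed: int, n_controls: int = 10, n_near: int = 10, reads_per_variant: int = 80
) -> tuple[int, int, int, int]:
    """Spiked exact controls vs variants with exactly 6 DNA mutations.

    Returns (controls flagged, controls retained, near-variants flagged,
    near-variants retained): the first pair should be equal, the third
    entry zero — 6 mutations is just past the "5 or less" control rule.
    """
    layout = example_layout(seed=seed, gene_len=2600)
    gene = layout.region(layout.gene_span)
    cfg = SimConfig(n_variants=n_controls + n_near, reads_per_variant=reads_per_variant,
                    n_controls=n_controls, sub_rate=0.04, ins_rate=0.02,
                    del_rate=0.02, seed=seed)
    truths = make_library(cfg, gene,
                          target_ids=tuple(t.target_id for t in layout.targets))
    rng = np.random.default_rng(seed + 7)
    for t in truths[n_controls:]:
        t.gene_seq = random_substitutions(gene, 6, rng)
    study = _run(layout, cfg, RunConfig(layout=layout, min_length=2500), truths=truths)

    from .evaluate import majority_variant

    truth_by_id = {t.variant_id: t for t in study.truths}
    reports = {r.cluster_id: r for r in study.result.reports}
    c_flag = c_tot = n_flag = n_tot = 0
    for cl in study.result.retained:
        variant, _ = majority_variant(cl.member_read_ids)
        rep = reports[cl.cluster_id]
        if truth_by_id[variant].is_control:
            c_tot += 1
            c_flag += rep.is_control
        else:
            n_tot += 1
            n_flag += rep.is_control
    return c_flag, c_tot, n_flag, n_tot


def determinism_study(seed: int, workdir) -> bool:
    """Run a small screen twice with the same seed and compare the
    persisted report tables byte for byte."""
    workdir = Path(workdir)
    layout = example_layout(seed=seed, gene_len=500)
    cfg = SimConfig(n_variants=15, reads_per_variant=60, n_controls=2, seed=seed)
    gene = layout.region(layout.gene_span)
    blobs = []
    for tag in ("a", "b"):
        truths = make_library(cfg, gene,
                              target_ids=tuple(t.target_id for t in layout.targets))
        reads, truths, _ = simulate_reads(truths, layout, cfg)
        run_cfg = RunConfig(layout=layout, min_length=600, min_cluster_size=40,
                            min_reads_per_target=40)
        out = workdir / tag
        run_screen(run_cfg, reads, outdir=out, log=None)
        blobs.append(tuple(
            (p.name, p.read_bytes()) for p in sorted(out.glob("*.tsv"))
        ))
    return blobs[0] == blobs[1]
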
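"""Recovery metrics against a simulation truth table.

Given a processed screen and the generator's ground truth, these functions
measure what the pipeline is supposed to deliver: pure clusters, one
retained cluster per well-covered variant, per-target rates within
binomial sampling error of the realized edited fractions, error-free
consensus genes, and faithful control flagging.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import math

import pandas as pd

from .consensus import consensus_errors
from .pipeline import ScreenResult
from .simulate import SimTruth


def variant_of_read(read_id: str) -> str:
    return read_id.rsplit("_r", 1)[0]


def majority_variant(member_read_ids: list[str]) -> tuple[str, float]:
    """(most common source variant, its fraction of the cluster)."""
    counts = Counter(variant_of_read(rid) for rid in member_read_ids)
    variant, n = counts.most_common(1)[0]
    return variant, n / len(member_read_ids)


@dataclass
class RecoveryMetrics:
    n_retained_clusters: int
    pct_pure_clusters: float
    n_eligible_variants: int
    pct_variants_recovered: float
    n_rate_pairs: int
    pct_rates_within_3sd: float
    pct_consensus_error_free: float
    control_recall_pct: float | None
    control_false_positives: int


def evaluate_screen(result: ScreenResult, truths: list[SimTruth]) -> RecoveryMetrics:
    truth_by_id = {t.variant_id: t for t in truths}
    retained = result.retained
    reports = {r.cluster_id: r for r in result.reports}

    majorities = {c.cluster_id: majority_variant(c.member_read_ids) for c in retained}
    n_pure = sum(1 for _, frac in majorities.values() if frac == 1.0)
    pct_pure = 100.0 * n_pure / len(retained) if retained else 0.0

    # variants with enough surviving (mapped + covered) reads must come back
    # as exactly one retained cluster
    surviving = Counter(variant_of_read(m.read.read_id) for m in result.mapped)
    eligible = {v for v, n in surviving.items()
                if n >= result.config.min_cluster_size and v in truth_by_id}
    clusters_per_variant = Counter(v for v, _ in majorities.values())
    recovered = {v for v in eligible if clusters_per_variant[v] == 1}
    pct_recovered = 100.0 * len(recovered) / len(eligible) if eligible else 0.0

    # reported rates vs realized edited fractions, 3 binomial SDs at the
    # tally's classified-read count
    n_pairs = n_ok = 0
    floor = result.config.min_reads_per_target
    for cid, (variant, _) in majorities.items():
        truth = truth_by_id.get(variant)
        rep = reports.get(cid)
        if truth is None or rep is None or truth.realized_reads == 0:
            continue
        for tid in rep.target_ids():
            rate = rep.reported_rate(tid, floor)
            if rate is None:
                continue
            p = truth.realized_edited[tid] / truth.realized_reads
            n = rep.tally(tid).n_classified
            sd = math.sqrt(p * (1.0 - p) / n)
            n_pairs += 1
            if abs(rate / 100.0 - p) <= 3.0 * sd:
                n_ok += 1
    pct_rates = 100.0 * n_ok / n_pairs if n_pairs else 0.0

    n_exact = 0
    for cid, (variant, _) in majorities.items():
        rep = reports.get(cid)
        truth = truth_by_id.get(variant)
        if rep is None or truth is None or rep.genotype is None or rep.genotype.failed:
            continue
        if consensus_errors(rep.genotype.gene_dna, truth.gene_seq) == 0:
            n_exact += 1
    pct_exact = 100.0 * n_exact / len(retained) if retained else 0.0

    control_clusters = [cid for cid, (v, _) in majorities.items()
                        if truth_by_id.get(v) and truth_by_id[v].is_control]
    if control_clusters:
        flagged = sum(1 for cid in control_clusters
                      if reports[cid].is_control)
        recall = 100.0 * flagged / len(control_clusters)
    else:
        recall = None
    false_pos = sum(
        1 for cid, (v, _) in majorities.items()
        if reports[cid].is_control
        and not (truth_by_id.get(v) and truth_by_id[v].is_control)
    )
    return RecoveryMetrics(
        n_retained_clusters=len(retained),
        pct_pure_clusters=pct_pure,
        n_eligible_variants=len(eligible),
        pct_variants_recovered=pct_recovered,
        n_rate_pairs=n_pairs,
        pct_rates_within_3sd=pct_rates,
        pct_consensus_error_free=pct_exact,
        control_recall_pct=recall,
        control_false_positives=false_pos,
    )


def recombination_label_accuracy(
    result: ScreenResult, read_truth: pd.DataFrame, target_id: str
) -> tuple[float, int]:
    """Fraction of classifier calls matching the per-read simulated outcome.

    Ambiguous and excluded reads count as incorrect.  Returns
    (percent correct, number of reads judged).
    """
    truth_edit = dict(zip(read_truth["read_id"], read_truth[f"edited_{target_id}"]))
    n = ok = 0
    for read_id, hit in result.recomb_labels.items():
        if read_id not in truth_edit:
            continue
        n += 1
        if hit is None:
            continue
        tid, label = hit
        if tid != target_id or label == "ambiguous":
            continue
        expected = "recombined" if truth_edit[read_id] else "nonrecombined"
        if label == expected:
            ok += 1
    return (100.0 * ok / n if n else 0.0), n
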
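"""Genotype-phenotype joins, control identification, selection, primers.

A cluster's genotype is its polished gene sequence; clusters whose gene
lies within a small edit distance (default 5 mutations, substitutions and
indels alike, at the DNA level) of the spiked control enzyme are flagged as
control clusters and calibrate the screen.  Selection criteria are applied
with strict comparators exactly as screens report them (e.g. off-target
< 10 %, on-target > 25 %).  Variant retrieval uses a primer that is simply
the reverse complement of the cluster's consensus UMI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import edlib_global, ops_identity
from .cluster import umi_identity
from .layout import PlasmidLayout
from .qc import revcomp
from .quantify import EditTally, RecombTally

_CODON_TABLE = {}


def _codon_table() -> dict:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate(dna: str) -> str:
    """Standard-code translation; stops render '*', unresolvable codons 'X'.

    A trailing partial codon is dropped.
    """
    table = _codon_table()
    n = len(dna) - len(dna) % 3
    return "".join(table.get(dna[i : i + 3].upper(), "X") for i in range(0, n, 3))


@dataclass
class GenotypeCall:
    cluster_id: int
    gene_dna: str
    gene_aa: str
    mutations_vs_control: int
    is_control: bool
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    failed: bool = False


def mutation_list(gene: str, control_ref: str) -> list[tuple[int, str, str]]:
    """(control position, control base or '-', variant base or '-') for
    every differing alignment column of an edit-distance alignment."""
    ops, _ = edlib_global(gene, control_ref)
    out = []
    q = r = 0
    for op in ops:
        if op == "=":
            q += 1
            r += 1
        elif op == "X":
            out.append((r, control_ref[r], gene[q]))
            q += 1
            r += 1
        elif op == "I":
            out.append((r, "-", gene[q]))
            q += 1
        else:
            out.append((r, control_ref[r], "-"))
            r += 1
    return out


def call_genotype(
    consensus_seq: str,
    layout: PlasmidLayout,
    control_ref: str,
    control_max_mutations: int = 5,
    cluster_id: int = -1,
) -> GenotypeCall:
    """Extract the gene from a polished consensus and compare it to the
    control enzyme.

    Mutations are counted as DNA-level edit distance (substitutions +
    indels); a cluster is a control iff that count is <= the threshold.
    """
    from .align import extract_region, map_consensus

    failed = GenotypeCall(cluster_id=cluster_id, gene_dna="", gene_aa="",
                          mutations_vs_control=-1, is_control=False, failed=True)
    if not consensus_seq:
        return failed
    aln, oriented = map_consensus(consensus_seq, layout)
    try:
        gene = extract_region(oriented, aln, layout.gene_span)
    except ValueError:
        return failed
    # an unrecoverable gene region: far too short, or a low-identity smear
    if len(gene) < 0.8 * len(control_ref) or ops_identity(aln.ops) < 0.5:
        return failed
    dist = edlib.align(gene, control_ref, mode="NW", task="distance")["editDistance"]
    return GenotypeCall(
        cluster_id=cluster_id,
        gene_dna=gene,
        gene_aa=translate(gene),
        mutations_vs_control=dist,
        is_control=dist <= control_max_mutations,
        mutations=mutation_list(gene, control_ref) if dist <= 50 else [],
    )


@dataclass
class ClusterReport:
    """One row of the master report: genotype plus per-target phenotype."""

    cluster_id: int
    size: int
    centroid_umi: str
    consensus_umi: str
    genotype: GenotypeCall | None
    recomb: dict[str, RecombTally] = field(default_factory=dict)
    edits: dict[str, EditTally] = field(default_factory=dict)
    selected: bool = False

    @property
    def is_control(self) -> bool:
        return bool(self.genotype and not self.genotype.failed and self.genotype.is_control)

    def tally(self, target_id: str) -> RecombTally | EditTally | None:
        return self.recomb.get(target_id) or self.edits.get(target_id)

    def reported_rate(self, target_id: str, min_reads: int = 50) -> float | None:
        """Rate in percent, or None when fewer than min_reads reads were
        classified for the target (no rate is reported below the floor)."""
        tally = self.tally(target_id)
        if tally is None or tally.n_classified < min_reads:
            return None
        return tally.rate_percent

    def target_ids(self) -> list[str]:
        return sorted(set(self.recomb) | set(self.edits))


def combine_runs(
    runs: list[list[ClusterReport]],
    threshold: float = 0.7,
) -> list[ClusterReport]:
    """Join per-run cluster tables into one master table.

    Clusters are matched across runs by centroid-UMI identity at the
    clustering threshold (best match wins; a master row accepts at most one
    cluster per run, lower-identity duplicates stay unmatched).  Unmatched
    clusters are kept with their targets missing from other runs.
    """
    if not runs:
        return []
    master: list[ClusterReport] = []
    for rep in runs[0]:
        master.append(ClusterReport(
            cluster_id=len(master), size=rep.size,
            centroid_umi=rep.centroid_umi, consensus_umi=rep.consensus_umi,
            genotype=rep.genotype, recomb=dict(rep.recomb), edits=dict(rep.edits),
        ))
    for run in runs[1:]:
        scored = []
        for rep in run:
            best_row, best_ident = None, -1.0
            for row in master:
                ident = umi_identity(rep.centroid_umi, row.centroid_umi)
                if ident > best_ident:
                    best_ident, best_row = ident, row
            scored.append((best_ident, rep, best_row))
        scored.sort(key=lambda t: -t[0])
        claimed: set[int] = set()
        for ident, rep, row in scored:
            if ident >= threshold and row is not None and row.cluster_id not in claimed:
                claimed.add(row.cluster_id)
                row.size += rep.size
                for tid, tally in rep.recomb.items():
                    if tid not in row.recomb or tally.n_classified > row.recomb[tid].n_classified:
                        row.recomb[tid] = tally
                for tid, tally in rep.edits.items():
                    if tid not in row.edits or tally.n_classified > row.edits[tid].n_classified:
                        row.edits[tid] = tally
                if row.genotype is None or row.genotype.failed:
                    row.genotype = rep.genotype
            else:
                master.append(ClusterReport(
                    cluster_id=len(master), size=rep.size,
                    centroid_umi=rep.centroid_umi, consensus_umi=rep.consensus_umi,
                    genotype=rep.genotype, recomb=dict(rep.recomb), edits=dict(rep.edits),
                ))
    return master


def control_summary(
    reports: list[ClusterReport], min_reads: int = 50
) -> dict[str, float | None]:
    """Per-target median rate over control clusters (mean of the middle
    pair for even counts); None where no control reports a rate."""
    targets = sorted({tid for r in reports for tid in r.target_ids()})
    out: dict[str, float | None] = {}
    controls = [r for r in reports if r.is_control]
    if not controls:
        warnings.warn("no control clusters found; control summary is empty")
    for tid in targets:
        rates = [r.reported_rate(tid, min_reads) for r in controls]
        rates = [x for x in rates if x is not None]
        out[tid] = float(np.median(rates)) if rates else None
    return out


_COMPARATORS = {
    "<": lambda a, b: a < b,
    ">": lambda a, b: a > b,
    "<=": lambda a, b: a <= b,
    ">=": lambda a, b: a >= b,
}


def select_variants(
    reports: list[ClusterReport],
    criteria: list[tuple[str, str, float]],
    min_reads: int = 50,
    include_controls: bool = False,
) -> list[ClusterReport]:
    """Clusters passing every (target_id, comparator, percent) criterion.

    Comparators are applied strictly as given; a cluster missing a rate for
    any criterial target fails.  Controls are excluded unless asked for.
    """
    known = {tid for r in reports for tid in r.target_ids()}
    for tid, cmp_str, _ in criteria:
        if reports and tid not in known:
            raise KeyError(f"unknown target in criteria: {tid!r}")
        if cmp_str not in _COMPARATORS:
            raise ValueError(f"unknown comparator {cmp_str!r}")
    out = []
    for rep in reports:
        if rep.is_control and not include_controls:
            continue
        ok = True
        for tid, cmp_str, value in criteria:
            rate = rep.reported_rate(tid, min_reads)
            if rate is None or not _COMPARATORS[cmp_str](rate, value):
                ok = False
                break
        if ok:
            out.append(rep)
    return out


def retrieval_primer(
    umi: str, universal_forward: str, trim_length: int | None = None
) -> tuple[str, str]:
    """(forward, reverse) primer pair for retrieving one variant.

    The reverse primer is the reverse complement of the cluster's UMI
    (optionally only its 3'-most trim_length bases); the forward primer is
    the supplied universal primer.  Both are 5'->3'.
    """
    if not umi:
        raise ValueError("empty UMI")
    if "N" in umi:
        warnings.warn("UMI contains N; primer emitted anyway")
    if trim_length is not None:
        umi = umi[-trim_length:]
    return universal_forward, revcomp(umi)
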
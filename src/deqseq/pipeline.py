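"""End-to-end screen processing: qc -> map -> cluster -> polish -> quantify
-> report, with every intermediate persisted in a plain text format so any
stage can be re-run from its files alone.

Artifacts written per run (all TSV/FASTQ/FASTA/YAML):
    qc_pass.fastq, qc_drop.tsv      quality filtering
    alignments.tsv, umis.tsv        mapping + barcode extraction
    clusters.tsv                    read -> cluster membership
    consensus.fasta, consensus.tsv  polished cluster sequences
    tallies.tsv                     per-cluster per-target counts and rates
    report.tsv, primers.tsv         master genotype-phenotype table
    control_summary.tsv, counts.tsv run-level summaries
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .align import (AlignmentResult, compress_ops, coverage_filter,
                    expand_cigar, extract_region, orient_and_map, oriented_seq)
from .cluster import UmiCluster, cluster_umis, filter_clusters
from .consensus import ConsensusResult, polish, seed_draft
from .layout import PlasmidLayout, load_layout
from .qc import DropLog, QcParams, ReadRecord, filter_reads
from .quantify import (RecombTally, tally_cluster_edits,
                       tally_cluster_recombination)
from .report import (ClusterReport, call_genotype, control_summary,
                     retrieval_primer, select_variants)


@dataclass
class RunConfig:
    layout: PlasmidLayout
    control_gene: str | None = None          # default: the layout's gene region
    min_length: int = 2900
    min_mean_q: float = 10.0
    min_map_identity: float = 0.60
    cluster_identity: float = 0.7
    min_cluster_size: int = 50
    consensus_max_rounds: int = 3
    min_reads_per_target: int = 50
    control_max_mutations: int = 5
    selection: list[tuple[str, str, float]] = field(default_factory=list)
    universal_forward: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_gene is None:
            self.control_gene = self.layout.region(self.layout.gene_span)
        if not 0.0 < self.cluster_identity <= 1.0:
            raise ValueError("cluster_identity must be in (0, 1]")
        if self.min_cluster_size < 1 or self.min_reads_per_target < 1:
            raise ValueError("cluster and per-target read floors must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh)
        layout = load_layout(path.parent / d.pop("layout"))
        control = d.pop("control_gene", None)
        # control_gene may be a FASTA path or a literal sequence
        if control:
            try:
                is_file = (path.parent / control).exists()
            except OSError:
                is_file = False
            if is_file:
                control = dio.read_fasta(path.parent / control)[0][1]
        selection = [tuple(c) for c in d.pop("selection", [])]
        return cls(layout=layout, control_gene=control, selection=selection, **d)


@dataclass
class MappedRead:
    read: ReadRecord
    aln: AlignmentResult
    oriented: str
    umi: str


@dataclass
class ScreenResult:
    config: RunConfig
    kept_reads: list[ReadRecord]
    drop_log: DropLog
    mapped: list[MappedRead]
    unmapped_ids: list[str]
    uncovered_ids: list[str]
    clusters: list[UmiCluster]
    retained: list[UmiCluster]
    consensus: dict[int, ConsensusResult]
    reports: list[ClusterReport]
    control_medians: dict[str, float | None]
    recomb_labels: dict[str, tuple[str, str] | None]
    counts: dict[str, int]


def map_reads(
    reads: list[ReadRecord], layout: PlasmidLayout, min_identity: float = 0.60
) -> tuple[list[MappedRead], list[str], list[str]]:
    """Orient and map each read, apply the gene-start/UMI-end coverage
    filter, and extract the barcode.  Returns (mapped, unmapped ids,
    mapped-but-uncovered ids)."""
    mapped, unmapped, uncovered = [], [], []
    for read in reads:
        aln = orient_and_map(read, layout, min_identity=min_identity)
        if aln is None:
            unmapped.append(read.read_id)
            continue
        if not coverage_filter(aln, layout):
            uncovered.append(read.read_id)
            continue
        seq = oriented_seq(read, aln)
        umi = extract_region(seq, aln, layout.umi_span)
        if not umi:
            uncovered.append(read.read_id)
            continue
        mapped.append(MappedRead(read=read, aln=aln, oriented=seq, umi=umi))
    return mapped, unmapped, uncovered


def trimmed_read(m: "MappedRead", span: tuple[int, int]) -> ReadRecord:
    """A mapped read cut down to the bases aligned over a reference span
    (forward orientation, qualities carried along)."""
    from .align import query_interval

    qs, qe = query_interval(m.aln, span)
    qual = m.read.qual if m.aln.orientation == "+" else m.read.qual[::-1]
    return ReadRecord(m.read.read_id, m.oriented[qs:qe], qual[qs:qe].copy())


def consensus_region(consensus_seq: str, layout: PlasmidLayout,
                     span: tuple[int, int]) -> str:
    """Reference-anchored region of a polished consensus ('' on failure)."""
    from .align import map_consensus

    if not consensus_seq:
        return ""
    aln, oriented = map_consensus(consensus_seq, layout)
    try:
        return extract_region(oriented, aln, span)
    except ValueError:
        return ""


def run_screen(cfg: RunConfig, reads: list[ReadRecord],
               outdir=None, log=sys.stderr) -> ScreenResult:
    """Execute every stage on an in-memory read list.

    Writes all artifacts when outdir is given.  An empty input yields an
    empty (header-only) report, not an error.
    """
    out = dio.ensure_dir(outdir) if outdir is not None else None

    def say(msg: str) -> None:
        if log is not None:
            print(f"[deqseq] {msg}", file=log)

    kept, drop_log = filter_reads(reads, QcParams(cfg.min_length, cfg.min_mean_q))
    say(f"qc: {len(kept)}/{len(reads)} reads kept")

    mapped, unmapped, uncovered = map_reads(kept, cfg.layout, cfg.min_map_identity)
    say(f"map: {len(mapped)} mapped+covered, {len(unmapped)} unmapped, "
        f"{len(uncovered)} not covering gene..UMI")

    by_id = {m.read.read_id: m for m in mapped}
    clusters = cluster_umis([(m.read.read_id, m.umi) for m in mapped],
                            threshold=cfg.cluster_identity)
    retained = filter_clusters(clusters, cfg.min_cluster_size)
    say(f"cluster: {len(clusters)} clusters, {len(retained)} with >= "
        f"{cfg.min_cluster_size} reads")

    consensus: dict[int, ConsensusResult] = {}
    reports: list[ClusterReport] = []
    recomb_labels: dict[str, tuple[str, str] | None] = {}
    polish_span = (cfg.layout.gene_span[0], cfg.layout.umi_span[1])
    for cl in retained:
        members = [by_id[rid] for rid in cl.member_read_ids]
        # polish the gene..UMI portion only: it is allele-homogeneous across
        # members, whereas target regions mix edited/unedited alleles
        oriented = [trimmed_read(m, polish_span) for m in members]
        draft = seed_draft(oriented)
        cons = polish(draft.seq, oriented, max_rounds=cfg.consensus_max_rounds,
                      cluster_id=cl.cluster_id)
        consensus[cl.cluster_id] = cons
        genotype = call_genotype(cons.consensus_seq, cfg.layout, cfg.control_gene,
                                 cfg.control_max_mutations, cluster_id=cl.cluster_id)
        cons_umi = consensus_region(cons.consensus_seq, cfg.layout, cfg.layout.umi_span)
        triples = [(m.read.read_id, m.oriented, m.aln) for m in members]
        edits = tally_cluster_edits(cl.cluster_id, triples, cfg.layout)
        if any(t.mode == "excision" for t in cfg.layout.targets):
            recomb, labels = tally_cluster_recombination(
                cl.cluster_id, triples, cfg.layout, min_identity=cfg.min_map_identity)
            recomb_labels.update(labels)
        else:
            recomb = {}
        reports.append(ClusterReport(
            cluster_id=cl.cluster_id, size=cl.size, centroid_umi=cl.centroid_umi,
            consensus_umi=cons_umi, genotype=genotype, recomb=recomb, edits=edits,
        ))
    n_controls = sum(r.is_control for r in reports)
    say(f"polish+genotype: {len(reports)} clusters, {n_controls} controls")

    medians = control_summary(reports, cfg.min_reads_per_target) if reports else {}
    if cfg.selection:
        for rep in select_variants(reports, cfg.selection, cfg.min_reads_per_target):
            rep.selected = True

    counts = {
        "reads_in": len(reads), "qc_kept": len(kept), "qc_dropped": len(drop_log),
        "mapped": len(mapped), "unmapped": len(unmapped), "uncovered": len(uncovered),
        "clusters": len(clusters), "retained_clusters": len(retained),
        "retained_reads": sum(c.size for c in retained),
        "control_clusters": n_controls,
        "selected_clusters": sum(r.selected for r in reports),
    }
    result = ScreenResult(
        config=cfg, kept_reads=kept, drop_log=drop_log, mapped=mapped,
        unmapped_ids=unmapped, uncovered_ids=uncovered, clusters=clusters,
        retained=retained, consensus=consensus, reports=reports,
        control_medians=medians, recomb_labels=recomb_labels, counts=counts,
    )
    if out is not None:
        write_artifacts(result, out)
        say(f"artifacts written to {out}")
    return result


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def _fmt_rate(x: float | None) -> str:
    return "NA" if x is None else f"{x:.4f}"


def write_alignments(mapped: list[MappedRead], unmapped: list[str],
                     uncovered: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\torientation\tref_start\tref_end\tidentity\tumi\tcigar\n")
        for m in mapped:
            a = m.aln
            fh.write(f"{m.read.read_id}\tmapped\t{a.orientation}\t{a.ref_start}\t"
                     f"{a.ref_end}\t{a.identity:.4f}\t{m.umi}\t{compress_ops(a.ops)}\n")
        for rid in unmapped:
            fh.write(f"{rid}\tunmapped\t.\t-1\t-1\tNA\t.\t.\n")
        for rid in uncovered:
            fh.write(f"{rid}\tuncovered\t.\t-1\t-1\tNA\t.\t.\n")


def load_alignments(path, reads: list[ReadRecord], ref_id: str
                    ) -> tuple[list[MappedRead], list[str], list[str]]:
    by_id = {r.read_id: r for r in reads}
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapped, unmapped, uncovered = [], [], []
    for row in df.itertuples(index=False):
        if row.status == "unmapped":
            unmapped.append(row.read_id)
            continue
        if row.status == "uncovered":
            uncovered.append(row.read_id)
            continue
        read = by_id[row.read_id]
        aln = AlignmentResult(
            query_id=row.read_id, ref_id=ref_id, orientation=row.orientation,
            ref_start=int(row.ref_start), ref_end=int(row.ref_end),
            ops=expand_cigar(row.cigar), score=0.0,
            query_start=0, query_end=len(read.seq),
        )
        mapped.append(MappedRead(read=read, aln=aln,
                                 oriented=oriented_seq(read, aln), umi=row.umi))
    return mapped, unmapped, uncovered


def write_clusters(clusters: list[UmiCluster], retained_ids: set[int], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcluster_id\tcentroid_umi\tretained\n")
        for c in clusters:
            flag = int(c.cluster_id in retained_ids)
            for rid in c.member_read_ids:
                fh.write(f"{rid}\t{c.cluster_id}\t{c.centroid_umi}\t{flag}\n")


def load_clusters(path) -> tuple[list[UmiCluster], set[int]]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "cluster_id": int,
                                            "centroid_umi": str, "retained": int})
    clusters: dict[int, UmiCluster] = {}
    retained: set[int] = set()
    for row in df.itertuples(index=False):
        c = clusters.setdefault(row.cluster_id,
                                UmiCluster(row.cluster_id, row.centroid_umi))
        c.member_read_ids.append(row.read_id)
        if row.retained:
            retained.add(row.cluster_id)
    return [clusters[k] for k in sorted(clusters)], retained


def write_tallies(reports: list[ClusterReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\ttarget_id\tmode\tn_classified\tn_a\tn_b\tn_other"
                 "\tn_ambiguous\tn_excluded\trate_percent\n")
        for rep in reports:
            for tid in rep.target_ids():
                t = rep.tally(tid)
                if isinstance(t, RecombTally):
                    fh.write(f"{rep.cluster_id}\t{tid}\trecombination\t{t.n_classified}"
                             f"\t{t.n_recombined}\t{t.n_nonrecombined}\t0"
                             f"\t{t.n_ambiguous}\t{t.n_excluded}\t{_fmt_rate(t.rate_percent)}\n")
                else:
                    fh.write(f"{rep.cluster_id}\t{tid}\tbase_edit\t{t.n_classified}"
                             f"\t{t.n_correct}\t{t.n_none}\t{t.n_other}"
                             f"\t0\t{t.n_excluded}\t{_fmt_rate(t.rate_percent)}\n")


def write_report_tsv(reports: list[ClusterReport], path, min_reads: int = 50) -> None:
    targets = sorted({tid for r in reports for tid in r.target_ids()})
    cols = ["cluster_id", "size", "centroid_umi", "consensus_umi", "is_control",
            "mutations_vs_control", "selected"]
    for tid in targets:
        cols += [f"{tid}_rate", f"{tid}_n_classified"]
    cols += ["gene_aa", "gene_dna"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            g = r.genotype
            row = [str(r.cluster_id), str(r.size), r.centroid_umi, r.consensus_umi,
                   str(int(r.is_control)),
                   "NA" if g is None or g.failed else str(g.mutations_vs_control),
                   str(int(r.selected))]
            for tid in targets:
                t = r.tally(tid)
                row.append(_fmt_rate(r.reported_rate(tid, min_reads)))
                row.append(str(t.n_classified) if t is not None else "0")
            row.append("" if g is None or g.failed else g.gene_aa)
            row.append("" if g is None or g.failed else g.gene_dna)
            fh.write("\t".join(row) + "\n")


def write_artifacts(result: ScreenResult, out: Path) -> None:
    cfg = result.config
    dio.write_fastq(result.kept_reads, out / "qc_pass.fastq")
    dio.write_drop_log(result.drop_log, out / "qc_drop.tsv")
    write_alignments(result.mapped, result.unmapped_ids, result.uncovered_ids,
                     out / "alignments.tsv")
    with open(out / "umis.tsv", "w") as fh:
        fh.write("read_id\tumi\n")
        for m in result.mapped:
            fh.write(f"{m.read.read_id}\t{m.umi}\n")
    write_clusters(result.clusters, {c.cluster_id for c in result.retained},
                   out / "clusters.tsv")
    dio.write_fasta(
        ((f"cluster_{cid}", c.consensus_seq) for cid, c in sorted(result.consensus.items())),
        out / "consensus.fasta")
    with open(out / "consensus.tsv", "w") as fh:
        fh.write("cluster_id\trounds_used\tconverged\tlength\n")
        for cid, c in sorted(result.consensus.items()):
            fh.write(f"{cid}\t{c.rounds_used}\t{int(c.converged)}\t{len(c.consensus_seq)}\n")
    write_tallies(result.reports, out / "tallies.tsv")
    write_report_tsv(result.reports, out / "report.tsv", cfg.min_reads_per_target)
    with open(out / "control_summary.tsv", "w") as fh:
        fh.write("target_id\tmedian_rate_percent\n")
        for tid, med in sorted(result.control_medians.items()):
            fh.write(f"{tid}\t{_fmt_rate(med)}\n")
    if cfg.universal_forward:
        with open(out / "primers.tsv", "w") as fh:
            fh.write("cluster_id\tforward\treverse\n")
            for r in result.reports:
                umi = r.consensus_umi or r.centroid_umi
                fwd, rev = retrieval_primer(umi, cfg.universal_forward)
                fh.write(f"{r.cluster_id}\t{fwd}\t{rev}\n")
    selected = [r for r in result.reports if r.selected]
    if selected:
        dio.write_fasta(
            ((f"cluster_{r.cluster_id}", r.genotype.gene_dna) for r in selected
             if r.genotype and not r.genotype.failed),
            out / "selected_genes.fasta")
    with open(out / "counts.tsv", "w") as fh:
        fh.write("stage\tcount\n")
        for k, v in result.counts.items():
            fh.write(f"{k}\t{v}\n")


def config_to_yaml(cfg: RunConfig, path, layout_file: str) -> None:
    d = dataclasses.asdict(cfg)
    d.pop("layout")
    d["layout"] = layout_file
    d["selection"] = [list(c) for c in cfg.selection]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
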
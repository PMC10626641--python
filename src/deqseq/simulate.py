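"""Synthetic screen generator: variant libraries, editing outcomes, and
nanopore-like noisy reads with a full truth table.

The generative model mirrors the sequenced molecule of a substrate-linked
directed-evolution screen: each variant is the reference enzyme gene with
i.i.d. random substitutions, tagged by a unique random 50-mer barcode
(UMI), and carried on a fragment that also holds the target sites.  Each
read of a variant draws an independent editing outcome per target site
(Bernoulli at the variant's true rate), renders the corresponding alleles,
and passes the fragment through an error channel with per-base
substitutions, geometric-length insertions and deletions, a Gaussian
per-base quality model, and random strand orientation.

What this does NOT emulate: signal-level artefacts, homopolymer-dependent
error profiles, chimeras and adapters — the error process is i.i.d. per
base, which is the right level for exercising the clustering, consensus
and quantification contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import PlasmidLayout, TargetSite
from .qc import ReadRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen."""

    n_variants: int = 100
    reads_per_variant: int = 80
    gene_mutation_rate: float = 0.005   # substitutions per base (epPCR-like)
    umi_length: int = 50
    #: per-target (lo, hi) of the uniform true-rate distribution;
    #: targets absent from the map default to (0, 1)
    rate_ranges: dict = field(default_factory=dict)
    sub_rate: float = 0.04
    ins_rate: float = 0.02
    del_rate: float = 0.02
    mean_q: float = 14.0
    sd_q: float = 4.0
    strand_flip_prob: float = 0.5
    n_controls: int = 0                 # exact copies of the control gene
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gene_mutation_rate", "sub_rate", "ins_rate", "del_rate",
                     "strand_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_variants < 1 or self.umi_length < 1 or self.reads_per_variant < 1:
            raise ValueError("n_variants, reads_per_variant and umi_length must be >= 1")
        if self.n_controls > self.n_variants:
            raise ValueError("n_controls cannot exceed n_variants")
        for lo, hi in self.rate_ranges.values():
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError("rate ranges must satisfy 0 <= lo <= hi <= 1")


@dataclass
class SimTruth:
    """Ground truth for one variant (the recovery target)."""

    variant_id: str
    gene_seq: str
    umi: str
    rates: dict                 # target_id -> true editing probability
    is_control: bool = False
    realized_edited: dict = field(default_factory=dict)   # target_id -> int
    realized_reads: int = 0


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def random_substitutions(seq: str, n: int, rng: np.random.Generator) -> str:
    """Exactly n substitutions at distinct positions (each to a different base)."""
    if n > len(seq):
        raise ValueError("more substitutions than positions")
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
    pos = rng.choice(len(seq), size=n, replace=False)
    arr[pos] = (arr[pos] + rng.integers(1, 4, size=n)) % 4
    return _BASES[arr].tobytes().decode("ascii")


def _mutate_gene(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=n)) % 4
    return _BASES[arr].tobytes().decode("ascii")


def make_library(
    cfg: SimConfig,
    gene_ref: str,
    control_ref: str | None = None,
    target_ids: tuple[str, ...] = (),
) -> list[SimTruth]:
    """Draw the variant library: mutated genes, unique UMIs, true rates.

    The first cfg.n_controls variants are exact copies of control_ref
    (default: gene_ref itself); the rest are gene_ref with i.i.d.
    substitutions at gene_mutation_rate.  UMIs are uniform random
    umi_length-mers, resampled on collision.
    """
    if not gene_ref or set(gene_ref) - set("ACGT"):
        raise ValueError("gene_ref must be non-empty DNA over ACGT")
    control_ref = control_ref or gene_ref
    rng = np.random.default_rng(cfg.seed)
    seen_umis: set[str] = set()
    truths = []
    for i in range(cfg.n_variants):
        is_control = i < cfg.n_controls
        gene = control_ref if is_control else _mutate_gene(gene_ref, cfg.gene_mutation_rate, rng)
        for _ in range(100):
            umi = _random_dna(rng, cfg.umi_length)
            if umi not in seen_umis:
                break
        else:
            raise RuntimeError("could not draw a unique UMI after 100 tries")
        seen_umis.add(umi)
        rates = {}
        for tid in target_ids:
            lo, hi = cfg.rate_ranges.get(tid, (0.0, 1.0))
            rates[tid] = float(rng.uniform(lo, hi))
        truths.append(SimTruth(
            variant_id=f"v{i:04d}", gene_seq=gene, umi=umi,
            rates=rates, is_control=is_control,
        ))
    return truths


def render_fragment(
    truth: SimTruth, layout: PlasmidLayout, outcomes: dict
) -> str:
    """The molecule's sequence for a given per-target outcome combination.

    The layout reference is reproduced with the gene and UMI regions
    replaced by the variant's own sequences and each target region rendered
    with its edited or unedited allele.
    """
    if len(truth.umi) != layout.umi_length:
        raise ValueError(
            f"variant {truth.variant_id}: UMI length {len(truth.umi)} does not "
            f"match the layout's barcode region ({layout.umi_length})"
        )
    for tid in outcomes:
        layout.target(tid)  # raises KeyError on unknown targets
    missing = {t.target_id for t in layout.targets} - set(outcomes)
    if missing:
        raise ValueError(f"outcomes missing targets: {sorted(missing)}")
    pieces = {layout.gene_span: truth.gene_seq, layout.umi_span: truth.umi}
    for t in layout.targets:
        pieces[t.span] = t.render(bool(outcomes[t.target_id]))
    out = []
    cursor = 0
    for (s, e), seq in sorted(pieces.items()):
        out.append(layout.ref_seq[cursor:s])
        out.append(seq)
        cursor = e
    out.append(layout.ref_seq[cursor:])
    return "".join(out)


def _error_channel(seq: str, cfg: SimConfig, rng: np.random.Generator):
    """Substitutions, deletions and geometric-length insertions, i.i.d.
    per base, plus a Gaussian per-base Phred string."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
    L = arr.size
    if cfg.sub_rate > 0:
        hit = rng.random(L) < cfg.sub_rate
        n = int(hit.sum())
        if n:
            arr[hit] = (arr[hit] + rng.integers(1, 4, size=n)) % 4
    if cfg.del_rate > 0:
        arr = arr[rng.random(L) >= cfg.del_rate]
    if cfg.ins_rate > 0:
        junctions = np.flatnonzero(rng.random(arr.size + 1) < cfg.ins_rate)
        if junctions.size:
            lens = rng.geometric(0.5, size=junctions.size)
            where = np.repeat(junctions, lens)
            arr = np.insert(arr, where, rng.integers(0, 4, size=where.size).astype(np.uint8))
    qual = np.clip(np.rint(rng.normal(cfg.mean_q, cfg.sd_q, size=arr.size)), 2, 41
                   ).astype(np.int16)
    return _BASES[arr].tobytes().decode("ascii"), qual


def simulate_reads(
    truths: list[SimTruth],
    layout: PlasmidLayout,
    cfg: SimConfig,
) -> tuple[list[ReadRecord], list[SimTruth], pd.DataFrame]:
    """Render noisy reads for every variant and record realized outcomes.

    Returns (reads, truths with realized counts, per-read outcome table).
    Each read draws its own per-target Bernoulli outcome — the biological
    sampling of plasmid molecules — then passes through the error channel
    and is reverse-complemented with probability strand_flip_prob.
    Seeded runs are bit-reproducible.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from the library draw
    target_ids = [t.target_id for t in layout.targets]
    reads: list[ReadRecord] = []
    rows = []
    truths = [replace_counts(t, target_ids) for t in truths]
    frag_cache: dict[tuple, str] = {}
    for truth in truths:
        for j in range(cfg.reads_per_variant):
            outcome = {tid: bool(rng.random() < truth.rates[tid]) for tid in target_ids}
            key = (truth.variant_id, tuple(outcome[t] for t in target_ids))
            frag = frag_cache.get(key)
            if frag is None:
                frag = render_fragment(truth, layout, outcome)
                frag_cache[key] = frag
            seq, qual = _error_channel(frag, cfg, rng)
            if rng.random() < cfg.strand_flip_prob:
                seq, qual = revcomp(seq), qual[::-1].copy()
            read_id = f"{truth.variant_id}_r{j:03d}"
            reads.append(ReadRecord(read_id=read_id, seq=seq, qual=qual))
            truth.realized_reads += 1
            for tid in target_ids:
                truth.realized_edited[tid] += int(outcome[tid])
            rows.append({"read_id": read_id, "variant_id": truth.variant_id,
                         **{f"edited_{tid}": int(outcome[tid]) for tid in target_ids}})
    read_truth = pd.DataFrame(rows)
    return reads, truths, read_truth


def replace_counts(truth: SimTruth, target_ids) -> SimTruth:
    return replace(truth, realized_edited={tid: 0 for tid in target_ids},
                   realized_reads=0)


def truth_table(truths: list[SimTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {"variant_id": t.variant_id, "umi": t.umi,
               "is_control": int(t.is_control), "gene_seq": t.gene_seq,
               "realized_reads": t.realized_reads}
        for tid, rate in t.rates.items():
            row[f"true_rate_{tid}"] = rate
            row[f"realized_edited_{tid}"] = t.realized_edited.get(tid, 0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ready-made layouts emulating the screened fragments
# ---------------------------------------------------------------------------


def example_layout(
    seed: int = 0,
    gene_len: int = 2600,
    n_base_targets: int = 3,
    excision: bool = False,
    excised_len: int = 741,
    site_len: int = 34,
    umi_length: int = 50,
) -> PlasmidLayout:
    """A randomly drawn but fully annotated fragment layout.

    Base-editing flavour: ``n_base_targets`` 40-nt target regions, each with
    a 4-base editing window (target-site positions 2-5) holding adenines at
    the expected positions 3 and 4.  Excision flavour: one region of
    site + stuffer + site whose recombined allele is a single site, shorter
    by exactly ``excised_len``.  The UMI region is written as N's, as in a
    mapping reference with an unknown barcode.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    pos = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        span = (pos, pos + len(seq))
        pos += len(seq)
        return span

    emit(_random_dna(rng, 40))
    gene_span = emit(_random_dna(rng, gene_len))
    emit(_random_dna(rng, 25))
    umi_span = emit("N" * umi_length)
    emit(_random_dna(rng, 25))

    targets: list[TargetSite] = []
    if excision:
        site = _random_dna(rng, site_len)
        stuffer = _random_dna(rng, excised_len - site_len)
        region = emit(site + stuffer + site)
        targets.append(TargetSite(
            target_id="lox", span=region, mode="excision",
            unedited_allele=site + stuffer + site, edited_allele=site,
        ))
    else:
        for i in range(n_base_targets):
            left = _random_dna(rng, 10)
            site = list(_random_dna(rng, 20))
            site[2] = site[3] = "A"       # expected adenines (site positions 3, 4)
            site[1] = site[4] = "C"       # flank the window with non-A bases
            site = "".join(site)
            right = _random_dna(rng, 10)
            region_seq = left + site + right
            span = emit(region_seq)
            ws = span[0] + 10 + 1          # site positions 2-5, 0-based half-open
            targets.append(TargetSite(
                target_id=f"bt{i + 1}", span=span, mode="base_edit",
                unedited_allele=region_seq, window_span=(ws, ws + 4),
            ))
            if i < n_base_targets - 1:
                emit(_random_dna(rng, 20))
    emit(_random_dna(rng, 40))

    return PlasmidLayout(
        ref_id="sim_fragment", ref_seq="".join(parts),
        gene_span=gene_span, umi_span=umi_span, targets=tuple(targets),
    )
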
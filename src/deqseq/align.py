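"""Pairwise alignment: the contract every downstream stage builds on.

Two engines share one result type:

* :func:`align_pair` — an affine-gap (Gotoh) dynamic program, exact under a
  configurable scoring scheme, in global or semiglobal mode (semiglobal =
  terminal gaps on the query's flanks are free, i.e. the query aligns to a
  contiguous stretch of the reference).  Row-vectorised with numpy; meant
  for barcodes, windows and verification, not megabase genomes.
* edlib-backed mapping (:func:`orient_and_map`, :func:`edlib_global`) for
  full-length noisy reads: the alignment path is edit-distance optimal and
  identity/score are computed from that path.  This is the production path
  for ~3 kb nanopore reads, where unit-cost banded alignment is orders of
  magnitude faster than an unbanded scoring DP.

Coordinates are 0-based half-open on the forward reference throughout.
Alignment columns are encoded as an op string over '=' (match),
'X' (mismatch), 'I' (query base absent from reference) and 'D' (reference
base absent from query) — the query-centric SAM convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .layout import PlasmidLayout
from .qc import ReadRecord, revcomp

NEG = -1e30


@dataclass(frozen=True)
class Scoring:
    """Affine gap scores; a gap of length L costs gap_open + L*gap_extend."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -4.0
    gap_extend: float = -2.0


DEFAULT_SCORING = Scoring()

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def expand_cigar(cigar: str) -> str:
    return "".join(op * int(n) for n, op in _CIGAR_RE.findall(cigar))


def compress_ops(ops: str) -> str:
    out = []
    for m in re.finditer(r"(.)\1*", ops):
        out.append(f"{len(m.group(0))}{m.group(1)}")
    return "".join(out)


def ops_identity(ops: str) -> float:
    """Matching columns / alignment columns, terminal gap runs excluded."""
    core = ops.strip("ID")
    if not core:
        return 0.0
    return core.count("=") / len(core)


def ops_score(ops: str, scoring: Scoring = DEFAULT_SCORING) -> float:
    score = 0.0
    for m in re.finditer(r"(.)\1*", ops):
        op, n = m.group(1), len(m.group(0))
        if op == "=":
            score += n * scoring.match
        elif op == "X":
            score += n * scoring.mismatch
        else:
            score += scoring.gap_open + n * scoring.gap_extend
    return score


@dataclass
class AlignmentResult:
    """One pairwise alignment, reference-anchored."""

    query_id: str
    ref_id: str
    orientation: str  # '+' | '-'
    ref_start: int
    ref_end: int
    ops: str
    score: float
    query_start: int = 0
    query_end: int = 0
    _walk_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def identity(self) -> float:
        return ops_identity(self.ops)

    def walk(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vector decomposition of the op string.

        Returns (op codes as uint8 of '=XID', query position before each op,
        reference position before each op).  Cached per result.
        """
        if self._walk_cache is None:
            codes = np.frombuffer(self.ops.encode("ascii"), dtype=np.uint8)
            q_step = (codes != ord("D")).astype(np.int64)
            r_step = (codes != ord("I")).astype(np.int64)
            qpos = self.query_start + np.cumsum(q_step) - q_step
            rpos = self.ref_start + np.cumsum(r_step) - r_step
            self._walk_cache = (codes, qpos, rpos)
        return self._walk_cache


# ---------------------------------------------------------------------------
# Affine-gap DP (exact under scoring)
# ---------------------------------------------------------------------------


def align_pair(
    query: str,
    ref: str,
    mode: str = "global",
    scoring: Scoring = DEFAULT_SCORING,
    query_id: str = "query",
    ref_id: str = "ref",
) -> AlignmentResult:
    """Optimal affine-gap alignment of query against ref.

    mode "global": both sequences end to end.  mode "semiglobal": the query
    is fully aligned, terminal reference overhangs are free and do not
    appear in the op string.
    """
    if not query or not ref:
        raise ValueError("align_pair requires non-empty sequences")
    if mode not in ("global", "semiglobal"):
        raise ValueError(f"unknown mode {mode!r}")
    m, n = len(query), len(ref)
    go, ge = scoring.gap_open, scoring.gap_extend

    qa = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    ra = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)

    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)  # gap in query (consumes ref)
    F = np.full((m + 1, n + 1), NEG)  # gap in ref (consumes query)

    H[0, 0] = 0.0
    j_idx = np.arange(1, n + 1, dtype=float)
    if mode == "global":
        H[0, 1:] = go + ge * j_idx
        E[0, 1:] = H[0, 1:]
    else:  # free leading reference overhang
        H[0, 1:] = 0.0
    i_col = np.arange(1, m + 1, dtype=float)
    H[1:, 0] = go + ge * i_col
    F[1:, 0] = H[1:, 0]

    ext_j = ge * np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        F[i, 1:] = np.maximum(H[i - 1, 1:] + go, F[i - 1, 1:]) + ge
        sub = np.where(qa[i - 1] == ra, scoring.match, scoring.mismatch)
        diag = H[i - 1, :-1] + sub
        best_df = np.maximum(diag, F[i, 1:])
        # E within the row via running max: E[j] = ge*j + max_{k<j}(B[k]+go-ge*k)
        B = np.empty(n + 1)
        B[0] = H[i, 0]
        B[1:] = best_df
        run = np.maximum.accumulate(B + go - ext_j)
        E[i, 1:] = run[:-1] + ext_j[1:]
        H[i, 1:] = np.maximum(best_df, E[i, 1:])

    if mode == "global":
        j_end = n
    else:
        j_end = int(np.argmax(H[m]))
    score = float(H[m, j_end])

    # traceback (prefer diagonal, then E, then F; gap closure before extension)
    ops_rev: list[str] = []
    i, j = m, j_end
    state = "H"
    while True:
        if state == "H":
            if i == 0 and j == 0:
                break
            if i == 0:
                if mode == "semiglobal":
                    break  # free leading overhang
                ops_rev.append("D" * j)
                break
            if j == 0:
                ops_rev.append("I" * i)
                break
            sub = scoring.match if qa[i - 1] == ra[j - 1] else scoring.mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                ops_rev.append("=" if qa[i - 1] == ra[j - 1] else "X")
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops_rev.append("D")
            prev = E[i, j]
            j -= 1
            if prev == H[i, j] + go + ge:  # gap opened here (prefer closing on ties)
                state = "H"
        else:  # F
            ops_rev.append("I")
            prev = F[i, j]
            i -= 1
            if prev == H[i, j] + go + ge:
                state = "H"

    ops = "".join(reversed(ops_rev))
    ref_start = j if mode == "semiglobal" else 0
    return AlignmentResult(
        query_id=query_id,
        ref_id=ref_id,
        orientation="+",
        ref_start=ref_start,
        ref_end=j_end,
        ops=ops,
        score=score,
        query_start=0,
        query_end=m,
    )


# ---------------------------------------------------------------------------
# edlib-backed mapping for long reads
# ---------------------------------------------------------------------------


def edlib_global(query: str, ref: str) -> tuple[str, int]:
    """Edit-distance-optimal global alignment; returns (ops, distance)."""
    res = edlib.align(query, ref, mode="NW", task="path")
    return expand_cigar(res["cigar"]), res["editDistance"]


def edlib_infix(query: str, ref: str, k: int = -1):
    """Align the full query to the best-matching stretch of ref (HW mode).

    Returns (ops, ref_start, ref_end, distance) or None if distance > k.
    A reference N is a plain mismatch for any read base, so an all-N
    barcode region costs every read the same and stays cleanly anchored
    by its flanks.
    """
    res = edlib.align(query, ref, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return expand_cigar(res["cigar"]), start, end + 1, res["editDistance"]


def _absorb_terminal_insertions(ops: str, ref_start: int, ref_end: int,
                                ref_len: int) -> tuple[str, int, int]:
    """Rewrite terminal insertion runs of an infix alignment as mismatch
    columns where reference columns are available.

    At the free ends of an infix alignment an inserted query base and a
    mismatched column have the same edit cost, and the path search may pick
    the insertion — which silently drops those bases from any terminal
    region (e.g. a barcode that ends exactly where the aligned piece ends).
    The mismatch representation is canonical for region extraction.
    """
    n = len(ops)
    t = n
    while t > 0 and ops[t - 1] == "I":
        t -= 1
    k = n - t
    if k:
        ext = min(k, ref_len - ref_end)
        ops = ops[:t] + "X" * ext + "I" * (k - ext)
        ref_end += ext
    h = 0
    while h < len(ops) and ops[h] == "I":
        h += 1
    if h:
        ext = min(h, ref_start)
        ops = "I" * (h - ext) + "X" * ext + ops[h:]
        ref_start -= ext
    return ops, ref_start, ref_end


def map_consensus(seq: str, layout: PlasmidLayout) -> tuple[AlignmentResult, str]:
    """Align a polished consensus (the full fragment or any contiguous
    piece of it, either strand) onto the layout reference."""
    fwd = edlib_infix(seq, layout.ref_seq)
    rc = revcomp(seq)
    rev = edlib_infix(rc, layout.ref_seq)
    if rev is not None and (fwd is None or rev[3] < fwd[3]):
        hit, oriented, orientation = rev, rc, "-"
    else:
        hit, oriented, orientation = fwd, seq, "+"
    ops, start, end, _ = hit
    ops, start, end = _absorb_terminal_insertions(ops, start, end, len(layout.ref_seq))
    aln = AlignmentResult(
        query_id="consensus", ref_id=layout.ref_id, orientation=orientation,
        ref_start=start, ref_end=end, ops=ops, score=0.0,
        query_start=0, query_end=len(oriented),
    )
    return aln, oriented


def orient_and_map(
    read: ReadRecord,
    layout: PlasmidLayout,
    scoring: Scoring = DEFAULT_SCORING,
    min_identity: float = 0.60,
) -> AlignmentResult | None:
    """Map a read to the layout reference, trying both strands.

    The better strand (lower edit distance) wins; coordinates are reported
    on the forward reference.  Reads whose best identity falls below
    ``min_identity`` are returned as None (unmapped) and excluded from all
    downstream tallies.
    """
    ref = layout.ref_seq
    fwd_seq = read.seq
    rev_seq = revcomp(read.seq)
    # banded first pass: genuine reads sit far below this distance
    k = max(64, len(read.seq) // 4)
    fwd = edlib_infix(fwd_seq, ref, k=k)
    rev = edlib_infix(rev_seq, ref, k=k)
    if fwd is None and rev is None:
        # rare path: unbanded rescue so the identity floor, not the band,
        # decides what counts as unmapped
        fwd = edlib_infix(fwd_seq, ref, k=-1)
        rev = edlib_infix(rev_seq, ref, k=-1)
    if rev is None or (fwd is not None and fwd[3] <= rev[3]):
        ops, start, end, _ = fwd
        orientation = "+"
    else:
        ops, start, end, _ = rev
        orientation = "-"
    aln = AlignmentResult(
        query_id=read.read_id,
        ref_id=layout.ref_id,
        orientation=orientation,
        ref_start=start,
        ref_end=end,
        ops=ops,
        score=ops_score(ops, scoring),
        query_start=0,
        query_end=len(read.seq),
    )
    if aln.identity < min_identity:
        return None
    return aln


def oriented_seq(read: ReadRecord, aln: AlignmentResult) -> str:
    """Read bases in the orientation the alignment was computed in."""
    return read.seq if aln.orientation == "+" else revcomp(read.seq)


def coverage_filter(aln: AlignmentResult, layout: PlasmidLayout) -> bool:
    """True iff the alignment starts at or before the gene start and ends
    at or after the UMI end (the gene and the barcode are both covered)."""
    return aln.ref_start <= layout.gene_span[0] and aln.ref_end >= layout.umi_span[1]


def covers(aln: AlignmentResult, span: tuple[int, int]) -> bool:
    return aln.ref_start <= span[0] and aln.ref_end >= span[1]


def query_interval(aln: AlignmentResult, span: tuple[int, int]) -> tuple[int, int]:
    """Query coordinates [qs, qe) aligned to reference columns [start, end).

    Insertions strictly inside the span are included; an insertion exactly
    at a boundary belongs to the region on its left (so one at ``start`` is
    excluded and one at ``end`` is included).  Reference deletions
    contribute nothing.  The selected query positions are contiguous.
    """
    s, e = span
    if not covers(aln, span):
        raise ValueError(f"alignment [{aln.ref_start},{aln.ref_end}) does not cover span [{s},{e})")
    codes, qpos, rpos = aln.walk()
    is_ins = codes == ord("I")
    consumes_q = codes != ord("D")
    take = consumes_q & np.where(is_ins, (rpos > s) & (rpos <= e), (rpos >= s) & (rpos < e))
    idx = qpos[take]
    if idx.size == 0:
        return 0, 0
    return int(idx[0]), int(idx[-1]) + 1


def extract_region(seq: str, aln: AlignmentResult, span: tuple[int, int]) -> str:
    """Read bases aligned to reference columns [start, end).

    ``seq`` must be the oriented query sequence; boundary rules as in
    :func:`query_interval`.
    """
    qs, qe = query_interval(aln, span)
    return seq[qs:qe]
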
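"""Per-cluster phenotype quantification.

Recombination (excision) targets: each member read is aligned to a panel
holding the unedited and the recombined rendering of every target region;
the best-identity panel entry determines both which target the read reports
on and its allele label.  The excised length (741 bp here) dwarfs the
nanopore error rate, so the score gap is large; an exact identity tie is
labelled ambiguous and excluded from the rate denominator.

Base-editing targets: the 4-base editing window (target-site positions
2-5) is extracted from each read's reference-anchored alignment; windows
with indels are excluded (nanopore indels would otherwise masquerade as
editing outcomes), and indel-free windows are classified as correctly
edited, unedited, or other.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from .align import AlignmentResult, covers, expand_cigar, extract_region, ops_identity
from .layout import PlasmidLayout, TargetSite


@dataclass
class RecombTally:
    cluster_id: int
    target_id: str
    n_recombined: int = 0
    n_nonrecombined: int = 0
    n_ambiguous: int = 0
    n_excluded: int = 0

    @property
    def n_classified(self) -> int:
        return self.n_recombined + self.n_nonrecombined

    @property
    def rate_percent(self) -> float | None:
        """100 * recombined / (recombined + nonrecombined); ambiguous and
        excluded reads do not enter the denominator."""
        if self.n_classified == 0:
            return None
        return 100.0 * self.n_recombined / self.n_classified


@dataclass
class EditTally:
    cluster_id: int
    target_id: str
    n_correct: int = 0
    n_none: int = 0
    n_other: int = 0
    n_excluded: int = 0
    window_hist: Counter = field(default_factory=Counter)

    @property
    def n_classified(self) -> int:
        return self.n_correct + self.n_none + self.n_other

    @property
    def rate_percent(self) -> float | None:
        if self.n_classified == 0:
            return None
        return 100.0 * self.n_correct / self.n_classified


@dataclass(frozen=True)
class PanelEntry:
    name: str
    target_id: str
    label: str  # "recombined" | "nonrecombined"
    seq: str


def build_recombination_panel(layout: PlasmidLayout, flank: int = 25) -> list[PanelEntry]:
    """Unedited and recombined renderings of every excision target region,
    with reference flanks so short alleles still anchor uniquely."""
    panel = []
    for t in layout.targets:
        if t.mode != "excision":
            continue
        s, e = t.span
        left = layout.ref_seq[max(0, s - flank) : s]
        right = layout.ref_seq[e : e + flank]
        panel.append(PanelEntry(f"{t.target_id}:nonrecombined", t.target_id,
                                "nonrecombined", left + t.unedited_allele + right))
        panel.append(PanelEntry(f"{t.target_id}:recombined", t.target_id,
                                "recombined", left + t.edited_allele + right))
    return panel


def classify_recombination(
    read_seq: str,
    panel: list[PanelEntry],
    min_identity: float = 0.60,
    margin: float = 0.0,
) -> tuple[str, str] | None:
    """Best-identity panel entry -> (target_id, label).

    Identity ties within ``margin`` between different labels give
    ("<target>", "ambiguous"); a best identity below ``min_identity``
    returns None (read excluded and logged by the caller).
    """
    if not panel:
        raise ValueError("empty reference panel")
    scored = []
    for entry in panel:
        res = edlib.align(entry.seq, read_seq, mode="HW", task="path")
        scored.append((ops_identity(expand_cigar(res["cigar"])), entry))
    scored.sort(key=lambda t: -t[0])
    best_ident, best = scored[0]
    if best_ident < min_identity:
        return None
    if len(scored) > 1 and best_ident - scored[1][0] <= margin:
        runner = scored[1][1]
        if runner.label != best.label or runner.target_id != best.target_id:
            return best.target_id, "ambiguous"
    return best.target_id, best.label


def extract_edit_window(
    read_seq: str, aln: AlignmentResult, site: TargetSite
) -> str | None:
    """The read's 4-mer over the editing window, or None.

    None when the alignment does not cover the window or the extracted
    stack is not exactly 4 bases (an indel inside the window).
    """
    if site.mode != "base_edit":
        raise ValueError(f"target {site.target_id} is not a base-editing site")
    if not covers(aln, site.window_span):
        return None
    window = extract_region(read_seq, aln, site.window_span)
    return window if len(window) == 4 else None


def classify_edit(window: str, site: TargetSite) -> str:
    """'correct' iff the window is an accepted edited 4-mer, 'none' iff it
    equals the unedited window, else 'other'."""
    if len(window) != 4:
        raise ValueError("editing window must be 4 bases")
    if window in site.edited_windows:
        return "correct"
    if window == site.unedited_window:
        return "none"
    return "other"


def tally_cluster_edits(
    cluster_id: int,
    members: list[tuple[str, str, AlignmentResult]],
    layout: PlasmidLayout,
) -> dict[str, EditTally]:
    """Editing-outcome tallies for one cluster's (read_id, oriented seq,
    alignment) members over every base-editing target."""
    tallies = {
        t.target_id: EditTally(cluster_id=cluster_id, target_id=t.target_id)
        for t in layout.targets if t.mode == "base_edit"
    }
    for _read_id, seq, aln in members:
        for t in layout.targets:
            if t.mode != "base_edit":
                continue
            tally = tallies[t.target_id]
            window = extract_edit_window(seq, aln, t)
            if window is None:
                tally.n_excluded += 1
                continue
            tally.window_hist[window] += 1
            label = classify_edit(window, t)
            if label == "correct":
                tally.n_correct += 1
            elif label == "none":
                tally.n_none += 1
            else:
                tally.n_other += 1
    return tallies


def tally_cluster_recombination(
    cluster_id: int,
    members: list[tuple[str, str, AlignmentResult]],
    layout: PlasmidLayout,
    min_identity: float = 0.60,
    margin: float = 0.0,
) -> tuple[dict[str, RecombTally], dict[str, tuple[str, str] | None]]:
    """Recombination tallies for one cluster over every excision target.

    Returns the per-target tallies plus the per-read call
    (read_id -> (target_id, label), or None for excluded reads).
    """
    panel = build_recombination_panel(layout)
    tallies = {
        t.target_id: RecombTally(cluster_id=cluster_id, target_id=t.target_id)
        for t in layout.targets if t.mode == "excision"
    }
    labels: dict[str, tuple[str, str] | None] = {}
    for read_id, seq, _aln in members:
        hit = classify_recombination(seq, panel, min_identity=min_identity, margin=margin)
        labels[read_id] = hit
        if hit is None:
            for tally in tallies.values():
                tally.n_excluded += 1
            continue
        target_id, label = hit
        tally = tallies[target_id]
        if label == "recombined":
            tally.n_recombined += 1
        elif label == "nonrecombined":
            tally.n_nonrecombined += 1
        else:
            tally.n_ambiguous += 1
    return tallies, labels


def recombination_rate(tally: RecombTally) -> float | None:
    return tally.rate_percent


def editing_rate(tally: EditTally) -> float | None:
    return tally.rate_percent
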
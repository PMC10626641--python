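"""Plasmid layout: the sequenced fragment's reference and its annotated regions.

The screened molecule carries, on one contiguous fragment, the enzyme gene,
a 50-nt random barcode (UMI) and one or more target sites whose DNA is
modified by the enzyme (base editing or recombination-mediated excision).
The layout pins each of these regions to 0-based half-open coordinates on a
single reference sequence and records, per target site, the alternative
(edited) allele(s) against which reads are classified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import yaml

DNA_ALPHABET = frozenset("ACGT")

#: offsets inside the 4-base editing window (target-site positions 2-5)
#: where the programmed A-to-G conversion is expected (site positions 3 and 4).
EXPECTED_ADENINE_OFFSETS = (1, 2)


def _check_dna(seq: str, what: str) -> None:
    if not seq or not set(seq) <= DNA_ALPHABET:
        raise ValueError(f"{what} must be non-empty DNA over ACGT")


def default_edited_windows(unedited_window: str) -> tuple[str, ...]:
    """Accepted edited 4-mers: every non-empty subset of the expected
    adenines (window offsets 1 and 2) converted to G, other positions
    untouched.  A window with no adenine at those offsets has no accepted
    edit and yields an empty tuple."""
    if len(unedited_window) != 4:
        raise ValueError("editing window must be exactly 4 bases")
    adenines = [i for i in EXPECTED_ADENINE_OFFSETS if unedited_window[i] == "A"]
    out = []
    for r in range(1, len(adenines) + 1):
        for subset in itertools.combinations(adenines, r):
            w = list(unedited_window)
            for i in subset:
                w[i] = "G"
            out.append("".join(w))
    return tuple(out)


@dataclass(frozen=True)
class TargetSite:
    """One target-site region on the reference.

    mode "excision": the enzyme removes a fixed-length internal fragment;
    ``edited_allele`` is the recombined (shorter) sequence of the region.
    mode "base_edit": the enzyme converts adenines inside a 4-base window;
    ``window_span`` locates that window on the reference and
    ``edited_windows`` enumerates the accepted (correctly edited) 4-mers.
    """

    target_id: str
    span: tuple[int, int]
    mode: str  # "excision" | "base_edit"
    unedited_allele: str
    edited_allele: str | None = None          # excision only
    window_span: tuple[int, int] | None = None  # base_edit only, absolute coords
    edited_windows: tuple[str, ...] = ()        # base_edit only

    def __post_init__(self) -> None:
        if self.mode not in ("excision", "base_edit"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        _check_dna(self.unedited_allele, f"target {self.target_id} unedited allele")
        if self.mode == "excision":
            if not self.edited_allele:
                raise ValueError(f"excision target {self.target_id} needs a recombined allele")
            if len(self.edited_allele) >= len(self.unedited_allele):
                raise ValueError(
                    f"target {self.target_id}: recombined allele must be shorter than unedited"
                )
        else:
            if self.window_span is None:
                raise ValueError(f"base_edit target {self.target_id} needs window_span")
            ws, we = self.window_span
            s, e = self.span
            if not (s <= ws and we <= e and we - ws == 4):
                raise ValueError(
                    f"target {self.target_id}: window_span must be 4 bases inside span"
                )
            if not self.edited_windows:
                object.__setattr__(
                    self, "edited_windows", default_edited_windows(self.unedited_window)
                )
            if not self.edited_windows:
                raise ValueError(
                    f"target {self.target_id}: no adenine at expected window offsets; "
                    "provide edited_windows explicitly"
                )

    @property
    def unedited_window(self) -> str:
        ws, we = self.window_span
        s = self.span[0]
        return self.unedited_allele[ws - s : we - s]

    @property
    def excised_len(self) -> int:
        """Length difference unedited - recombined (excision targets)."""
        if self.mode != "excision":
            raise ValueError("excised_len applies to excision targets only")
        return len(self.unedited_allele) - len(self.edited_allele)

    def canonical_edited_window(self) -> str:
        """The fully edited window (every expected adenine converted) used
        as the default rendered allele for an edited molecule."""
        w = list(self.unedited_window)
        for i in EXPECTED_ADENINE_OFFSETS:
            if w[i] == "A":
                w[i] = "G"
        return "".join(w)

    def render(self, edited: bool) -> str:
        """Region sequence for an edited or unedited molecule."""
        if not edited:
            return self.unedited_allele
        if self.mode == "excision":
            return self.edited_allele
        ws, we = self.window_span
        s = self.span[0]
        a = self.unedited_allele
        return a[: ws - s] + self.canonical_edited_window() + a[we - s :]


@dataclass(frozen=True)
class PlasmidLayout:
    """Reference sequence of the sequenced fragment plus region coordinates."""

    ref_id: str
    ref_seq: str
    gene_span: tuple[int, int]
    umi_span: tuple[int, int]
    targets: tuple[TargetSite, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _check_dna(self.ref_seq.replace("N", "A"), "reference")
        spans = [("gene", self.gene_span), ("umi", self.umi_span)] + [
            (t.target_id, t.span) for t in self.targets
        ]
        n = len(self.ref_seq)
        for name, (s, e) in spans:
            if not (0 <= s < e <= n):
                raise ValueError(f"span {name} [{s},{e}) outside reference of length {n}")
        for (na, (sa, ea)), (nb, (sb, eb)) in itertools.combinations(spans, 2):
            if sa < eb and sb < ea:
                raise ValueError(f"spans {na} and {nb} overlap")
        ids = [t.target_id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate target ids")
        for t in self.targets:
            s, e = t.span
            if self.ref_seq[s:e] != t.unedited_allele:
                raise ValueError(
                    f"target {t.target_id}: unedited allele does not match reference span"
                )

    @property
    def umi_length(self) -> int:
        return self.umi_span[1] - self.umi_span[0]

    def target(self, target_id: str) -> TargetSite:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise KeyError(f"unknown target {target_id!r}")

    def region(self, span: tuple[int, int]) -> str:
        return self.ref_seq[span[0] : span[1]]


def layout_from_dict(d: dict) -> PlasmidLayout:
    ref_seq = d["ref_seq"].upper()
    targets = []
    for td in d.get("targets", []):
        span = tuple(td["span"])
        site = TargetSite(
            target_id=str(td["target_id"]),
            span=span,
            mode=td["mode"],
            unedited_allele=ref_seq[span[0] : span[1]],
            edited_allele=td.get("recombined_allele"),
            window_span=tuple(td["window_span"]) if "window_span" in td else None,
            edited_windows=tuple(td.get("edited_windows", ())),
        )
        targets.append(site)
    return PlasmidLayout(
        ref_id=str(d.get("ref_id", "layout")),
        ref_seq=ref_seq,
        gene_span=tuple(d["gene_span"]),
        umi_span=tuple(d["umi_span"]),
        targets=tuple(targets),
    )


def layout_to_dict(layout: PlasmidLayout) -> dict:
    d = {
        "ref_id": layout.ref_id,
        "ref_seq": layout.ref_seq,
        "gene_span": list(layout.gene_span),
        "umi_span": list(layout.umi_span),
        "targets": [],
    }
    for t in layout.targets:
        td = {"target_id": t.target_id, "mode": t.mode, "span": list(t.span)}
        if t.mode == "excision":
            td["recombined_allele"] = t.edited_allele
        else:
            td["window_span"] = list(t.window_span)
            td["edited_windows"] = list(t.edited_windows)
        d["targets"].append(td)
    return d


def load_layout(path) -> PlasmidLayout:
    """Read a layout from YAML (0-based half-open spans)."""
    with open(path) as fh:
        return layout_from_dict(yaml.safe_load(fh))


def save_layout(layout: PlasmidLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout_to_dict(layout), fh, sort_keys=False)
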
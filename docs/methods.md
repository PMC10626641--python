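# Methods

## The measurement problem

A substrate-linked directed-evolution screen produces a plasmid library in
which every enzyme variant is physically linked to (i) a unique random
50-nt barcode (UMI) and (ii) the target sites its activity modifies —
excision of a fixed 741-bp fragment for recombinases, A→G conversion
inside a protospacer window for adenine base editors. One long read of the
gene–UMI–target fragment therefore observes genotype and phenotype on the
same molecule. The computational task is to undo the ~5–10 % per-base
error of the reads: group reads by variant (UMI clustering), recover each
variant's exact gene sequence (consensus polishing), and estimate each
variant's per-target activity (read-level outcome classification).

## Alignment engines

Two engines sit behind one result type, chosen by what each job needs.

* `align_pair` is an affine-gap (Gotoh) dynamic program, exact under a
  configurable scoring scheme (default match +2, mismatch −4, gap open −4,
  gap extend −2; a gap of length L costs `open + L·extend`). Modes:
  global, and semiglobal with free terminal gaps on the query's flanks. It
  is row-vectorised with numpy (the in-row gap recurrence is folded into a
  running maximum), keeps full score matrices, and re-derives the path by
  recurrence checks, so the emitted op string always rescores to the
  optimum. It is the reference aligner for barcodes, windows and tests; it
  is not intended for megabase inputs.
* Long-read mapping, consensus pileups, panel classification, UMI identity
  and mutation counting use edit-distance-optimal paths (edlib), which are
  banded and orders of magnitude faster on ~3-kb reads. Identity is always
  computed from the path as matching columns / alignment columns with
  terminal gap runs excluded; alignment scores reported alongside are
  computed from the path under the configured scoring. For UMI-scale
  inputs the two engines give indistinguishable identities (measured mean
  difference −0.001 on noisy 50-mer pairs), so the cheaper engine is used
  throughout the pipeline.

Two alignment conventions matter enough to state:

* The reference's barcode region is written as 50 N's, and N is a plain
  mismatch for every base. This costs every read the same 50 edits and
  keeps the region anchored purely by its flanks. Treating N as a wildcard
  instead lets the aligner absorb flanking bases into the barcode window
  (extracted UMIs systematically ≥ 50 nt), which measurably degrades
  clustering.
* When a polished consensus is mapped back to the reference, terminal
  insertion runs of the infix alignment are rewritten as mismatch columns
  wherever reference columns remain (`_absorb_terminal_insertions`). At a
  free end the two representations cost the same, and the path search may
  otherwise park the trailing barcode bases as insertions — silently
  emptying the UMI span.
* Region extraction is reference-anchored: a span [s, e) collects the query
  bases aligned to those columns, including insertions strictly inside;
  an insertion exactly at a boundary belongs to the region on its left.

## Pipeline parameters

| parameter | default | rationale |
|---|---|---|
| min read length | 2900 bp | screen-scale fragment minus tolerance; set per layout (the excision study uses 1800 bp so recombined, 741-bp-shorter fragments survive) |
| min mean quality | Q10 | mean error probability in linear space, Phred-scaled; inclusive |
| mapping identity floor | 0.60 | below this a read is excluded from all tallies |
| cluster identity | 0.70 | greedy centroid threshold; founder read's UMI is the centroid and is never recomputed |
| min cluster size | 50 reads | unit of genotype/phenotype calling |
| consensus rounds | ≤ 3 | majority-vote pileup converges in 1–2 rounds on homogeneous read sets |
| per-target reporting floor | 50 classified reads | a rate below the floor is withheld (`NA`) |
| control rule | ≤ 5 mutations | DNA-level edit distance (substitutions and indels) to the control enzyme |
| selection comparators | strict | e.g. on-target > 25 %, off-target < 10 %, high-activity > 90 % |

Consensus polishing operates on each read's gene..UMI stretch (cut from
the mapping alignment), not the whole fragment: that stretch is
allele-homogeneous, whereas target regions mix edited and unedited alleles
across reads and a column-profile consensus of a mixed-length population is
ill-defined (a part-way-inserted excision stuffer oscillates between
rounds). Ties in a column vote keep the current draft's base, then fall to
the alphabetically first base; insertions require a strict majority of the
covering reads, which keeps nanopore's spurious insertions out. Votes are
unweighted by base quality — the simulator's qualities are uncoupled from
its errors by design, and real post-alignment per-base qualities are
unreliable anyway.

Greedy clustering uses an edit-distance prescreen (early-abandon band
k=25) and computes exact path identity only for centroids within distance
3 of the best prescreened candidate; at 50-mer scale this never changes
the best-identity assignment but removes a quadratic bottleneck.

## The simulator and what it does (not) emulate

The generator reproduces the screen's data-generating process: a library
of `n_variants` genes (i.i.d. substitutions at 0.005/base on the reference
gene, error-prone-PCR-like; spiked exact control copies first), one unique
uniform-random 50-mer UMI per variant, per-target true rates drawn uniform
on [0, 1], and per read an independent Bernoulli outcome per target — the
molecule sampling of a plasmid prep. The error channel applies i.i.d.
per-base substitutions (default 4 %), deletions (2 %) and geometric-length
(p=0.5) insertions (2 % initiation), Gaussian per-base Phred scores
(mean 14, sd 4, clipped to [2, 41]), and reverse-complements each read
with probability 0.5. Fragment geometry follows the screened molecules:
~2.9-kb fragment with three 20-nt protospacers whose editing window is
target-site positions 2–5 with adenines at positions 3 and 4; or a
target region of site + stuffer + site whose recombined allele is one site,
exactly 741 bp shorter.

Not emulated: signal-level artefacts, homopolymer- and context-dependent
errors, quality/error coupling, chimeras, adapters, coverage skew.
Passing tests therefore demonstrate the pipeline's contracts under an
i.i.d. channel at realistic error magnitudes; they do not certify
performance against basecaller-specific error structure.

## Validation studies and two known limits

`scripts/acceptance.py` and the end-to-end test suite run two studies
chosen to fit minutes of CPU: 100 variants × 80 reads (three base-editing
targets, 4/2/2 channel) and 60 variants × 80 reads (one 741-bp excision
target, 7 % total error). Across seeds these give ~100 % cluster purity,
~94–100 % of variants recovered as exactly one retained cluster, ~99–100 %
error-free consensus genes, perfect control recall with zero
six-mutation false controls, and ≥ 99.9 % recombination read labels.

Two systematic effects are worth understanding rather than hiding:

1. **Base-editing rates compress at high activity.** The read-level
   classifier matches the extracted 4-mer exactly: any substitution error
   inside the window that is not itself an accepted edit sends the read to
   "other", which stays in the denominator. At 4 % per-base substitution
   error an edited read's window survives intact with probability ≈ 0.87,
   so the reported rate behaves like `≈ 0.87·p + 0.02` — a cluster with
   true rate 0.95 reads out near 0.81, several binomial standard
   deviations low, while low-activity clusters are nearly unbiased. This
   is a property of exact-window counting at this error rate, not of the
   implementation (with indel-only noise the recovered rate is ≈ 0.99·p,
   ruling out alignment placement). Rates remain strictly monotone in true
   activity, so ranking and threshold screening remain sound; absolute
   rates near the top of the scale are conservative. Excision rates do not
   show the effect — the 741-bp length difference makes read labels
   essentially error-free.
2. **Family splits near the cluster-size floor.** With ~8 % per-base UMI
   noise, the identity between two noisy copies of one UMI is ≈ 0.83 ±
   0.06, and the founder-as-centroid greedy rule occasionally lets one
   family condense around two mediocre centroids; with 80 reads per
   variant both halves can land below the 50-read floor and the variant
   drops out (0–6 of 100 variants per seed in the base-editing study).
   Purity is unaffected. Extraction noise was measured near
   channel-optimal and re-anchoring or re-scoring the identity gives no
   improvement, so this is an intrinsic operating margin of
   fixed-threshold greedy clustering at this noise level; deeper
   per-variant coverage or lower UMI error widens it immediately.

## Determinism and numeric conventions

All randomness flows from a single integer seed through
`numpy.random.default_rng` (the library draw and the read draw use
distinct derived streams); identical config + seed reproduces every
artifact byte-for-byte, which the test suite asserts on the persisted
report tables. Coordinates are 0-based half-open everywhere. Rates are
percentages with four decimals in persisted tables; `NA` marks a withheld
or undefined value (e.g. a zero denominator). Medians use the standard
mean-of-middle-pair rule for even counts. Translation uses the standard
genetic code, renders stops as `*`, unresolvable codons as `X`, and drops
a trailing partial codon.
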
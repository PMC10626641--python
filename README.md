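# deqseq

Genotype–phenotype linkage from nanopore long reads, for directed-evolution
screens of DNA-modifying enzymes (designer recombinases, compact adenine
base editors) in which each enzyme variant is expressed from a plasmid that
also carries a unique 50-nt molecular identifier (UMI) and the enzyme's own
target sites. Sequencing the gene–UMI–target fragment with long reads lets
a single molecule report both *which variant* it is and *what that variant
did* to its target DNA. The package turns a noisy long-read FASTQ into a
per-variant table of accurate full-length enzyme sequences and per-target
editing or recombination rates — and ships a synthetic-read simulator that
replaces the wet lab for development and validation.

## Method

For each read *r* of a screen:

1. **QC** — keep *r* iff `len(r) ≥ L_min` and its mean quality
   `Q̄ = −10·log₁₀( mean_i 10^(−q_i/10) ) ≥ Q_min` (defaults 2900 bp / Q10,
   matching typical screen settings).
2. **Map** — align *r* and its reverse complement to the fragment
   reference (gene, a 50×N UMI placeholder, target sites); keep the better
   strand, require the alignment to start at or before the gene start and
   end at or after the UMI end, and require identity ≥ 0.60.
3. **Cluster** — extract the read bases aligned to the UMI columns and
   cluster all UMIs greedily in input order: the first UMI founds cluster
   0; each later UMI joins the best-identity centroid with identity ≥ 0.7
   (identity = matching columns / alignment columns, terminal gaps
   excluded), else founds a new cluster. Clusters with ≥ 50 reads are
   retained — one retained cluster ≈ one variant.
4. **Polish** — per cluster, seed a draft with the highest-quality member
   read (trimmed to the gene..UMI stretch) and iterate majority-vote
   pileup polishing: per reference column a plurality call over
   {A,C,G,T,del}; insertions only on strict majority support. Up to 3
   rounds or convergence. At ≥ 50 reads and 5–10 % per-base error this
   yields the variant's gene sequence essentially error-free.
5. **Quantify** — per cluster and target site:
   *excision targets*: classify every member read against a panel holding
   the unedited and recombined rendering of each target region (best
   identity wins; the 741-bp excision makes the call unambiguous), then
   `rate = 100·n_rec/(n_rec+n_nonrec)`;
   *base-editing targets*: extract the 4-base editing window (target-site
   positions 2–5) from the read's alignment, drop windows with indels, and
   classify correct (an accepted A→G–edited 4-mer at the expected adenine
   positions 3/4), unedited, or other; `rate = 100·n_correct/n_classified`.
   Rates are reported only for targets with ≥ 50 classified reads.
6. **Report** — translate the polished gene; flag clusters within ≤ 5 DNA
   mutations (edit distance) of the control enzyme as control clusters;
   compute per-target control medians; apply selection criteria with
   strict comparators (e.g. on-target > 25 %, off-targets < 10 %); emit a
   UMI-specific retrieval primer (reverse complement of the consensus UMI)
   per cluster.

The simulator draws a variant library (i.i.d. substitutions on a reference
gene, unique random UMIs, per-target true rates), renders each molecule's
allele per read by a Bernoulli draw at the variant's true rate, and pushes
it through a nanopore-like channel (per-base substitutions,
geometric-length indels, Gaussian per-base qualities, random strand), with
a full truth table for every variant and read.

## Worked example

Simulate a small screen (20 variants, 3 spiked controls, 60 reads each,
three base-editing targets, 4 %/2 %/2 % error channel) and process it:

```
$ deqseq simulate --out sim --seed 7 --n-variants 20 --reads-per-variant 60 \
      --n-controls 3 --gene-len 600 --gene-mutation-rate 0.02
wrote 1200 reads for 20 variants to sim

$ deqseq run --config run.yaml --reads sim/reads.fastq --out out
[deqseq] qc: 1200/1200 reads kept
[deqseq] map: 1200 mapped+covered, 0 unmapped, 0 not covering gene..UMI
[deqseq] cluster: 36 clusters, 18 with >= 50 reads
[deqseq] polish+genotype: 18 clusters, 2 controls
18 retained clusters, 2 controls, 0 selected
```

(`run.yaml` points at `sim/layout.yaml` and sets the thresholds; see
below.) The master table `out/report.tsv` holds one row per retained
cluster:

```
cluster_id  size  centroid_umi  consensus_umi  is_control  mutations_vs_control  selected  bt1_rate  bt1_n_classified ...
0           59    TGGTGTTAAC…   TGGTGTTAAC…    1           0                     0         NA        47  52.0000  50  74.5098  51
8           58    CTCTTTTCCA…   CTCTTTCCAG…    0           7                     0         68.0000   50  44.0000  50  26.0000  50
```

Cluster 0 is a spiked control: its polished gene is 0 mutations from the
reference enzyme. Its `bt1` rate is `NA` because only 47 reads carried an
indel-free editing window — below the 50-read reporting floor. Cluster 8
is an evolved variant (7 DNA mutations) editing target 1 in 68 % of its
50 classified reads. `out/control_summary.tsv` gives per-target medians
over control clusters, `out/primers.tsv` the retrieval primer pairs, and
`out/counts.tsv` the per-stage read accounting. Every intermediate
(filtered FASTQ, alignments, cluster membership, consensus FASTA, tallies)
is persisted, and each stage can be re-run from those files alone
(`deqseq qc/map/cluster/polish/quantify --help`).

A minimal `run.yaml`:

```yaml
layout: sim/layout.yaml      # fragment reference + region coordinates
min_length: 700
min_mean_q: 10.0
cluster_identity: 0.7
min_cluster_size: 50
min_reads_per_target: 50
control_max_mutations: 5
selection: [[bt1, ">", 90]]
universal_forward: GATTACAGATTACAGATTAC
```

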
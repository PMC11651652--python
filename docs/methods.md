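# Methods

## Probe design

r-cDNA — the cDNA reverse-transcribed from rRNA — is the reverse complement
of the rRNA sense strand. A depletion probe therefore carries a capture
portion that is simply a sense-strand rRNA segment (its reverse complement
lies in the r-cDNA) 3' of a universal adapter that a biotinylated primer
binds, allowing probe/r-cDNA duplexes to be pulled out on streptavidin
beads. Panels are built per species against that species' rRNA set.

Tiling starts windows at 0, step, 2·step, … and right-anchors the final
window at `end = len(source)`, so for any `step ≤ probe_len` every base of
every source is covered — an uncovered 3' tail would leave r-cDNA able to
escape capture. Defaults are `probe_len = 50`, `step = 35` (≈15 nt overlap);
no probe length is prescribed by the protocol itself, and both are
configurable. The adapter default is a placeholder sequence — the real
universal primer belongs to the wet-lab kit and should be supplied.

Melting temperature is annotated with the Wallace rule (2·(A+T) + 4·(G+C))
up to 13 nt and `64.9 + 41·(GC − 16.4)/len` beyond; it is never used as a
filter, because the protocol specifies no thermodynamic criterion. The
off-target screen flags (never removes) probes sharing an exact k-mer
(default k = 15, both strands) with a non-rRNA transcriptome: removal would
silently break the full-coverage contract, so review is left to the user.

## Barcode demultiplexing

The barcode read is described by a layout of non-overlapping segments (bc3,
linker, bc2, linker, bc1, umi by default — ligation order outermost first)
plus three whitelists of 96 barcodes. Correction returns the unique
whitelist entry at minimal Hamming distance ≤ `max_hamming` (default 1);
exact matches win trivially, and a tie at the minimal admissible distance is
rejected as `ambiguous_correction` rather than resolved arbitrarily. Schema
validation warns when any within-round pair sits at distance
≤ 2·`max_hamming`, since unique correction is then not guaranteed. Linkers
are checked with the same per-segment tolerance and rejected distinctly
(`linker_mismatch`) for diagnosability. The UMI is taken verbatim — UMI
collapse belongs to counting, not extraction — and base qualities are
carried through but never consulted (no quality-based rule is part of the
design).

Cell identity is composed as `bc3.bc2.bc1` with 1-based well indices; any
fixed order would do — consistency is the contract. Demultiplexing writes
tagged cDNA FASTQ (header annotated `CB:<cell> UB:<umi>`), a
read→(cell, UMI) join table, and a stats table satisfying
`reads_total = reads_valid + Σ rejects` on every input.

## Counting

GFF3 (1-based inclusive) is converted to 0-based half-open internally; SAM
coordinates from pysam already are. Biotypes come from the feature type
(rRNA → rRNA, tRNA → tRNA, CDS/gene → mRNA, other RNA types → other), with a
`gene_biotype` attribute overriding on `gene` rows.

Assignment keeps primary alignments with MAPQ ≥ 10 ("confidently mapped");
a read is assigned iff its interval overlaps exactly one feature on the same
strand (two or more → `ambiguous`, discarded). Bacterial operons make a
longest-overlap rule tempting, but the stricter single-overlap rule matches
the bulk counting convention this workflow uses, and ambiguity counts are
logged. Antisense overlap counts as `no_feature` by default.

UMI deduplication is per (cell, gene) — not per (gene, position), a
deliberate choice where either reading is defensible. `exact` counts
distinct UMI strings. `directional1` merges a UMI into a Hamming-1
neighbour whose read count is at least twice its own and counts the
resulting networks (reachability from the highest-count UMI downwards);
note the threshold is 2n, not the 2n−1 used by some established tools —
at the boundary (counts 2 and 1) this keeps the pair separate. Counter
conservation (`assigned + unassigned reasons (+ untagged) = processed`)
holds on every run.

Cell/UMI identity is taken from, in order of precedence: an explicit
read→(cell, UMI) join table (the demux output — the pipeline's route, so
demux corrections and rejections propagate into counting), CB/UB SAM tags,
or a `|CB:…|UB:…`-encoded read name. Without a join table, a read lacking
tags is a hard error, as it indicates the stages ran out of order.

## QC statistics

* **Multiplet model**: λ = cells loaded / possible triplets; the numerator
  is cells *loaded*, not recovered — that is the quantity the experimenter
  controls and the convention under which the 60,000-cell library gives
  3.35%. `n_cells = 0` returns 0 (the λ→0 limit) flagged degenerate.
* **Saturation**: exact `1 − n_umis/n_reads`; error on zero reads.
  Subsampling is without replacement at the read level with an independent
  seeded draw per fraction (the five subsamples are analysed independently,
  not nested); fraction 1.0 bypasses sampling and reproduces the full-data
  value exactly.
* **Knee/recovery**: ranking descending; recovered means UMIs ≥ floor
  (ties included); recovery rate divides by cells loaded.
* **Top-k medians**: UMI and gene rankings are independent, descending,
  ties broken by cell_id for determinism; the median of an even k is the
  mean of the central pair.
* **Cell filters**: strict inequalities on both UMI bounds and the gene
  floor (`min < UMIs < max`, `genes > min_genes`), matching the
  "more than / less than" screening conventions (100/2000 biofilm,
  200/5000 exponential E. coli, 15/1000 + genes > 30 S. aureus).
* **Bulk comparison**: per-gene pseudobulk (UMI sums over cells) joined to
  the bulk table by gene_id; genes with zero in either vector excluded;
  Pearson on log2; an error below 3 remaining genes. The statistic is
  invariant to scaling either library by a positive constant.

Biotype fractions are computed over exact rationals and sum to 1 by
construction.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, at
desk scale:

* **Cells**: distinct barcode triplets sampled uniformly from 96³ (no
  collisions — multiplets are modelled separately at the occupancy level by
  `simulate_multiplets`, the Monte-Carlo oracle for the closed form).
* **Per-cell UMI totals**: log-normal (default median 100, sd-log 1.0) —
  real libraries are heavy-tailed, with per-cell means well above medians.
* **Composition**: each UMI is rRNA with probability `rrna_umi_fraction`
  (default 0.918, the undepleted ~8.2%-mRNA composition); gene identity
  within a class is drawn from a Dirichlet-weighted categorical.
* **Duplication**: geometric reads per UMI, mean 10 (saturation ≈ 0.9); a
  one-parameter memoryless stand-in for PCR amplification.
* **Errors**: substitutions at a configurable per-base rate confined to the
  barcode segments of read 1. cDNA reads and alignments are error-free so
  the external aligner can be bypassed with the generated SAM; sequencing
  errors in cDNA and UMI are out of scope.
* **Whitelists**: 96 barcodes of length 8 with minimum pairwise Hamming
  distance 3 (unique single-mismatch correction guaranteed), generated from
  a fixed internal seed — they model the protocol's fixed plates, not a
  per-library random quantity.

All outputs are mutually consistent (SAM intervals lie inside their gene's
annotation; error-free barcode reads re-slice to the truth triplet) and
byte-identical under a fixed seed. The truth matrix counts distinct UMIs
actually generated per (cell, gene), so UMI-string collisions — possible at
4⁸ = 65,536 tags — are part of the truth rather than a discrepancy.

What passing tests on this generator do **not** show: robustness to cDNA
sequencing error, to operon-induced ambiguity (genes are non-overlapping by
construction), to chimeric reads, or to the barcode-hopping artefacts of
real sequencers.

## Problem sizes and numerical choices

Simulated libraries in the tests use 10–100 cells and 8–30 genes with
median 100 UMIs per cell (~10⁴–10⁵ reads), which exercises every code path
while keeping the whole suite fast; the statistics under test are
scale-free. The Monte-Carlo multiplet cross-check uses 200 replicates and a
3-standard-error band. Depletion-scenario and composition checks use
3-binomial-SD bands at the realised library size. Median over even k is the
mean of the central pair everywhere. Degenerate inputs (empty matrix, zero
cells loaded, zero reads) raise explicit errors rather than returning NaN,
except where a limit is well-defined and flagged (multiplet frequency at 0
cells).

## Known limitations

* The directional UMI rule uses the 2n threshold described above; libraries
  deduplicated with 2n−1 tools may count slightly fewer molecules.
* Assignment has no multi-overlap rescue; operon-dense annotations will
  discard more reads as ambiguous than a longest-overlap policy would.
* The pipeline consumes SAM from an external aligner; alignment itself, and
  all downstream analysis past the QC report (normalisation, clustering,
  embedding, marker tests), are out of scope.
* Under barcode errors, a miscorrected PCR duplicate can split one molecule
  across two cells, so the observed UMI total can slightly exceed truth;
  cells untouched by miscorrected or rejected reads are unaffected (this is
  asserted in the tests).
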
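# ribod

Bacterial single-cell RNA-seq by split-pool combinatorial barcoding suffers
from one dominant nuisance: without poly(A) tails to select on, ~95% of
captured molecules are rRNA. `ribod` is a toolkit around an
rRNA-depletion-by-hybridisation workflow for such libraries (PETRI-seq-style
three-round 96×96×96 barcoding with probe-based removal of rRNA-derived
cDNA). It provides, as a Python library with a thin `ribod` CLI:

* **Probe design** — panels that tile every base of an rRNA reference with
  capture sequences reverse-complementary to the rRNA-derived cDNA
  (r-cDNA), plus a 5' universal adapter and a k-mer off-target screen.
* **Demultiplexing** — extraction and Hamming-distance correction of the
  three well barcodes and the UMI from the barcode read, producing tagged
  cDNA FASTQ and a read→(cell, UMI) table.
* **Counting** — strand-aware read→gene assignment (featureCounts-style
  single-overlap rule) over a GFF3 annotation and UMI deduplication (exact
  or directional) into a sparse cell×gene MatrixMarket matrix with biotype
  totals.
* **QC statistics** — the Poisson multiplet model, sequencing saturation
  with a subsampling curve, knee/recovery at a UMI floor, top-k medians,
  transcriptome-wide gene coverage, strict-bound cell filters, and the
  log2 Pearson comparison against bulk RNA-seq.
* **Synthetic data** — a seeded generator of ground-truthed libraries
  (genome, GFF3, FASTQ pair, SAM, truth tables) so every stage is testable
  without external downloads.

## The statistics at the core

**Multiplet frequency.** Cells land on barcode triplets as Poisson with
rate λ = n_cells / n_combos (n_combos = 96³ = 884,736 for three 96-well
rounds). With p(0) = e^(−λ) and p(1) = λe^(−λ), the multiplet frequency —
the probability that an occupied barcode holds more than one cell — is

    f = p(≥2) / p(≥1) = (1 − p0 − p1) / (1 − p0)

At 60,000 cells loaded, f = 3.35%.

**Sequencing saturation.** `1 − n_umis / n_reads` over confidently mapped
reads (primary alignments at or above the MAPQ threshold), evaluated on
independent 20/40/60/80/100% subsamples of the reads.

**Knee/recovery.** Cells ranked by UMI count; those with ≥ `min_umis`
(default 15) count as recovered, relative to cells loaded.

**Bulk comparison.** Pearson r between log2 per-gene pseudobulk UMIs and
log2 bulk reads, excluding genes with zero counts in either library.

## Worked example

```bash
python examples/demux_and_count.py
```

```
reads demultiplexed:  89693/89693
cells x genes:        50 x 20
total UMIs:           8941
matrix equals truth:  True
```

A 50-cell zero-error synthetic library demultiplexes completely (every read
resolves to its true barcode triplet) and the deduplicated count matrix
reproduces the generator's truth exactly — 8,941 distinct molecules from
89,693 reads (≈10 reads per molecule, i.e. saturation ≈ 0.90).

`python examples/qc_report.py` prints the QC side: the 3.35% multiplet
frequency at a 60,000-cell load, a saturation curve rising 0.641 → 0.900
across subsamples, 96/100 cells recovered at the 15-UMI floor, and a 92%/8%
rRNA/mRNA UMI split — the undepleted composition that motivates probe-based
depletion. `python examples/depletion_scenario.py` solves the per-molecule
depletion efficiency (0.979) that lifts an 8.2%-mRNA library to 81% and
verifies the simulated shift. `ribod --help` lists the equivalent shell
commands (`design-probes`, `demux`, `count`, `qc`, `simulate`, `run`).

## Layout

* `src/ribod/` — `probe_design`, `barcode_demux`, `feature_counting`,
  `qc_stats`, `synthetic_data`, `pipeline`, `cli`
* `examples/` — narrative scripts, one per capability
* `docs/methods.md` — models, assumptions, parameter choices, limitations
* `tests/` — pytest suite with brute-force oracles and property tests
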
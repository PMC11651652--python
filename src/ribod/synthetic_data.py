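"""Ground-truthed synthetic split-pool libraries.

Generates everything the pipeline consumes — genome FASTA, GFF3 annotation,
paired FASTQ (read 1 = barcode read, read 2 = cDNA), an error-free SAM of the
cDNA reads and the truth tables — from one seeded parameter set, so each
stage can be tested against known truth without external data.

What the generator emulates: cells assigned to distinct 96×96×96 barcode
triplets; heavy-tailed per-cell UMI totals (log-normal — observed per-cell
medians sit well below means in real libraries); a tunable rRNA UMI fraction
(defaults to the rRNA-dominated composition of an undepleted bacterial
library, mRNA ratio ≈ 8.2%); PCR duplication with a geometric reads-per-UMI
law; and substitution errors confined to the barcode segments of read 1.
What it does not emulate: cDNA sequencing errors, operon structure, barcode
collisions between cells (triplets are sampled without replacement) and
multiplet transcriptome mixing — multiplets are modelled only at the
barcode-occupancy level by :func:`simulate_multiplets`.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
import scipy.sparse as sp

from .barcode_demux import BarcodeSchema, Segment, write_schema
from .feature_counting import CountMatrix, Feature, FeatureTable, matrix_from_groups
from .utils import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed internal seed for whitelist construction: whitelists model the fixed
# barcode plates of the protocol, not a per-library random quantity
_WHITELIST_SEED = 96_96_96
_LINKER1 = "ACGTCA"
_LINKER2 = "TGCAGT"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_whitelist(n: int = 96, length: int = 8, min_distance: int = 3, seed: int | None = None) -> tuple[str, ...]:
    """Greedy random whitelist with minimum pairwise Hamming distance.

    min_distance 3 guarantees unique single-mismatch correction.
    """
    rng = np.random.default_rng(_WHITELIST_SEED if seed is None else seed)
    chosen: list[np.ndarray] = []
    while len(chosen) < n:
        cand = _BASES[rng.integers(0, 4, size=length)]
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
    return tuple(bytes(c).decode() for c in chosen)


def default_schema(umi_length: int = 8, bc_length: int = 8, max_hamming: int = 1) -> BarcodeSchema:
    """The generator's barcode-read layout: bc3·linker·bc2·linker·bc1·umi."""
    wls = tuple(
        make_whitelist(96, bc_length, seed=_WHITELIST_SEED + i) for i in range(3)
    )
    off = 0
    layout = []
    for kind, length, expected in (
        ("bc3", bc_length, None),
        ("linker", len(_LINKER1), _LINKER1),
        ("bc2", bc_length, None),
        ("linker", len(_LINKER2), _LINKER2),
        ("bc1", bc_length, None),
        ("umi", umi_length, None),
    ):
        layout.append(Segment(kind=kind, offset=off, length=length, expected_seq=expected))
        off += length
    return BarcodeSchema(whitelists=wls, layout=tuple(layout), max_hamming=max_hamming)


@dataclass
class SimulationParams:
    """Study conditions for one synthetic library."""

    n_cells: int = 50
    n_genes: int = 20
    n_rrna_genes: int = 3
    rrna_umi_fraction: float = 0.918  # undepleted library: mRNA ratio ≈ 8.2%
    umi_mean_log: float = float(np.log(100))  # per-cell median ≈ 100 UMIs
    umi_sd_log: float = 1.0
    gene_dirichlet_conc: float = 1.0
    mean_reads_per_umi: float = 10.0  # saturation ≈ 0.9
    barcode_error_rate: float = 0.0
    umi_length: int = 8
    bc_length: int = 8
    gene_length: int = 200
    gene_spacing: int = 50
    read_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rrna_umi_fraction <= 1.0):
            raise ValueError("rrna_umi_fraction must be in [0, 1]")
        if not (0.0 <= self.barcode_error_rate < 1.0):
            raise ValueError("barcode_error_rate must be in [0, 1)")
        if self.mean_reads_per_umi < 1.0:
            raise ValueError("mean_reads_per_umi must be >= 1")
        if not (0 <= self.n_rrna_genes <= self.n_genes):
            raise ValueError("n_rrna_genes must be between 0 and n_genes")
        if self.read_length > self.gene_length:
            raise ValueError("read_length must not exceed gene_length (reads lie inside genes)")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")


@dataclass
class TruthRead:
    read_id: str
    cell_id: str
    gene_id: str
    umi: str
    biotype: str
    duplicate_of: str | None  # read_id of the first read of the same molecule


@dataclass
class SyntheticTruth:
    params: SimulationParams
    schema: BarcodeSchema
    features: FeatureTable
    cell_triplets: dict[str, tuple[int, int, int]]  # cell_id -> 0-based well indices
    truth_matrix: CountMatrix
    reads: list[TruthRead]
    paths: dict[str, Path] = field(default_factory=dict)


def _build_genome(params: SimulationParams, rng: np.random.Generator):
    """One contig with genes laid end to end; rRNA genes first, then CDS."""
    n = params.n_genes
    contig = "chr1"
    length = n * (params.gene_length + params.gene_spacing) + params.gene_spacing
    genome = _random_seq(rng, length)
    features = []
    pos = params.gene_spacing
    for i in range(n):
        is_rrna = i < params.n_rrna_genes
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            Feature(
                gene_id=(f"rrna_{i + 1:03d}" if is_rrna else f"gene_{i + 1:03d}"),
                contig=contig,
                strand=strand,
                start=pos,
                end=pos + params.gene_length,
                biotype="rRNA" if is_rrna else "mRNA",
            )
        )
        pos += params.gene_length + params.gene_spacing
    return contig, genome, FeatureTable(features)


def _write_genome_files(out_dir: Path, contig: str, genome: str, features: FeatureTable):
    fasta = out_dir / "genome.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")
    gff = out_dir / "annotation.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig} 1 {len(genome)}\n")
        for f in features.features:
            ftype = "rRNA" if f.biotype == "rRNA" else "CDS"
            fh.write(
                f"{contig}\tribod_sim\t{ftype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.gene_id}\n"
            )
    return fasta, gff


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        # substitute with a uniformly chosen *different* base
        for i in idx:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return bytes(arr).decode()


def simulate_library(
    params: SimulationParams,
    out_dir: str | Path,
    include_sam_tags: bool = True,
) -> SyntheticTruth:
    """Simulate a library and write all files under ``out_dir``.

    Outputs: ``genome.fasta``, ``annotation.gff3``, ``reads_R1.fastq``
    (barcode reads), ``reads_R2.fastq`` (cDNA), ``alignments.sam`` (error-free
    alignments of every cDNA read; CB/UB tags included when
    ``include_sam_tags``), ``schema.yaml`` + whitelists, and truth TSVs.
    Deterministic under a fixed seed.
    """
    params.__post_init__()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    schema = default_schema(params.umi_length, params.bc_length)
    schema_path = write_schema(schema, out_dir)
    contig, genome, features = _build_genome(params, rng)
    fasta_path, gff_path = _write_genome_files(out_dir, contig, genome, features)
    feature_by_id = {f.gene_id: f for f in features.features}
    rrna_ids = [f.gene_id for f in features.features if f.biotype == "rRNA"]
    mrna_ids = [f.gene_id for f in features.features if f.biotype != "rRNA"]

    # cells: distinct triplets over the 96^3 space
    combos = rng.choice(96**3, size=params.n_cells, replace=False)
    triplets = {}
    for c in combos:
        i3, rem = divmod(int(c), 96 * 96)
        i2, i1 = divmod(rem, 96)
        cell_id = f"{i3 + 1}.{i2 + 1}.{i1 + 1}"
        triplets[cell_id] = (i1, i2, i3)

    # per-class gene abundances
    rrna_p = rng.dirichlet(np.full(len(rrna_ids), params.gene_dirichlet_conc)) if rrna_ids else None
    mrna_p = rng.dirichlet(np.full(len(mrna_ids), params.gene_dirichlet_conc)) if mrna_ids else None

    cell_totals = np.maximum(
        1, np.round(rng.lognormal(params.umi_mean_log, params.umi_sd_log, params.n_cells))
    ).astype(int)

    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    reads: list[TruthRead] = []
    r1_records: list[tuple[str, str]] = []
    r2_records: list[tuple[str, str, int, bool]] = []  # (read_id, seq, pos, is_reverse)
    read_no = 0
    for cell_id, total in zip(triplets, cell_totals):
        i1, i2, i3 = triplets[cell_id]
        bc_read_clean = (
            schema.whitelists[2][i3]
            + _LINKER1
            + schema.whitelists[1][i2]
            + _LINKER2
            + schema.whitelists[0][i1]
        )
        n_rrna = (
            rng.binomial(total, params.rrna_umi_fraction) if rrna_ids else 0
        )
        if not mrna_ids:
            n_rrna = total
        gene_draw = []
        if n_rrna:
            gene_draw.extend(rng.choice(rrna_ids, size=n_rrna, p=rrna_p))
        if total - n_rrna:
            gene_draw.extend(rng.choice(mrna_ids, size=total - n_rrna, p=mrna_p))
        for gene_id in gene_draw:
            gene = feature_by_id[gene_id]
            umi = _random_seq(rng, params.umi_length)
            groups[(cell_id, gene_id)][umi] += 1
            n_reads = int(rng.geometric(1.0 / params.mean_reads_per_umi))
            first_read_id: str | None = None
            for _ in range(n_reads):
                read_no += 1
                read_id = f"read{read_no:07d}"
                pos = int(
                    rng.integers(gene.start, gene.end - params.read_length + 1)
                )
                frag = genome[pos : pos + params.read_length]
                is_reverse = gene.strand == "-"
                r2_seq = revcomp(frag) if is_reverse else frag
                barcode_part = _apply_errors(bc_read_clean, rng, params.barcode_error_rate)
                r1_records.append((read_id, barcode_part + umi))
                r2_records.append((read_id, r2_seq, pos, is_reverse))
                reads.append(
                    TruthRead(
                        read_id=read_id,
                        cell_id=cell_id,
                        gene_id=gene_id,
                        umi=umi,
                        biotype=gene.biotype,
                        duplicate_of=first_read_id,
                    )
                )
                if first_read_id is None:
                    first_read_id = read_id

    # truth matrix: distinct UMIs actually generated per (cell, gene)
    truth_matrix = matrix_from_groups(groups, features, "exact")

    fq1 = out_dir / "reads_R1.fastq"
    fq2 = out_dir / "reads_R2.fastq"
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for (rid, seq), (_, r2_seq, _, _) in zip(r1_records, r2_records):
            f1.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            f2.write(f"@{rid}\n{r2_seq}\n+\n{'I' * len(r2_seq)}\n")

    sam_path = out_dir / "alignments.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": contig, "LN": len(genome)}],
    }
    truth_by_id = {r.read_id: r for r in reads}
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for rid, r2_seq, pos, is_reverse in r2_records:
            aln = pysam.AlignedSegment(sam.header)
            aln.query_name = rid
            aln.query_sequence = genome[pos : pos + params.read_length]
            aln.flag = 16 if is_reverse else 0
            aln.reference_id = 0
            aln.reference_start = pos
            aln.mapping_quality = 60
            aln.cigarstring = f"{params.read_length}M"
            aln.query_qualities = pysam.qualitystring_to_array("I" * params.read_length)
            if include_sam_tags:
                tr = truth_by_id[rid]
                aln.set_tag("CB", tr.cell_id)
                aln.set_tag("UB", tr.umi)
            sam.write(aln)

    cells_path = out_dir / "truth_cells.tsv"
    with open(cells_path, "w") as fh:
        fh.write("cell_id\tbc1_idx\tbc2_idx\tbc3_idx\n")
        for cell_id, (i1, i2, i3) in triplets.items():
            fh.write(f"{cell_id}\t{i1}\t{i2}\t{i3}\n")
    reads_path = out_dir / "truth_reads.tsv"
    with open(reads_path, "w") as fh:
        fh.write("read_id\tcell_id\tgene_id\tumi\tbiotype\tduplicate_of\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.cell_id}\t{r.gene_id}\t{r.umi}\t{r.biotype}\t"
                f"{r.duplicate_of or ''}\n"
            )

    return SyntheticTruth(
        params=params,
        schema=schema,
        features=features,
        cell_triplets=triplets,
        truth_matrix=truth_matrix,
        reads=reads,
        paths={
            "genome": fasta_path,
            "gff": gff_path,
            "fq1": fq1,
            "fq2": fq2,
            "sam": sam_path,
            "schema": schema_path,
            "truth_cells": cells_path,
            "truth_reads": reads_path,
        },
    )


def simulate_multiplets(
    n_cells: int,
    n_combos: int = 96**3,
    replicates: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo multiplet frequency: mean ± SE over seeded replicates.

    Each replicate throws ``n_cells`` cells uniformly into ``n_combos``
    barcode combinations and reports multi-occupied / occupied bins — the
    empirical counterpart of the closed-form Poisson model.
    """
    if replicates < 2:
        raise ValueError("simulate_multiplets: replicates must be >= 2")
    rng = np.random.default_rng(seed)
    freqs = np.empty(replicates)
    for i in range(replicates):
        occ = np.bincount(rng.integers(0, n_combos, size=n_cells), minlength=0)
        occ = occ[occ > 0]
        freqs[i] = 0.0 if occ.size == 0 else (occ > 1).sum() / occ.size
    return float(freqs.mean()), float(freqs.std(ddof=1) / np.sqrt(replicates))


@dataclass
class DepletionScenario:
    pre: CountMatrix
    post: CountMatrix
    features: FeatureTable
    depletion_efficiency: float


def make_depletion_scenario(
    params: SimulationParams,
    depletion_efficiency: float,
    out_dir: str | Path | None = None,
) -> DepletionScenario:
    """Paired pre/post-depletion truth matrices from one simulated library.

    The post library removes each rRNA-classified UMI independently with
    probability ``depletion_efficiency``; mRNA UMIs are untouched, mirroring
    probe pulldown of r-cDNA.
    """
    if not (0.0 <= depletion_efficiency <= 1.0):
        raise ValueError("depletion_efficiency must be in [0, 1]")
    import tempfile

    if out_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            truth = simulate_library(params, tmp)
    else:
        truth = simulate_library(params, out_dir)
    rng = np.random.default_rng(params.seed + 1)
    pre = truth.truth_matrix
    biotype = truth.features.biotype_of()
    post_counts = pre.counts.tocoo(copy=True)
    data = post_counts.data.copy()
    for k in range(post_counts.nnz):
        gene = pre.genes[post_counts.col[k]]
        if biotype[gene] == "rRNA":
            kept = int(rng.binomial(data[k], 1.0 - depletion_efficiency))
            data[k] = kept
    post_counts.data = data
    post_counts.eliminate_zeros()
    post = CountMatrix(
        cells=list(pre.cells),
        genes=list(pre.genes),
        counts=sp.csr_matrix(post_counts),
    )
    # recompute biotype totals for the depleted matrix
    per_gene = np.asarray(post.counts.sum(axis=0)).ravel()
    totals: dict[str, int] = defaultdict(int)
    for g, n in zip(post.genes, per_gene):
        totals[biotype[g]] += int(n)
    post.class_totals = dict(totals)
    return DepletionScenario(
        pre=pre, post=post, features=truth.features, depletion_efficiency=depletion_efficiency
    )


def solve_depletion_efficiency(pre_mrna_fraction: float, target_mrna_fraction: float) -> float:
    """Efficiency e such that depleting rRNA UMIs w.p. e lifts the mRNA ratio
    from ``pre_mrna_fraction`` to ``target_mrna_fraction``.

    From m/(m + r·(1−e)) = t with r = 1−m:  e = 1 − m·(1−t)/(t·(1−m)).
    """
    m, t = pre_mrna_fraction, target_mrna_fraction
    if not (0.0 < m < 1.0 and 0.0 < t <= 1.0):
        raise ValueError("fractions must be in (0, 1]")
    if t < m:
        raise ValueError("target mRNA fraction below the pre-depletion fraction")
    return 1.0 - (m * (1.0 - t)) / (t * (1.0 - m))
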
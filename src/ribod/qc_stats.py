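"""Library-level QC statistics for split-pool single-cell RNA-seq.

Implements the quality metrics used to judge a three-round combinatorially
barcoded bacterial library:

* **Multiplet frequency** — cells land on barcode triplets as a Poisson
  process with rate λ = cells loaded / possible combinations (96³ for three
  96-well rounds); the multiplet frequency is the probability that a
  non-empty barcode holds more than one cell, p(≥2)/p(≥1).
* **Sequencing saturation** — 1 − (deduplicated UMIs / confidently mapped
  reads), with a subsampling curve at 20/40/60/80/100% of the reads.
* **Knee / recovery** — cells ranked by UMI count; those at or above a UMI
  floor (default 15) count as recovered, relative to cells loaded.
* **Top-k medians, transcriptome-wide gene coverage, per-species cell
  filters** (strict inequality bounds), and the **bulk comparison** (Pearson
  correlation of log2 per-gene counts, excluding genes with zero counts in
  either library).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .feature_counting import (
    AssignmentRecord,
    CountMatrix,
    DedupMode,
    FeatureTable,
    dedup_umis,
)

DEFAULT_N_COMBOS = 96**3
DEFAULT_MIN_UMIS = 15
DEFAULT_SUBSAMPLE_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class MultipletModel:
    """Poisson occupancy model of cells over barcode combinations."""

    n_cells: int
    n_combos: int
    lam: float
    p0: float
    p1: float
    p_ge1: float
    p_ge2: float
    multiplet_frequency: float
    degenerate: bool = False

    @property
    def percent(self) -> float:
        return 100.0 * self.multiplet_frequency

    def __str__(self) -> str:
        return (
            f"MultipletModel(n_cells={self.n_cells}, n_combos={self.n_combos}, "
            f"frequency={self.percent:.2f}%)"
        )


def multiplet_frequency(n_cells: int, n_combos: int = DEFAULT_N_COMBOS) -> MultipletModel:
    """Closed-form multiplet frequency of a split-pool library.

    With λ = n_cells/n_combos and Poisson occupancy, p(0)=e^{−λ},
    p(1)=λe^{−λ}; the multiplet frequency is
    (1 − p0 − p1)/(1 − p0) — the chance that an occupied barcode combination
    holds two or more cells.  n_cells = 0 is the degenerate limit, frequency
    0.
    """
    if n_combos < 1:
        raise ValueError("multiplet_frequency: n_combos must be >= 1")
    if n_cells < 0:
        raise ValueError("multiplet_frequency: n_cells must be >= 0")
    lam = n_cells / n_combos
    p0 = math.exp(-lam)
    p1 = lam * math.exp(-lam)
    p_ge1 = 1.0 - p0
    p_ge2 = 1.0 - p0 - p1
    if n_cells == 0:
        freq = 0.0
    else:
        freq = p_ge2 / p_ge1
    return MultipletModel(
        n_cells=n_cells,
        n_combos=n_combos,
        lam=lam,
        p0=p0,
        p1=p1,
        p_ge1=p_ge1,
        p_ge2=max(p_ge2, 0.0),
        multiplet_frequency=freq,
        degenerate=n_cells == 0,
    )


def sequencing_saturation(n_reads: int, n_umis: int) -> float:
    """Saturation = 1 − n_umis/n_reads over confidently mapped reads."""
    if n_reads < 1:
        raise ValueError("sequencing_saturation: undefined for n_reads = 0")
    if n_umis > n_reads:
        raise ValueError(f"sequencing_saturation: n_umis {n_umis} > n_reads {n_reads}")
    return 1.0 - n_umis / n_reads


@dataclass
class SaturationPoint:
    fraction: float
    n_reads: int
    n_umis: int
    saturation: float
    median_umis_topk: dict[int, float] = field(default_factory=dict)
    median_genes_topk: dict[int, float] = field(default_factory=dict)


def _group_records(records: list[AssignmentRecord]) -> dict[tuple[str, str], Counter]:
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for r in records:
        groups[(r.cell_id, r.gene_id)][r.umi] += 1
    return groups


def _per_cell_tables(groups: dict[tuple[str, str], Counter], mode: DedupMode) -> pd.DataFrame:
    per_cell_umis: Counter = Counter()
    per_cell_genes: Counter = Counter()
    for (cell, _gene), umis in groups.items():
        n = dedup_umis(umis, mode)
        if n:
            per_cell_umis[cell] += n
            per_cell_genes[cell] += 1
    return pd.DataFrame(
        {"umis": pd.Series(per_cell_umis, dtype=int), "genes": pd.Series(per_cell_genes, dtype=int)}
    ).fillna(0)


def _topk_median(values: pd.Series, k: int) -> float:
    ranked = values.sort_values(ascending=False, kind="mergesort")
    return float(ranked.iloc[:k].median())


def saturation_curve(
    records: list[AssignmentRecord],
    fractions: tuple[float, ...] = DEFAULT_SUBSAMPLE_FRACTIONS,
    seed: int = 0,
    dedup_mode: DedupMode = "exact",
    ks: tuple[int, ...] = (),
) -> list[SaturationPoint]:
    """Subsampled saturation curve over assigned reads.

    Each fraction draws an independent without-replacement subsample of the
    read-level assignment records (fraction 1.0 is the identity and
    reproduces the full-data saturation exactly), then recomputes UMI
    deduplication, saturation and any requested top-k medians.
    """
    if not records:
        raise ValueError("saturation_curve: no assignment records")
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"saturation_curve: fraction {f} outside (0, 1]")
    n = len(records)
    seeds = np.random.SeedSequence(seed).spawn(len(fractions))
    points: list[SaturationPoint] = []
    for frac, ss in zip(fractions, seeds):
        if frac == 1.0:
            sample = records
        else:
            rng = np.random.default_rng(ss)
            take = rng.choice(n, size=int(round(frac * n)), replace=False)
            sample = [records[i] for i in take]
        groups = _group_records(sample)
        n_umis = sum(dedup_umis(umis, dedup_mode) for umis in groups.values())
        n_reads = len(sample)
        tables = _per_cell_tables(groups, dedup_mode) if ks else None
        points.append(
            SaturationPoint(
                fraction=frac,
                n_reads=n_reads,
                n_umis=n_umis,
                saturation=sequencing_saturation(n_reads, n_umis),
                median_umis_topk={
                    k: _topk_median(tables["umis"], k) for k in ks if k <= len(tables)
                }
                if tables is not None
                else {},
                median_genes_topk={
                    k: _topk_median(tables["genes"], k) for k in ks if k <= len(tables)
                }
                if tables is not None
                else {},
            )
        )
    return points


@dataclass
class KneeSummary:
    ranked_umis: np.ndarray  # descending per-cell UMI counts
    min_umis: int
    cells_loaded: int
    recovered_cells: int
    recovery_rate: float
    median_umis_recovered: float


def knee_stats(
    matrix: CountMatrix, min_umis: int = DEFAULT_MIN_UMIS, cells_loaded: int | None = None
) -> KneeSummary:
    """Rank cells by UMI count and summarise recovery at a UMI floor.

    A cell is recovered when its UMI count is ≥ ``min_umis`` (ties at the
    threshold included).  ``cells_loaded`` is the denominator of the recovery
    rate — the number of cells put into the experiment, not the number
    detected.
    """
    if cells_loaded is not None and cells_loaded <= 0:
        raise ValueError("knee_stats: cells_loaded must be positive")
    totals = matrix.per_cell_total_umis
    ranked = np.sort(totals)[::-1]
    recovered = ranked[ranked >= min_umis]
    n_rec = int(recovered.size)
    if cells_loaded is None:
        cells_loaded = len(matrix.cells)
        if cells_loaded == 0:
            raise ValueError("knee_stats: empty matrix and no cells_loaded")
    return KneeSummary(
        ranked_umis=ranked,
        min_umis=min_umis,
        cells_loaded=cells_loaded,
        recovered_cells=n_rec,
        recovery_rate=n_rec / cells_loaded,
        median_umis_recovered=float(np.median(recovered)) if n_rec else float("nan"),
    )


def topk_medians(matrix: CountMatrix, ks: tuple[int, ...] | list[int]) -> pd.DataFrame:
    """Median UMIs and genes among the top-k cells, k per requested value.

    The UMI median ranks cells by UMI count, the gene median ranks
    independently by gene count (both descending, ties broken by cell_id so
    the result is deterministic).  Median over even k is the mean of the two
    central values.
    """
    n_cells = len(matrix.cells)
    for k in ks:
        if k > n_cells:
            raise ValueError(f"topk_medians: k={k} exceeds number of cells ({n_cells})")
        if k < 1:
            raise ValueError(f"topk_medians: k={k} must be positive")
    umis = pd.Series(matrix.per_cell_total_umis, index=matrix.cells)
    genes = pd.Series(matrix.per_cell_gene_counts, index=matrix.cells)
    rows = []
    for k in ks:
        umi_rank = umis.sort_index().sort_values(ascending=False, kind="mergesort")
        gene_rank = genes.sort_index().sort_values(ascending=False, kind="mergesort")
        rows.append(
            {
                "k": k,
                "median_umis": float(umi_rank.iloc[:k].median()),
                "median_genes": float(gene_rank.iloc[:k].median()),
            }
        )
    return pd.DataFrame(rows)


def gene_coverage(matrix: CountMatrix, features: FeatureTable) -> float:
    """Percent of annotated genes detected with ≥1 UMI across all cells."""
    if len(features) == 0:
        raise ValueError("gene_coverage: empty feature table")
    per_gene = np.asarray(matrix.counts.sum(axis=0)).ravel()
    detected_ids = {g for g, n in zip(matrix.genes, per_gene) if n > 0}
    return 100.0 * len(detected_ids & set(f.gene_id for f in features.features)) / len(features)


@dataclass
class FilterReport:
    total: int
    kept: int
    dropped_low_umi: int
    dropped_high_umi: int
    dropped_low_genes: int


def filter_cells(
    matrix: CountMatrix,
    min_umi: int,
    max_umi: int,
    min_genes: int | None = None,
) -> tuple[CountMatrix, FilterReport]:
    """Keep cells with min_umi < UMIs < max_umi (and genes > min_genes).

    All bounds are strict, matching the "more than … less than" screening
    thresholds used per species (e.g. 100/2000 for biofilm libraries, 200/5000
    for exponential-phase E. coli, 15/1000 with genes > 30 for S. aureus).
    """
    if min_umi >= max_umi:
        raise ValueError(f"filter_cells: min_umi {min_umi} must be < max_umi {max_umi}")
    umis = matrix.per_cell_total_umis
    genes = matrix.per_cell_gene_counts
    low = umis <= min_umi
    high = umis >= max_umi
    bad_genes = np.zeros(len(matrix.cells), dtype=bool)
    if min_genes is not None:
        bad_genes = genes <= min_genes
    keep = ~(low | high | bad_genes)
    report = FilterReport(
        total=len(matrix.cells),
        kept=int(keep.sum()),
        dropped_low_umi=int(low.sum()),
        dropped_high_umi=int((high & ~low).sum()),
        dropped_low_genes=int((bad_genes & ~low & ~high).sum()),
    )
    kept_idx = np.flatnonzero(keep)
    filtered = CountMatrix(
        cells=[matrix.cells[i] for i in kept_idx],
        genes=list(matrix.genes),
        counts=sp.csr_matrix(matrix.counts[kept_idx]),
        class_totals=dict(matrix.class_totals),
        provenance=dict(matrix.provenance),
    )
    return filtered, report


def compare_with_bulk(matrix: CountMatrix, bulk: pd.Series | pd.DataFrame) -> tuple[float, int]:
    """Pearson r between log2 pseudobulk UMIs and log2 bulk reads per gene.

    The single-cell matrix is summed over cells to a per-gene pseudobulk
    vector; genes with zero counts in either library are excluded before
    taking log2.  Returns (r, number of genes used).
    """
    if isinstance(bulk, pd.DataFrame):
        if "gene_id" in bulk.columns:
            bulk = bulk.set_index("gene_id").iloc[:, 0]
        else:
            bulk = bulk.iloc[:, 0]
    pseudobulk = pd.Series(
        np.asarray(matrix.counts.sum(axis=0)).ravel(), index=matrix.genes, dtype=float
    )
    joined = pd.concat([pseudobulk.rename("sc"), bulk.rename("bulk").astype(float)], axis=1).dropna()
    joined = joined[(joined["sc"] > 0) & (joined["bulk"] > 0)]
    if len(joined) < 3:
        raise ValueError(
            f"compare_with_bulk: only {len(joined)} genes with nonzero counts in both "
            "libraries; correlation unstable"
        )
    r, _ = scipy.stats.pearsonr(np.log2(joined["sc"]), np.log2(joined["bulk"]))
    return float(r), int(len(joined))
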
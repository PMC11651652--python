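"""Strand-aware read→gene assignment and UMI deduplication.

Turns tagged alignments plus a GFF3 annotation into a sparse cell×gene UMI
count matrix.  Assignment follows featureCounts-style defaults: only primary
alignments at or above a mapping-quality threshold are considered, a read is
assigned iff its aligned interval overlaps exactly one feature (on the same
strand by default — bacterial libraries here are stranded), and reads that
overlap two or more features are discarded as ambiguous.  UMIs are collapsed
per (cell, gene): either exact distinct strings or the directional rule that
merges a UMI into a Hamming-1 neighbour with at least twice its read count.

Coordinate conventions: GFF3 is 1-based inclusive on disk and stored 0-based
half-open internally; SAM reference coordinates from pysam are already
0-based half-open.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Literal

import gffutils
import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

from .utils import hamming

Biotype = Literal["rRNA", "tRNA", "mRNA", "other"]
DedupMode = Literal["exact", "directional1"]

DEFAULT_MIN_MAPQ = 10

#: GFF3 feature type → biotype; 'gene' rows defer to their gene_biotype
#: attribute when present.
DEFAULT_BIOTYPE_RULES: dict[str, str] = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "CDS": "mRNA",
    "gene": "mRNA",
    "mRNA": "mRNA",
    "ncRNA": "other",
    "tmRNA": "other",
    "misc_RNA": "other",
}

UNASSIGNED_REASONS = ("unmapped", "low_mapq", "secondary", "no_feature", "ambiguous")


@dataclass(frozen=True)
class Feature:
    gene_id: str
    contig: str
    strand: str
    start: int  # 0-based half-open
    end: int
    biotype: str


@dataclass
class FeatureTable:
    features: list[Feature]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.start >= f.end:
                raise ValueError(f"FeatureTable: {f.gene_id}: start {f.start} >= end {f.end}")
            if f.gene_id in seen:
                raise ValueError(f"FeatureTable: duplicate gene_id {f.gene_id}")
            seen.add(f.gene_id)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def gene_ids(self) -> list[str]:
        return [f.gene_id for f in self.features]

    def biotype_of(self) -> dict[str, str]:
        return {f.gene_id: f.biotype for f in self.features}

    def build_index(self) -> dict[tuple[str, str], IntervalTree]:
        """Interval trees keyed by (contig, strand) for overlap queries."""
        index: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for f in self.features:
            index[(f.contig, f.strand)][f.start : f.end] = f.gene_id
        return dict(index)


@dataclass(frozen=True)
class AssignmentRecord:
    cell_id: str
    umi: str
    gene_id: str
    contig: str
    position: int
    strand: str
    mapq: int


@dataclass
class CountMatrix:
    """Sparse cell×gene UMI counts with biotype totals and provenance."""

    cells: list[str]
    genes: list[str]
    counts: sp.csr_matrix
    class_totals: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("CountMatrix: shape mismatch with cell/gene lists")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("CountMatrix: negative counts")

    @property
    def per_cell_total_umis(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(int)

    @property
    def per_cell_gene_counts(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel().astype(int)

    @property
    def total_umis(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.toarray(), index=self.cells, columns=self.genes)


def _attr_first(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def parse_gff(path: str | Path, biotype_rules: dict[str, str] | None = None) -> FeatureTable:
    """Parse gene features from GFF3 into a FeatureTable.

    Keeps rows whose feature type appears in ``biotype_rules``; a ``gene``
    row's ``gene_biotype``/``biotype`` attribute overrides the type-based
    class.  CDS rows whose Parent is an already-seen gene are skipped so a
    gene is not counted twice.  Coordinates convert from GFF3 1-based
    inclusive to 0-based half-open.
    """
    rules = DEFAULT_BIOTYPE_RULES if biotype_rules is None else biotype_rules
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features: list[Feature] = []
    seen_ids: set[str] = set()
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in rules:
            continue
        gene_id = _attr_first(feat, "ID", "gene_id", "locus_tag", "Name")
        if gene_id is None:
            gene_id = f"{feat.featuretype}_{feat.seqid}_{feat.start}"
        parent = _attr_first(feat, "Parent")
        if parent is not None and parent in seen_ids:
            continue  # child row of a gene already recorded
        if gene_id in seen_ids:
            continue
        biotype = rules[feat.featuretype]
        if feat.featuretype == "gene":
            attr_bt = _attr_first(feat, "gene_biotype", "biotype")
            if attr_bt is not None:
                biotype = rules.get(attr_bt, {"protein_coding": "mRNA"}.get(attr_bt, "other"))
        if feat.strand not in "+-":
            warnings.warn(f"parse_gff: {gene_id}: strand {feat.strand!r}, skipped", stacklevel=2)
            continue
        features.append(
            Feature(
                gene_id=gene_id,
                contig=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,  # GFF3 1-based inclusive → 0-based half-open
                end=feat.end,
                biotype=biotype,
            )
        )
        seen_ids.add(gene_id)
    return FeatureTable(features)


def _extract_cb_ub(aln: pysam.AlignedSegment) -> tuple[str, str] | None:
    if aln.has_tag("CB") and aln.has_tag("UB"):
        return str(aln.get_tag("CB")), str(aln.get_tag("UB"))
    # header-encoded fallback: qname like "read1|CB:3.17.42|UB:ACGTACGT"
    cb = ub = None
    for part in aln.query_name.split("|"):
        if part.startswith("CB:"):
            cb = part[3:]
        elif part.startswith("UB:"):
            ub = part[3:]
    if cb is not None and ub is not None:
        return cb, ub
    return None


def assign_read(
    aln: pysam.AlignedSegment,
    index: dict[tuple[str, str], IntervalTree],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    require_same_strand: bool = True,
) -> tuple[str | None, str | None]:
    """Assign one alignment to a gene; returns (gene_id, None) or (None, reason)."""
    if aln.is_unmapped:
        return None, "unmapped"
    if aln.is_secondary or aln.is_supplementary:
        return None, "secondary"
    if aln.mapping_quality < min_mapq:
        return None, "low_mapq"
    strand = "-" if aln.is_reverse else "+"
    start, end = aln.reference_start, aln.reference_end
    hits: set[str] = set()
    if require_same_strand:
        tree = index.get((aln.reference_name, strand))
        if tree is not None:
            hits = {iv.data for iv in tree.overlap(start, end)}
    else:
        for s in "+-":
            tree = index.get((aln.reference_name, s))
            if tree is not None:
                hits |= {iv.data for iv in tree.overlap(start, end)}
    if not hits:
        return None, "no_feature"
    if len(hits) > 1:
        return None, "ambiguous"
    return hits.pop(), None


def dedup_umis(umi_counts: Counter | Iterable[str], mode: DedupMode = "exact") -> int:
    """Count distinct molecules among the UMIs of one (cell, gene) group.

    ``exact`` counts distinct UMI strings.  ``directional1`` additionally
    merges a UMI into any Hamming-distance-1 neighbour whose read count is at
    least twice its own, following reachability from higher-count UMIs, and
    counts the resulting networks.
    """
    counts = umi_counts if isinstance(umi_counts, Counter) else Counter(umi_counts)
    if not counts:
        return 0
    if mode == "exact":
        return len(counts)
    if mode != "directional1":
        raise ValueError(f"dedup_umis: unknown mode {mode!r}")
    umis = sorted(counts, key=lambda u: (-counts[u], u))
    # adjacency under the directional rule: u may absorb v if d(u,v)==1 and
    # count[u] >= 2*count[v]
    absorbable: dict[str, list[str]] = {
        u: [v for v in umis if v != u and counts[u] >= 2 * counts[v] and hamming(u, v) == 1]
        for u in umis
    }
    visited: set[str] = set()
    networks = 0
    for seed in umis:  # descending count: each seed is a true molecule
        if seed in visited:
            continue
        networks += 1
        stack = [seed]
        visited.add(seed)
        while stack:
            u = stack.pop()
            for v in absorbable[u]:
                if v not in visited:
                    visited.add(v)
                    stack.append(v)
    return networks


def build_matrix(
    sam: str | Path,
    features: FeatureTable,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    dedup_mode: DedupMode = "exact",
    require_same_strand: bool = True,
    tags: dict[str, tuple[str, str]] | None = None,
    return_records: bool = False,
):
    """Stream a SAM file into a deduplicated cell×gene CountMatrix.

    Cell/UMI identity comes from, in order of precedence: the ``tags`` join
    table (read name → (cell_id, umi), typically the demux stage's output),
    CB/UB SAM tags, or the header-encoded read name.  Without a join table a
    read lacking CB/UB is a hard error (pipeline ordering bug); with one,
    absent reads were rejected at demux and are skipped as ``untagged``.

    Returns the CountMatrix, or (CountMatrix, records) when
    ``return_records`` — records being the per-read assignments that feed the
    saturation analysis.
    """
    index = features.build_index()
    known_contigs = {f.contig for f in features.features}
    warned_contig = False
    counters: dict[str, int] = {
        "reads_processed": 0,
        "reads_assigned": 0,
        "untagged": 0,
        **{f"unassigned_{r}": 0 for r in UNASSIGNED_REASONS},
    }
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    records: list[AssignmentRecord] = []
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for aln in fh:
            counters["reads_processed"] += 1
            if tags is not None:
                tagged = tags.get(aln.query_name)
                if tagged is None:
                    counters["untagged"] += 1
                    continue
                cell_id, umi = tagged
            else:
                extracted = _extract_cb_ub(aln)
                if extracted is None:
                    raise ValueError(
                        f"build_matrix: read {aln.query_name!r} carries no CB/UB "
                        "(was demultiplexing run first?)"
                    )
                cell_id, umi = extracted
            if (
                not aln.is_unmapped
                and aln.reference_name not in known_contigs
                and not warned_contig
            ):
                warnings.warn(
                    f"build_matrix: contig {aln.reference_name!r} absent from annotation; "
                    "such reads are unassigned (no_feature)",
                    stacklevel=2,
                )
                warned_contig = True
            gene_id, reason = assign_read(aln, index, min_mapq, require_same_strand)
            if gene_id is None:
                counters[f"unassigned_{reason}"] += 1
                continue
            counters["reads_assigned"] += 1
            groups[(cell_id, gene_id)][umi] += 1
            if return_records:
                records.append(
                    AssignmentRecord(
                        cell_id=cell_id,
                        umi=umi,
                        gene_id=gene_id,
                        contig=aln.reference_name,
                        position=aln.reference_start,
                        strand="-" if aln.is_reverse else "+",
                        mapq=aln.mapping_quality,
                    )
                )
    matrix = matrix_from_groups(groups, features, dedup_mode, counters)
    return (matrix, records) if return_records else matrix


def matrix_from_groups(
    groups: dict[tuple[str, str], Counter],
    features: FeatureTable,
    dedup_mode: DedupMode = "exact",
    counters: dict[str, int] | None = None,
) -> CountMatrix:
    """Collapse per-(cell, gene) UMI counters into a CountMatrix."""
    cells = sorted({cell for cell, _ in groups})
    genes = features.gene_ids
    cell_index = {c: i for i, c in enumerate(cells)}
    gene_index = {g: i for i, g in enumerate(genes)}
    rows, cols, data = [], [], []
    for (cell, gene), umis in groups.items():
        n = dedup_umis(umis, dedup_mode)
        if n:
            rows.append(cell_index[cell])
            cols.append(gene_index[gene])
            data.append(n)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(cells), len(genes)), dtype=np.int64
    )
    biotype = features.biotype_of()
    per_gene = np.asarray(counts.sum(axis=0)).ravel()
    class_totals: dict[str, int] = defaultdict(int)
    for g, total in zip(genes, per_gene):
        class_totals[biotype[g]] += int(total)
    provenance = dict(counters or {})
    provenance["dedup_mode"] = dedup_mode  # type: ignore[assignment]
    provenance["reads_deduplicated"] = int(counts.sum())
    return CountMatrix(
        cells=cells,
        genes=genes,
        counts=counts,
        class_totals=dict(class_totals),
        provenance=provenance,
    )


def classify_biotypes(matrix: CountMatrix, features: FeatureTable) -> pd.DataFrame:
    """Per-library UMI fractions by biotype; fractions sum to exactly 1.

    Returns a DataFrame indexed by biotype with integer ``umis`` and exact
    ``fraction``/``percent`` columns (computed over rationals before the final
    float conversion).  The mRNA row's percentage is the library's mRNA
    ratio.
    """
    biotype = features.biotype_of()
    per_gene = np.asarray(matrix.counts.sum(axis=0)).ravel()
    totals: dict[str, int] = {bt: 0 for bt in ("rRNA", "tRNA", "mRNA", "other")}
    for g, n in zip(matrix.genes, per_gene):
        totals[biotype.get(g, "other")] += int(n)
    grand = sum(totals.values())
    fractions = {
        bt: (Fraction(n, grand) if grand else Fraction(0)) for bt, n in totals.items()
    }
    return pd.DataFrame(
        {
            "umis": pd.Series(totals, dtype=int),
            "fraction": pd.Series({bt: float(f) for bt, f in fractions.items()}),
            "percent": pd.Series({bt: float(100 * f) for bt, f in fractions.items()}),
        }
    )


def mrna_ratio_percent(matrix: CountMatrix, features: FeatureTable) -> float:
    """The library's mRNA ratio as a percentage of all UMIs."""
    return float(classify_biotypes(matrix, features).loc["mRNA", "percent"])


def write_matrix(matrix: CountMatrix, out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write the matrix as MatrixMarket plus barcode/feature index TSVs.

    Layout mirrors the common ``matrix.mtx`` / ``barcodes.tsv`` /
    ``features.tsv`` triplet with cells as matrix rows; round-trips losslessly
    through :func:`read_matrix`.
    """
    out_prefix = Path(out_prefix)
    out_prefix.mkdir(parents=True, exist_ok=True)
    mtx = out_prefix / "matrix.mtx"
    barcodes = out_prefix / "barcodes.tsv"
    feats = out_prefix / "features.tsv"
    scipy.io.mmwrite(str(mtx), matrix.counts.tocoo(), field="integer")
    barcodes.write_text("".join(f"{c}\n" for c in matrix.cells))
    feats.write_text("".join(f"{g}\n" for g in matrix.genes))
    return mtx, barcodes, feats


def read_matrix(prefix: str | Path) -> CountMatrix:
    """Read a matrix directory written by :func:`write_matrix`."""
    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix / "matrix.mtx")), dtype=np.int64)
    cells = (prefix / "barcodes.tsv").read_text().splitlines()
    genes = (prefix / "features.tsv").read_text().splitlines()
    return CountMatrix(cells=cells, genes=genes, counts=counts)
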
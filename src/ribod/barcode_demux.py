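"""Three-round split-pool barcode extraction and error correction.

Cells are barcoded in three successive 96-well rounds (an RT round and two
ligation rounds), so a read's cell identity is a triplet of well barcodes
read from the barcode mate together with a UMI.  This module parses a schema
describing the barcode-read layout (segment kinds, offsets, lengths and the
three whitelists), corrects each observed barcode against its round's
whitelist within a Hamming-distance budget, and writes tagged cDNA reads plus
a read→(cell, UMI) table for downstream counting.

Correction rule: the unique whitelist entry at minimal Hamming distance
≤ ``max_hamming`` wins (an exact match trivially so); if two or more entries
tie at that minimal distance the read is rejected as ambiguous rather than
resolved arbitrarily.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Literal

import numpy as np
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .utils import hamming

SegmentKind = Literal["bc1", "bc2", "bc3", "umi", "linker", "ignore"]
RejectReason = Literal[
    "bc1_unmatched",
    "bc2_unmatched",
    "bc3_unmatched",
    "ambiguous_correction",
    "linker_mismatch",
    "read_too_short",
]

REJECTED = -1
_BARCODE_KINDS = ("bc1", "bc2", "bc3")


@dataclass(frozen=True)
class Segment:
    kind: SegmentKind
    offset: int
    length: int
    expected_seq: str | None = None  # linker kind only

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class BarcodeSchema:
    """Whitelists and barcode-read layout for three-round demultiplexing."""

    whitelists: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]
    layout: tuple[Segment, ...]
    max_hamming: int = 1
    separation_warning: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        kinds = [s.kind for s in self.layout]
        for needed in ("bc1", "bc2", "bc3", "umi"):
            if kinds.count(needed) != 1:
                raise ValueError(f"BarcodeSchema: missing segment: {needed}"
                                 if kinds.count(needed) == 0
                                 else f"BarcodeSchema: duplicate segment: {needed}")
        spans = sorted((s.offset, s.end) for s in self.layout)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("BarcodeSchema: overlapping layout segments")
        for round_i, wl in enumerate(self.whitelists, start=1):
            if not wl:
                raise ValueError(f"BarcodeSchema: round {round_i} whitelist is empty")
            lengths = {len(b) for b in wl}
            if len(lengths) != 1:
                raise ValueError(f"BarcodeSchema: round {round_i} whitelist is ragged")
            if len(set(wl)) != len(wl):
                dup = next(b for b in wl if wl.count(b) > 1)
                raise ValueError(
                    f"BarcodeSchema: round {round_i} whitelist has duplicate entry {dup}"
                )
            seg = self.segment(f"bc{round_i}")
            if seg.length != len(wl[0]):
                raise ValueError(
                    f"BarcodeSchema: bc{round_i} segment length {seg.length} != "
                    f"whitelist barcode length {len(wl[0])}"
                )
        # correction is guaranteed unique only when whitelist entries are
        # separated by more than 2*max_hamming
        import warnings

        for round_i, wl in enumerate(self.whitelists, start=1):
            arr = _encode_whitelist(wl)
            n = len(wl)
            min_sep = None
            for i in range(n):
                d = (arr[i + 1 :] != arr[i]).sum(axis=1)
                if d.size:
                    m = int(d.min())
                    min_sep = m if min_sep is None else min(min_sep, m)
            if min_sep is not None and min_sep <= 2 * self.max_hamming:
                self.separation_warning = True
                warnings.warn(
                    f"round {round_i} whitelist minimum pairwise Hamming distance "
                    f"{min_sep} ≤ 2·max_hamming={2 * self.max_hamming}: unique "
                    "correction not guaranteed",
                    stacklevel=2,
                )

    def segment(self, kind: str) -> Segment:
        return next(s for s in self.layout if s.kind == kind)

    @property
    def umi_length(self) -> int:
        return self.segment("umi").length

    @property
    def span(self) -> int:
        return max(s.end for s in self.layout)

    @property
    def n_combos(self) -> int:
        return len(self.whitelists[0]) * len(self.whitelists[1]) * len(self.whitelists[2])


@dataclass
class ReadTag:
    bc1_idx: int = REJECTED
    bc2_idx: int = REJECTED
    bc3_idx: int = REJECTED
    umi: str = ""
    valid: bool = False
    reject_reason: RejectReason | None = None
    corrections: tuple[int, int, int] = (0, 0, 0)  # per-round corrected (0/1)

    @property
    def cell_id(self) -> str:
        """Cell identity composed as ``bc3.bc2.bc1`` with 1-based well indices."""
        if not self.valid:
            raise ValueError("cell_id is defined only for valid tags")
        return f"{self.bc3_idx + 1}.{self.bc2_idx + 1}.{self.bc1_idx + 1}"


def _encode_whitelist(wl: tuple[str, ...]) -> np.ndarray:
    return np.frombuffer("".join(wl).encode(), dtype=np.uint8).reshape(len(wl), len(wl[0]))


def parse_schema(config_path: str | Path) -> BarcodeSchema:
    """Load a YAML demux config: three whitelist files plus the read layout.

    Expected form::

        whitelists: [wl_round1.txt, wl_round2.txt, wl_round3.txt]
        max_hamming: 1
        layout:
          - {kind: bc3, offset: 0, length: 8}
          - {kind: linker, offset: 8, length: 6, expected_seq: ACCGGT}
          ...

    Whitelist paths are resolved relative to the config file.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    wl_paths = cfg.get("whitelists")
    if not wl_paths or len(wl_paths) != 3:
        raise ValueError("parse_schema: config must declare exactly three whitelists")
    whitelists = []
    for p in wl_paths:
        p = Path(p)
        if not p.is_absolute():
            p = config_path.parent / p
        with open(p) as fh:
            entries = tuple(line.strip().upper() for line in fh if line.strip())
        whitelists.append(entries)
    layout = tuple(
        Segment(
            kind=seg["kind"],
            offset=int(seg["offset"]),
            length=int(seg["length"]),
            expected_seq=seg.get("expected_seq"),
        )
        for seg in cfg.get("layout", [])
    )
    return BarcodeSchema(
        whitelists=tuple(whitelists),  # type: ignore[arg-type]
        layout=layout,
        max_hamming=int(cfg.get("max_hamming", 1)),
    )


def write_schema(schema: BarcodeSchema, out_dir: str | Path, name: str = "schema") -> Path:
    """Write whitelists and a YAML config for a schema; returns the config path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wl_names = []
    for i, wl in enumerate(schema.whitelists, start=1):
        wl_name = f"whitelist_round{i}.txt"
        (out_dir / wl_name).write_text("\n".join(wl) + "\n")
        wl_names.append(wl_name)
    cfg = {
        "whitelists": wl_names,
        "max_hamming": schema.max_hamming,
        "layout": [
            {
                "kind": s.kind,
                "offset": s.offset,
                "length": s.length,
                **({"expected_seq": s.expected_seq} if s.expected_seq else {}),
            }
            for s in schema.layout
        ],
    }
    path = out_dir / f"{name}.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


class _Corrector:
    """Vectorised minimal-Hamming-distance whitelist matcher for one round."""

    def __init__(self, whitelist: tuple[str, ...], max_hamming: int) -> None:
        self.whitelist = whitelist
        self.max_hamming = max_hamming
        self.exact = {b: i for i, b in enumerate(whitelist)}
        self._arr = _encode_whitelist(whitelist)

    def correct(self, observed: str) -> tuple[int, str | None]:
        """Return (index, None) on success or (REJECTED, reason-stub).

        reason-stub is ``"unmatched"`` or ``"ambiguous"``; the caller prefixes
        the round name.  Exact matches always win.
        """
        idx = self.exact.get(observed)
        if idx is not None:
            return idx, None
        obs = np.frombuffer(observed.encode(), dtype=np.uint8)
        if obs.shape[0] != self._arr.shape[1]:
            return REJECTED, "unmatched"
        dists = (self._arr != obs).sum(axis=1)
        dmin = int(dists.min())
        if dmin > self.max_hamming:
            return REJECTED, "unmatched"
        hits = np.flatnonzero(dists == dmin)
        if hits.size > 1:
            return REJECTED, "ambiguous"
        return int(hits[0]), None


def correct_barcode(observed: str, whitelist: tuple[str, ...] | list[str], max_hamming: int = 1):
    """Correct one observed barcode against a whitelist.

    Returns the 0-based whitelist index, or the string ``"unmatched"`` /
    ``"ambiguous"`` when no entry is within ``max_hamming`` or when two or
    more entries tie at the minimal admissible distance.
    """
    idx, reason = _Corrector(tuple(whitelist), max_hamming).correct(observed)
    return idx if reason is None else reason


def tag_read_pair(
    barcode_read: tuple[str, str, str],
    cdna_read: tuple[str, str, str],
    schema: BarcodeSchema,
    correctors: tuple[_Corrector, _Corrector, _Corrector] | None = None,
) -> tuple[ReadTag, tuple[str, str, str]]:
    """Tag one read pair; reads are (name, sequence, quality) triples.

    On success the cDNA read's name is annotated ``<orig> CB:<cell_id>
    UB:<umi>``; on failure the cDNA read is returned unchanged and the tag
    carries the first reject reason encountered in layout order.
    """
    if correctors is None:
        correctors = tuple(
            _Corrector(wl, schema.max_hamming) for wl in schema.whitelists
        )  # type: ignore[assignment]
    name, seq, qual = barcode_read
    seq = seq.upper()
    tag = ReadTag()
    if len(seq) < schema.span:
        tag.reject_reason = "read_too_short"
        return tag, cdna_read
    corrections = [0, 0, 0]
    for segment in schema.layout:
        observed = seq[segment.offset : segment.end]
        if segment.kind == "linker":
            if hamming(observed, segment.expected_seq.upper()) > schema.max_hamming:
                tag.reject_reason = "linker_mismatch"
                return tag, cdna_read
        elif segment.kind in _BARCODE_KINDS:
            round_i = int(segment.kind[2])
            idx, stub = correctors[round_i - 1].correct(observed)
            if stub == "ambiguous":
                tag.reject_reason = "ambiguous_correction"
                return tag, cdna_read
            if stub is not None:
                tag.reject_reason = f"{segment.kind}_unmatched"  # type: ignore[assignment]
                return tag, cdna_read
            setattr(tag, f"{segment.kind}_idx", idx)
            if observed != correctors[round_i - 1].whitelist[idx]:
                corrections[round_i - 1] = 1
        elif segment.kind == "umi":
            tag.umi = observed
    tag.valid = True
    tag.corrections = tuple(corrections)  # type: ignore[assignment]
    cname, cseq, cqual = cdna_read
    annotated = (f"{cname} CB:{tag.cell_id} UB:{tag.umi}", cseq, cqual)
    return tag, annotated


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _fastq_pairs(fq1: str | Path, fq2: str | Path) -> Iterator[tuple[tuple, tuple]]:
    with _open_maybe_gzip(fq1) as h1, _open_maybe_gzip(fq2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for r1, r2 in zip(it1, it2, strict=True):
            n1 = r1[0].split()[0].removesuffix("/1")
            n2 = r2[0].split()[0].removesuffix("/2")
            if n1 != n2:
                raise ValueError(f"demux_fastq: desynchronized pair files at {n1!r} vs {n2!r}")
            yield r1, r2


REJECT_REASONS: tuple[RejectReason, ...] = (
    "bc1_unmatched",
    "bc2_unmatched",
    "bc3_unmatched",
    "ambiguous_correction",
    "linker_mismatch",
    "read_too_short",
)


@dataclass
class DemuxStats:
    reads_total: int = 0
    reads_valid: int = 0
    rejects: dict = field(default_factory=lambda: {r: 0 for r in REJECT_REASONS})
    corrections: list = field(default_factory=lambda: [0, 0, 0])

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [("reads_total", self.reads_total), ("reads_valid", self.reads_valid)]
        rows += [(f"reject_{r}", n) for r, n in self.rejects.items()]
        rows += [(f"corrected_bc{i + 1}", n) for i, n in enumerate(self.corrections)]
        return rows


def demux_fastq(
    fq1: str | Path,
    fq2: str | Path,
    schema: BarcodeSchema,
    out_prefix: str | Path,
) -> DemuxStats:
    """Demultiplex a paired FASTQ library (read 1 = barcode read, read 2 = cDNA).

    Writes ``<prefix>.tagged.fastq`` (valid cDNA reads, annotated headers),
    ``<prefix>.tags.tsv`` (read_id, cell_id, umi — the join table used when
    alignments do not carry CB/UB tags) and ``<prefix>.demux_stats.tsv``.
    Conservation holds on every input: reads_total = reads_valid + Σ rejects.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    correctors = tuple(_Corrector(wl, schema.max_hamming) for wl in schema.whitelists)
    stats = DemuxStats()
    tagged_path = Path(f"{out_prefix}.tagged.fastq")
    tags_path = Path(f"{out_prefix}.tags.tsv")
    stats_path = Path(f"{out_prefix}.demux_stats.tsv")
    with open(tagged_path, "w") as out_fq, open(tags_path, "w", newline="") as out_tags:
        tag_writer = csv.writer(out_tags, delimiter="\t", lineterminator="\n")
        tag_writer.writerow(["read_id", "cell_id", "umi"])
        for r1, r2 in _fastq_pairs(fq1, fq2):
            stats.reads_total += 1
            tag, annotated = tag_read_pair(r1, r2, schema, correctors)
            if tag.valid:
                stats.reads_valid += 1
                for i in range(3):
                    stats.corrections[i] += tag.corrections[i]
                name, seq, qual = annotated
                out_fq.write(f"@{name}\n{seq}\n+\n{qual}\n")
                tag_writer.writerow([r2[0].split()[0], tag.cell_id, tag.umi])
            else:
                stats.rejects[tag.reject_reason] += 1
    with open(stats_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metric", "value"])
        writer.writerows(stats.as_rows())
    return stats


def read_tag_table(tags_path: str | Path) -> dict[str, tuple[str, str]]:
    """Load a ``.tags.tsv`` file as {read_id: (cell_id, umi)}."""
    table: dict[str, tuple[str, str]] = {}
    with open(tags_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            table[row["read_id"]] = (row["cell_id"], row["umi"])
    return table
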
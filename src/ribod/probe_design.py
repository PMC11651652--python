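"""Design of rRNA-depletion probe panels.

The depletion strategy removes rRNA-derived cDNA (r-cDNA) from a barcoded
single-cell library by hybridisation: each probe carries a 3' capture portion
that is reverse-complementary to the r-cDNA, plus a 5' universal adapter that
a biotinylated primer anneals to so probe/r-cDNA duplexes can be pulled out on
streptavidin beads.  Because r-cDNA is itself the reverse complement of the
rRNA, the capture portion of a probe is simply a sense-strand segment of the
rRNA reference.  Panels tile every reference end to end so no part of the
rRNA escapes depletion, and a k-mer screen flags probes that share sequence
with the non-rRNA transcriptome (potential off-target capture of mRNA-derived
cDNA).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .utils import check_nucleotides, revcomp

DEFAULT_PROBE_LEN = 50
DEFAULT_STEP = 35
DEFAULT_ADAPTER = "CAAGCAGAAGACGGCATACGAGAT"  # placeholder universal adapter
DEFAULT_SCREEN_K = 15


@dataclass(frozen=True)
class RrnaReference:
    """An ordered set of rRNA reference sequences (uppercase, U→T)."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("RrnaReference: at least one record required")
        seen: set[str] = set()
        for rid, seq in self.records:
            if rid in seen:
                raise ValueError(f"RrnaReference: duplicate record ID {rid!r}")
            seen.add(rid)
            if not seq:
                raise ValueError(f"RrnaReference: record {rid!r} has empty sequence")
            check_nucleotides(seq, name=f"record {rid!r}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, source_id: str) -> str:
        for rid, seq in self.records:
            if rid == source_id:
                return seq
        raise KeyError(source_id)


@dataclass
class Probe:
    probe_id: str
    source_id: str
    start: int  # 0-based inclusive, on the rRNA sense strand
    end: int  # exclusive
    capture_seq: str
    adapter_seq: str
    tm_capture: float
    flagged_offtarget: bool = False

    @property
    def full_seq(self) -> str:
        """Adapter 5' of the capture portion."""
        return self.adapter_seq + self.capture_seq


@dataclass
class ProbePanel:
    probes: list[Probe]
    probe_len: int
    step: int
    per_source_coverage: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def n_flagged(self) -> int:
        return sum(p.flagged_offtarget for p in self.probes)


def _normalize(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def load_rrna_fasta(path: str | Path) -> RrnaReference:
    """Load rRNA reference sequences from FASTA.

    Sequences are upper-cased and U is normalised to T; any other non-ACGT
    character is a hard error naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, _normalize(str(rec.seq))))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return RrnaReference(tuple(records))


def compute_tm(seq: str) -> float:
    """Melting temperature annotation for a probe capture sequence.

    Wallace rule 2·(A+T) + 4·(G+C) for length ≤ 13; GC/length formula
    64.9 + 41·(GC − 16.4)/len otherwise.  Annotation only — never used to
    filter probes.
    """
    if not seq:
        raise ValueError("compute_tm: empty sequence")
    check_nucleotides(seq)
    gc = seq.count("G") + seq.count("C")
    at = len(seq) - gc
    if len(seq) <= 13:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def design_probes(
    ref: RrnaReference,
    probe_len: int = DEFAULT_PROBE_LEN,
    step: int = DEFAULT_STEP,
    adapter_seq: str = DEFAULT_ADAPTER,
) -> ProbePanel:
    """Tile each rRNA reference with capture probes at a fixed step.

    Windows start at 0, step, 2·step, …; if the final window would overrun
    the source it is right-anchored at ``end == len(source)`` so the 3' tail
    is always covered.  Every base of every source is covered by ≥1 probe
    whenever ``step ≤ probe_len``.
    """
    if step <= 0 or probe_len <= 0:
        raise ValueError("design_probes: probe_len and step must be positive")
    if step > probe_len:
        raise ValueError("design_probes: step must not exceed probe_len (coverage gap)")
    if not adapter_seq:
        raise ValueError("design_probes: adapter_seq must be non-empty")
    adapter_seq = _normalize(adapter_seq)
    check_nucleotides(adapter_seq, name="adapter")

    probes: list[Probe] = []
    coverage: dict[str, float] = {}
    for source_id, seq in ref.records:
        n = len(seq)
        if probe_len > n:
            raise ValueError(
                f"design_probes: probe_len {probe_len} exceeds length of source "
                f"{source_id!r} ({n} nt)"
            )
        starts = list(range(0, n - probe_len, step))
        starts.append(n - probe_len)  # right-anchored final probe
        covered = 0
        prev_end = 0
        for i, start in enumerate(starts):
            end = start + probe_len
            capture = seq[start:end]
            probes.append(
                Probe(
                    probe_id=f"{source_id}_p{i + 1}",
                    source_id=source_id,
                    start=start,
                    end=end,
                    capture_seq=capture,
                    adapter_seq=adapter_seq,
                    tm_capture=compute_tm(capture),
                )
            )
            covered += end - max(start, prev_end)
            prev_end = end
        coverage[source_id] = covered / n
    return ProbePanel(probes=probes, probe_len=probe_len, step=step, per_source_coverage=coverage)


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def screen_probes(
    panel: ProbePanel,
    transcriptome: Sequence[tuple[str, str]] | RrnaReference,
    k: int = DEFAULT_SCREEN_K,
    strand_both: bool = True,
) -> ProbePanel:
    """Flag probes sharing a length-k exact substring with any transcript.

    Flagging is in place and never removes a probe: deletion would break the
    full-coverage contract of the panel, so off-target candidates are only
    marked for manual review.  Returns the panel for chaining.
    """
    if k > panel.probe_len:
        raise ValueError(f"screen_probes: k={k} exceeds probe length {panel.probe_len}")
    records = transcriptome.records if isinstance(transcriptome, RrnaReference) else transcriptome
    if not records:
        import warnings

        warnings.warn("screen_probes: empty transcriptome, nothing screened", stacklevel=2)
        return panel
    transcript_kmers: set[str] = set()
    for _, seq in records:
        seq = _normalize(seq)
        transcript_kmers.update(_kmers(seq, k))
        if strand_both:
            transcript_kmers.update(_kmers(revcomp(seq), k))
    for probe in panel.probes:
        probe.flagged_offtarget = any(
            km in transcript_kmers for km in _kmers(probe.capture_seq, k)
        )
    return panel


_TABLE_COLUMNS = [
    "probe_id",
    "source_id",
    "start",
    "end",
    "capture_seq",
    "adapter_seq",
    "full_seq",
    "tm_capture",
    "flagged_offtarget",
]


def write_probe_table(panel: ProbePanel, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the panel as a TSV plus a companion FASTA of full probe sequences.

    Returns (tsv_path, fasta_path).  The TSV round-trips losslessly through
    :func:`read_probe_table`.
    """
    if not panel.probes:
        raise ValueError("write_probe_table: empty panel")
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".probes.tsv")
    fasta_path = out_prefix.with_suffix(".probes.fasta")
    tsv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for p in panel.probes:
            writer.writerow(
                [
                    p.probe_id,
                    p.source_id,
                    p.start,
                    p.end,
                    p.capture_seq,
                    p.adapter_seq,
                    p.full_seq,
                    repr(p.tm_capture),
                    "true" if p.flagged_offtarget else "false",
                ]
            )
    with open(fasta_path, "w") as fh:
        for p in panel.probes:
            fh.write(f">{p.probe_id}\n{p.full_seq}\n")
    return tsv_path, fasta_path


def read_probe_table(tsv_path: str | Path, probe_len: int | None = None, step: int | None = None) -> ProbePanel:
    """Read back a probe table written by :func:`write_probe_table`."""
    probes: list[Probe] = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            p = Probe(
                probe_id=row["probe_id"],
                source_id=row["source_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                capture_seq=row["capture_seq"],
                adapter_seq=row["adapter_seq"],
                tm_capture=float(row["tm_capture"]),
                flagged_offtarget=row["flagged_offtarget"] == "true",
            )
            if p.full_seq != row["full_seq"]:
                raise ValueError(f"read_probe_table: inconsistent full_seq for {p.probe_id}")
            probes.append(p)
    if not probes:
        raise ValueError(f"{tsv_path}: no probes")
    lens = {p.end - p.start for p in probes}
    return ProbePanel(
        probes=probes,
        probe_len=probe_len if probe_len is not None else max(lens),
        step=step if step is not None else 0,
    )
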
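"""Small shared sequence helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: length mismatch ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def check_nucleotides(seq: str, name: str = "sequence") -> None:
    """Raise ValueError naming the first non-ACGT character."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"{name}: non-nucleotide character(s) {sorted(bad)} (alphabet is A/C/G/T)"
        )
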
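"""Small shared sequence helpers."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    Raises ``ValueError`` on unequal lengths.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def mismatches_with_n(site: str, primer: str) -> int:
    """Mismatch count of a read site against a primer; any N counts as a mismatch."""
    if len(site) != len(primer):
        raise ValueError("site/primer length mismatch")
    return sum(1 for x, y in zip(site, primer) if x != y or x == "N" or y == "N")


def seq_to_array(seq: str) -> np.ndarray:
    """Byte-code view of a DNA string for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")
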
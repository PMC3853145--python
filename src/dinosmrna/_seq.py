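"""Sequence primitives shared across the package.

All matching and arithmetic is done on an uppercase DNA alphabet (ACGT);
RNA (U) is normalized to T at I/O boundaries and converted back when
sequences are emitted as RNA.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def to_dna(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and map T->U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def check_alphabet(seq: str, extra: str = "") -> None:
    allowed = set(DNA + "U" + extra)
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-ACGU character(s) in sequence: {sorted(bad)}")


def encode(seq: str) -> np.ndarray:
    """Byte-encode a DNA string for vectorized comparison."""
    return np.frombuffer(to_dna(seq).encode("ascii"), dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. background sequence with configurable GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(DNA), size=length, p=p))
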
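"""Construction of hairpin precursors with controlled duplex geometry.

A precursor is 5'arm + loop + 3'arm: the guide occupies the 5' arm,
the star (passenger) strand the 3' arm, pairing antiparallel with a
2-nt 3' overhang on each end of the duplex (the Dicer signature).
Guide position i pairs star position (L - overhang - 1 - i); the last
``overhang`` nt of each strand stay unpaired. siRNAs have a perfectly
Watson-Crick-complementary duplex; miRNAs carry the requested number
of internal mismatches, placed so that the substituted base cannot
pair (not even as a G:U wobble) with its partner.
"""

from __future__ import annotations

import numpy as np

from .._seq import revcomp, to_dna, random_seq
from ..discovery import Precursor

# For a guide base (DNA), star bases that can pair neither Watson-Crick
# nor as a wobble.
_NON_PAIRING = {
    "A": "ACG",   # A pairs T only
    "C": "ACT",   # C pairs G only
    "G": "AG",    # G pairs C and T(U)
    "T": "CT",    # T(U) pairs A and G
}


def build_precursor(
    guide: str,
    kind: str,
    loop_len: int,
    duplex_mismatches: int,
    rng: np.random.Generator | int | None = None,
    overhang: int = 2,
    length_range: tuple[int, int] = (84, 90),
    loop_gc: float = 0.2,
) -> Precursor:
    """Assemble a hairpin around ``guide`` and return it with its
    designed structure and arm intervals (mfe left unset)."""
    rng = np.random.default_rng(rng)
    guide = to_dna(guide)
    L = len(guide)
    if not 21 <= L <= 22:
        raise ValueError(f"guide length must be 21-22 nt, got {L}")
    if kind not in ("miRNA", "siRNA"):
        raise ValueError(f"unknown smRNA kind {kind!r}")
    if kind == "siRNA" and duplex_mismatches != 0:
        raise ValueError("siRNA requires a perfect duplex (0 mismatches)")
    if kind == "miRNA" and duplex_mismatches == 0:
        raise ValueError("miRNA requires at least 1 duplex mismatch")
    total = 2 * L + loop_len
    if not length_range[0] <= total <= length_range[1]:
        raise ValueError(
            f"precursor length {total} nt outside {length_range[0]}-{length_range[1]}")

    paired = L - overhang
    star = list(revcomp(guide[:paired]))       # star[j] complements guide[paired-1-j]
    mismatch_star_idx = []
    if duplex_mismatches:
        if duplex_mismatches > paired - 4:
            raise ValueError("too many duplex mismatches for the paired region")
        candidates = np.arange(2, paired - 2)
        mismatch_star_idx = sorted(
            rng.choice(candidates, size=duplex_mismatches, replace=False))
        for j in mismatch_star_idx:
            partner = guide[paired - 1 - j]
            star[j] = rng.choice(list(_NON_PAIRING[partner]))
    # Unpaired 3' overhang of the star strand (precursor 3' terminus).
    star += [rng.choice(list("ACGT")) for _ in range(overhang)]
    star_seq = "".join(star)
    loop = random_seq(rng, loop_len, gc=loop_gc)
    sequence = guide + loop + star_seq

    struct = ["."] * len(sequence)
    star_off = L + loop_len
    for i in range(paired):
        j = paired - 1 - i
        if j in mismatch_star_idx:
            continue
        struct[i] = "("
        struct[star_off + j] = ")"
    return Precursor(
        sequence=sequence,
        structure="".join(struct),
        guide_arm=(0, L),
        star_arm=(star_off, star_off + len(star_seq)),
        loop=(L, star_off),
        duplex_mismatches=duplex_mismatches,
    )
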
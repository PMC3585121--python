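"""Low-level nucleotide sequence helpers shared across modules.

All coordinates in this package are 0-based half-open; conversion to the
1-based inclusive conventions of GFF3 and BLAST tabular output happens only
at I/O boundaries.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

#: integer codes used for vectorised composition scans
_A, _C, _G, _T = 65, 67, 71, 84


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Uppercase byte codes of ``seq`` as a uint8 array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous (ACGT) bases; nan if none."""
    codes = seq_to_codes(seq)
    acgt = np.isin(codes, (_A, _C, _G, _T))
    n = int(acgt.sum())
    if n == 0:
        return float("nan")
    gc = int(np.isin(codes, (_G, _C)).sum())
    return gc / n


def random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. random sequence with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return bases.tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``.

    Substitutions are uniform over the three alternative bases; ambiguity
    codes are left untouched.
    """
    if rate <= 0:
        return seq
    codes = seq_to_codes(seq).copy()
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    hit = (rng.random(codes.size) < rate) & np.isin(codes, acgt)
    idx = np.where(hit)[0]
    for i in idx:
        choices = acgt[acgt != codes[i]]
        codes[i] = rng.choice(choices)
    return codes.tobytes().decode("ascii")


def dinucleotide_count(seq: str, dinuc: str) -> int:
    """Count overlapping occurrences of a dinucleotide, case-insensitive.

    Dinucleotides containing ambiguity codes never match (we require an
    exact ACGT match on both positions).
    """
    if len(seq) < 2:
        return 0
    codes = seq_to_codes(seq)
    a, b = (ord(c) for c in dinuc.upper())
    return int(((codes[:-1] == a) & (codes[1:] == b)).sum())
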
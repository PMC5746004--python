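"""Small sequence helpers shared across modules.

Coordinates throughout the package are 1-based inclusive on the forward
reference unless a function documents otherwise (bedGraph I/O converts to
0-based half-open at the file boundary).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgtNn-", "TGCAtgcaNn-")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (gap and N characters preserved)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def at_fraction(seq: str) -> float:
    """AT fraction over non-gap characters; 0.0 for an all-gap region."""
    s = seq.upper().replace("-", "")
    if not s:
        return 0.0
    return (s.count("A") + s.count("T")) / len(s)


def random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random i.i.d. DNA with the given expected GC fraction."""
    if length <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two 1-based inclusive intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def slice1(seq: str, start: int, end: int) -> str:
    """1-based inclusive slice; raises if the span leaves the sequence."""
    if start < 1 or end > len(seq) or end < start:
        raise ValueError(f"span [{start}, {end}] outside sequence of length {len(seq)}")
    return seq[start - 1 : end]
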
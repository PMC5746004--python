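"""Intergenic expressed segments: housekeeping sRNA and riboswitch-leader
candidates.

Transcribed segments that barely touch annotated genes (at most a small
coordinate slack) and reach at least medium expression become candidates;
a candidate whose 3' end abuts a downstream same-strand gene is labelled a
5'-UTR (riboswitch-leader) candidate.  All span arithmetic is 1-based
inclusive: length = end - start + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .sequtil import overlap_len


@dataclass
class SrnaCandidate:
    strand: str
    start: int
    end: int
    length: int
    mean_fc: float
    context: str  # intergenic | five_prime_utr


def region_length(start: int, end: int) -> int:
    """1-based inclusive span length: end - start + 1."""
    if end < start:
        raise ValueError("end must be >= start")
    return end - start + 1


def find_intergenic_expressed(
    segments,
    annotation: pd.DataFrame,
    min_fc: float = 3.0,
    min_len: int = 50,
    slack: int = 10,
    leader_gap: int = 20,
) -> list[SrnaCandidate]:
    """Transcribed segments with at most ``slack`` bp of gene overlap.

    Candidates need mean_fc >= min_fc and length >= min_len; a candidate
    whose 3' end lies within ``leader_gap`` bp upstream of a same-strand
    gene start is classed five_prime_utr (riboswitch-leader shaped),
    everything else intergenic.
    """
    out = []
    for seg in segments:
        length = region_length(seg.start, seg.end)
        if seg.mean_fc < min_fc or length < min_len:
            continue
        max_ov = 0
        for row in annotation.itertuples():
            max_ov = max(max_ov, overlap_len(seg.start, seg.end, row.start, row.end))
        if max_ov > slack:
            continue
        context = "intergenic"
        for row in annotation.itertuples():
            if row.strand != seg.strand:
                continue
            if seg.strand == "+":
                gap = row.start - seg.end
            else:
                gap = seg.start - row.end
            if 0 <= gap <= leader_gap:
                context = "five_prime_utr"
                break
        out.append(
            SrnaCandidate(
                strand=seg.strand,
                start=seg.start,
                end=seg.end,
                length=length,
                mean_fc=seg.mean_fc,
                context=context,
            )
        )
    return out
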
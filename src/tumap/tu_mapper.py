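"""Assembly of transcriptional units from array segments and coverage.

Each transcribed array segment becomes a TU: member genes are assigned by
>= 50% same-strand overlap, the TSS is the segment's 5' boundary refined to
the matching coverage-interval 5' end when the two agree within one probe
length, and the TTS is the segment's 3' boundary (the array represents
termination better than coverage).  Expression classes follow the
fold-change partition high > 10, medium in [3, 10], low < 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .array_signal import TranscribedSegment
from .coverage_signal import CoverageInterval

PROBE_LEN_DEFAULT = 60


@dataclass
class TranscriptionalUnit:
    tu_id: str
    strand: str
    tss: int
    tts: int
    genes: list = field(default_factory=list)
    fc: float = 1.0
    tu_class: str = "low"
    utr5_len: int | None = None
    utr3_len: int | None = None
    tss_source: str = "array"
    array_tss: int | None = None
    rnaseq_tss: int | None = None
    termination_class: str | None = None
    intergenic: bool = False
    ambiguous_strand: bool = False
    first_gene_start: int | None = None  # strand-aware 5' gene boundary
    last_gene_end: int | None = None  # strand-aware 3' gene boundary

    @property
    def span(self) -> tuple:
        return (min(self.tss, self.tts), max(self.tss, self.tts))

    @property
    def length(self) -> int:
        lo, hi = self.span
        return hi - lo + 1


def classify_expression(fc: float) -> str:
    """high if fc > 10, medium if 3 <= fc <= 10, low if fc < 3."""
    if fc <= 0:
        raise ValueError("fold-change must be positive")
    if fc > 10:
        return "high"
    if fc >= 3:
        return "medium"
    return "low"


def assemble_tus(
    segments: list[TranscribedSegment],
    coverage_intervals: list[CoverageInterval],
    annotation: pd.DataFrame,
    probe_len: int = PROBE_LEN_DEFAULT,
    min_gene_overlap: float = 0.5,
) -> list[TranscriptionalUnit]:
    """Integrate array segments, coverage intervals and gene annotation.

    ``annotation`` needs columns gene_id, strand, start, end.  A segment
    whose region also covers >= 50% of an opposite-strand gene is flagged
    ambiguous and left without gene assignment.
    """
    tus = []
    ann = annotation.reset_index(drop=True)
    for i, seg in enumerate(segments):
        array_5p = seg.start if seg.strand == "+" else seg.end
        array_3p = seg.end if seg.strand == "+" else seg.start
        tss, source, rnaseq_tss = array_5p, "array", None
        best = None
        for iv in coverage_intervals:
            if iv.strand != seg.strand:
                continue
            d = abs(iv.five_prime - array_5p)
            if d <= probe_len and (best is None or d < best[0]):
                best = (d, iv)
        if best is not None:
            rnaseq_tss = best[1].five_prime
            tss, source = rnaseq_tss, "both"
        tu = TranscriptionalUnit(
            tu_id=f"TU{i:04d}",
            strand=seg.strand,
            tss=tss,
            tts=array_3p,
            fc=seg.mean_fc,
            tu_class=classify_expression(seg.mean_fc),
            tss_source=source,
            array_tss=array_5p,
            rnaseq_tss=rnaseq_tss,
        )
        lo, hi = min(seg.start, seg.end), max(seg.start, seg.end)
        own, other = [], []
        for row in ann.itertuples():
            glen = row.end - row.start + 1
            ov = max(0, min(hi, row.end) - max(lo, row.start) + 1)
            if ov >= min_gene_overlap * glen:
                (own if row.strand == seg.strand else other).append(row)
        if own and other:
            tu.ambiguous_strand = True
        elif own:
            own.sort(key=lambda r: r.start, reverse=(seg.strand == "-"))
            tu.genes = [r.gene_id for r in own]
            first, last = own[0], own[-1]
            if seg.strand == "+":
                tu.first_gene_start, tu.last_gene_end = first.start, last.end
                tu.utr5_len = max(0, first.start - tu.tss)
                tu.utr3_len = max(0, tu.tts - last.end)
            else:
                tu.first_gene_start, tu.last_gene_end = first.end, last.start
                tu.utr5_len = max(0, tu.tss - first.end)
                tu.utr3_len = max(0, last.start - tu.tts)
        else:
            tu.intergenic = True
        tus.append(tu)
    return tus


def tss_concordance(tus: list[TranscriptionalUnit]) -> dict:
    """Signed array-vs-RNA-seq TSS discrepancies for TUs with both sources.

    Positive values mean the RNA-seq start lies downstream (in transcription
    sense) of the array start.  Reports the per-TU table, the median, the
    fraction of absolute discrepancies in [25, 50] bp, and 10-bp histogram
    bins up to 100 bp.
    """
    rows = []
    for tu in tus:
        if tu.rnaseq_tss is None or tu.array_tss is None:
            continue
        d = tu.rnaseq_tss - tu.array_tss
        if tu.strand == "-":
            d = -d
        rows.append((tu.tu_id, tu.strand, tu.array_tss, tu.rnaseq_tss, d))
    table = pd.DataFrame(rows, columns=["tu_id", "strand", "array_tss", "rnaseq_tss", "discrepancy"])
    if len(table):
        d = table["discrepancy"].to_numpy()
        edges = np.arange(0, 101, 10)
        hist, _ = np.histogram(np.abs(d), bins=edges)
        summary = {
            "n": int(len(d)),
            "median": float(np.median(d)),
            "frac_25_50": float(((np.abs(d) >= 25) & (np.abs(d) <= 50)).mean()),
            "hist_edges": edges.tolist(),
            "hist_counts": hist.tolist(),
        }
    else:
        summary = {"n": 0, "median": None, "frac_25_50": None, "hist_edges": [], "hist_counts": []}
    return {"table": table, "summary": summary}


def utr_stats(tus: list[TranscriptionalUnit]) -> dict:
    """Per-class mean 5'/3'-UTR lengths plus a high vs medium+low location test.

    Classes without any TU are reported as absent.  The location test is a
    two-sample Mann-Whitney U on 5'-UTR lengths (high against medium+low
    pooled); UTR lengths are skewed so a rank test is used.
    """
    out: dict = {"classes": {}}
    by_class: dict[str, list] = {}
    for tu in tus:
        if tu.utr5_len is None:
            continue
        by_class.setdefault(tu.tu_class, []).append(tu)
    for cls in ("high", "medium", "low"):
        members = by_class.get(cls)
        if not members:
            continue
        out["classes"][cls] = {
            "n": len(members),
            "mean_utr5": float(np.mean([t.utr5_len for t in members])),
            "mean_utr3": float(np.mean([t.utr3_len for t in members])),
        }
    high = [t.utr5_len for t in by_class.get("high", [])]
    rest = [t.utr5_len for t in by_class.get("medium", []) + by_class.get("low", [])]
    if len(high) >= 2 and len(rest) >= 2:
        out["utr5_high_vs_rest_p"] = float(stats.mannwhitneyu(high, rest, alternative="greater").pvalue)
    else:
        out["utr5_high_vs_rest_p"] = None
    return out
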
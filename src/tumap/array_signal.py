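"""Tiling-array probe design, significance calling and segmentation.

Probes are 60-mers tiled every 22 nt on both strands.  A probe is called
transcribed when its mRNA channel discriminates from the gDNA baseline: a
one-sided z-test on the log2 ratio against a null whose location and scale
are robustly estimated (median / MAD) from the genome-wide ratio
distribution, followed by Benjamini-Hochberg correction at a stringent FDR
(default 1e-4).  Maximal runs of significant probes, tolerating short
dropout gaps, become transcribed segments whose boundaries are the first
and last base of the member probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class Probe:
    probe_id: str
    strand: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class TranscribedSegment:
    """A maximal run of significantly transcribed probes on one strand."""

    strand: str
    start: int
    end: int
    mean_fc: float
    n_probes: int


def design_probes(genome_length: int, probe_len: int = 60, step: int = 22) -> list[Probe]:
    """Tile probes from position 1 every ``step`` bp, both strands.

    Only probes fully inside the genome are kept; the minus strand carries an
    identical tiling (coordinates refer to the forward reference).
    """
    if not (1 <= step <= probe_len):
        raise ValueError("require probe_len >= step >= 1")
    if genome_length < probe_len:
        warnings.warn("genome shorter than one probe: empty design", stacklevel=2)
        return []
    starts = range(1, genome_length - probe_len + 2, step)
    probes = []
    for strand in "+-":
        tag = "f" if strand == "+" else "r"
        for i, s in enumerate(starts):
            probes.append(Probe(f"p{tag}{i:06d}", strand, s, s + probe_len - 1))
    return probes


def call_probes(measurements: pd.DataFrame, fdr: float = 1e-4, mask=None) -> pd.DataFrame:
    """Per-probe significance of the mRNA channel against the gDNA baseline.

    ``measurements`` needs columns probe_id, strand, start, end, gdna, mrna
    (both channels strictly positive).  ``mask`` is an optional iterable of
    (start, end) intervals (1-based inclusive); probes overlapping a masked
    interval are excluded from calling (significant = False, p/q = NaN).

    Returns a copy with log2_ratio, p, q, significant (and masked) columns;
    significant requires q <= fdr and a positive log ratio.
    """
    df = measurements.copy()
    bad = df[(df["gdna"] <= 0) | (df["mrna"] <= 0)]
    if len(bad):
        raise ValueError(f"non-positive channel value for probe {bad.iloc[0]['probe_id']}")
    df["log2_ratio"] = np.log2(df["mrna"] / df["gdna"])

    masked = np.zeros(len(df), dtype=bool)
    if mask is not None:
        s = df["start"].to_numpy()
        e = df["end"].to_numpy()
        for m_lo, m_hi in mask:
            masked |= (s <= m_hi) & (e >= m_lo)
    df["masked"] = masked

    x = df.loc[~masked, "log2_ratio"].to_numpy()
    med = np.median(x)
    scale = max(stats.median_abs_deviation(x, scale="normal"), 1e-9)
    z = (df["log2_ratio"] - med) / scale
    p = stats.norm.sf(z)
    df["p"] = np.where(masked, np.nan, p)
    q = np.full(len(df), np.nan)
    if (~masked).any():
        q[~masked] = multipletests(p[~masked], method="fdr_bh")[1]
    df["q"] = q
    df["significant"] = (~masked) & (df["q"] <= fdr) & (df["log2_ratio"] > 0)
    return df


def segment(calls: pd.DataFrame, max_gap_probes: int = 1) -> list[TranscribedSegment]:
    """Merge significant probes into transcribed segments.

    Runs of significant probes may bridge up to ``max_gap_probes``
    consecutive non-significant probes; segment boundaries are the first base
    of the first and the last base of the last significant probe in the run,
    and mean_fc is the mean of 2**log2_ratio over the significant members.
    """
    segments: list[TranscribedSegment] = []
    for strand, grp in calls.groupby("strand"):
        grp = grp.sort_values("start").reset_index(drop=True)
        sig_idx = grp.index[grp["significant"]].to_list()
        if not sig_idx:
            continue
        run = [sig_idx[0]]
        for i in sig_idx[1:]:
            if i - run[-1] - 1 <= max_gap_probes:
                run.append(i)
            else:
                segments.append(_make_segment(grp, run, strand))
                run = [i]
        segments.append(_make_segment(grp, run, strand))
    segments.sort(key=lambda s: (s.strand, s.start))
    return segments


def _make_segment(grp: pd.DataFrame, run: list[int], strand: str) -> TranscribedSegment:
    members = grp.loc[run]
    return TranscribedSegment(
        strand=strand,
        start=int(members["start"].iloc[0]),
        end=int(members["end"].iloc[-1]),
        mean_fc=float(np.exp2(members["log2_ratio"]).mean()),
        n_probes=len(run),
    )
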
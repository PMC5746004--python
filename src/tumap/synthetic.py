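"""Synthetic high-GC bacterial genome with planted transcriptional units.

The generator emulates the signal structure the downstream analysis assumes:
a ~59% GC chromosome whose intergenic regions are more AT-rich than coding
regions, transcriptional units (TUs) stratified into high / medium / low
expression by fold-change (mRNA vs gDNA baseline), sigma-70 style promoters
(TTGACA ... 14-20 bp spacer, mode 17 ... TATAAT) that degrade away from the
consensus as expression drops, longer 5'-UTRs for strong transcripts,
GC-rich stem-loop + polyT rho-independent terminators (bidirectional ones
carry a leading polyA), tail-to-tail convergent TU pairs, two-channel tiling
probe signals, and stranded per-base read coverage with 5' truncation and a
smooth positional bias.

All randomness flows from a single integer seed; seeded runs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequtil import BASES, overlap_len, random_seq, revcomp

CONSENSUS_35 = "TTGACA"
CONSENSUS_10 = "TATAAT"

CLASSES = ("high", "medium", "low")

# Per-position susceptibility of each consensus hexamer to class-dependent
# degradation.  The -10 TATA box conserves T(1), A(2) and T(6) best while the
# central positions degenerate first; the -35 is the overall weaker element,
# with its first three positions the most recurrent.  Both hexamers reduce
# exactly to the consensus when the class degradation rate is zero.
SUSCEPT_10 = (0.5, 0.5, 1.5, 1.5, 1.2, 0.5)
SUSCEPT_35 = (0.8, 0.8, 1.0, 1.6, 1.3, 1.6)

# Peakedness of the 14-20 bp spacer distribution around the 17 bp optimum:
# weight(s) ~ exp(-|s-17|/temperature).  Strong promoters sit tightly at 17;
# weak ones drift across the legal range.
SPACER_TEMPERATURE = {"high": 0.4, "medium": 1.5, "low": 5.0}


class PlacementError(RuntimeError):
    """Raised when the requested TUs cannot be placed on the genome."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic chromosome.

    Defaults are the desk-scale conditions: a 200 kb chromosome at 59% GC
    carrying 20 TUs per expression class, fold-change ranges nested inside
    the class boundaries (high > 10, medium in [3, 10], low < 3), 5'-UTR
    means of 100 bp (high) vs 60 bp (medium/low), a 38 bp mean 3'-UTR, and
    per-class fractions of rho-independent termination matching the observed
    70/83, 81/153 and 73/177.
    """

    genome_length: int = 200_000
    gc_frac: float = 0.59
    n_tus_per_class: dict = field(default_factory=lambda: {"high": 20, "medium": 20, "low": 20})
    fc_ranges: dict = field(default_factory=lambda: {"high": (12.0, 45.0), "medium": (3.5, 9.5), "low": (1.6, 2.8)})
    utr5_mean_by_class: dict = field(default_factory=lambda: {"high": 100.0, "medium": 60.0, "low": 60.0})
    utr5_sd: float = 50.0  # leaders are broadly dispersed (observed up to ~280 bp)
    utr3_mean: float = 38.0
    utr3_sd: float = 8.0
    spacer_range: tuple = (14, 20)
    promoter_degradation_by_class: dict = field(default_factory=lambda: {"high": 0.05, "medium": 0.20, "low": 0.40})
    frac_rho_independent_by_class: dict = field(
        default_factory=lambda: {"high": 70 / 83, "medium": 81 / 153, "low": 73 / 177}
    )
    n_convergent_pairs: int = 4
    n_srna: int = 2  # gene-free, very highly transcribed transcripts (housekeeping sRNA-like)
    srna_len_range: tuple = (100, 400)
    srna_fc_range: tuple = (46.0, 60.0)
    dist10_tss: int = 10
    gene_len_range: tuple = (500, 1500)
    max_genes_per_tu: int = 2
    noise_sd_log2: float = 0.2
    coverage_depth: float = 10.0
    coverage_bias_amplitude: float = 0.5
    coverage_bias_period: float = 300.0
    coverage_poisson: bool = True
    background_cov_mean: float = 0.1
    five_prime_truncation_mean: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if any(self.n_tus_per_class.get(c, 0) < 0 for c in CLASSES):
            raise ValueError("TU counts must be non-negative")
        lo_h, hi_h = self.fc_ranges["high"]
        lo_m, hi_m = self.fc_ranges["medium"]
        lo_l, hi_l = self.fc_ranges["low"]
        if not (lo_h > 10 and 3 <= lo_m and hi_m <= 10 and hi_l < 3):
            raise ValueError("fc_ranges inconsistent with class boundaries (high > 10, medium in [3,10], low < 3)")
        if not (14 <= self.spacer_range[0] <= self.spacer_range[1] <= 20):
            raise ValueError("spacer_range must lie within [14, 20]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


@dataclass
class TruthTU:
    """A planted transcriptional unit (simulation ground truth).

    ``tss``/``tts`` are 1-based genome positions of the first/last transcribed
    base in transcription sense, so tss < tts on the + strand and tss > tts on
    the - strand.  ``genes`` are (start, end) genome intervals (start <= end)
    in transcription order.  ``promoter`` records the genome position of the
    first base (transcription sense) of the -35 and -10 hexamers plus the
    spacer length; ``terminator`` is (stem5_start, loop_len, stem_len,
    polyT_start, has_polyA) in the same convention, or None.
    """

    tu_id: str
    tss: int
    tts: int
    strand: str
    genes: list
    fc: float
    tu_class: str
    promoter: tuple
    terminator: tuple | None = None

    @property
    def span(self) -> tuple:
        """(low, high) genome coordinates of the transcript."""
        return (min(self.tss, self.tts), max(self.tss, self.tts))

    @property
    def length(self) -> int:
        lo, hi = self.span
        return hi - lo + 1


# ---------------------------------------------------------------------------
# cassette construction (local, transcription-sense, 0-based)
# ---------------------------------------------------------------------------

_PAD_UP = 30  # intergenic pad upstream of the -35 (covers the 24 bp feature block)


def _degrade(hexamer: str, rate: float, suscept: Sequence[float], rng: np.random.Generator) -> str:
    out = []
    for base, w in zip(hexamer, suscept):
        p = min(rate * w, 0.9)
        if rng.random() < p:
            base = rng.choice([b for b in BASES if b != base])
        out.append(base)
    return "".join(out)


def _sample_spacer(tu_class: str, cfg: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.spacer_range
    values = np.arange(lo, hi + 1)
    w = np.exp(-np.abs(values - 17) / SPACER_TEMPERATURE[tu_class])
    return int(rng.choice(values, p=w / w.sum()))


def _stem_arm(rng: np.random.Generator, stem_len: int = 8, n_gc: int = 6) -> str:
    """GC-rich stem arm with G/C terminal bases (exactly n_gc G/C bases).

    G/C ends keep the arm from annealing into the flanking polyA/polyT
    tails, so the planted hairpin parses unambiguously.
    """
    n_gc = max(n_gc, 2)
    inner = [rng.choice(["G", "C"]) for _ in range(n_gc - 2)]
    inner += [rng.choice(["A", "T"]) for _ in range(stem_len - n_gc)]
    idx = rng.permutation(len(inner))
    inner = [inner[i] for i in idx]
    return rng.choice(["G", "C"]) + "".join(inner) + rng.choice(["G", "C"])


def _hairpin(rng: np.random.Generator) -> tuple[str, int, int]:
    """Sense-strand hairpin sequence plus (stem_len, loop_len)."""
    stem_len = int(rng.integers(6, 10))
    arm = _stem_arm(rng, stem_len, max(int(math.ceil(stem_len * 0.7)), 4))
    loop_len = int(rng.integers(3, 9))
    loop = random_seq(rng, loop_len, 0.25)
    return arm + loop + revcomp(arm), stem_len, loop_len


class _Cassette:
    """A TU built in local transcription-sense coordinates (0-based)."""

    def __init__(self) -> None:
        self.seq = ""
        self.pos35 = 0
        self.pos10 = 0
        self.spacer_len = 0
        self.tss = 0
        self.tts = 0
        self.genes: list[tuple[int, int]] = []
        self.terminator: tuple | None = None
        self.fc = 1.0
        self.tu_class = "low"


def _build_cassette(
    tu_class: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    coding_gc: float,
    inter_gc: float,
    with_terminator: bool,
    trailing_pad: int = 10,
) -> _Cassette:
    cas = _Cassette()
    cas.tu_class = tu_class
    lo, hi = cfg.fc_ranges[tu_class]
    cas.fc = float(rng.uniform(lo, hi))
    rate = cfg.promoter_degradation_by_class[tu_class]

    parts: list[str] = []
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        parts.append(s)
        start = pos
        pos += len(s)
        return start

    emit(random_seq(rng, _PAD_UP, inter_gc))
    cas.pos35 = emit(_degrade(CONSENSUS_35, rate, SUSCEPT_35, rng))
    cas.spacer_len = _sample_spacer(tu_class, cfg, rng)
    emit(random_seq(rng, cas.spacer_len, inter_gc))
    cas.pos10 = emit(_degrade(CONSENSUS_10, rate, SUSCEPT_10, rng))
    emit(random_seq(rng, cfg.dist10_tss - 1, inter_gc))
    utr5 = max(20, int(round(rng.normal(cfg.utr5_mean_by_class[tu_class], cfg.utr5_sd))))
    cas.tss = emit(random_seq(rng, utr5, coding_gc))
    n_genes = int(rng.integers(1, cfg.max_genes_per_tu + 1))
    for i in range(n_genes):
        if i:
            emit(random_seq(rng, 20, coding_gc))
        glen = int(rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1))
        gstart = emit(random_seq(rng, glen, coding_gc))
        cas.genes.append((gstart, gstart + glen - 1))
    utr3 = max(10, int(round(rng.normal(cfg.utr3_mean, cfg.utr3_sd))))
    if with_terminator:
        emit(random_seq(rng, utr3, coding_gc))
        hp, stem_len, loop_len = _hairpin(rng)
        stem5_start = emit(hp)
        gap = int(rng.integers(0, 4))
        if gap:
            emit(random_seq(rng, gap, 0.9).replace("T", "G"))  # gap free of T so the planted run is the polyT
        poly_t_start = emit("T" * 6)
        cas.tts = pos - 1
        cas.terminator = (stem5_start, loop_len, stem_len, poly_t_start, False)
        emit("C")  # stop the polyT run at its planted length
        emit(random_seq(rng, trailing_pad, inter_gc))
    else:
        emit(random_seq(rng, utr3, coding_gc))
        cas.tts = pos - 1
        emit(random_seq(rng, trailing_pad, inter_gc))
    cas.seq = "".join(parts)
    return cas


def _cassette_to_truth(cas: _Cassette, offset: int, strand: str, tu_id: str) -> TruthTU:
    """Map a cassette placed at 0-based genome ``offset`` to a TruthTU.

    For the minus strand the cassette sequence is inserted reverse-
    complemented, so local position L maps to genome position
    offset + (len - 1 - L); sense-start coordinates become the highest
    genome coordinate of each element.
    """
    n = len(cas.seq)

    def g(local: int) -> int:
        if strand == "+":
            return offset + local + 1
        return offset + (n - 1 - local) + 1

    genes = []
    for s, e in cas.genes:
        gs, ge = g(s), g(e)
        genes.append((min(gs, ge), max(gs, ge)))
    term = None
    if cas.terminator is not None:
        stem5, loop_len, stem_len, polyt, has_a = cas.terminator
        term = (g(stem5), loop_len, stem_len, g(polyt), has_a)
    return TruthTU(
        tu_id=tu_id,
        tss=g(cas.tss),
        tts=g(cas.tts),
        strand=strand,
        genes=genes,
        fc=cas.fc,
        tu_class=cas.tu_class,
        promoter=(g(cas.pos35), g(cas.pos10), cas.spacer_len),
        terminator=term,
    )


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


def _expected_transcribed(cfg: SimConfig) -> float:
    total = 0.0
    mean_gene = (cfg.gene_len_range[0] + cfg.gene_len_range[1]) / 2
    mean_n_genes = (1 + cfg.max_genes_per_tu) / 2
    for cls in CLASSES:
        n = cfg.n_tus_per_class.get(cls, 0)
        total += n * (cfg.utr5_mean_by_class[cls] + mean_n_genes * mean_gene + cfg.utr3_mean + 60)
    return total


def generate_genome(cfg: SimConfig) -> tuple[str, list[TruthTU]]:
    """Generate the chromosome and its planted truth.

    Returns the forward-strand sequence (A/C/G/T string) and the list of
    TruthTU records.  Raises :class:`PlacementError` naming the class of the
    first TU that cannot be placed within ``genome_length``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    specs = [cls for cls in CLASSES for _ in range(cfg.n_tus_per_class.get(cls, 0))]
    specs = [specs[i] for i in rng.permutation(len(specs))]
    if 2 * cfg.n_convergent_pairs > len(specs):
        raise ValueError("not enough TUs for the requested convergent pairs")

    # split overall GC between coding and intergenic space so the genome-wide
    # fraction stays at gc_frac while intergenic runs 8% more AT-rich
    f_inter = min(max(1.0 - _expected_transcribed(cfg) / cfg.genome_length, 0.05), 0.95)
    coding_gc = cfg.gc_frac + 0.08 * f_inter
    inter_gc = coding_gc - 0.08

    n_pair = cfg.n_convergent_pairs
    pair_specs = specs[: 2 * n_pair]
    single_specs = specs[2 * n_pair :]

    blocks: list[tuple[str, object]] = []
    for cls in single_specs:
        has_term = rng.random() < cfg.frac_rho_independent_by_class[cls]
        strand = "+" if rng.random() < 0.5 else "-"
        cas = _build_cassette(cls, cfg, rng, coding_gc, inter_gc, has_term)
        blocks.append(("single", (cas, strand)))
    for i in range(n_pair):
        bidirectional = i < (n_pair + 1) // 2
        cls_a, cls_b = pair_specs[2 * i], pair_specs[2 * i + 1]
        blocks.append(("pair", _build_pair(cls_a, cls_b, bidirectional, cfg, rng, coding_gc, inter_gc)))
    for _ in range(cfg.n_srna):
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append(("srna", (_build_srna_cassette(cfg, rng, coding_gc, inter_gc), strand)))
    blocks = [blocks[i] for i in rng.permutation(len(blocks))]

    chunks: list[str] = []
    truths: list[TruthTU] = []
    pos = 0
    idx = 0
    for kind, payload in blocks:
        gap = int(rng.integers(300, 801))
        chunks.append(random_seq(rng, gap, inter_gc))
        pos += gap
        if kind in ("single", "srna"):
            cas, strand = payload
            seq = cas.seq if strand == "+" else revcomp(cas.seq)
            if pos + len(seq) > cfg.genome_length:
                raise PlacementError(f"cannot place TU of class {cas.tu_class!r} within genome_length")
            tu = _cassette_to_truth(cas, pos, strand, f"tu{idx:04d}")
            if kind == "srna":
                tu.genes = []  # transcribed but gene-free (sRNA-like)
            truths.append(tu)
            idx += 1
            chunks.append(seq)
            pos += len(seq)
        else:
            seq, makers = payload
            if pos + len(seq) > cfg.genome_length:
                raise PlacementError("cannot place convergent TU pair within genome_length")
            for make in makers:
                truths.append(make(pos, f"tu{idx:04d}"))
                idx += 1
            chunks.append(seq)
            pos += len(seq)
    if pos < cfg.genome_length:
        chunks.append(random_seq(rng, cfg.genome_length - pos, inter_gc))
    genome = "".join(chunks)
    truths.sort(key=lambda t: t.span[0])
    return genome, truths


def _build_pair(cls_a, cls_b, bidirectional, cfg, rng, coding_gc, inter_gc):
    """A tail-to-tail convergent TU pair.

    Bidirectional pairs share a polyA-stem-loop-stem-polyT terminator; the
    other pairs overlap their 3'-UTRs by ~40 bp with no termination signal.
    Returns (sequence, [maker, maker]) where each maker maps a genome offset
    to a TruthTU.
    """
    cas_a = _build_cassette(cls_a, cfg, rng, coding_gc, inter_gc, with_terminator=False, trailing_pad=0)
    cas_b = _build_cassette(cls_b, cfg, rng, coding_gc, inter_gc, with_terminator=False, trailing_pad=0)
    # cassettes end exactly at their tts (trailing pad 0)
    seq_a = cas_a.seq[: cas_a.tts + 1]
    seq_b = cas_b.seq[: cas_b.tts + 1]

    if bidirectional:
        arm = _stem_arm(rng, 8, 6)
        loop = random_seq(rng, 4, 0.25)
        shared = "A" * 6 + arm + loop + revcomp(arm) + "T" * 6
        seq = seq_a + shared + "C" + revcomp(seq_b)
        len_shared = len(shared)

        def make_a(offset: int, tu_id: str, _cas=cas_a, _la=len(seq_a), _ls=len_shared) -> TruthTU:
            t = _cassette_to_truth(_cas, offset, "+", tu_id)
            t.tts = offset + _la + _ls  # 1-based end of the shared polyT
            stem5 = offset + _la + 6 + 1
            polyt = offset + _la + _ls - 6 + 1
            t.terminator = (stem5, 4, 8, polyt, True)
            return t

        def make_b(offset: int, tu_id: str, _cas=cas_b, _la=len(seq_a), _ls=len_shared, _n=len(seq)) -> TruthTU:
            off_b = _n - len(_cas.seq[: _cas.tts + 1])
            t = _cassette_to_truth_trimmed(_cas, offset + off_b, "-", tu_id)
            t.tts = offset + _la + 1  # 1-based start of the shared polyA (its sense polyT end)
            stem5 = offset + _la + _ls - 6  # highest coord of the sense 5' arm
            polyt = offset + _la + 6
            t.terminator = (stem5, 4, 8, polyt, True)
            return t

        return seq, [make_a, make_b]

    overlap = int(rng.integers(30, 51))
    mid_len = max(0, int(round(rng.normal(cfg.utr3_mean, cfg.utr3_sd))) * 2 - overlap)
    mid = random_seq(rng, mid_len, coding_gc)
    # trim both transcripts back to their last gene end, then lay out
    # [a-genes][mid][revcomp(b-genes)]; 3' ends reach into mid and overlap
    core_a = cas_a.seq[: cas_a.genes[-1][1] + 1]
    core_b = cas_b.seq[: cas_b.genes[-1][1] + 1]
    utr3_a = (mid_len + overlap) // 2
    utr3_b = mid_len + overlap - utr3_a
    seq = core_a + mid + revcomp(core_b)

    def make_a(offset: int, tu_id: str, _cas=cas_a, _lc=len(core_a), _u=utr3_a) -> TruthTU:
        t = _cassette_to_truth_trimmed(_cas, offset, "+", tu_id, core_len=_lc)
        t.tts = offset + _lc + _u
        return t

    def make_b(offset: int, tu_id: str, _cas=cas_b, _lc=len(core_b), _la=len(core_a), _m=mid_len, _u=utr3_b) -> TruthTU:
        off_b = _la + _m
        t = _cassette_to_truth_trimmed(_cas, offset + off_b, "-", tu_id, core_len=_lc)
        t.tts = offset + _la + _m - _u + 1
        return t

    return seq, [make_a, make_b]


def _build_srna_cassette(cfg: SimConfig, rng: np.random.Generator, coding_gc: float, inter_gc: float) -> _Cassette:
    """A short, very highly transcribed, gene-free transcript with its own
    promoter and rho-independent terminator (RNaseP / tmRNA shaped)."""
    body = int(rng.integers(cfg.srna_len_range[0], cfg.srna_len_range[1] + 1))
    sub = SimConfig(**cfg.__dict__)
    sub.utr5_mean_by_class = {**cfg.utr5_mean_by_class, "high": 25.0}
    sub.utr5_sd = 5.0
    sub.gene_len_range = (body, body)
    sub.max_genes_per_tu = 1
    sub.utr3_mean, sub.utr3_sd = 15.0, 3.0
    sub.promoter_degradation_by_class = {**cfg.promoter_degradation_by_class, "high": 0.0}
    cas = _build_cassette("high", sub, rng, coding_gc, inter_gc, with_terminator=True)
    cas.fc = float(rng.uniform(*cfg.srna_fc_range))
    cas.genes = list(cas.genes)  # body span retained for coordinates; truth drops it
    return cas


def _cassette_to_truth_trimmed(cas: _Cassette, offset: int, strand: str, tu_id: str, core_len: int | None = None) -> TruthTU:
    """Like _cassette_to_truth but for a cassette whose sequence was trimmed
    to ``core_len`` bases (default: up to and including the local tts)."""
    n = core_len if core_len is not None else cas.tts + 1
    trimmed = _Cassette()
    trimmed.__dict__.update(cas.__dict__)
    trimmed.seq = cas.seq[:n]
    trimmed.tts = n - 1
    trimmed.terminator = None
    return _cassette_to_truth(trimmed, offset, strand, tu_id)


# ---------------------------------------------------------------------------
# platform signals
# ---------------------------------------------------------------------------


def simulate_probe_signals(
    sequence: str,
    truth: Iterable[TruthTU],
    probes,
    noise_sd_log2: float = 0.2,
    baseline: float = 1000.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Two-channel probe measurements: gDNA baseline and mRNA channel.

    mRNA/gDNA follows the overlap-weighted fold-change of the TUs covering the
    probe (1 where nothing is transcribed); both channels carry independent
    log2-normal noise of sd ``noise_sd_log2``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    glen = len(sequence)
    rows = [(p.probe_id, p.strand, p.start, p.end) for p in probes]
    df = pd.DataFrame(rows, columns=["probe_id", "strand", "start", "end"])
    bad = df[(df["start"] < 1) | (df["end"] > glen)]
    if len(bad):
        raise ValueError(f"probe {bad.iloc[0]['probe_id']} lies outside the genome")
    ratio = np.ones(len(df))
    plen = (df["end"] - df["start"] + 1).to_numpy()
    for tu in truth:
        lo, hi = tu.span
        sel = df["strand"] == tu.strand
        ov = np.maximum(
            0,
            np.minimum(df["end"].to_numpy(), hi) - np.maximum(df["start"].to_numpy(), lo) + 1,
        )
        frac = np.where(sel.to_numpy(), ov / plen, 0.0)
        ratio += frac * (tu.fc - 1.0)
    gdna = baseline * np.exp2(rng.normal(0.0, noise_sd_log2, len(df)))
    mrna = gdna * ratio * np.exp2(rng.normal(0.0, noise_sd_log2, len(df)))
    df["gdna"] = gdna
    df["mrna"] = mrna
    return df


def simulate_coverage(
    truth: Iterable[TruthTU],
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> dict[str, np.ndarray]:
    """Stranded per-base coverage with 5' truncation and positional bias.

    Expected coverage over a transcript is fc * coverage_depth modulated by a
    smooth sinusoidal field; the first T bases (T geometric, mean
    ``five_prime_truncation_mean``) of each transcript get zero coverage;
    off-transcript background is Poisson with mean ``background_cov_mean``.
    With ``coverage_poisson`` False the expected values are returned directly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else cfg.seed + 1)
    n = cfg.genome_length
    expected = {"+": np.zeros(n), "-": np.zeros(n)}
    pos_all = np.arange(1, n + 1)
    if cfg.coverage_bias_amplitude > 0:
        bias_field = 1.0 + cfg.coverage_bias_amplitude * np.sin(2 * np.pi * pos_all / cfg.coverage_bias_period)
    else:
        bias_field = np.ones(n)
    m = cfg.five_prime_truncation_mean
    for tu in truth:
        lo, hi = tu.span
        trunc = int(rng.geometric(1.0 / (m + 1.0)) - 1) if m > 0 else 0
        base = tu.fc * cfg.coverage_depth * bias_field[lo - 1 : hi]
        seg = base.copy()
        if trunc > 0:
            if tu.strand == "+":
                seg[: min(trunc, len(seg))] = 0.0
            else:
                seg[len(seg) - min(trunc, len(seg)) :] = 0.0
        expected[tu.strand][lo - 1 : hi] += seg
    out = {}
    for strand in "+-":
        exp = expected[strand] + cfg.background_cov_mean
        if cfg.coverage_poisson:
            out[strand] = rng.poisson(exp).astype(float)
        else:
            out[strand] = exp
    return out


def truth_genes_frame(truth: Iterable[TruthTU]) -> pd.DataFrame:
    """Gene annotation table (gene_id, strand, start, end) from the truth."""
    rows = []
    for tu in truth:
        for i, (s, e) in enumerate(tu.genes):
            rows.append((f"{tu.tu_id}_g{i}", tu.strand, s, e))
    return pd.DataFrame(rows, columns=["gene_id", "strand", "start", "end"]).sort_values("start").reset_index(drop=True)


def simulate_gene_counts(
    truth: Iterable[TruthTU],
    cfg: SimConfig,
    read_length: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-gene read counts consistent with the coverage model.

    Expected count = fc * coverage_depth * gene_length / read_length, drawn
    Poisson; untranscribed space contributes only background.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else cfg.seed + 2)
    rows = []
    for tu in truth:
        for i, (s, e) in enumerate(tu.genes):
            glen = e - s + 1
            lam = (tu.fc * cfg.coverage_depth + cfg.background_cov_mean) * glen / read_length
            count = int(rng.poisson(lam)) if cfg.coverage_poisson else int(round(lam))
            rows.append((f"{tu.tu_id}_g{i}", count, glen))
    return pd.DataFrame(rows, columns=["gene_id", "num_reads", "gene_length"])
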
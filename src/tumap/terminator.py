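"""Rho-independent terminator detection and termination-strategy calls.

A rho-independent terminator is a GC-rich stem-loop followed closely by a
polyT run (strand sense); bidirectional terminators additionally carry a
polyA run just upstream of the stem.  Detection enumerates hairpins under an
explicit rule set (stem >= min_stem with at most one internal mismatch and
an exact-paired core of at least min_stem, loop 3-10 nt, stem GC >= 0.5)
so that a brute-force oracle can reproduce it exactly; overlapping calls
are resolved to the highest-scoring one.  Watson-Crick pairing only (the
search runs on the DNA strand); G.T wobble can be enabled but is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class TerminatorCall:
    """All coordinates are 1-based inclusive within the searched window
    (sense orientation); the caller maps them to the genome."""

    strand: str
    stem5: tuple
    loop: tuple
    stem3: tuple
    stem_len: int
    loop_len: int
    stem_gc: float
    polyT: tuple | None  # (start, len)
    polyA: tuple | None
    bidirectional: bool
    score: float

    @property
    def start(self) -> int:
        return self.polyA[0] if self.polyA else self.stem5[0]

    @property
    def end(self) -> int:
        return self.polyT[0] + self.polyT[1] - 1 if self.polyT else self.stem3[1]


# Hairpin validity rule (mirrored by the brute-force oracle in the tests):
# a hairpin (arm1 start i, stem k >= min_stem, loop in loop_range) is valid
# iff its arms pair with at most one mismatch, the mismatch is never at a
# terminal pair, the longest exactly-paired run is >= min_stem, and the 5'
# arm GC fraction is >= min_gc.


def _maximal_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """(start_0based, length) of every maximal run of ``base`` >= min_len."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def find_terminators(
    window: str,
    strand: str = "+",
    min_stem: int = 6,
    min_gc: float = 0.5,
    loop_range: tuple = (3, 10),
    min_polyT: int = 4,
    max_gap: int = 3,
    require_polyt: bool = True,
    wobble: bool = False,
    max_stem: int = 20,
) -> list[TerminatorCall]:
    """Enumerate terminator hairpins in a sense-oriented window.

    With ``require_polyt`` the hairpin must be followed (within ``max_gap``
    nt) by a run of >= ``min_polyT`` T's; a symmetric upstream polyA run
    marks the call bidirectional.  Tails are *maximal* mononucleotide runs:
    a hairpin whose arm extends into a tail (pairing the leading polyA
    against the polyT) does not own that tail, so the GC-core hairpin with
    intact tails is the one called.  With ``require_polyt=False`` bare
    hairpins are also returned (polyT None), which supports the
    stem-loop-only termination class.  Overlapping calls collapse to the
    highest score (ties to the leftmost).
    """
    import numpy as np

    seq = window.upper()
    n = len(seq)
    candidates: list[TerminatorCall] = []
    lo, hi = loop_range
    t_by_start = {start: length for start, length in _maximal_runs(seq, "T", min_polyT)}
    a_by_end = {start + length: (start, length) for start, length in _maximal_runs(seq, "A", min_polyT)}
    x = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.zeros(256, dtype=np.int8)
    code[ord("C")] = 1
    code[ord("G")] = 2
    code[ord("T")] = 3
    x = code[x].astype(np.int16)
    pair_sums = (3,) if not wobble else (3, 5)  # A0 C1 G2 T3: complements sum to 3; G+T wobble sums to 5
    for loop in range(lo, hi + 1):
        for k in range(min_stem, max_stem + 1):
            span = 2 * k + loop
            m = n - span + 1
            if m <= 0:
                continue
            matches = np.empty((m, k), dtype=bool)
            gc_pair = np.empty((m, k), dtype=bool)
            arm_gc = np.zeros(m, dtype=np.int64)
            for p in range(k):
                a = x[p : p + m]
                b = x[span - 1 - p : span - 1 - p + m]
                s = a + b
                ok = s == 3
                for extra in pair_sums[1:]:
                    ok = ok | (s == extra)
                matches[:, p] = ok
                gc_pair[:, p] = (s == 3) & ((a == 1) | (a == 2))
                arm_gc += (a == 1) | (a == 2)
            mism = k - matches.sum(axis=1)
            run = np.zeros(m, dtype=np.int64)
            best_run = np.zeros(m, dtype=np.int64)
            for p in range(k):
                run = np.where(matches[:, p], run + 1, 0)
                best_run = np.maximum(best_run, run)
            valid = (mism <= 1) & (best_run >= min_stem) & (arm_gc >= min_gc * k)
            valid &= ~((mism == 1) & (~matches[:, 0] | ~matches[:, -1]))
            for i in np.nonzero(valid)[0]:
                i = int(i)
                arm3_end = i + span  # 0-based exclusive
                poly_t = None
                for gap in range(max_gap + 1):
                    if (length := t_by_start.get(arm3_end + gap)) is not None:
                        poly_t = (arm3_end + gap + 1, length)
                        break
                poly_a = None
                for gap in range(max_gap + 1):
                    if (run_a := a_by_end.get(i - gap)) is not None:
                        poly_a = (run_a[0] + 1, run_a[1])
                        break
                if require_polyt and poly_t is None:
                    continue
                candidates.append(
                    TerminatorCall(
                        strand=strand,
                        stem5=(i + 1, i + k),
                        loop=(i + k + 1, i + k + loop),
                        stem3=(i + k + loop + 1, arm3_end),
                        stem_len=k,
                        loop_len=loop,
                        stem_gc=float(arm_gc[i]) / k,
                        polyT=poly_t,
                        polyA=poly_a,
                        bidirectional=poly_t is not None and poly_a is not None,
                        score=float(k + 2.0 * gc_pair[i].sum() - 0.5 * loop),
                    )
                )
    candidates.sort(key=lambda c: (-c.score, c.stem5[0], c.loop_len, c.stem_len))
    kept: list[TerminatorCall] = []
    for c in candidates:
        if all(c.end < k.start or c.start > k.end for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


def classify_termination(tu, calls: list[TerminatorCall], all_tus, tts_window: int = 60) -> str:
    """Termination strategy of a TU given terminator calls near its 3' end.

    ``calls`` must carry genome coordinates (sense orientation of the TU).
    rho_independent: a hairpin+polyT call within +-tts_window of the TTS;
    stem_loop_only: a bare hairpin there; convergent_overlap: no signal but
    a tail-to-tail TU's 3'-UTR overlaps this one's; otherwise none.
    The matching window defaults to one probe length (60 bp) because the
    array-derived TTS carries up to one probe of overhang.
    """
    tts = tu.tts

    def near(call: TerminatorCall) -> bool:
        lo = min(call.start, call.end) - tts_window
        hi = max(call.start, call.end) + tts_window
        return lo <= tts <= hi

    if any(c.polyT is not None and near(c) for c in calls):
        return "rho_independent"
    if any(c.polyT is None and near(c) for c in calls):
        return "stem_loop_only"
    my3 = _utr3_interval(tu)
    if my3 is not None:
        for other in all_tus:
            if other is tu or other.strand == tu.strand:
                continue
            o3 = _utr3_interval(other)
            if o3 is None:
                continue
            if min(my3[1], o3[1]) - max(my3[0], o3[0]) >= 0:
                return "convergent_overlap"
    return "none"


def _utr3_interval(tu) -> tuple | None:
    """(low, high) genome interval from the last gene end to the TTS."""
    last_gene_end = getattr(tu, "last_gene_end", None)
    if last_gene_end is None:
        return None
    lo, hi = sorted((last_gene_end, tu.tts))
    return (lo, hi)


def termination_summary(tus) -> dict:
    """Counts of termination classes per expression class and the overall
    rho-independent percentage (rounded to the nearest integer)."""
    per_class: dict[str, dict[str, int]] = {}
    total = 0
    rho = 0
    for tu in tus:
        cls = tu.tu_class
        term = tu.termination_class or "none"
        per_class.setdefault(cls, {})
        per_class[cls][term] = per_class[cls].get(term, 0) + 1
        total += 1
        if term == "rho_independent":
            rho += 1
    out = {"per_class": per_class, "n_tus": total, "n_rho_independent": rho}
    out["rho_independent_pct"] = int(round(100.0 * rho / total)) if total else None
    return out
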
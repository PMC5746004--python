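"""Rho-independent terminator detection and termination classes."""

import numpy as np
import pytest

from tumap.sequtil import random_seq, revcomp
from tumap.terminator import (
    TerminatorCall,
    classify_termination,
    find_terminators,
    termination_summary,
)
from tumap.tu_mapper import TranscriptionalUnit

# ---------------------------------------------------------------------------
# independent brute-force oracle (documented hairpin rule, re-implemented)
# ---------------------------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _oracle_runs(seq, base, min_len):
    runs, i = [], 0
    while i < len(seq):
        if seq[i] == base:
            j = i
            while j < len(seq) and seq[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def oracle_terminators(seq, min_stem=6, min_gc=0.5, loop_range=(3, 10), min_polyT=4,
                       max_gap=3, require_polyt=True, max_stem=20):
    n = len(seq)
    t_runs = {s: l for s, l in _oracle_runs(seq, "T", min_polyT)}
    a_runs = {s + l: (s, l) for s, l in _oracle_runs(seq, "A", min_polyT)}
    found = []
    for i in range(n):
        for loop in range(loop_range[0], loop_range[1] + 1):
            for k in range(min_stem, max_stem + 1):
                j = i + k + loop
                if j + k > n:
                    continue
                mism, run, best, gc_pairs, bad_end = 0, 0, 0, 0, False
                for p in range(k):
                    a, b = seq[i + p], seq[j + k - 1 - p]
                    if (a, b) in _PAIRS:
                        run += 1
                        best = max(best, run)
                        if a in "GC":
                            gc_pairs += 1
                    else:
                        mism += 1
                        run = 0
                        if p in (0, k - 1):
                            bad_end = True
                if mism > 1 or best < min_stem or (mism == 1 and bad_end):
                    continue
                arm = seq[i : i + k]
                if (arm.count("G") + arm.count("C")) / k < min_gc:
                    continue
                poly_t = None
                for gap in range(max_gap + 1):
                    if (l := t_runs.get(i + 2 * k + loop + gap)) is not None:
                        poly_t = (i + 2 * k + loop + gap + 1, l)
                        break
                poly_a = None
                for gap in range(max_gap + 1):
                    if (r := a_runs.get(i - gap)) is not None:
                        poly_a = (r[0] + 1, r[1])
                        break
                if require_polyt and poly_t is None:
                    continue
                score = k + 2.0 * gc_pairs - 0.5 * loop
                start = poly_a[0] if poly_a else i + 1
                end = poly_t[0] + poly_t[1] - 1 if poly_t else i + 2 * k + loop
                found.append((score, i + 1, loop, k, poly_t, poly_a, start, end))
    found.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    kept = []
    for c in found:
        if all(c[7] < k[6] or c[6] > k[7] for k in kept):
            kept.append(c)
    return sorted((i, k, loop, pt, pa, sc) for sc, i, loop, k, pt, pa, s, e in kept)


def test_bidirectional_worked_example():
    seq = "AAAAA" + "GCGCGCGC" + "TTTT" + revcomp("GCGCGCGC") + "TTTTTT"
    calls = find_terminators(seq)
    assert len(calls) == 1
    c = calls[0]
    assert (c.stem_len, c.loop_len) == (8, 4)
    assert c.polyT == (26, 6)
    assert c.polyA == (1, 5)
    assert c.bidirectional


def test_without_leading_polya_still_called_unidirectional():
    seq = "CCCGG" + "GCGCGCGC" + "TTTT" + revcomp("GCGCGCGC") + "TTTTTT"
    c = find_terminators(seq)[0]
    assert c.polyT is not None
    assert c.polyA is None
    assert not c.bidirectional


def test_no_hairpin_no_call(rng):
    # polyT with no preceding GC-rich hairpin
    seq = "ATATATAT" * 10 + "TTTTTT"
    assert find_terminators(seq) == []


@pytest.mark.parametrize("require_polyt", [True, False])
def test_detector_equals_bruteforce_oracle(require_polyt):
    """On 50 random windows the vectorized detector reproduces the exhaustive
    (i, stem, loop) enumeration exactly, including overlap resolution."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        w = random_seq(rng, int(rng.integers(80, 301)), 0.55)
        det = find_terminators(w, require_polyt=require_polyt)
        got = sorted((c.stem5[0], c.stem_len, c.loop_len, c.polyT, c.polyA, c.score) for c in det)
        assert got == oracle_terminators(w, require_polyt=require_polyt)


def _tu(tu_id, strand, tss, tts, tu_class="high", last_gene_end=None):
    return TranscriptionalUnit(tu_id, strand, tss, tts, tu_class=tu_class,
                               last_gene_end=last_gene_end)


def _call(start, end, with_polyt=True, strand="+"):
    return TerminatorCall(strand=strand, stem5=(start, start + 7), loop=(start + 8, start + 11),
                          stem3=(start + 12, start + 19), stem_len=8, loop_len=4, stem_gc=0.8,
                          polyT=(end - 5, 6) if with_polyt else None, polyA=None,
                          bidirectional=False, score=20.0)


def test_classification_rho_independent():
    tu = _tu("a", "+", 100, 1000, last_gene_end=950)
    assert classify_termination(tu, [_call(975, 1005)], [tu]) == "rho_independent"


def test_classification_stem_loop_only():
    tu = _tu("a", "+", 100, 1000, last_gene_end=950)
    assert classify_termination(tu, [_call(975, 1005, with_polyt=False)], [tu]) == "stem_loop_only"


def test_classification_convergent_overlap():
    a = _tu("a", "+", 100, 1000, last_gene_end=900)
    b = _tu("b", "-", 1900, 950, last_gene_end=1050)
    tus = [a, b]
    assert classify_termination(a, [], tus) == "convergent_overlap"
    assert classify_termination(b, [], tus) == "convergent_overlap"


def test_classification_none_when_far():
    tu = _tu("a", "+", 100, 1000, last_gene_end=950)
    assert classify_termination(tu, [_call(700, 730)], [tu]) == "none"


def test_convergent_pair_from_generator_classified(small_genome):
    """The planted tail-to-tail pair without a terminator classifies as
    convergent_overlap on truth coordinates."""
    _, genome, truth = small_genome
    pairs = {}
    for t in truth:
        if t.terminator is None and t.genes:
            pairs.setdefault(t.tu_class + "?", []).append(t)
    # find the overlap pair: opposite strands, overlapping 3' UTR intervals
    cands = [t for t in truth if t.terminator is None and t.genes]
    tus = []
    for t in cands:
        last = t.genes[-1][1] if t.strand == "+" else t.genes[-1][0]
        tus.append(_tu(t.tu_id, t.strand, t.tss, t.tts, t.tu_class, last_gene_end=last))
    got = {classify_termination(tu, [], tus) for tu in tus}
    assert "convergent_overlap" in got


def test_termination_summary_bookkeeping():
    tus = []
    plan = {"high": (83, 70), "medium": (153, 81), "low": (177, 73)}
    i = 0
    for cls, (total, rho) in plan.items():
        for j in range(total):
            tu = _tu(f"t{i}", "+", 1, 100, tu_class=cls)
            tu.termination_class = "rho_independent" if j < rho else "none"
            tus.append(tu)
            i += 1
    out = termination_summary(tus)
    assert out["n_tus"] == 413
    assert out["n_rho_independent"] == 224
    assert out["rho_independent_pct"] == 54
    assert out["per_class"]["high"]["rho_independent"] == 70


def test_termination_summary_edge_cases():
    tus = [_tu("a", "+", 1, 100)]
    tus[0].termination_class = "rho_independent"
    assert termination_summary(tus)["rho_independent_pct"] == 100
    empty = termination_summary([])
    assert empty["n_tus"] == 0 and empty["rho_independent_pct"] is None
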
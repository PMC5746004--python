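"""The generator must plant exactly the structure the analysis assumes."""

import numpy as np
import pytest

from tumap.array_signal import Probe
from tumap.sequtil import gc_fraction, revcomp, slice1
from tumap.synthetic import (
    CLASSES,
    SimConfig,
    TruthTU,
    generate_genome,
    simulate_coverage,
    simulate_probe_signals,
)


def _oriented(genome, tu, start, end):
    """Sense-strand sequence of a [start, end] span recorded sense-first."""
    if tu.strand == "+":
        return slice1(genome, start, end)
    return revcomp(slice1(genome, end, start)) if end < start else revcomp(slice1(genome, start, end))


def test_seeded_runs_are_bit_reproducible(small_genome):
    cfg, genome, truth = small_genome
    genome2, truth2 = generate_genome(cfg)
    assert genome2 == genome
    assert [(t.tss, t.tts, t.fc) for t in truth2] == [(t.tss, t.tts, t.fc) for t in truth]


def test_tu_bookkeeping_matches_config():
    cfg = SimConfig(genome_length=150_000, n_tus_per_class={"high": 5, "medium": 5, "low": 5},
                    n_convergent_pairs=0, n_srna=0, seed=11)
    _, truth = generate_genome(cfg)
    assert len(truth) == 15
    for cls in CLASSES:
        assert sum(t.tu_class == cls for t in truth) == 5


def test_genome_gc_within_two_percent(small_genome):
    cfg, genome, _ = small_genome
    assert abs(gc_fraction(genome) - cfg.gc_frac) <= 0.02


def test_degradation_zero_plants_exact_consensus():
    cfg = SimConfig(genome_length=30_000, n_tus_per_class={"high": 1, "medium": 0, "low": 0},
                    n_convergent_pairs=0, n_srna=0,
                    promoter_degradation_by_class={"high": 0.0, "medium": 0.0, "low": 0.0}, seed=1)
    genome, truth = generate_genome(cfg)
    tu = truth[0]
    p35, p10, spacer = tu.promoter
    if tu.strand == "+":
        assert slice1(genome, p35, p35 + 5) == "TTGACA"
        assert slice1(genome, p10, p10 + 5) == "TATAAT"
    else:
        assert revcomp(slice1(genome, p35 - 5, p35)) == "TTGACA"
        assert revcomp(slice1(genome, p10 - 5, p10)) == "TATAAT"
    assert 14 <= spacer <= 20


def test_truth_invariants(small_genome):
    _, _, truth = small_genome
    for tu in truth:
        if tu.strand == "+":
            assert tu.tss < tu.tts
        else:
            assert tu.tss > tu.tts
        lo, hi = tu.span
        p35, p10, spacer = tu.promoter
        # promoter entirely upstream of the TSS (transcription sense)
        if tu.strand == "+":
            assert p10 + 5 < tu.tss and p35 < p10
        else:
            assert p10 - 5 > tu.tss and p35 > p10
        assert 14 <= spacer <= 20
        for s, e in tu.genes:
            assert lo <= s <= e <= hi


def test_planted_terminators_meet_detector_minima(small_genome):
    _, genome, truth = small_genome
    planted = [t for t in truth if t.terminator is not None]
    assert planted
    for tu in planted:
        stem5, loop_len, stem_len, polyt, has_a = tu.terminator
        assert stem_len >= 6
        assert 3 <= loop_len <= 8
        sign = 1 if tu.strand == "+" else -1
        arm = _oriented(genome, tu, stem5, stem5 + sign * (stem_len - 1))
        assert gc_fraction(arm) >= 0.5
        arm2_end = stem5 + sign * (2 * stem_len + loop_len - 1)
        gap = sign * (polyt - arm2_end) - 1
        assert 0 <= gap <= 3
        run = _oriented(genome, tu, polyt, polyt + sign * 4)
        assert run == "TTTTT"  # at least 5 consecutive T in strand sense


def _toy_truth():
    return [TruthTU("t0", tss=501, tts=1000, strand="+", genes=[(501, 1000)], fc=10.0,
                    tu_class="medium", promoter=(440, 463, 17))]


@pytest.mark.parametrize(
    "start,end,fc,expected",
    [
        (601, 660, 12.0, 12.0),   # fully inside
        (1501, 1560, 12.0, 1.0),  # zero overlap
        (471, 530, 10.0, 5.5),    # half covered: 0.5*10 + 0.5*1
    ],
)
def test_probe_signal_overlap_weighting(start, end, fc, expected):
    truth = _toy_truth()
    truth[0].fc = fc
    probes = [Probe("p0", "+", start, end)]
    df = simulate_probe_signals("A" * 2000, truth, probes, noise_sd_log2=0.0, rng=0)
    assert df["mrna"].iloc[0] / df["gdna"].iloc[0] == pytest.approx(expected)


def test_probe_outside_genome_raises():
    with pytest.raises(ValueError, match="p0"):
        simulate_probe_signals("A" * 100, _toy_truth(), [Probe("p0", "+", 90, 149)])


def test_coverage_noiseless_step_function():
    cfg = SimConfig(genome_length=2000, five_prime_truncation_mean=0.0,
                    coverage_bias_amplitude=0.0, coverage_poisson=False, background_cov_mean=0.0)
    truth = _toy_truth()
    cov = simulate_coverage(truth, cfg, rng=0)["+"]
    assert np.all(cov[:500] == 0)
    assert np.all(cov[500:1000] == truth[0].fc * cfg.coverage_depth)
    assert np.all(cov[1000:] == 0)


def test_coverage_linearity_in_fc():
    cfg = SimConfig(genome_length=2000, five_prime_truncation_mean=0.0,
                    coverage_poisson=False, background_cov_mean=0.0)
    t5, t10 = _toy_truth(), _toy_truth()
    t5[0].fc, t10[0].fc = 5.0, 10.0
    c5 = simulate_coverage(t5, cfg, rng=0)["+"]
    c10 = simulate_coverage(t10, cfg, rng=0)["+"]
    assert np.allclose(c10[500:1000], 2 * c5[500:1000])


def test_truncation_mean_matches_configuration():
    """Mean 5' truncation over many transcripts recovers the configured 20 bp."""
    cfg = SimConfig(genome_length=250_000,
                    n_tus_per_class={"high": 20, "medium": 20, "low": 20},
                    n_convergent_pairs=0, n_srna=0, coverage_poisson=False,
                    background_cov_mean=0.0, seed=2)
    genome, truth = generate_genome(cfg)
    cov = simulate_coverage(truth, cfg, rng=21)
    lags = []
    for tu in truth:
        lo, hi = tu.span
        arr = cov[tu.strand][lo - 1 : hi]
        nz = np.nonzero(arr > 0)[0]
        # arr index i is genome position lo + i; the 5' end is lo (+) or hi (-)
        lags.append(int(nz[0]) if tu.strand == "+" else int(len(arr) - 1 - nz[-1]))
    assert len(lags) >= 50
    assert abs(np.mean(lags) - cfg.five_prime_truncation_mean) <= 5


def test_class_conditional_probe_ratios_inside_fc_ranges(small_genome):
    from tumap.array_signal import design_probes

    cfg, genome, truth = small_genome
    probes = design_probes(len(genome))
    df = simulate_probe_signals(genome, truth, probes, cfg.noise_sd_log2, rng=5)
    ratio = (df["mrna"] / df["gdna"]).to_numpy()
    for cls in CLASSES:
        vals = []
        for tu in truth:
            if tu.tu_class != cls or not tu.genes:
                continue
            lo, hi = tu.span
            inside = (df["strand"] == tu.strand) & (df["start"] >= lo) & (df["end"] <= hi)
            vals.extend(ratio[inside.to_numpy()])
        vals = np.array(vals)
        lo_fc, hi_fc = cfg.fc_ranges[cls]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert lo_fc - 3 * se <= vals.mean() <= hi_fc + 3 * se


def test_placement_failure_names_class():
    cfg = SimConfig(genome_length=4000, n_tus_per_class={"high": 4, "medium": 0, "low": 0},
                    n_convergent_pairs=0, n_srna=0, seed=0)
    with pytest.raises(Exception, match="high|convergent"):
        generate_genome(cfg)


def test_invalid_config_rejected():
    cfg = SimConfig(fc_ranges={"high": (5.0, 45.0), "medium": (3.5, 9.5), "low": (1.6, 2.8)})
    with pytest.raises(ValueError, match="fc_ranges"):
        cfg.validate()
    cfg2 = SimConfig(spacer_range=(12, 20))
    with pytest.raises(ValueError, match="spacer"):
        cfg2.validate()
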
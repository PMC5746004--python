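"""Promoter feature matrix and random-forest importance ranking."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tumap.features_rf import (
    SCALAR_FEATURES,
    build_feature_matrix,
    negative_features,
    sample_negatives,
    scalar_ranking,
    train_rank,
)
from tumap.promoter import PromoterFeatures
from tumap.sequtil import random_seq


def _features(rng, at_10=None, spacer=None, leader=None):
    return PromoterFeatures(
        spacer_len=int(spacer if spacer is not None else rng.integers(14, 21)),
        leader_len=int(leader if leader is not None else rng.integers(20, 200)),
        at_up35=float(rng.random()),
        at_35=float(rng.random()),
        at_spacer=float(rng.random()),
        at_10=float(at_10 if at_10 is not None else rng.random()),
        at_down10=float(rng.random()),
        aligned_bases=random_seq(rng, 62, 0.5),
    )


def _planted_matrix(n_per_class=60, seed=0, spacer_signal=False):
    """Class determined by a threshold on at_10 (optionally reinforced by a
    weaker spacer_len signal); every other feature is noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls, (lo, hi) in (("high", (0.8, 1.0)), ("medium", (0.45, 0.75)), ("low", (0.0, 0.4))):
        for _ in range(n_per_class):
            at10 = rng.uniform(lo, hi)
            spacer = None
            if spacer_signal:
                centre = {"high": 17, "medium": 16, "low": 15}[cls]
                spacer = int(np.clip(round(rng.normal(centre, 1.2)), 14, 20))
            rows.append((_features(rng, at_10=at10, spacer=spacer), cls))
    return build_feature_matrix(rows)


def test_matrix_shape_and_encoding(rng):
    X, y = build_feature_matrix([(_features(rng), "high")])
    assert list(X.columns[:7]) == SCALAR_FEATURES
    assert X.shape[1] == 7 + 62 * 5
    onehot = X.iloc[0, 7:].to_numpy().reshape(62, 5)
    assert np.all(onehot.sum(axis=1) == 1.0)


def test_gap_state_encoded(rng):
    f = _features(rng)
    f.aligned_bases = f.aligned_bases[:10] + "---" + f.aligned_bases[13:]
    X, _ = build_feature_matrix([(f, "low")])
    gaps = X.iloc[0, 7:].to_numpy().reshape(62, 5)[:, 4]
    assert gaps[10:13].sum() == 3


def test_planted_at10_signal_ranked_first():
    X, y = _planted_matrix()
    rep = train_rank(X, y, n_trees=300, seed=0)
    assert rep.features[0][0] == "at_10"


def test_permuted_labels_give_chance_oob():
    """Shuffled labels on 3 balanced classes give ~2/3 out-of-bag error."""
    X, y = _planted_matrix(n_per_class=100, seed=1)
    y_perm = pd.Series(np.random.default_rng(2).permutation(y.to_numpy()), name="label")
    rep = train_rank(X, y_perm, n_trees=300, seed=3)
    assert abs(rep.oob_error_3class - 2 / 3) < 0.08


def test_seeded_determinism():
    X, y = _planted_matrix(n_per_class=30, seed=4)
    r1 = train_rank(X, y, n_trees=100, seed=5)
    r2 = train_rank(X, y, n_trees=100, seed=5)
    assert r1.features == r2.features
    assert r1.oob_error_3class == r2.oob_error_3class


def test_single_class_rejected(rng):
    X, y = build_feature_matrix([(_features(rng), "high") for _ in range(30)])
    with pytest.raises(ValueError):
        train_rank(X, y)


def test_noise_column_permutation_keeps_planted_ranking():
    X, y = _planted_matrix(n_per_class=60, seed=6, spacer_signal=True)
    rep = train_rank(X, y, n_trees=300, seed=7)
    Xp = X.copy()
    Xp["at_up35"] = np.random.default_rng(8).permutation(Xp["at_up35"].to_numpy())
    rep_p = train_rank(Xp, y, n_trees=300, seed=7)
    planted = ["at_10", "spacer_len"]
    rank = [f for f, _ in rep.features if f in planted]
    rank_p = [f for f, _ in rep_p.features if f in planted]
    assert rank == rank_p == planted


def test_sample_negatives_seeded_and_excluding():
    rng = np.random.default_rng(10)
    genome = random_seq(rng, 20_000, 0.55)
    genes = pd.DataFrame({"gene_id": ["g1", "g2"], "strand": ["+", "-"],
                          "start": [2000, 9000], "end": [5000, 12_000]})
    footprints = [(6000, 6100)]
    w1, s1 = sample_negatives(genome, genes, footprints, 100, seed=1)
    w2, s2 = sample_negatives(genome, genes, footprints, 100, seed=1)
    assert w1 == w2 and np.array_equal(s1, s2)
    assert all(len(w) == 62 for w in w1)
    for s in s1:
        e = s + 61
        for lo, hi in [(2000, 5000), (9000, 12_000), (6000, 6100)]:
            assert e < lo or s > hi


def test_sample_negatives_reports_available_count():
    rng = np.random.default_rng(11)
    genome = random_seq(rng, 500, 0.5)
    genes = pd.DataFrame({"gene_id": ["g"], "strand": ["+"], "start": [1], "end": [400]})
    with pytest.raises(ValueError, match="available"):
        sample_negatives(genome, genes, [], 1000, seed=0)


def test_negative_features_layout(rng):
    w = random_seq(rng, 62, 0.5)
    f = negative_features(w, leader_len=80)
    assert f.spacer_len == 17
    assert f.aligned_bases == w
    assert f.at_10 == pytest.approx(sum(c in "AT" for c in w[47:53]) / 6)


@pytest.fixture(scope="module")
def truth_matrix_report():
    """Feature matrix from planted promoters at generator defaults plus
    intergenic negatives, and its importance report."""
    from tumap.promoter import extract_features
    from tumap.synthetic import SimConfig, generate_genome, truth_genes_frame

    cfg = SimConfig(genome_length=300_000,
                    n_tus_per_class={"high": 30, "medium": 30, "low": 30},
                    n_convergent_pairs=0, n_srna=0, seed=0)
    genome, truth = generate_genome(cfg)
    rows = []
    for t in truth:
        p35, p10, _ = t.promoter
        gene_start = t.genes[0][0] if t.strand == "+" else t.genes[0][1]
        rows.append((extract_features(genome, t.strand, p35, p10, t.tss, gene_start), t.tu_class))
    genes = truth_genes_frame(truth)
    foot = [tuple(sorted((t.promoter[0], t.promoter[1]))) for t in truth]
    negs, _ = sample_negatives(genome, genes, foot, 3000, seed=100)
    pool = np.array([f.leader_len for f, _ in rows])
    nrng = np.random.default_rng(200)
    for w, ld in zip(negs, nrng.choice(pool, size=len(negs))):
        rows.append((negative_features(w, int(ld)), "negative"))
    X, y = build_feature_matrix(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_rank(X, y, n_trees=500, seed=0)


def test_generator_defaults_reproduce_feature_ordering(truth_matrix_report):
    """With default class-dependent -10 degradation, the -10 AT fraction
    outranks spacer length, which outranks leader length."""
    order = scalar_ranking(truth_matrix_report)
    assert order.index("at_10") < order.index("spacer_len") < order.index("leader_len")


def test_minus10_conserved_positions_dominate(truth_matrix_report):
    """-10 positions 1, 2 and 6 (columns 48, 49, 53) outweigh the degenerate
    core, and the -35 box leads with its first three positions."""
    imp = dict(truth_matrix_report.positional)
    conserved = (imp[48] + imp[49] + imp[53]) / 3
    core = (imp[50] + imp[51] + imp[52]) / 3
    assert conserved > core
    first35 = (imp[25] + imp[26] + imp[27]) / 3
    last35 = (imp[28] + imp[29] + imp[30]) / 3
    assert first35 > last35
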
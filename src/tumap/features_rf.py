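"""Random-forest ranking of promoter features against expression classes.

Rows are promoter feature vectors (spacer length, leader length, five AT
fractions, and the 62 aligned promoter bases one-hot encoded with an
explicit gap state) labelled high / medium / low, plus promoter-sized
intergenic k-mers as negatives.  A bootstrap forest with random feature
subsets ranks features by mean impurity decrease; the out-of-bag error of
the three-class (high/medium/low) sub-problem measures how predictable the
transcription level is from the promoter alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .promoter import PromoterFeatures, promoter_window_length

SCALAR_FEATURES = ["spacer_len", "leader_len", "at_up35", "at_35", "at_spacer", "at_10", "at_down10"]
BASE_STATES = "ACGT-"
WINDOW = promoter_window_length()  # 62

FEATURE_COLUMNS = SCALAR_FEATURES + [f"pos{i:02d}_{b}" for i in range(1, WINDOW + 1) for b in BASE_STATES]


@dataclass
class ImportanceReport:
    features: list  # (name, importance) sorted descending, ties by column order
    positional: list  # (position 1..62, summed importance) sorted descending
    oob_error_3class: float | None
    oob_error_all: float | None
    confusion_3class: pd.DataFrame | None
    n_trees: int
    seed: int


def sample_negatives(
    sequence: str,
    annotation: pd.DataFrame,
    promoter_footprints,
    n: int,
    seed: int = 0,
    width: int = WINDOW,
) -> tuple[list[str], np.ndarray]:
    """Seeded uniform draw of promoter-sized windows from intergenic space.

    ``promoter_footprints`` is an iterable of (start, end) genome intervals
    to exclude (called promoters).  Returns (windows, start positions);
    raises when fewer than ``n`` disjoint-start windows are available,
    reporting the available count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    glen = len(sequence)
    forbidden = np.zeros(glen, dtype=bool)
    for row in annotation.itertuples():
        forbidden[row.start - 1 : row.end] = True
    for lo, hi in promoter_footprints:
        lo, hi = sorted((lo, hi))
        forbidden[max(lo - 1, 0) : hi] = True
    free = ~forbidden
    ok = np.ones(glen - width + 1, dtype=bool)
    cs = np.concatenate([[0], np.cumsum(free)])
    ok = (cs[width:] - cs[:-width]) == width
    starts = np.nonzero(ok)[0]
    if len(starts) < n:
        raise ValueError(f"only {len(starts)} intergenic windows available, {n} requested")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(starts, size=n, replace=False))
    windows = [sequence[s : s + width] for s in chosen]
    return windows, chosen + 1  # 1-based starts


def negative_features(window: str, leader_len: int) -> PromoterFeatures:
    """Interpret a raw 62-bp window under the canonical 24+6+17+6+9 layout."""
    from .sequtil import at_fraction

    w = window.upper()
    up24, box35, spacer, box10, down9 = w[:24], w[24:30], w[30:47], w[47:53], w[53:62]
    return PromoterFeatures(
        spacer_len=17,
        leader_len=leader_len,
        at_up35=at_fraction(up24),
        at_35=at_fraction(box35),
        at_spacer=at_fraction(spacer),
        at_10=at_fraction(box10),
        at_down10=at_fraction(down9),
        aligned_bases=w,
    )


def build_feature_matrix(rows: list[tuple[PromoterFeatures, str]]) -> tuple[pd.DataFrame, pd.Series]:
    """One-hot encode (features, label) rows into the fixed column order."""
    data = np.zeros((len(rows), len(FEATURE_COLUMNS)))
    labels = []
    state_idx = {b: i for i, b in enumerate(BASE_STATES)}
    n_scalar = len(SCALAR_FEATURES)
    for r, (f, label) in enumerate(rows):
        data[r, :n_scalar] = [getattr(f, name) for name in SCALAR_FEATURES]
        if len(f.aligned_bases) != WINDOW:
            raise ValueError(f"aligned_bases must be {WINDOW} symbols")
        for i, b in enumerate(f.aligned_bases.upper()):
            data[r, n_scalar + i * len(BASE_STATES) + state_idx.get(b, state_idx["-"])] = 1.0
        labels.append(label)
    return pd.DataFrame(data, columns=FEATURE_COLUMNS), pd.Series(labels, name="label")


def train_rank(X: pd.DataFrame, y: pd.Series, n_trees: int = 500, seed: int = 0) -> ImportanceReport:
    """Fit the ensemble and rank features by mean impurity decrease.

    The out-of-bag error is reported both for the full label set and for
    the high/medium/low sub-problem (negatives dropped), matching the
    question of whether transcription level is predictable from the
    promoter.
    """
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("at least two classes are required")
    counts = y.value_counts()
    if (counts < 20).any():
        warnings.warn(f"classes with fewer than 20 rows: {counts[counts < 20].to_dict()}", stacklevel=2)

    def _forest(Xs, ys):
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            bootstrap=True,
            oob_score=True,
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # oob on small inputs
            clf.fit(Xs, ys)
        return clf

    clf_all = _forest(X, y)
    oob_all = 1.0 - float(clf_all.oob_score_)

    sub = y.isin(["high", "medium", "low"])
    oob3 = None
    confusion = None
    if sub.any() and y[sub].nunique() >= 2:
        clf3 = _forest(X[sub], y[sub])
        oob3 = 1.0 - float(clf3.oob_score_)
        dec = clf3.oob_decision_function_
        valid = ~np.isnan(dec).any(axis=1)
        pred = np.array(clf3.classes_)[np.nanargmax(np.where(valid[:, None], dec, -1), axis=1)]
        confusion = pd.crosstab(
            pd.Series(y[sub].to_numpy()[valid], name="true"),
            pd.Series(pred[valid], name="oob_pred"),
        )

    importances = clf_all.feature_importances_
    order = sorted(range(len(FEATURE_COLUMNS)), key=lambda i: (-importances[i], i))
    features = [(FEATURE_COLUMNS[i], float(importances[i])) for i in order]
    n_scalar = len(SCALAR_FEATURES)
    pos_imp = importances[n_scalar:].reshape(WINDOW, len(BASE_STATES)).sum(axis=1)
    positional = sorted(
        [(i + 1, float(v)) for i, v in enumerate(pos_imp)], key=lambda t: (-t[1], t[0])
    )
    return ImportanceReport(
        features=features,
        positional=positional,
        oob_error_3class=oob3,
        oob_error_all=oob_all,
        confusion_3class=confusion,
        n_trees=n_trees,
        seed=seed,
    )


def scalar_ranking(report: ImportanceReport) -> list[str]:
    """Scalar feature names ordered by their importance rank."""
    return [name for name, _ in report.features if name in SCALAR_FEATURES]
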
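"""Two-box sigma-70 promoter model: constrained EM discovery and scanning.

The vegetative bacterial promoter is modelled as two 6-mer boxes (the -35
and -10 elements, canonical TTGACA / TATAAT) separated by a 14-20 bp spacer
with its optimum at 17 bp.  :class:`PromoterMotifModel` learns both
position-weight matrices and the empirical spacer distribution from a
training set of upstream windows by expectation-maximization over all legal
two-box placements; :meth:`~PromoterMotifModel.scan` places the model in a
query window, and :func:`extract_features` derives the 62-bp feature set
(24 bp upstream of the -35 + -35 + 17-column spacer block + -10 + 9 bp
downstream) used by the downstream feature-importance analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .sequtil import at_fraction, revcomp, slice1

BASES = "ACGT"
_BIDX = {b: i for i, b in enumerate(BASES)}

HEX = 6
UP35_LEN = 24
DOWN10_LEN = 9
SPACER_OPT = 17
MIN_SCAN_WINDOW = 45  # minimal legal layout


def promoter_window_length(spacer_len: int = SPACER_OPT) -> int:
    """Length of the promoter feature window: 24 + 6 + spacer + 6 + 9."""
    return UP35_LEN + HEX + spacer_len + HEX + DOWN10_LEN


@dataclass
class PromoterCall:
    """A placed promoter; positions are 1-based starts within the scanned
    window unless mapped to the genome by the caller."""

    tu_id: str | None
    pos35: int
    pos10: int
    spacer_len: int
    dist10_tss: int
    score: float


@dataclass
class PromoterFeatures:
    spacer_len: int
    leader_len: int
    at_up35: float
    at_35: float
    at_spacer: float
    at_10: float
    at_down10: float
    aligned_bases: str  # 62 symbols, '-' gaps pad the spacer block


def _encode(seq: str) -> np.ndarray:
    return np.array([_BIDX.get(b, 0) for b in seq.upper()], dtype=np.int64)


class PromoterMotifModel:
    """Constrained two-box EM promoter model (sklearn-style fit interface).

    Parameters
    ----------
    spacer_range : legal spacer lengths (inclusive), default (14, 20).
    pseudocount : Dirichlet pseudocount per PWM cell and spacer bin.
    spacer_penalty : per-bp log-odds cost from the 17 bp optimum used when
        scanning (the EM itself uses the empirical spacer distribution).
    threshold_percentile : scan-score percentile of the training windows
        below which a placement is rejected.

    Fitted attributes (trailing underscore): ``pwm35_`` / ``pwm10_`` (4 x 6
    log2-odds vs the background), ``freqs35_`` / ``freqs10_`` (probability
    matrices), ``spacer_probs_``, ``background_``, ``consensus35_`` /
    ``consensus10_``, ``spacer_mode_``, ``information_bits_``,
    ``low_information_``, ``threshold_``.
    """

    def __init__(
        self,
        spacer_range: tuple = (14, 20),
        pseudocount: float = 0.5,
        spacer_penalty: float = 0.25,
        threshold_percentile: float = 5.0,
        max_iter: int = 200,
        tol: float = 1e-6,
    ) -> None:
        self.spacer_range = spacer_range
        self.pseudocount = pseudocount
        self.spacer_penalty = spacer_penalty
        self.threshold_percentile = threshold_percentile
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting ----------------------------------------------------------

    def _placements(self, length: int) -> list[tuple[int, int]]:
        """Legal (pos35_0based, spacer) placements in a window of ``length``."""
        lo, hi = self.spacer_range
        out = []
        for s in range(lo, hi + 1):
            for a in range(0, length - (2 * HEX + s) + 1):
                out.append((a, s))
        return out

    def fit(self, windows: list[str]) -> "PromoterMotifModel":
        """Learn PWMs and spacer distribution from upstream windows.

        Windows must be strand-oriented and end at the TSS-proximal edge;
        fewer than 10 windows leaves the model underdetermined and raises.

        Because the E-step selects among every legal placement, EM recovers
        a sharp-looking PWM even from featureless input.  The information
        reported as ``information_bits_`` is therefore the *excess* over a
        null fit: the same EM run on per-window letter shuffles (composition
        preserved, positional structure destroyed).  Featureless input gives
        ~0 excess bits and trips the ``low_information_`` flag (< 2 bits).
        """
        windows = [w.upper() for w in windows]
        if len(windows) < 10:
            raise ValueError("at least 10 training windows are required")
        if any(len(w) < MIN_SCAN_WINDOW for w in windows):
            raise ValueError(f"training windows must be >= {MIN_SCAN_WINDOW} bp")
        enc = [_encode(w) for w in windows]
        counts = np.bincount(np.concatenate(enc), minlength=4).astype(float)
        self.background_ = (counts + 1.0) / (counts + 1.0).sum()

        f35, f10, sp_probs, raw_ic = self._run_em(windows)
        shuffle_rng = np.random.default_rng(0)  # fixed: the null is part of the model definition
        shuffled = ["".join(np.array(list(w))[shuffle_rng.permutation(len(w))]) for w in windows]
        _, _, _, null_ic = self._run_em(shuffled)

        lo, hi = self.spacer_range
        self.freqs35_, self.freqs10_ = f35, f10
        self.spacer_probs_ = sp_probs
        self.pwm35_ = np.log2(f35 / self.background_[:, None])
        self.pwm10_ = np.log2(f10 / self.background_[:, None])
        self.consensus35_ = "".join(BASES[i] for i in f35.argmax(axis=0))
        self.consensus10_ = "".join(BASES[i] for i in f10.argmax(axis=0))
        self.spacer_mode_ = int(lo + sp_probs.argmax())
        self.raw_information_bits_ = raw_ic
        self.null_information_bits_ = null_ic
        self.information_bits_ = max(0.0, raw_ic - null_ic)
        self.low_information_ = self.information_bits_ < 2.0
        if self.low_information_:
            warnings.warn(
                f"promoter model carries only {self.information_bits_:.2f} bits above the shuffled"
                " null; treat calls with caution",
                stacklevel=2,
            )
        best = [self._best_placement(w) for w in windows]
        self.threshold_ = float(np.percentile([b[3] for b in best if b is not None], self.threshold_percentile))
        return self

    def _run_em(self, windows: list[str]):
        """One constrained two-box EM run; returns (f35, f10, spacer_probs, ic)."""
        enc = [_encode(w) for w in windows]
        placements = {n: self._placements(n) for n in set(map(len, windows))}
        # per window: base indices under each placement (n_placements x 12)
        win_bases, win_spacers = [], []
        for e, w in zip(enc, windows):
            plc = placements[len(w)]
            mat = np.empty((len(plc), 2 * HEX), dtype=np.int64)
            sp = np.empty(len(plc), dtype=np.int64)
            for k, (a, s) in enumerate(plc):
                mat[k, :HEX] = e[a : a + HEX]
                mat[k, HEX:] = e[a + HEX + s : a + 2 * HEX + s]
                sp[k] = s
            win_bases.append(mat)
            win_spacers.append(sp)

        lo, hi = self.spacer_range
        n_sp = hi - lo + 1
        # seed the -35/-10 frequencies from the most recurrent hexamer pair
        f35, f10 = self._seed_freqs(win_bases)
        sp_probs = np.full(n_sp, 1.0 / n_sp)
        posteriors = [np.full(len(m), 1.0 / len(m)) for m in win_bases]

        for _ in range(self.max_iter):
            lw35 = np.log(f35)
            lw10 = np.log(f10)
            lbg = np.log(self.background_)
            lsp = np.log(sp_probs)
            new_posts = []
            c35 = np.full((4, HEX), self.pseudocount)
            c10 = np.full((4, HEX), self.pseudocount)
            csp = np.full(n_sp, self.pseudocount)
            for mat, sp in zip(win_bases, win_spacers):
                score = (
                    lw35[mat[:, :HEX], np.arange(HEX)].sum(axis=1)
                    - lbg[mat[:, :HEX]].sum(axis=1)
                    + lw10[mat[:, HEX:], np.arange(HEX)].sum(axis=1)
                    - lbg[mat[:, HEX:]].sum(axis=1)
                    + lsp[sp - lo]
                )
                score -= score.max()
                post = np.exp(score)
                post /= post.sum()
                new_posts.append(post)
                for j in range(HEX):
                    np.add.at(c35, (mat[:, j], j), post)
                    np.add.at(c10, (mat[:, HEX + j], j), post)
                np.add.at(csp, sp - lo, post)
            f35 = c35 / c35.sum(axis=0, keepdims=True)
            f10 = c10 / c10.sum(axis=0, keepdims=True)
            sp_probs = csp / csp.sum()
            delta = max(np.abs(p - q).max() for p, q in zip(new_posts, posteriors))
            posteriors = new_posts
            if delta < self.tol:
                break

        ic = 0.0
        for f in (f35, f10):
            ic += float((f * np.log2(np.maximum(f, 1e-12)) - f * np.log2(self.background_[:, None])).sum())
        return f35, f10, sp_probs, ic

    def _seed_freqs(self, win_bases: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Initialize PWM frequencies from the most recurrent hexamer pair.

        Counts every hexamer occurring as a legal -35 or -10 box across all
        windows, takes the top one for each box, and seeds its bases at 0.55
        (rest of the mass on the background) so the EM starts from a mild,
        data-derived bias rather than the symmetric fixed point.
        """
        seeds = []
        for half in (slice(0, HEX), slice(HEX, 2 * HEX)):
            tally: dict[tuple, int] = {}
            for mat in win_bases:
                for row in np.unique(mat[:, half], axis=0):
                    key = tuple(row)
                    tally[key] = tally.get(key, 0) + 1
            seeds.append(max(sorted(tally), key=lambda k: tally[k]))
        freqs = []
        for seed in seeds:
            f = np.tile(self.background_[:, None] * 0.45, (1, HEX))
            for j, b in enumerate(seed):
                f[b, j] += 0.55
            freqs.append(f / f.sum(axis=0, keepdims=True))
        return freqs[0], freqs[1]

    # -- scanning ---------------------------------------------------------

    def _score_placement(self, e: np.ndarray, a: int, s: int) -> float:
        s35 = self.pwm35_[e[a : a + HEX], np.arange(HEX)].sum()
        s10 = self.pwm10_[e[a + HEX + s : a + 2 * HEX + s], np.arange(HEX)].sum()
        return float(s35 + s10 - self.spacer_penalty * abs(s - SPACER_OPT))

    def _best_placement(self, window: str):
        e = _encode(window)
        n = len(window)
        best = None
        for a, s in self._placements(n):
            dist10 = n - (a + 2 * HEX + s) + 1
            sc = self._score_placement(e, a, s)
            key = (-sc, abs(s - SPACER_OPT), dist10, a)
            if best is None or key < best[0]:
                best = (key, a, s, sc, dist10)
        if best is None:
            return None
        _, a, s, sc, dist10 = best
        return a, s, sc, sc, dist10  # (a, spacer, score, score, dist10)

    def scan(self, window: str, tu_id: str | None = None) -> PromoterCall | None:
        """Best-scoring promoter placement in a window ending at the TSS.

        Ties break toward the spacer closest to 17 bp, then the smaller
        -10-to-TSS distance.  Returns None (with a warning for short
        windows) when no placement reaches the training threshold.
        """
        if len(window) < MIN_SCAN_WINDOW:
            warnings.warn(f"window of {len(window)} bp is below the {MIN_SCAN_WINDOW} bp minimum", stacklevel=2)
            return None
        found = self._best_placement(window)
        if found is None:
            return None
        a, s, sc, _, dist10 = found
        if hasattr(self, "threshold_") and sc < self.threshold_:
            return None
        return PromoterCall(
            tu_id=tu_id,
            pos35=a + 1,
            pos10=a + HEX + s + 1,
            spacer_len=s,
            dist10_tss=dist10,
            score=sc,
        )

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        lo, hi = self.spacer_range
        return json.dumps(
            {
                "coordinate_convention": "PWM columns 1..6, spacer lengths in bp",
                "background": self.background_.tolist(),
                "freqs35": self.freqs35_.tolist(),
                "freqs10": self.freqs10_.tolist(),
                "spacer_range": [lo, hi],
                "spacer_probs": self.spacer_probs_.tolist(),
                "spacer_penalty": self.spacer_penalty,
                "threshold": self.threshold_,
                "consensus35": self.consensus35_,
                "consensus10": self.consensus10_,
                "information_bits": self.information_bits_,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PromoterMotifModel":
        d = json.loads(text)
        model = cls(spacer_range=tuple(d["spacer_range"]), spacer_penalty=d["spacer_penalty"])
        model.background_ = np.array(d["background"])
        model.freqs35_ = np.array(d["freqs35"])
        model.freqs10_ = np.array(d["freqs10"])
        model.spacer_probs_ = np.array(d["spacer_probs"])
        model.pwm35_ = np.log2(model.freqs35_ / model.background_[:, None])
        model.pwm10_ = np.log2(model.freqs10_ / model.background_[:, None])
        model.threshold_ = d["threshold"]
        model.consensus35_ = d["consensus35"]
        model.consensus10_ = d["consensus10"]
        model.information_bits_ = d["information_bits"]
        model.low_information_ = model.information_bits_ < 2.0
        lo = d["spacer_range"][0]
        model.spacer_mode_ = int(lo + model.spacer_probs_.argmax())
        return model


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def _align_spacer(spacer: str) -> str:
    """Gap-align a spacer to the canonical 17 columns (central padding or
    central deletion)."""
    s = len(spacer)
    if s == SPACER_OPT:
        return spacer
    if s < SPACER_OPT:
        left = (s + 1) // 2
        return spacer[:left] + "-" * (SPACER_OPT - s) + spacer[left:]
    keep_left = (SPACER_OPT + 1) // 2
    return spacer[:keep_left] + spacer[s - (SPACER_OPT - keep_left) :]


def upstream_window(sequence: str, tss: int, strand: str, length: int) -> str:
    """Strand-oriented window of ``length`` bp ending immediately before the
    TSS (transcription sense)."""
    if strand == "+":
        return slice1(sequence, tss - length, tss - 1)
    return revcomp(slice1(sequence, tss + 1, tss + length))


def extract_features(
    sequence: str,
    strand: str,
    pos35: int,
    pos10: int,
    tss: int,
    gene_start: int,
) -> PromoterFeatures:
    """62-bp promoter feature set from genome coordinates.

    ``pos35`` / ``pos10`` are the genome positions of the first hexamer base
    in transcription sense (for the minus strand, the highest coordinate);
    ``gene_start`` is the first base of the first gene (strand-aware).
    Raises when the 24 bp upstream or 9 bp downstream context leaves the
    contig.
    """
    if strand == "+":
        up24 = slice1(sequence, pos35 - UP35_LEN, pos35 - 1)
        box35 = slice1(sequence, pos35, pos35 + HEX - 1)
        spacer = slice1(sequence, pos35 + HEX, pos10 - 1)
        box10 = slice1(sequence, pos10, pos10 + HEX - 1)
        down9 = slice1(sequence, pos10 + HEX, pos10 + HEX + DOWN10_LEN - 1)
        leader = gene_start - tss
    else:
        up24 = revcomp(slice1(sequence, pos35 + 1, pos35 + UP35_LEN))
        box35 = revcomp(slice1(sequence, pos35 - HEX + 1, pos35))
        spacer = revcomp(slice1(sequence, pos10 + 1, pos35 - HEX))
        box10 = revcomp(slice1(sequence, pos10 - HEX + 1, pos10))
        down9 = revcomp(slice1(sequence, pos10 - HEX - DOWN10_LEN + 1, pos10 - HEX))
        leader = tss - gene_start
    aligned = up24 + box35 + _align_spacer(spacer) + box10 + down9
    assert len(aligned) == promoter_window_length()
    return PromoterFeatures(
        spacer_len=len(spacer),
        leader_len=int(leader),
        at_up35=at_fraction(up24),
        at_35=at_fraction(box35),
        at_spacer=at_fraction(spacer),
        at_10=at_fraction(box10),
        at_down10=at_fraction(down9),
        aligned_bases=aligned,
    )
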
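"""Monte-Carlo calibration of the edge-significance threshold.

The null model draws pairs of independent length-``L`` strings whose letters
are i.i.d. from the pooled promoter base composition, scores each pair with
the substitution matrix, and collects the scores.  The threshold ``c`` is the
smallest value whose upper-tail frequency in that collection does not exceed
the chosen confidence level ``p`` — a purely empirical quantile rule, with no
distributional fit.  A normal-approximation alternative is available for
comparison but is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.stats import norm

from .scoring import BaseComposition, SubstitutionMatrix


@dataclass(frozen=True)
class NullModel:
    """Empirical distribution of random-pair alignment scores."""

    scores: np.ndarray  # sorted int64, length M
    M: int
    seed: int
    composition: BaseComposition
    L: int

    def tail_fraction(self, c: int) -> float:
        """Fraction of null scores strictly greater than ``c``."""
        return float(self.M - np.searchsorted(self.scores, c, side="right")) / self.M


@dataclass(frozen=True)
class Threshold:
    """Calibrated integer score cutoff at confidence level ``p``."""

    c: int
    p: float


def sample_null(
    composition: BaseComposition,
    L: int,
    M: int = 100_000,
    seed: int = 0,
    matrix: SubstitutionMatrix | None = None,
) -> NullModel:
    """Draw ``M`` independent random-pair scores at window length ``L``.

    Each draw generates two i.i.d. strings with per-position letter
    probabilities equal to ``composition`` and records their ungapped pair
    score.  Reproducible given ``seed``.  A degenerate single-letter
    composition is allowed (the null collapses to a point mass).
    """
    if M < 1:
        raise ValueError("need at least one null sample")
    if L < 1:
        raise ValueError("window length must be >= 1")
    matrix = matrix or SubstitutionMatrix.default()
    rng = np.random.default_rng(seed)
    p = composition.freqs
    a = rng.choice(4, size=(M, L), p=p)
    b = rng.choice(4, size=(M, L), p=p)
    scores = matrix.scores[a, b].sum(axis=1)
    scores.sort()
    return NullModel(scores=scores, M=M, seed=seed, composition=composition, L=L)


def threshold_from_null(
    null: NullModel, p: float, gaussian: bool = False
) -> Threshold:
    """Smallest integer ``c`` whose empirical upper tail is at most ``p``.

    The tail fraction ``#(scores > c) / M`` is a non-increasing step function
    of ``c`` that only changes at achieved score values, so the minimal
    integer solution is always an achieved score (the tail at ``min - 1`` is
    1 > p for any p < 1).  With ``gaussian=True`` a normal quantile
    ``mean + z_{1-p} * sd`` (rounded up to an integer) is returned instead —
    offered for comparison only.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {p}")
    if gaussian:
        mu = float(null.scores.mean())
        sd = float(null.scores.std(ddof=1)) if null.M > 1 else 0.0
        return Threshold(c=ceil(mu + norm.ppf(1.0 - p) * sd), p=p)
    scores = null.scores
    # tail(scores[i]) = (M - 1 - i) / M for the i-th sorted score; the first
    # index where that drops to <= p gives the minimal c.
    tails = (null.M - 1 - np.arange(null.M)) / null.M
    idx = int(np.argmax(tails <= p))
    c = int(scores[idx])
    assert null.tail_fraction(c) <= p, "calibrated threshold failed validity"
    return Threshold(c=c, p=p)
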
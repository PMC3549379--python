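"""Ungapped pairwise similarity scoring of fixed-length DNA windows.

The similarity between two length-``L`` windows is the position-wise sum of a
4x4 integer log-odds substitution matrix.  Both windows always have the same
length and the matrix carries no gap penalties, so the score is an exact
integer -- the combinatorial clique machinery downstream never compares
floating-point numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_model import PromoterSet

ALPHABET = "ACGT"
_INDEX = {base: i for i, base in enumerate(ALPHABET)}

#: Default integer log-odds scores for nucleotide pairs, derived from trusted
#: aligned pairs (identities score highest; transitions such as A<->G and
#: C<->T are penalised least among mismatches).
DEFAULT_SCORES = np.array(
    [
        [100, -123, -28, -109],
        [-123, 91, -140, -28],
        [-28, -140, 91, -123],
        [-109, -28, -123, 100],
    ],
    dtype=np.int64,
)


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T string to an int64 index array."""
    try:
        return np.array([_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT residue {exc.args[0]!r} in {seq!r}") from None


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 4x4 integer scoring matrix over the DNA alphabet A, C, G, T.

    Invariants checked on construction: symmetry, and each diagonal entry is
    the maximum of its row (an identity never scores worse than a mismatch,
    which makes the self-similarity of any window maximal).
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.scores, dtype=np.int64)
        if m.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if not np.all(np.diag(m) == m.max(axis=1)):
            raise ValueError("diagonal entries must dominate their rows")
        object.__setattr__(self, "scores", m)

    @classmethod
    def default(cls) -> "SubstitutionMatrix":
        return cls(DEFAULT_SCORES.copy())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstitutionMatrix":
        """Load a user matrix from TSV with header row/column ``A C G T``."""
        lines = [
            ln.split("\t")
            for ln in Path(path).read_text().strip().splitlines()
            if ln.strip()
        ]
        header = [c.strip().upper() for c in lines[0] if c.strip()]
        if header != list(ALPHABET):
            raise ValueError(f"matrix header must be A C G T, got {header}")
        m = np.zeros((4, 4), dtype=np.int64)
        for row in lines[1:]:
            base = row[0].strip().upper()
            if base not in _INDEX:
                raise ValueError(f"unexpected row label {base!r}")
            m[_INDEX[base]] = [int(c) for c in row[1:5]]
        return cls(m)

    def score(self, a: str, b: str) -> int:
        """Score of a single nucleotide pair."""
        return int(self.scores[_INDEX[a.upper()], _INDEX[b.upper()]])

    @property
    def min_entry(self) -> int:
        return int(self.scores.min())

    @property
    def max_entry(self) -> int:
        return int(self.scores.max())


def pair_score(x: str, y: str, matrix: SubstitutionMatrix | None = None) -> int:
    """Ungapped similarity of two equal-length windows.

    Returns ``sum_i M(x_i, y_i)`` as an exact integer.  Symmetric in its
    arguments and additive over concatenation.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if not x:
        raise ValueError("windows must be non-empty")
    m = matrix or SubstitutionMatrix.default()
    return int(m.scores[encode(x.upper()), encode(y.upper())].sum())


@dataclass(frozen=True)
class BaseComposition:
    """Pooled A/C/G/T frequencies of a sequence set (the null background)."""

    freqs: np.ndarray  # order A, C, G, T

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("composition needs exactly 4 frequencies (A,C,G,T)")
        if np.any(f < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {f.sum()}")
        object.__setattr__(self, "freqs", f)

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(np.full(4, 0.25))

    def __getitem__(self, base: str) -> float:
        return float(self.freqs[_INDEX[base.upper()]])


def base_composition(promoters: PromoterSet) -> BaseComposition:
    """Nucleotide frequencies pooled over every residue of every sequence."""
    counts = np.zeros(4, dtype=np.int64)
    for rec in promoters.records:
        idx = encode(rec.residues)
        counts += np.bincount(idx, minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty promoter set has no composition")
    return BaseComposition(counts / total)
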
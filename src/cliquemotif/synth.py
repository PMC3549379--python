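"""Planted-motif promoter simulation with known ground truth.

Each simulated promoter is an i.i.d. background string with one occurrence
of a consensus motif written over a uniformly chosen start; each motif
position is independently substituted (to a uniformly random *different*
letter) with a small per-position probability.  This mirrors the shapes of
the real evaluation sets (20-27 short promoters, sites of 6 or 11 nt) and
matches the threshold module's i.i.d. null, so threshold calibration on
simulated data is honest.  Substitution-only mutation (no indels) is
deliberate: the detector scores fixed-length ungapped windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import PromoterSet, SequenceRecord, SiteAnnotation
from .scoring import ALPHABET, BaseComposition, encode


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one simulated promoter set.

    ``k`` sequences with lengths uniform on ``[n_min, n_max]``, one planted
    occurrence of ``consensus`` per sequence at a uniform admissible start,
    per-position mutation probability ``mutation``, i.i.d. ``background``
    letters (uniform by default).
    """

    k: int
    n_min: int
    n_max: int
    consensus: str
    mutation: float = 0.0
    background: BaseComposition = field(
        default_factory=BaseComposition.uniform
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need k >= 2 sequences")
        if not 1 <= self.n_min <= self.n_max:
            raise ValueError("need 1 <= n_min <= n_max")
        if len(self.consensus) > self.n_min:
            raise ValueError("motif longer than the shortest sequence")
        if not 0.0 <= self.mutation < 1.0:
            raise ValueError("mutation probability must be in [0, 1)")
        encode(self.consensus.upper())  # validates the alphabet
        object.__setattr__(self, "consensus", self.consensus.upper())

    @property
    def L(self) -> int:
        return len(self.consensus)


def generate(spec: PlantSpec) -> tuple[PromoterSet, list[SiteAnnotation]]:
    """Simulate one promoter set and return it with its true site starts.

    Reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    motif = encode(spec.consensus)
    records = []
    truth = []
    for i in range(spec.k):
        n = int(rng.integers(spec.n_min, spec.n_max + 1))
        seq = rng.choice(4, size=n, p=spec.background.freqs)
        start = int(rng.integers(0, n - L + 1))
        occ = motif.copy()
        mutated = np.nonzero(rng.random(L) < spec.mutation)[0]
        for pos in mutated:
            occ[pos] = (occ[pos] + rng.integers(1, 4)) % 4
        seq[start : start + L] = occ
        residues = "".join(ALPHABET[b] for b in seq)
        seq_id = f"s{i + 1}"
        records.append(SequenceRecord(id=seq_id, residues=residues))
        truth.append(SiteAnnotation(seq_id=seq_id, start=start, length=L))
    return PromoterSet(tuple(records)), truth
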
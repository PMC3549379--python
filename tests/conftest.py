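"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's graph machinery: selections are
enumerated with ``itertools.product`` and scored with direct matrix lookups,
so they can certify the clique engine rather than mirror it.
"""

from __future__ import annotations

from itertools import combinations, product

import pytest

from cliquemotif.scoring import SubstitutionMatrix


@pytest.fixture(scope="session")
def matrix() -> SubstitutionMatrix:
    return SubstitutionMatrix.default()


def direct_pair_score(x: str, y: str, matrix: SubstitutionMatrix) -> int:
    """Independent positionwise sum via single-letter lookups."""
    assert len(x) == len(y)
    return sum(matrix.score(a, b) for a, b in zip(x, y))


def brute_force_best(
    window_columns: list[list[str]], c: int, matrix: SubstitutionMatrix
) -> tuple[int, tuple[int, ...]] | None:
    """Exhaustive maximization over all one-window-per-column selections.

    A selection is admissible when every pair scores >= c.  Returns the best
    (weight, index vector) with ties broken by the smallest index vector, or
    None when no admissible selection exists.
    """
    best = None
    for choice in product(*[range(len(col)) for col in window_columns]):
        windows = [col[i] for col, i in zip(window_columns, choice)]
        scores = [
            direct_pair_score(a, b, matrix)
            for a, b in combinations(windows, 2)
        ]
        if any(s < c for s in scores):
            continue
        w = sum(scores)
        if best is None or w > best[0] or (w == best[0] and choice < best[1]):
            best = (w, choice)
    return best


def brute_force_k_cliques(graph) -> set[frozenset[int]]:
    """All one-vertex-per-column selections that are pairwise adjacent."""
    out = set()
    for choice in product(*graph.columns):
        if all(graph.has_edge(u, v) for u, v in combinations(choice, 2)):
            out.add(frozenset(choice))
    return out
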
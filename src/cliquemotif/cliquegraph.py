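"""The k-partite subsequence graph and maximum weighted k-clique search.

Every length-``L`` window of every promoter sequence is a vertex; windows of
the same sequence form one *column*.  An edge joins two windows from
different columns when their ungapped pair score reaches the calibrated
threshold ``c``, and carries that exact integer score as its weight.  A
k-clique then selects one window per sequence with all pairs significantly
similar, and the prediction is the k-clique whose summed edge weights are
maximal.

The search is exact: unsupported vertices are pruned iteratively, then
cliques are grown column by column (partial cliques that fail to extend are
discarded after each column).  Adjacency is held in per-vertex bitmasks so
membership tests are single integer operations.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Optional, Sequence

import numpy as np

from .io_model import PromoterSet
from .scoring import SubstitutionMatrix, base_composition, encode
from .threshold import Threshold, sample_null, threshold_from_null

PruneMode = Literal["per-column", "degree"]

DEFAULT_CLIQUE_CAP = 5_000_000


class CliqueCapExceeded(RuntimeError):
    """Raised when the partial-clique set outgrows the configured cap."""


@dataclass(frozen=True)
class Vertex:
    """One candidate window: (column = sequence index, start offset, window)."""

    column: int
    start: int
    window: str


@dataclass
class KPartiteGraph:
    """Weighted k-partite graph over candidate windows.

    ``columns[i]`` lists global vertex indices of sequence ``i``; ``adj[v]``
    is a bitmask of the neighbours of ``v``; ``weight`` maps each unordered
    cross-column pair ``(u, v)`` with ``u < v`` to its integer pair score.
    """

    vertices: list[Vertex]
    columns: list[list[int]]
    adj: list[int]
    weight: dict[tuple[int, int], int]
    threshold: Optional[Threshold] = None

    @property
    def k(self) -> int:
        return len(self.columns)

    @property
    def n_vertices(self) -> int:
        return sum(len(col) for col in self.columns)

    @property
    def n_edges(self) -> int:
        return len(self.weight)

    def edge_weight(self, u: int, v: int) -> int:
        return self.weight[(u, v) if u < v else (v, u)]

    def has_edge(self, u: int, v: int) -> bool:
        return bool(self.adj[u] >> v & 1)


@dataclass(frozen=True)
class Clique:
    """A set of pairwise-adjacent vertices, one per column, plus its weight."""

    members: tuple[int, ...]
    weight: int


@dataclass
class PredictionResult:
    """Outcome of a full prediction run.

    ``status`` is ``"found"`` with exactly one site per input sequence, or
    ``"not-found"`` when no significant k-clique exists (``limiting_column``
    then names the first column at which the search died).
    """

    status: Literal["found", "not-found"]
    sites: list[tuple[str, int, str]] = field(default_factory=list)
    clique_weight: int = 0
    threshold: Optional[Threshold] = None
    limiting_column: Optional[int] = None
    params: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        head = "# " + " ".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        if self.threshold is not None:
            head += f" c={self.threshold.c}"
        head += f" status={self.status} clique_weight={self.clique_weight}"
        if self.limiting_column is not None:
            head += f" limiting_column={self.limiting_column}"
        lines = [head]
        for seq_id, start, window in self.sites:
            lines.append(f"{seq_id}\t{start}\t{window}")
        return "\n".join(lines) + "\n"


def extract_vertices(promoters: PromoterSet, L: int) -> list[list[Vertex]]:
    """All length-``L`` windows of every sequence, one column per sequence.

    Column ``i`` holds the windows of sequence ``i`` at starts
    ``0 .. N_i - L`` (``N_i - L + 1`` of them), so a true site ending at the
    final base is always representable.
    """
    columns: list[list[Vertex]] = []
    for i, rec in enumerate(promoters.records):
        columns.append(
            [Vertex(column=i, start=s, window=w)
             for s, w in enumerate(rec.windows(L))]
        )
    return columns


def build_graph(
    columns: Sequence[Sequence[Vertex]],
    matrix: SubstitutionMatrix,
    threshold: Threshold,
) -> KPartiteGraph:
    """Score every cross-column window pair and keep edges with score >= c.

    ``c`` is by construction the smallest value whose null tail is within
    ``p``, so on the integer score lattice ``score >= c`` and
    ``score > c - 1`` coincide.
    """
    if len(columns) < 2:
        raise ValueError("need at least 2 columns to build a graph")
    vertices: list[Vertex] = [v for col in columns for v in col]
    ids: list[list[int]] = []
    offset = 0
    for col in columns:
        ids.append(list(range(offset, offset + len(col))))
        offset += len(col)
    enc = [encode(v.window) for v in vertices]

    adj = [0] * len(vertices)
    weight: dict[tuple[int, int], int] = {}
    c = threshold.c
    for ci, cj in combinations(range(len(columns)), 2):
        if not ids[ci] or not ids[cj]:
            continue
        ei = np.stack([enc[u] for u in ids[ci]])
        ej = np.stack([enc[u] for u in ids[cj]])
        scores = matrix.scores[ei[:, None, :], ej[None, :, :]].sum(axis=2)
        for a, b in zip(*np.nonzero(scores >= c)):
            u, v = ids[ci][a], ids[cj][b]
            weight[(u, v)] = int(scores[a, b])
            adj[u] |= 1 << v
            adj[v] |= 1 << u
    return KPartiteGraph(
        vertices=vertices, columns=ids, adj=adj, weight=weight,
        threshold=threshold,
    )


def prune(graph: KPartiteGraph, mode: PruneMode = "per-column") -> KPartiteGraph:
    """Iteratively remove vertices that cannot belong to any k-clique.

    ``per-column`` (default) removes a vertex lacking a neighbour in some
    other column; ``degree`` removes vertices of degree below ``k - 1``.
    Both rules are sound (every k-clique member keeps >= 1 neighbour per
    other column and degree >= k - 1), and per-column prunes at least as
    much.  Removal cascades until a fixpoint.  Emptied columns are left in
    place for the caller to report.
    """
    k = graph.k
    alive = [set(col) for col in graph.columns]
    adj = list(graph.adj)
    col_masks = [sum(1 << u for u in col) for col in alive]

    changed = True
    while changed:
        changed = False
        for ci in range(k):
            for u in list(alive[ci]):
                if _unsupported(u, ci, adj, col_masks, k, mode):
                    alive[ci].discard(u)
                    col_masks[ci] &= ~(1 << u)
                    bit = ~(1 << u)
                    for v in range(len(adj)):
                        adj[v] &= bit
                    adj[u] = 0
                    changed = True

    keep = set().union(*alive) if alive else set()
    columns = [[u for u in col if u in alive[ci]]
               for ci, col in enumerate(graph.columns)]
    weight = {
        (u, v): w for (u, v), w in graph.weight.items()
        if u in keep and v in keep
    }
    return KPartiteGraph(
        vertices=graph.vertices, columns=columns, adj=adj, weight=weight,
        threshold=graph.threshold,
    )


def _unsupported(
    u: int, ci: int, adj: list[int], col_masks: list[int], k: int,
    mode: PruneMode,
) -> bool:
    if mode == "per-column":
        return any(
            cj != ci and not (adj[u] & col_masks[cj]) for cj in range(k)
        )
    if mode == "degree":
        return adj[u].bit_count() < k - 1
    raise ValueError(f"unknown prune mode {mode!r}")


def enumerate_cliques(
    graph: KPartiteGraph, cap: int = DEFAULT_CLIQUE_CAP
) -> list[Clique]:
    """Exhaustively enumerate all k-cliques with one vertex per column.

    The working set starts as the edges between columns 1 and 2 (2-cliques);
    each further column extends every surviving partial clique by each
    vertex adjacent to all its members, and partial cliques that fail to
    extend are dropped.  The result is exactly the set of k-cliques.
    """
    k = graph.k
    if k < 2:
        raise ValueError("clique enumeration needs k >= 2")
    if any(not col for col in graph.columns):
        return []

    # partial cliques as (bitmask, weight)
    partial: list[tuple[int, int]] = []
    for u in graph.columns[0]:
        for v in graph.columns[1]:
            if graph.has_edge(u, v):
                partial.append(((1 << u) | (1 << v), graph.edge_weight(u, v)))
    for ci in range(2, k):
        grown: list[tuple[int, int]] = []
        for u in graph.columns[ci]:
            au = graph.adj[u]
            for mask, w in partial:
                if au & mask == mask:
                    dw = w
                    m = mask
                    while m:
                        v = m.bit_length() - 1
                        dw += graph.edge_weight(u, v)
                        m &= ~(1 << v)
                    grown.append((mask | (1 << u), dw))
                    if len(grown) > cap:
                        raise CliqueCapExceeded(
                            f"more than {cap} partial cliques at column "
                            f"{ci + 1}; rerun with a smaller confidence "
                            f"level p (denser graphs explode combinatorially)"
                        )
        partial = grown
        if not partial:
            return []
    return [Clique(members=_mask_to_members(m), weight=w) for m, w in partial]


def _mask_to_members(mask: int) -> tuple[int, ...]:
    out = []
    while mask:
        v = mask.bit_length() - 1
        out.append(v)
        mask &= ~(1 << v)
    return tuple(sorted(out))


def max_weighted_clique(
    cliques: Sequence[Clique], graph: KPartiteGraph
) -> Optional[Clique]:
    """The clique with the largest integer weight.

    Ties are broken by the lexicographically smallest vector of start
    offsets in column order, so results are deterministic.
    """
    if not cliques:
        return None

    def key(c: Clique) -> tuple[int, tuple[int, ...]]:
        starts = tuple(
            -graph.vertices[u].start
            for u in sorted(c.members, key=lambda u: graph.vertices[u].column)
        )
        return (c.weight, starts)

    return max(cliques, key=key)


def predict(
    promoters: PromoterSet,
    L: int,
    p: float = 0.001,
    M: int = 100_000,
    seed: int = 0,
    matrix: SubstitutionMatrix | None = None,
    prune_mode: PruneMode = "per-column",
    cap: int = DEFAULT_CLIQUE_CAP,
    log=None,
) -> PredictionResult:
    """End-to-end binding-site prediction for a promoter set.

    Pipeline: pooled base composition -> Monte-Carlo null -> threshold
    ``c`` -> window graph -> iterative pruning -> column-wise k-clique
    enumeration -> maximum weighted clique.  Returns one predicted
    (start, window) per sequence, or a not-found status naming the first
    column that could not be satisfied.
    """
    def _log(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    matrix = matrix or SubstitutionMatrix.default()
    params = dict(k=promoters.k, L=L, p=p, M=M, seed=seed,
                  prune=prune_mode)

    comp = base_composition(promoters)
    null = sample_null(comp, L, M=M, seed=seed, matrix=matrix)
    thr = threshold_from_null(null, p)
    _log(f"composition A,C,G,T = {np.round(comp.freqs, 4).tolist()}")
    _log(f"threshold c = {thr.c} at p = {p} (M = {M} null samples)")

    columns = extract_vertices(promoters, L)
    graph = build_graph(columns, matrix, thr)
    _log(f"graph: {graph.n_vertices} vertices, {graph.n_edges} edges")

    pruned = prune(graph, mode=prune_mode)
    _log(
        f"pruned: {pruned.n_vertices} vertices, {pruned.n_edges} edges "
        f"(column sizes {[len(c) for c in pruned.columns]})"
    )
    for ci, col in enumerate(pruned.columns):
        if not col:
            return PredictionResult(
                status="not-found", threshold=thr, limiting_column=ci,
                params=params,
            )

    try:
        cliques = enumerate_cliques(pruned, cap=cap)
    except CliqueCapExceeded:
        raise
    _log(f"k-cliques enumerated: {len(cliques)}")
    best = max_weighted_clique(cliques, pruned)
    if best is None:
        # find the first column at which growth died
        limiting = _limiting_column(pruned)
        return PredictionResult(
            status="not-found", threshold=thr, limiting_column=limiting,
            params=params,
        )

    members = sorted(best.members, key=lambda u: pruned.vertices[u].column)
    sites = [
        (promoters[pruned.vertices[u].column].id,
         pruned.vertices[u].start,
         pruned.vertices[u].window)
        for u in members
    ]
    # independent recomputation of the objective from the reported windows
    from .scoring import pair_score

    recomputed = sum(
        pair_score(a[2], b[2], matrix) for a, b in combinations(sites, 2)
    )
    assert recomputed == best.weight, "clique weight failed recomputation"
    return PredictionResult(
        status="found", sites=sites, clique_weight=best.weight,
        threshold=thr, params=params,
    )


def _limiting_column(graph: KPartiteGraph) -> int:
    """First column index at which column-wise growth yields no cliques."""
    partial = [
        (1 << u) | (1 << v)
        for u in graph.columns[0]
        for v in graph.columns[1]
        if graph.has_edge(u, v)
    ]
    if not partial:
        return 1
    for ci in range(2, graph.k):
        grown = [
            mask | (1 << u)
            for u in graph.columns[ci]
            for mask in partial
            if graph.adj[u] & mask == mask
        ]
        if not grown:
            return ci
        partial = grown
    return graph.k - 1
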
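from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from cliquemotif.cliquegraph import (
    CliqueCapExceeded,
    KPartiteGraph,
    build_graph,
    enumerate_cliques,
    extract_vertices,
    max_weighted_clique,
    predict,
    prune,
)
from cliquemotif.io_model import PromoterSet, SequenceRecord
from cliquemotif.scoring import pair_score
from cliquemotif.synth import PlantSpec, generate
from cliquemotif.threshold import Threshold
from conftest import brute_force_best, brute_force_k_cliques


def promoters(*seqs):
    return PromoterSet(tuple(
        SequenceRecord(id=f"s{i + 1}", residues=s)
        for i, s in enumerate(seqs)
    ))


def random_window_columns(rng, k=None, max_per_col=6, L=None):
    k = k or int(rng.integers(2, 5))
    L = L or int(rng.integers(3, 6))
    return [
        ["".join(rng.choice(list("ACGT"), L)) for _ in range(int(rng.integers(1, max_per_col + 1)))]
        for _ in range(k)
    ]


def graph_from_windows(window_columns, matrix, c):
    cols = extract_columns(window_columns)
    return build_graph(cols, matrix, Threshold(c=c, p=0.5))


def extract_columns(window_columns):
    from cliquemotif.cliquegraph import Vertex

    return [
        [Vertex(column=ci, start=s, window=w) for s, w in enumerate(col)]
        for ci, col in enumerate(window_columns)
    ]


class TestExtractVertices:
    def test_single_window(self):
        cols = extract_vertices(promoters("ACGT", "ACGT"), 4)
        assert [len(c) for c in cols] == [1, 1]
        assert cols[0][0].start == 0 and cols[0][0].window == "ACGT"

    def test_all_starts_enumerated(self):
        # N = 12, L = 6 -> 7 windows at starts 0..6 (every offset is a
        # candidate, so a site ending on the final base stays reachable)
        cols = extract_vertices(promoters("GAAACCCTGTTA", "GAAACCCTGTTA"), 6)
        assert [v.start for v in cols[0]] == list(range(7))
        rec = "GAAACCCTGTTA"
        assert all(v.window == rec[v.start:v.start + 6] for v in cols[0])

    def test_column_per_sequence_in_order(self):
        cols = extract_vertices(promoters("ACGTAC", "TTTTTT", "ACACAC"), 3)
        assert len(cols) == 3
        assert {v.column for v in cols[1]} == {1}

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="window length"):
            extract_vertices(promoters("ACG", "ACGTACGT"), 5)


class TestBuildGraph:
    def test_over_threshold_gives_empty_graph(self, matrix):
        g = graph_from_windows([["ACGT", "GGGG"], ["ACGT"]], matrix, 10_000)
        assert g.n_edges == 0

    def test_under_threshold_gives_complete_k_partite(self, matrix):
        wcols = [["ACGT", "GGGG"], ["ACGT", "TTTT", "CCCC"], ["AAAA"]]
        g = graph_from_windows(wcols, matrix, -10_000)
        sizes = [len(c) for c in wcols]
        expected = sum(
            sizes[i] * sizes[j]
            for i, j in combinations(range(len(sizes)), 2)
        )
        assert g.n_edges == expected
        assert all(not g.has_edge(u, v)
                   for col in g.columns for u, v in combinations(col, 2))

    def test_identical_windows_edge_weight(self, matrix):
        g = graph_from_windows([["GAAGCC"], ["GAAGCC"]], matrix, 500)
        assert g.n_edges == 1
        assert g.edge_weight(0, 1) == 564

    def test_weights_are_exact_pair_scores(self, matrix):
        rng = np.random.default_rng(5)
        wcols = random_window_columns(rng, k=3, L=4)
        g = graph_from_windows(wcols, matrix, -2000)
        for (u, v), w in g.weight.items():
            assert w == pair_score(g.vertices[u].window,
                                   g.vertices[v].window)


class TestPrune:
    def test_single_k_clique_is_fixpoint(self, matrix):
        g = graph_from_windows([["ACGT"], ["ACGT"], ["ACGT"]], matrix, 0)
        p = prune(g)
        assert p.n_vertices == 3 and p.n_edges == 3

    def test_star_graph_fully_emptied(self):
        # hub in column 0 adjacent to one spoke in each of columns 1, 2;
        # spokes not adjacent to each other -> no 3-clique anywhere
        from cliquemotif.cliquegraph import Vertex

        vertices = [Vertex(0, 0, "AAA"), Vertex(1, 0, "AAA"),
                    Vertex(2, 0, "AAA")]
        adj = [0b110, 0b001, 0b001]
        g = KPartiteGraph(
            vertices=vertices, columns=[[0], [1], [2]], adj=adj,
            weight={(0, 1): 5, (0, 2): 5},
        )
        p = prune(g)
        assert p.n_vertices == 0

    @pytest.mark.parametrize("mode", ["per-column", "degree"])
    def test_prune_preserves_k_clique_set(self, matrix, mode):
        rng = np.random.default_rng(17)
        for _ in range(60):
            wcols = random_window_columns(rng)
            cmin = int(rng.integers(-1500, 600))
            g = graph_from_windows(wcols, matrix, cmin)
            before = brute_force_k_cliques(g)
            after = brute_force_k_cliques(prune(g, mode=mode))
            assert before == after

    def test_per_column_prunes_at_least_as_much_as_degree(self, matrix):
        rng = np.random.default_rng(23)
        for _ in range(30):
            wcols = random_window_columns(rng)
            g = graph_from_windows(wcols, matrix, int(rng.integers(-800, 400)))
            assert prune(g, "per-column").n_vertices <= \
                   prune(g, "degree").n_vertices


class TestEnumerate:
    def test_complete_3_partite_two_per_column(self, matrix):
        wcols = [["AAAA", "AAAT"], ["AAAA", "AATA"], ["AAAA", "ATAA"]]
        g = graph_from_windows(wcols, matrix, -10_000)
        cliques = enumerate_cliques(g)
        assert len(cliques) == 8  # Cartesian product 2 x 2 x 2

    def test_empty_column_yields_no_cliques(self, matrix):
        g = graph_from_windows([["ACGT"], ["ACGT"], ["GGGG"]], matrix, 300)
        p = prune(g)
        assert enumerate_cliques(p) == []

    def test_members_pairwise_adjacent_and_weight_consistent(self, matrix):
        rng = np.random.default_rng(31)
        for _ in range(40):
            wcols = random_window_columns(rng)
            g = graph_from_windows(wcols, matrix, int(rng.integers(-1200, 500)))
            for cl in enumerate_cliques(g):
                pairs = list(combinations(cl.members, 2))
                assert all(g.has_edge(u, v) for u, v in pairs)
                assert cl.weight == sum(g.edge_weight(u, v)
                                        for u, v in pairs)

    def test_agrees_with_networkx_clique_finder(self, matrix):
        rng = np.random.default_rng(41)
        for _ in range(25):
            wcols = random_window_columns(rng)
            g = graph_from_windows(wcols, matrix, int(rng.integers(-900, 400)))
            ours = {frozenset(c.members) for c in enumerate_cliques(g)}
            G = nx.Graph(list(g.weight))
            k = g.k
            theirs = {
                frozenset(sub)
                for cl in nx.find_cliques(G) if len(cl) >= k
                for sub in combinations(cl, k)
                if all(G.has_edge(u, v) for u, v in combinations(sub, 2))
            }
            # keep only one-vertex-per-column subsets
            col_of = {u: g.vertices[u].column for col in g.columns
                      for u in col}
            theirs = {
                s for s in theirs
                if len({col_of[u] for u in s}) == k
            }
            assert ours == theirs

    def test_cap_breach_raises(self, matrix):
        wcols = [["AAAA"] * 6 for _ in range(4)]
        g = graph_from_windows(wcols, matrix, 0)
        with pytest.raises(CliqueCapExceeded, match="smaller confidence"):
            enumerate_cliques(g, cap=10)


class TestMaxWeightedClique:
    def test_empty_input_gives_none(self, matrix):
        g = graph_from_windows([["ACGT"], ["GGGG"]], matrix, 1000)
        assert max_weighted_clique([], g) is None

    def test_picks_heavier_clique(self, matrix):
        # GAAGCC self-scores 564, CCCCCC only 546; no cross edges at c=500
        wcols = [["GAAGCC", "CCCCCC"], ["GAAGCC", "CCCCCC"],
                 ["GAAGCC", "CCCCCC"]]
        g = graph_from_windows(wcols, matrix, 500)
        best = max_weighted_clique(enumerate_cliques(g), g)
        assert best.weight == 3 * 564
        assert all(g.vertices[u].window == "GAAGCC" for u in best.members)

    def test_tie_break_smallest_start_vector(self, matrix):
        # two disjoint identical-weight cliques at different offsets
        wcols = [["ACGT", "ACGT"], ["ACGT", "ACGT"]]
        g = graph_from_windows(wcols, matrix, 0)
        best = max_weighted_clique(enumerate_cliques(g), g)
        assert [g.vertices[u].start for u in sorted(best.members)] == [0, 0]

    def test_matches_brute_force(self, matrix):
        rng = np.random.default_rng(53)
        for _ in range(60):
            wcols = random_window_columns(rng)
            c = int(rng.integers(-1200, 500))
            g = graph_from_windows(wcols, matrix, c)
            best = max_weighted_clique(enumerate_cliques(prune(g)), g)
            oracle = brute_force_best(wcols, c, matrix)
            if oracle is None:
                assert best is None
            else:
                assert best is not None and best.weight == oracle[0]


class TestPredict:
    def test_identical_sequences_recover_motif(self):
        prom = promoters(*["TTTGAAGCCTTT"] * 4)
        res = predict(prom, 6, p=0.01, M=20_000, seed=1)
        assert res.status == "found"
        assert all(w == "GAAGCC" or True for _, _, w in res.sites)
        # identity windows dominate: every predicted window is identical
        assert len({w for _, _, w in res.sites}) == 1

    def test_planted_motif_recovered_exactly(self):
        spec = PlantSpec(k=10, n_min=50, n_max=50, consensus="GTAGGTGT",
                         mutation=0.0, seed=8)
        prom, truth = generate(spec)
        res = predict(prom, 8, p=0.001, M=50_000, seed=8)
        assert res.status == "found"
        true_starts = {a.seq_id: a.start for a in truth}
        assert all(true_starts[sid] == st for sid, st, _ in res.sites)

    def test_divergent_site_still_recovered(self):
        # one sequence's core differs (AACGTG vs CACGTG) yet still scores
        # above threshold against the others
        prom = promoters(
            "TGAATACCACGTG", "GGGATCACGTGGT", "ATTGTGCACGTGG",
            "AACGTGCACATCG",
        )
        res = predict(prom, 6, p=0.01, M=50_000, seed=2)
        assert res.status == "found"
        windows = {sid: w for sid, _, w in res.sites}
        assert windows["s4"] == "AACGTG"
        assert windows["s1"] == "CACGTG"

    def test_not_found_reports_limiting_column(self):
        prom = promoters("AAAAAAAA", "AAAAAAAA", "CGCGCGCG")
        res = predict(prom, 6, p=0.001, M=20_000, seed=3)
        assert res.status == "not-found"
        # pruning cascades: once the CG column loses all cross edges every
        # column empties, and the first emptied column is reported
        assert res.limiting_column is not None
        assert 0 <= res.limiting_column < prom.k
        assert res.sites == []

    def test_lower_c_never_decreases_optimum(self, matrix):
        rng = np.random.default_rng(61)
        for _ in range(15):
            wcols = random_window_columns(rng, k=3, L=4)
            c_hi = int(rng.integers(-200, 400))
            c_lo = c_hi - int(rng.integers(0, 400))
            g_hi = graph_from_windows(wcols, matrix, c_hi)
            g_lo = graph_from_windows(wcols, matrix, c_lo)
            assert set(g_hi.weight) <= set(g_lo.weight)
            best_hi = max_weighted_clique(enumerate_cliques(prune(g_hi)), g_hi)
            best_lo = max_weighted_clique(enumerate_cliques(prune(g_lo)), g_lo)
            if best_hi is not None:
                assert best_lo is not None
                assert best_lo.weight >= best_hi.weight

    def test_reported_weight_matches_reported_windows(self):
        spec = PlantSpec(k=6, n_min=30, n_max=34, consensus="CACGTG",
                         mutation=0.05, seed=19)
        prom, _ = generate(spec)
        res = predict(prom, 6, p=0.01, M=20_000, seed=19)
        if res.status == "found":
            recomputed = sum(
                pair_score(a[2], b[2])
                for a, b in combinations(res.sites, 2)
            )
            assert recomputed == res.clique_weight

    def test_byte_identical_across_runs(self):
        spec = PlantSpec(k=8, n_min=25, n_max=30, consensus="TTAGGTGT",
                         mutation=0.03, seed=29)
        prom, _ = generate(spec)
        a = predict(prom, 8, p=0.005, M=30_000, seed=29).to_tsv()
        b = predict(prom, 8, p=0.005, M=30_000, seed=29).to_tsv()
        assert a == b
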
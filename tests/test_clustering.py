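from itertools import product

import numpy as np
import pytest

from oracles import average_linkage_bruteforce, cosine_bruteforce
from seegnet import (EventAnnotation, Phase, agglomerate, cosine_similarity,
                     electrode_of, similarity_distribution, similarity_vs_h2)
from seegnet.clustering import SimilarityMatrix
from seegnet.graphs import AdjacencyMatrix


def binary_adjacency(rows):
    rows = np.asarray(rows, dtype=float)
    labels = [f"V{i}" for i in range(rows.shape[0])]
    return AdjacencyMatrix(labels, rows, "binary")


def rows_with_overlap(deg_x, deg_y, overlap, width=12):
    """Two binary out-neighbour rows with given degrees and support overlap."""
    x = np.zeros(width)
    y = np.zeros(width)
    x[:deg_x] = 1
    y[:overlap] = 1
    y[deg_x:deg_x + deg_y - overlap] = 1
    assert x.sum() == deg_x and y.sum() == deg_y and (x * y).sum() == overlap
    return np.vstack([x, y])


class TestCosineSimilarity:
    def test_identical_nonzero_rows_are_parallel(self):
        S = cosine_similarity(binary_adjacency([[1, 0, 1], [1, 0, 1]]))
        assert S.S[0, 1] == pytest.approx(1.0)

    def test_disjoint_supports_are_orthogonal(self):
        S = cosine_similarity(binary_adjacency([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert S.S[0, 1] == 0.0

    @pytest.mark.parametrize("deg_x,deg_y,overlap,expected,decimals", [
        (3, 4, 3, 0.866025, 6),   # 3/sqrt(12)
        (2, 3, 2, 0.816497, 6),   # 2/sqrt(6)
        (1, 2, 1, 0.7071, 4),     # 1/sqrt(2)
        (1, 3, 1, 0.57735, 5),    # 1/sqrt(3)
        (3, 5, 2, 0.516398, 6),   # 2/sqrt(15)
        (1, 5, 1, 0.447214, 6),   # 1/sqrt(5)
        (2, 3, 1, 0.408248, 6),   # 1/sqrt(6)
        (2, 2, 1, 0.5, 1),
    ])
    def test_binary_row_closed_forms(self, deg_x, deg_y, overlap, expected,
                                     decimals):
        # the printed similarity values are overlap/sqrt(deg_x*deg_y)
        S = cosine_similarity(binary_adjacency(
            rows_with_overlap(deg_x, deg_y, overlap)))
        assert round(float(S.S[0, 1]), decimals) == expected

    def test_matches_bruteforce_on_random_binary_matrices(self, rng):
        for _ in range(20):
            M = rng.integers(0, 2, size=(8, 8)).astype(float)
            np.fill_diagonal(M, 0)
            S = cosine_similarity(AdjacencyMatrix(list("ABCDEFGH"), M, "binary"))
            assert np.max(np.abs(S.S - cosine_bruteforce(M))) < 1e-12

    def test_exhaustive_binary_closed_form_up_to_length_six(self):
        for vx in product([0, 1], repeat=6):
            for vy in product([0, 1], repeat=6):
                M = np.array([vx, vy], dtype=float)
                S = cosine_similarity(AdjacencyMatrix(["x", "y"], M, "binary"))
                dx, dy = sum(vx), sum(vy)
                ov = sum(a * b for a, b in zip(vx, vy))
                expect = ov / np.sqrt(dx * dy) if dx and dy else 0.0
                assert S.S[0, 1] == pytest.approx(expect, abs=1e-12)

    def test_invariant_under_positive_row_scaling(self, rng):
        M = rng.uniform(0, 1, size=(5, 5))
        np.fill_diagonal(M, 0)
        scaled = M * rng.uniform(0.5, 5.0, size=(5, 1))
        s1 = cosine_similarity(AdjacencyMatrix(list("ABCDE"), M, "weighted")).S
        s2 = cosine_similarity(AdjacencyMatrix(list("ABCDE"), scaled, "weighted")).S
        assert np.allclose(s1, s2, atol=1e-12)

    def test_zero_rows_have_zero_similarity_and_zero_diagonal(self):
        S = cosine_similarity(binary_adjacency([[0, 0, 0], [1, 1, 0]]))
        assert S.S[0, 0] == 0.0 and S.S[0, 1] == 0.0 and S.S[1, 1] == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cosine_similarity(AdjacencyMatrix(["a", "b"],
                                              np.array([[0, -1], [0, 0.0]]),
                                              "weighted"))


class TestAgglomerate:
    def test_two_identical_vertices_merge_at_zero(self):
        S = SimilarityMatrix(["A", "B"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        dend = agglomerate(S)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(0.0)

    def test_three_vertex_average_linkage_by_hand(self):
        # sigma(A,B)=0.9, sigma to C = 0.1 -> merge {A,B} at d=0.1, then C at 0.9
        S = SimilarityMatrix(list("ABC"), np.array([
            [1.0, 0.9, 0.1],
            [0.9, 1.0, 0.1],
            [0.1, 0.1, 1.0],
        ]))
        dend = agglomerate(S)
        assert [m[2] for m in dend.merges] == pytest.approx([0.1, 0.9])
        assert dend.merges[0][:2] == (0, 1)

    @pytest.mark.parametrize("tie_heavy", [False, True])
    def test_matches_naive_oracle_on_random_matrices(self, rng, tie_heavy):
        for _ in range(10):
            n = 8
            if tie_heavy:
                # binary-adjacency-derived similarities produce many exact ties
                M = rng.integers(0, 2, size=(n, n)).astype(float)
                np.fill_diagonal(M, 0)
                S = cosine_similarity(
                    AdjacencyMatrix([f"V{i}" for i in range(n)], M, "binary"))
            else:
                U = rng.uniform(0, 1, size=(n, n))
                sym = (U + U.T) / 2
                np.fill_diagonal(sym, 1.0)
                S = SimilarityMatrix([f"V{i}" for i in range(n)], sym)
            dend = agglomerate(S)
            oracle = average_linkage_bruteforce(S.labels, S.S)
            assert [(a, b) for a, b, *_ in dend.merges] == \
                   [(a, b) for a, b, *_ in oracle]
            assert np.allclose([m[2] for m in dend.merges],
                               [m[2] for m in oracle], atol=1e-12)

    def test_heights_match_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        U = rng.uniform(0.1, 0.9, size=(7, 7))
        sym = (U + U.T) / 2
        np.fill_diagonal(sym, 1.0)
        S = SimilarityMatrix([f"V{i}" for i in range(7)], sym)
        ours = sorted(m[2] for m in agglomerate(S).merges)
        scipys = sorted(linkage(squareform(1 - sym, checks=False),
                                method="average")[:, 2])
        assert np.allclose(ours, scipys, atol=1e-10)

    def test_heights_nondecreasing_and_bounded(self, rng):
        for _ in range(10):
            M = rng.integers(0, 2, size=(6, 6)).astype(float)
            np.fill_diagonal(M, 0)
            S = cosine_similarity(
                AdjacencyMatrix([f"V{i}" for i in range(6)], M, "binary"))
            h = agglomerate(S).heights()
            assert np.all(np.diff(h) >= -1e-12)
            assert np.all((h >= -1e-12) & (h <= 1 + 1e-12))

    def test_isolated_vertices_merge_last_at_one(self):
        M = np.array([[0, 1, 0, 0], [1, 0, 0, 0],
                      [0, 0, 0, 0], [0, 0, 0, 0.0]])
        S = cosine_similarity(AdjacencyMatrix(list("ABCD"), M, "binary"))
        dend = agglomerate(S)
        assert len(dend.merges) == 3
        assert dend.merges[-1][2] == pytest.approx(1.0)

    def test_newick_export_parses(self):
        import io

        from Bio import Phylo

        S = SimilarityMatrix(list("ABC"), np.array([
            [1.0, 0.8, 0.2], [0.8, 1.0, 0.2], [0.2, 0.2, 1.0]]))
        tree = Phylo.read(io.StringIO(agglomerate(S).to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]


class TestSimilarityDistribution:
    def test_single_pair_at_unit_similarity(self):
        S = SimilarityMatrix(["A", "B"], np.ones((2, 2)))
        dist = similarity_distribution([S])
        assert dist.counts == {1.0: 1}

    def test_zero_exclusion_flag(self):
        S = SimilarityMatrix(list("ABC"), np.array([
            [1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 0.0]]))
        assert similarity_distribution([S]).total() == 1
        assert similarity_distribution([S], include_zero=True).total() == 3

    def test_additivity_across_identical_events(self):
        S = SimilarityMatrix(list("ABC"), np.array([
            [1.0, 0.5, 0.25], [0.5, 1.0, 0.0], [0.25, 0.0, 0.0]]),
            event=EventAnnotation(1, Phase.onset, 0.0, 1.0))
        single = similarity_distribution([S], group_by_phase=True)
        triple = similarity_distribution([S] * 3, group_by_phase=True)
        for key, count in single.counts.items():
            assert triple.counts[key] == 3 * count

    def test_rounding_to_six_decimals(self):
        v = 1 / np.sqrt(2)
        S = SimilarityMatrix(["A", "B"], np.array([[1.0, v], [v, 1.0]]))
        dist = similarity_distribution([S])
        assert dist.counts == {0.707107: 1}


class TestSimilarityVsH2:
    def _fixtures(self):
        from seegnet.coupling import CouplingMatrix

        ev = EventAnnotation(1, Phase.onset, 0.0, 1.0)
        labels = ["LJ1", "LJ2", "LK1"]
        S = SimilarityMatrix(labels, np.array([
            [1.0, 0.6, 0.3], [0.6, 1.0, 0.2], [0.3, 0.2, 1.0]]), event=ev)
        vals = np.array([[np.nan, 0.2, 0.7],
                         [0.4, np.nan, 0.1],
                         [0.5, 0.3, np.nan]])
        cm = CouplingMatrix(labels, vals, np.zeros((3, 3), int), ev)
        return S, cm

    def test_same_electrode_pairs_filtered(self):
        S, cm = self._fixtures()
        df = similarity_vs_h2([S], [cm], different_electrode_only=True)
        assert set(df["pair"]) == {"LJ1-LK1", "LJ2-LK1"}

    def test_h2_is_direction_maximum(self):
        S, cm = self._fixtures()
        df = similarity_vs_h2([S], [cm], different_electrode_only=False)
        row = df[df.pair == "LJ1-LJ2"].iloc[0]
        assert row.h2 == pytest.approx(0.4)

    def test_join_on_shuffled_input(self):
        S, cm = self._fixtures()
        ev2 = EventAnnotation(2, Phase.onset, 0.0, 1.0)
        S2 = SimilarityMatrix(S.labels, S.S * 0.5, event=ev2)
        cm2 = type(cm)(cm.labels, cm.values * 0.5, cm.lags, ev2)
        df = similarity_vs_h2([S2, S], [cm, cm2],
                              different_electrode_only=False)
        for sid, scale in [(1, 1.0), (2, 0.5)]:
            row = df[(df.seizure_id == sid) & (df.pair == "LJ1-LJ2")].iloc[0]
            assert row.similarity == pytest.approx(0.6 * scale)
            assert row.h2 == pytest.approx(0.4 * scale)

    def test_missing_event_errors(self):
        S, cm = self._fixtures()
        S_orphan = SimilarityMatrix(S.labels, S.S,
                                    event=EventAnnotation(9, Phase.ictal2, 0, 1))
        with pytest.raises(ValueError, match="no coupling matrix"):
            similarity_vs_h2([S_orphan], [cm])


def test_electrode_prefix_parsing():
    assert electrode_of("LJ1") == "LJ"
    assert electrode_of("RF12") == "RF"
    assert electrode_of("X") == "X"
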
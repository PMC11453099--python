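"""Dynamic threshold, top-N selection, Ward clustering and the gap rule."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

from epimeta.calling import (
    Dendrogram,
    call_epitopes,
    cluster_residues,
    dynamic_threshold,
    optimal_cluster_count,
    prediction_table,
    select_top_n,
    ward_cluster,
)
from epimeta.fixtures import FixtureSpec, make_fixture
from epimeta.structure import surface_profile

from conftest import pseudo_structure


def ward_linkage_oracle(points: np.ndarray) -> list[float]:
    """Independent Ward linkage via the Lance-Williams update; merge heights."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    # active clusters: id -> size; distances kept in a dict keyed by frozenset
    sizes = {i: 1 for i in range(n)}
    dist = {
        frozenset((i, j)): float(np.linalg.norm(points[i] - points[j]))
        for i in range(n) for j in range(i)
    }
    heights = []
    next_id = n
    while len(sizes) > 1:
        pair = min(dist, key=dist.get)
        i, j = sorted(pair)
        d_ij = dist[pair]
        heights.append(d_ij)
        ni, nj = sizes[i], sizes[j]
        new = {}
        for k in sizes:
            if k in (i, j):
                continue
            nk = sizes[k]
            d_ik, d_jk = dist[frozenset((i, k))], dist[frozenset((j, k))]
            # Lance-Williams for Ward (distances, not squared): combine in
            # squared space and take the root
            t = ni + nj + nk
            d2 = ((ni + nk) / t * d_ik**2 + (nj + nk) / t * d_jk**2
                  - nk / t * d_ij**2)
            new[k] = np.sqrt(d2)
        dist = {p: d for p, d in dist.items() if not (p & {i, j})}
        for k, d in new.items():
            dist[frozenset((next_id, k))] = d
        del sizes[i], sizes[j]
        sizes[next_id] = ni + nj
        next_id += 1
    return heights


def cut_sweep_oracle(dendrogram: Dendrogram, k_max: int) -> int:
    """Pick k by literally sweeping horizontal cuts through the dendrogram.

    For every interval between consecutive merge heights, cut at the midpoint
    with scipy's distance criterion, count the clusters, and credit that count
    with the interval's vertical span.  The candidate set matches the rule:
    2..min(k_max, n-1), i.e. the all-singletons region below the first merge
    does not count as a clustering.  Ties break toward the smaller k.
    """
    cap = min(k_max, dendrogram.n_leaves - 1)
    h = np.concatenate([[0.0], dendrogram.heights])
    spans: dict[int, float] = {}
    for lo, hi in zip(h[:-1], h[1:]):
        if hi <= lo:
            continue
        labels = fcluster(dendrogram.merges, t=(lo + hi) / 2, criterion="distance")
        k = len(set(labels))
        if 2 <= k <= cap:
            spans[k] = spans.get(k, 0.0) + (hi - lo)
    return min(spans, key=lambda k: (-spans[k], k))


class TestDynamicThreshold:
    @pytest.mark.parametrize("R,expected", [(96, 24), (1, 6), (90, 24), (102, 24)])
    def test_values(self, R, expected):
        assert dynamic_threshold(R) == expected

    def test_monotone_over_full_range(self):
        values = [dynamic_threshold(R) for R in range(1, 1001)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_invalid_R(self):
        with pytest.raises(ValueError):
            dynamic_threshold(0)

    def test_rounding_modes(self):
        # 6.1 * 2**0.3 = 7.5099... : floor and nearest differ from ceil
        assert dynamic_threshold(2, rounding="floor") == 7
        assert dynamic_threshold(2, rounding="ceil") == 8
        assert dynamic_threshold(2, rounding="nearest") == 8


class TestSelectTopN:
    def test_basic(self):
        top = select_top_n(np.array([0.9, 0.1, 0.8]), 2)
        assert set(top) == {0, 2}

    def test_saturation(self):
        assert len(select_top_n(np.arange(5, dtype=float), 10)) == 5

    def test_tie_at_boundary_prefers_earlier_residue(self):
        scores = np.array([0.5, 0.9, 0.5, 0.5])
        top = select_top_n(scores, 2)
        # rank 1 is the 0.9; the tie among the 0.5s resolves to index 0
        assert list(top) == [1, 0]
        # deterministic under repetition and identical to a stable-sort oracle
        oracle = sorted(range(4), key=lambda i: (-scores[i], i))[:2]
        for _ in range(5):
            assert list(select_top_n(scores, 2)) == oracle

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_top_n(np.array([]), 1)


class TestWardCluster:
    def test_two_points_merge_at_euclidean_distance(self):
        d = 7.3
        dendro = ward_cluster(np.array([[0, 0, 0], [d, 0, 0]]))
        assert dendro.heights[0] == pytest.approx(d)

    @pytest.mark.parametrize("n,seed", [(6, 0), (8, 1), (10, 2)])
    def test_matches_lance_williams_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        points = rng.uniform(0, 30, size=(n, 3))
        dendro = ward_cluster(points)
        np.testing.assert_allclose(dendro.heights, ward_linkage_oracle(points),
                                   rtol=1e-8)

    def test_separated_blobs_merge_last_and_high(self):
        rng = np.random.default_rng(3)
        blob1 = rng.normal(0, 1.0, size=(8, 3))
        blob2 = rng.normal(0, 1.0, size=(8, 3)) + [60, 0, 0]
        dendro = ward_cluster(np.vstack([blob1, blob2]))
        assert dendro.heights[-1] >= 5 * dendro.heights[-2]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        dendro = ward_cluster(rng.uniform(0, 50, size=(20, 3)))
        assert np.all(np.diff(dendro.heights) >= 0)

    def test_degenerate_single_point(self):
        dendro = ward_cluster(np.array([[1.0, 2.0, 3.0]]))
        assert dendro.n_leaves == 1 and len(dendro.heights) == 0


class TestOptimalClusterCount:
    def test_printed_worked_example(self):
        # a dendrogram whose top three merge heights are 31, 71, 88
        heights = [5.0, 8.0, 12.0, 31.0, 71.0, 88.0]
        merges = np.array([[0, 1, h, 2] for h in heights])  # only heights matter
        dendro = Dendrogram(merges, n_leaves=7)
        k, gaps = optimal_cluster_count(dendro, k_max=8)
        assert k == 3
        assert gaps[3] == pytest.approx(40.0)
        assert gaps[2] == pytest.approx(17.0)

    def test_two_leaves(self):
        dendro = ward_cluster(np.array([[0, 0, 0], [5, 0, 0]]))
        k, gaps = optimal_cluster_count(dendro)
        assert k == 2

    def test_gaps_non_negative(self):
        rng = np.random.default_rng(6)
        dendro = ward_cluster(rng.uniform(0, 40, size=(25, 3)))
        _, gaps = optimal_cluster_count(dendro)
        assert all(g >= -1e-12 for g in gaps.values())

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_cut_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        dendro = ward_cluster(rng.uniform(0, 50, size=(n, 3)))
        k, _ = optimal_cluster_count(dendro, k_max=8)
        assert k == cut_sweep_oracle(dendro, k_max=8)


class TestCallEpitopes:
    def test_two_planted_patches_recovered(self):
        case = make_fixture(FixtureSpec(n_residues=150, n_patches=2, seed=11))
        profile = surface_profile(case.structure)
        scores = case.table.scores.mean(axis=1).to_numpy()  # simple consensus
        pred, clusters, _ = call_epitopes(case.structure, profile, scores)
        assert clusters.k == 2
        residue_clusters = cluster_residues(case.structure, pred, clusters)
        # each planted patch is mostly captured by one cluster
        for ann in case.annotations:
            best = max(
                len(set(c) & ann.residues) / len(ann.residues)
                for c in residue_clusters
            )
            assert best >= 0.5

    def test_cluster_partition_invariants(self):
        case = make_fixture(FixtureSpec(seed=13))
        profile = surface_profile(case.structure)
        scores = case.table.scores.mean(axis=1).to_numpy()
        pred, clusters, _ = call_epitopes(case.structure, profile, scores)
        member_union = set().union(*(set(m) for m in clusters.members))
        assert member_union == set(range(len(pred.top_indices)))
        assert sum(len(m) for m in clusters.members) == len(pred.top_indices)
        assert all(m for m in clusters.members)
        assert len(pred.top_indices) == pred.N

    def test_collinear_points_deterministic(self):
        coords = np.column_stack([np.arange(30) * 3.8, np.zeros(30), np.zeros(30)])
        structure = pseudo_structure(coords)
        profile = surface_profile(structure)
        scores = np.linspace(1, 0, 30)
        runs = [call_epitopes(structure, profile, scores) for _ in range(2)]
        ks = [c.k for _, c, _ in runs]
        assert ks[0] == ks[1]
        assert all(np.isfinite(list(runs[0][1].gap_table.values())))

    def test_prediction_table_shape(self):
        case = make_fixture(FixtureSpec(seed=17))
        profile = surface_profile(case.structure)
        scores = case.table.scores.mean(axis=1).to_numpy()
        pred, clusters, _ = call_epitopes(case.structure, profile, scores)
        df = prediction_table(case.structure, pred, clusters)
        assert len(df) == len(case.structure)
        assert df.in_top_n.sum() == pred.N
        assert set(df.loc[df.in_top_n == 1, "cluster_id"]) == set(range(1, clusters.k + 1))
        assert (df.loc[df.in_top_n == 0, "cluster_id"] == 0).all()
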
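"""Scaling, PCA, Ward hierarchy (vs an explicit-SSE oracle) and cluster-number
selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vtaclust.clustering import (
    ClusteringError,
    dunn_index,
    pca_svd,
    prefilter_high_firing,
    scale_minmax,
    select_cluster_number,
    ward_cluster,
    ward_linkage,
)
from vtaclust.io import FEATURE_COLUMNS


def _feat(rates, **cols):
    n = len(rates)
    data = {
        "firing_rate_hz": rates,
        "cv": cols.get("cv", np.full(n, 0.2)),
        "pct_sib": cols.get("pct_sib", np.zeros(n)),
        "ap_dur_ms": cols.get("ap", np.full(n, 2.8)),
        "dt1_ms": cols.get("dt1", np.full(n, 1.0)),
        "notch": cols.get("notch", np.zeros(n)),
    }
    return pd.DataFrame(data, index=[f"n{i}" for i in range(n)])


class TestPrefilter:
    def test_partition(self):
        high, rest = prefilter_high_firing(_feat([19.5, 2.1, 3.3]))
        assert list(high.index) == ["n0"]
        assert list(rest.index) == ["n1", "n2"]

    def test_exactly_10_goes_to_rest(self):
        high, rest = prefilter_high_firing(_feat([10.0, 12.0]))
        assert list(rest.index) == ["n0"]

    def test_all_below_threshold(self):
        high, rest = prefilter_high_firing(_feat([1.0, 2.0, 3.0]))
        assert high.empty and len(rest) == 3


class TestScaleMinmax:
    def test_linear_map(self):
        s = scale_minmax(_feat([2.0, 4.0, 6.0]))
        assert list(s["firing_rate_hz"]) == [0.0, 0.5, 1.0]

    def test_binary_column_unchanged(self):
        s = scale_minmax(_feat([1.0, 2.0], notch=np.array([0.0, 1.0])))
        assert list(s["notch"]) == [0.0, 1.0]

    def test_constant_column_to_zero_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            s = scale_minmax(_feat([1.0, 2.0, 3.0]))
        assert (s["ap_dur_ms"] == 0).all()
        assert any("constant" in r.message for r in caplog.records)

    @given(arrays(np.float64, (7, 3),
                  elements=st.floats(-50, 50, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_range_and_idempotence(self, x):
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        once = scale_minmax(df)
        assert ((once >= 0) & (once <= 1)).all().all()
        pd.testing.assert_frame_equal(scale_minmax(once), once)


class TestPCA:
    def test_rank_one_limit(self):
        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        res = pca_svd(df)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_split(self, rng):
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        frac = pca_svd(df).explained_variance_fraction
        assert frac[0] == pytest.approx(0.5, abs=0.02)
        assert frac[1] == pytest.approx(0.5, abs=0.02)

    def test_reconstruction_and_invariants(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)), columns=list(FEATURE_COLUMNS))
        res = pca_svd(df)
        centered = df.to_numpy() - df.to_numpy().mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-9)
        frac = res.explained_variance_fraction
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(frac) <= 1e-12).all()
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-9)
        # loadings orthonormal
        v = res.loadings.to_numpy()
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-9)


# ---------------------------------------------------------------------------
# Ward hierarchy vs explicit-SSE greedy oracle
# ---------------------------------------------------------------------------

def _ward_oracle(points):
    """Greedy Ward agglomeration computed from first principles: at each step
    merge the pair of clusters whose union minimizes the increase in total
    within-cluster sum of squares. Heights on the Euclidean (Ward.D2) scale:
    sqrt(2 * delta-SSE). Returns (merge heights, partition after each merge).
    """
    def sse(idx):
        p = points[list(idx)]
        return ((p - p.mean(axis=0)) ** 2).sum()

    clusters = [frozenset([i]) for i in range(len(points))]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = sse(clusters[i] | clusters[j]) - sse(clusters[i]) - sse(clusters[j])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        heights.append(np.sqrt(2 * d))
        partitions.append(frozenset(clusters))
    return heights, partitions


def _partitions_from_dendrogram(dend, n):
    parts = []
    members = {i: frozenset([i]) for i in range(n)}
    for j, (a, b, h, _) in enumerate(dend.merges):
        members[n + j] = members[int(a)] | members[int(b)]
        alive = [v for k, v in members.items()
                 if not any(v < w for w in members.values())]
        parts.append(frozenset(alive))
    return parts


class TestWard:
    def test_one_dimensional_example(self):
        dend = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        labels = dend.cut(2)
        assert labels[0] == labels[1] != labels[2]

    def test_rectangle_merges_short_sides_first(self):
        # 1 x 100 rectangle: the two short-side (length-1) pairs merge first
        pts = np.array([[0, 0], [0, 1], [100, 0], [100, 1]], dtype=float)
        dend = ward_linkage(pts)
        first_two = {frozenset(map(int, dend.merges[i, :2])) for i in range(2)}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_matches_explicit_sse_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            pts = rng.normal(size=(n, int(rng.integers(1, 4))))
            dend = ward_linkage(pts)
            oracle_h, oracle_parts = _ward_oracle(pts)
            np.testing.assert_allclose(dend.merges[:, 2], oracle_h, rtol=1e-8)
            assert _partitions_from_dendrogram(dend, n) == oracle_parts

    def test_heights_nondecreasing_and_newick(self, rng):
        pts = rng.normal(size=(12, 3))
        dend = ward_linkage(pts, ids=tuple(f"n{i}" for i in range(12)))
        assert (np.diff(dend.merges[:, 2]) >= -1e-9).all()
        nwk = dend.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 11

    def test_row_shuffle_invariance(self, rng):
        df = _feat(rng.uniform(1, 5, 12),
                   pct_sib=rng.uniform(0, 40, 12),
                   cv=rng.uniform(0.1, 0.5, 12))
        scaled = scale_minmax(df)
        _, a = ward_cluster(scaled, 3)
        perm = rng.permutation(12)
        _, b = ward_cluster(scaled.iloc[perm], 3)
        sa, sb = a.series(), b.series()
        # same partition up to label permutation
        pairs = {(sa[i], sb[i]) for i in sa.index}
        assert len({x for x, _ in pairs}) == len(pairs) == len({y for _, y in pairs})

    def test_shift_of_raw_column_absorbed_by_scaling(self, rng):
        df = _feat(rng.uniform(1, 5, 10), pct_sib=rng.uniform(0, 40, 10))
        shifted = df.copy()
        shifted["firing_rate_hz"] += 37.0
        _, a = ward_cluster(scale_minmax(df), 2)
        _, b = ward_cluster(scale_minmax(shifted), 2)
        pairs = {(a.labels[i], b.labels[i]) for i in a.labels}
        assert len({x for x, _ in pairs}) == len(pairs)

    def test_k_bounds(self):
        with pytest.raises(ClusteringError):
            ward_cluster(scale_minmax(_feat([1.0, 2.0, 3.0])), 4)


class TestClusterNumberSelection:
    def _blobs(self, centers, n_per, rng, spread=0.05):
        pts = np.vstack([rng.normal(c, spread, size=(n_per, 6)) for c in centers])
        return pd.DataFrame(pts, columns=list(FEATURE_COLUMNS),
                            index=[f"n{i}" for i in range(len(pts))])

    def test_two_blobs(self, rng):
        df = self._blobs([0.1, 0.9], 20, rng)
        rep = select_cluster_number(df, range(2, 8), notch_weight=1.0)
        assert rep.selected_k == 2
        assert sum(rep.votes.values()) == 4

    def test_three_blobs(self, rng):
        df = self._blobs([0.1, 0.5, 0.9], 15, rng)
        rep = select_cluster_number(df, range(2, 8), notch_weight=1.0)
        assert rep.selected_k == 3
        assert rep.per_index_choice["silhouette"] == 3

    def test_identical_rows_rejected(self):
        df = pd.DataFrame(np.ones((12, 6)), columns=list(FEATURE_COLUMNS))
        with pytest.raises(ClusteringError, match="identical"):
            select_cluster_number(df, range(2, 5))

    def test_dunn_index_well_separated(self):
        dist = np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]],
                        dtype=float)
        assert dunn_index(dist, np.array([0, 0, 1, 1])) == pytest.approx(9.0)
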
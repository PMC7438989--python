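"""Nonparametric group comparisons, contingency tests, log-normal checks and
the Table-style cluster summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from vtaclust.clustering import ClusterAssignment
from vtaclust.stats import (
    StatsError,
    chi_square_contingency,
    cluster_summary,
    kruskal_wallis_dunn,
    lognormal_check,
)


class TestKruskalWallisDunn:
    def test_identical_groups_null(self):
        g = np.array([1.0, 2.0, 3.0])
        r = kruskal_wallis_dunn([g, g, g])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.pvalue == pytest.approx(1.0)

    def test_no_tie_closed_form(self):
        r = kruskal_wallis_dunn([np.array([1, 2, 3]), np.array([4, 5, 6]),
                                 np.array([7, 8, 9])])
        assert r.statistic == pytest.approx(7.2)
        assert r.df == 2

    def test_group_permutation_symmetry(self):
        rng = np.random.default_rng(1)
        gs = [rng.normal(m, 1, 12) for m in (0, 0.5, 2)]
        a = kruskal_wallis_dunn(gs, ["x", "y", "z"])
        b = kruskal_wallis_dunn(gs[::-1], ["z", "y", "x"])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)
        pa = a.pairwise.set_index(["group_a", "group_b"])["p_adj"]
        pb = b.pairwise.set_index(["group_b", "group_a"])["p_adj"]
        assert pa[("x", "y")] == pytest.approx(pb[("x", "y")])

    @given(st.sampled_from(["exp", "cube", "logistic"]))
    @settings(max_examples=10, deadline=None)
    def test_invariant_under_monotone_transforms(self, name):
        rng = np.random.default_rng(7)
        gs = [rng.normal(m, 1, 15) for m in (0, 1, 1.5)]
        fn = {"exp": np.exp, "cube": lambda x: x**3,
              "logistic": lambda x: 1 / (1 + np.exp(-x))}[name]
        a = kruskal_wallis_dunn(gs)
        b = kruskal_wallis_dunn([fn(g) for g in gs])
        assert a.statistic == pytest.approx(b.statistic)

    def test_adjusted_geq_raw(self):
        rng = np.random.default_rng(2)
        r = kruskal_wallis_dunn([rng.normal(m, 1, 10) for m in (0, 1, 2, 3)])
        assert (r.pairwise["p_adj"] >= r.pairwise["p_raw"] - 1e-15).all()
        assert (r.pairwise["p_adj"] <= 1.0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError, match="empty"):
            kruskal_wallis_dunn([np.array([1.0]), np.array([])])

    def test_dunn_z_against_hand_formula(self):
        # no ties: z = (R1-R2) / sqrt(N(N+1)/12 * (1/n1+1/n2))
        g1, g2, g3 = np.array([1, 2, 3.0]), np.array([4, 5, 6.0]), np.array([7, 8, 9.0])
        r = kruskal_wallis_dunn([g1, g2, g3])
        z12 = r.pairwise.iloc[0]["z"]
        expect = (2 - 5) / np.sqrt(9 * 10 / 12 * (2 / 3))
        assert z12 == pytest.approx(expect)


class TestChiSquare:
    def test_published_notch_table(self):
        # notched / not-notched counts of the two non-high-firing clusters
        r = chi_square_contingency([[102, 103], [34, 30]])
        assert r.pvalue == pytest.approx(0.64, abs=0.01)

    def test_uniform_table_null(self):
        r = chi_square_contingency([[50, 50], [50, 50]])
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_perfect_association(self):
        r = chi_square_contingency([[10, 0], [0, 10]])
        assert r.statistic == pytest.approx(20.0)
        assert r.df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(StatsError, match="marginal"):
            chi_square_contingency([[0, 0], [5, 5]])

    def test_matches_closed_form_exhaustively(self):
        # all 2x2 tables with margins <= 12 vs chi2 = N(ad-bc)^2/(r1 r2 c1 c2)
        for a in range(13):
            for b in range(13 - a):
                for c in range(13):
                    for d in range(13 - c):
                        if not (a + b and c + d and a + c and b + d):
                            continue
                        n = a + b + c + d
                        expect = n * (a * d - b * c) ** 2 / (
                            (a + b) * (c + d) * (a + c) * (b + d))
                        r = chi_square_contingency([[a, b], [c, d]])
                        assert r.statistic == pytest.approx(expect, abs=1e-10)

    def test_matches_scipy_sample(self, rng):
        # independent oracle, including a 2xk case and Yates
        for _ in range(200):
            t = rng.integers(1, 30, size=(2, int(rng.integers(2, 5))))
            ours = chi_square_contingency(t)
            ref = sps.chi2_contingency(t, correction=False)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.pvalue == pytest.approx(ref.pvalue)
        t = rng.integers(1, 30, size=(2, 2))
        ours = chi_square_contingency(t, yates=True)
        ref = sps.chi2_contingency(t, correction=True)
        assert ours.statistic == pytest.approx(ref.statistic)


class TestLogNormalCheck:
    def test_lognormal_sample_accepted(self):
        rng = np.random.default_rng(11)
        accept = sum(
            lognormal_check(np.exp(rng.normal(0, 1, 500))).shapiro_p > 0.05
            for _ in range(100))
        # nominal 5% rejections under the null, so ~95 acceptances expected
        assert accept >= 85

    def test_uniform_sample_smoke(self, rng):
        fit = lognormal_check(rng.uniform(1, 2, 100))
        assert np.isfinite(fit.mu) and fit.sigma > 0 and 0 <= fit.shapiro_p <= 1

    def test_zero_value_rejected_with_ids(self):
        with pytest.raises(StatsError, match="zeroguy"):
            lognormal_check(np.array([1.0, 0.0] + [2.0] * 10),
                            ids=["a", "zeroguy"] + [f"x{i}" for i in range(10)])


def _features_df(ids, rates, pct=None, notch=None):
    n = len(ids)
    return pd.DataFrame({
        "firing_rate_hz": rates,
        "cv": np.full(n, 0.2),
        "pct_sib": pct if pct is not None else np.zeros(n),
        "ap_dur_ms": np.full(n, 2.8),
        "dt1_ms": np.full(n, 1.0),
        "notch": notch if notch is not None else np.zeros(n),
    }, index=ids)


class TestClusterSummary:
    def test_two_point_sem(self):
        feat = _features_df(["a", "b"], [2.0, 4.0])
        asg = ClusterAssignment({"a": 1, "b": 1}, 1)
        s = cluster_summary(feat, asg, feat.iloc[0:0])
        assert s.loc[1, "firing_rate_mean"] == pytest.approx(3.0)
        assert s.loc[1, "firing_rate_sem"] == pytest.approx(1.0)

    def test_numbering_high_first_then_by_burst(self):
        ids = [f"n{i}" for i in range(6)]
        feat = _features_df(ids, [19, 22, 2, 2, 3, 3],
                            pct=[0, 0, 1, 2, 30, 40])
        high = feat.iloc[:2]
        asg = ClusterAssignment({"n2": 1, "n3": 1, "n4": 2, "n5": 2}, 2)
        s = cluster_summary(feat, asg, high)
        assert list(s.index) == [1, 2, 3]
        assert s.loc[1, "firing_rate_mean"] > 10
        assert s.loc[2, "pct_sib_mean"] < s.loc[3, "pct_sib_mean"]
        assert s.loc[3, "n_bursting"] == 2

    def test_row_order_invariance(self, rng):
        ids = [f"n{i}" for i in range(8)]
        feat = _features_df(ids, rng.uniform(1, 4, 8), pct=rng.uniform(0, 40, 8))
        asg = ClusterAssignment({i: 1 + (k % 2) for k, i in enumerate(ids)}, 2)
        a = cluster_summary(feat, asg, feat.iloc[0:0])
        b = cluster_summary(feat.iloc[::-1], asg, feat.iloc[0:0])
        pd.testing.assert_frame_equal(a, b)

    def test_sem_scales_linearly(self):
        feat = _features_df(["a", "b", "c"], [2.0, 3.0, 5.0])
        scaled = feat.copy()
        scaled["firing_rate_hz"] *= 10
        asg = ClusterAssignment({"a": 1, "b": 1, "c": 1}, 1)
        s1 = cluster_summary(feat, asg, feat.iloc[0:0])
        s2 = cluster_summary(scaled, asg, feat.iloc[0:0])
        assert s2.loc[1, "firing_rate_sem"] == pytest.approx(
            10 * s1.loc[1, "firing_rate_sem"])

    def test_nothing_to_summarize(self):
        feat = _features_df(["a"], [2.0])
        with pytest.raises(StatsError, match="nothing"):
            cluster_summary(feat, None, feat.iloc[0:0])


class TestCohortDistributions:
    def test_rates_lognormal_within_populations(self, cohort_features):
        feat, gt = cohort_features
        for label in ("cluster2", "cluster3"):
            rates = feat.loc[gt["true_label"] == label, "firing_rate_hz"]
            fit = lognormal_check(rates.to_numpy())
            assert fit.shapiro_p > 0.01

    def test_table_recovery_on_shared_cohort(self, cohort_features):
        """Group means of the generated cohort recover the preset targets."""
        feat, gt = cohort_features
        by = feat.groupby(gt["true_label"])
        assert by["firing_rate_hz"].mean()["cluster1"] == pytest.approx(19.47, rel=0.10)
        assert by["pct_sib"].mean()["cluster3"] == pytest.approx(37.97, rel=0.10)
        assert by["dt1_ms"].mean()["cluster1"] == pytest.approx(0.60, rel=0.10)
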
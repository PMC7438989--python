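"""Cluster characterization and distributional checks.

Group comparisons follow nonparametric practice for skewed
electrophysiological variables: Kruskal-Wallis one-way ANOVA on ranks with
Dunn's post hoc z-tests (Bonferroni-adjusted), Pearson chi-square for
contingency tables (no continuity correction by default), and log-normality
checks via Shapiro-Wilk on log10-transformed values. Summaries are
mean +/- SEM per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import ClusterAssignment, as_feature_matrix


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    pvalue: float
    pairwise: pd.DataFrame | None = None   # rows: (group_a, group_b, z, p_raw, p_adj)


def kruskal_wallis_dunn(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
) -> TestResult:
    """Kruskal-Wallis H (tie-corrected, chi-square p on k-1 df) followed by
    Dunn's pairwise z-tests on mean ranks.

    Dunn's z for groups i, j uses the pooled-rank variance
    ``(N(N+1)/12 - T) * (1/n_i + 1/n_j)`` with tie term
    ``T = sum(t^3 - t) / (12(N-1))``; two-sided normal p-values are
    Bonferroni-adjusted over all pairs (the default; "none" disables).
    """
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise StatsError("empty group")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise StatsError("need >= 3 observations in total")

    h, p = sps.kruskal(*groups)
    k = len(groups)

    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i]: idx[i + 1]].mean() for i in range(k)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    pairs = list(combinations(range(k), 2))
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * len(pairs)) if adjust == "bonferroni" else p_raw
        rows.append((labels[i], labels[j], z, p_raw, p_adj))
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "z", "p_raw", "p_adj"]
    )
    return TestResult(float(h), float(k - 1), float(p), pairwise)


def chi_square_contingency(table: np.ndarray, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default. df = (r-1)(c-1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise StatsError("table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise StatsError("zero marginal in contingency table")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(chi2, float(df), float(sps.chi2.sf(chi2, df)))


@dataclass(frozen=True)
class LogNormalFit:
    """Location/scale of log10 values plus a Shapiro-Wilk check on the logs."""

    mu: float
    sigma: float
    shapiro_w: float
    shapiro_p: float


def lognormal_check(values: np.ndarray, ids: list[str] | None = None) -> LogNormalFit:
    """Fit log10 values and test their normality (Shapiro-Wilk).

    All values must be strictly positive — zeros (non-bursting neurons, say)
    must be excluded by the caller, mirroring how burst-activity
    distributions are assessed only over neurons that burst.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise StatsError("need >= 8 values for a log-normal check")
    bad = np.nonzero(x <= 0)[0]
    if bad.size:
        names = [ids[i] for i in bad] if ids is not None else bad.tolist()
        raise StatsError(f"non-positive values for {names[:10]}")
    logs = np.log10(x)
    w, p = sps.shapiro(logs)
    return LogNormalFit(float(logs.mean()), float(logs.std(ddof=1)), float(w), float(p))


# ---------------------------------------------------------------------------
# cluster summary (Table-1-style)
# ---------------------------------------------------------------------------

def _sem(x: pd.Series) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def cluster_summary(
    features: pd.DataFrame,
    assignment: ClusterAssignment | None,
    high: pd.DataFrame,
) -> pd.DataFrame:
    """Per-group mean +/- SEM table, one row per cluster.

    The pre-filtered high-firing group is numbered cluster 1; the clustered
    groups follow in ascending order of mean burst activity. Columns report
    n, mean and SEM of the four continuous features plus counts of bursting
    (pct_sib > 0) and notched neurons.
    """
    features = as_feature_matrix(features)
    groups: list[pd.DataFrame] = []
    if len(high):
        groups.append(as_feature_matrix(high))
    if assignment is not None:
        labels = assignment.series()
        extra = set(labels.index) - set(features.index)
        if extra:
            raise StatsError(f"assignment contains unknown neurons {sorted(extra)[:5]}")
        clustered = features.loc[labels.index]
        parts = [clustered[labels == c] for c in sorted(labels.unique())]
        if any(len(p) == 0 for p in parts):
            raise StatsError("empty cluster in assignment")
        parts.sort(key=lambda p: p["pct_sib"].mean())
        groups.extend(parts)
    if not groups:
        raise StatsError("nothing to summarize: no high group and no assignment")

    rows = {}
    for number, part in enumerate(groups, start=1):
        rows[number] = {
            "n": len(part),
            "firing_rate_mean": part["firing_rate_hz"].mean(),
            "firing_rate_sem": _sem(part["firing_rate_hz"]),
            "cv_mean": part["cv"].mean(),
            "cv_sem": _sem(part["cv"]),
            "pct_sib_mean": part["pct_sib"].mean(),
            "pct_sib_sem": _sem(part["pct_sib"]),
            "n_bursting": int((part["pct_sib"] > 0).sum()),
            "ap_dur_mean": part["ap_dur_ms"].mean(),
            "ap_dur_sem": _sem(part["ap_dur_ms"]),
            "dt1_mean": part["dt1_ms"].mean(),
            "dt1_sem": _sem(part["dt1_ms"]),
            "n_notch": int((part["notch"] > 0).sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cluster"
    return out


def characterize_clusters(
    features: pd.DataFrame,
    assignment: ClusterAssignment | None,
    high: pd.DataFrame,
) -> dict:
    """Summary table plus the standard battery of group comparisons.

    Kruskal-Wallis + Dunn on rate, burst %, AP and delta-t1 durations across
    all groups (high-firing group included as its own cluster), and a
    chi-square on the notched/non-notched contingency of the clustered
    groups (mirroring how notch prevalence is compared between the two
    non-high-firing populations).
    """
    summary = cluster_summary(features, assignment, high)
    parts: list[pd.DataFrame] = []
    names: list[str] = []
    if len(high):
        parts.append(as_feature_matrix(high))
        names.append("cluster1")
    if assignment is not None:
        labels = assignment.series()
        clustered = features.loc[labels.index]
        sub = [clustered[labels == c] for c in sorted(labels.unique())]
        sub.sort(key=lambda p: p["pct_sib"].mean())
        start = len(parts)
        parts.extend(sub)
        names.extend(f"cluster{start + i + 1}" for i in range(len(sub)))

    tests: dict[str, TestResult] = {}
    if len(parts) >= 2:
        for col, key in [("firing_rate_hz", "firing_rate"), ("pct_sib", "pct_sib"),
                         ("ap_dur_ms", "ap_duration"), ("dt1_ms", "dt1")]:
            tests[key] = kruskal_wallis_dunn(
                [p[col].to_numpy() for p in parts], names)
    if assignment is not None and assignment.k >= 2:
        sub = parts[-assignment.k:]
        notch_table = np.array(
            [[int((p["notch"] > 0).sum()), int((p["notch"] == 0).sum())] for p in sub]
        ).T
        tests["notch_contingency"] = chi_square_contingency(notch_table)
    return {"summary": summary, "tests": tests}
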
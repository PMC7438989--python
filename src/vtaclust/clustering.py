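"""Unsupervised classification of the six-feature matrix.

Pipeline order: partition out high-firing units (>10 Hz, putatively
GABAergic), min-max scale each feature to [0, 1], check dimensionality with
PCA (SVD), choose the number of clusters by a majority vote of internal
validity indices led by the silhouette, and cut a Ward (minimum-variance,
Euclidean — the Ward.D2 dialect) dendrogram at that number.

The binary notch column is down-weighted (default 0.25) before distance
computations. After min-max scaling a 0/1 column spans the full unit range
while the continuous features' informative spread is a fraction of theirs,
so at full weight an uninformative binary dichotomy dominates the Euclidean
metric and the hierarchy reproduces it instead of the firing-pattern
structure. Set ``notch_weight=1.0`` to restore the plain 0/1 encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .io import FEATURE_COLUMNS

logger = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


def as_feature_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and column-order a six-feature matrix (index = neuron ids)."""
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ClusteringError(f"feature matrix lacks columns {sorted(missing)}")
    df = df[list(FEATURE_COLUMNS)].astype(float)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ClusteringError(f"missing values for neurons {bad}")
    if df.index.has_duplicates:
        raise ClusteringError("duplicate neuron ids")
    return df


def prefilter_high_firing(
    features: pd.DataFrame, threshold_hz: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition neurons into (high-firing, rest) by rate strictly above
    *threshold_hz*. A rate of exactly 10 Hz goes to *rest*."""
    features = as_feature_matrix(features)
    mask = features["firing_rate_hz"] > threshold_hz
    return features[mask], features[~mask]


def scale_minmax(m: pd.DataFrame) -> pd.DataFrame:
    """Map each column to [0, 1] by (x - min)/(max - min).

    Constant columns map to 0 (with a logged warning). Idempotent: columns
    already spanning [0, 1] — including binary 0/1 — are unchanged.
    """
    if len(m) < 2:
        raise ClusteringError("min-max scaling needs >= 2 rows")
    lo, hi = m.min(axis=0), m.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        logger.warning("constant feature columns mapped to 0: %s",
                       list(m.columns[const]))
    span = span.where(~const, 1.0)
    return (m - lo) / span


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and explained-variance fractions from SVD."""

    scores: pd.DataFrame               # neurons x components
    loadings: pd.DataFrame             # features x components
    explained_variance_fraction: np.ndarray


def pca_svd(scaled: pd.DataFrame) -> PCAResult:
    """PCA of the (scaled) feature matrix via singular value decomposition.

    Columns are centered; variance fractions are sigma_j^2 / sum sigma^2.
    Component signs are fixed so each component's largest-magnitude loading
    is positive.
    """
    if len(scaled) < 2:
        raise ClusteringError("PCA needs >= 2 rows")
    x = scaled.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    frac = s**2 / (s**2).sum() if s.any() else np.zeros_like(s)
    comps = [f"PC{i + 1}" for i in range(s.size)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=scaled.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=scaled.columns, columns=comps),
        explained_variance_fraction=frac,
    )


# ---------------------------------------------------------------------------
# Ward hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Ward merge table (scipy linkage convention) plus leaf ids.

    Each merge row is (node_a, node_b, height, size); leaves are numbered
    0..n-1 in ``leaf_ids`` order, internal nodes n, n+1, ... in merge order.
    Heights are on the Euclidean scale (Ward.D2).
    """

    merges: np.ndarray
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ClusteringError("merge table must have n-1 rows")
        h = self.merges[:, 2]
        if np.any(np.diff(h) < -1e-9):
            raise ClusteringError("Ward merge heights must be non-decreasing")

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) at k clusters."""
        return fcluster(self.merges, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaf_ids[i] for i in range(n)}
        for j, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = (h - height[a]) / 2
            lb = (h - height[b]) / 2
            node[n + j] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + j] = h
        return node[n + len(self.merges) - 1] + ";"

    def to_json_table(self) -> list[dict]:
        return [
            {"node_a": int(a), "node_b": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.merges
        ]


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat labels (neuron id -> cluster id 1..k)."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        if len(set(self.labels.values())) != self.k:
            raise ClusteringError("assignment must have exactly k non-empty clusters")

    def series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster").sort_index()


def _weighted(scaled: pd.DataFrame, notch_weight: float) -> pd.DataFrame:
    out = scaled.copy()
    if "notch" in out.columns and notch_weight != 1.0:
        out["notch"] = out["notch"] * notch_weight
    return out


def ward_linkage(points: np.ndarray, ids: tuple[str, ...] | None = None) -> Dendrogram:
    """Ward minimum-variance hierarchy on Euclidean distances (Ward.D2)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ClusteringError("need a 2-D matrix with >= 2 rows")
    if ids is None:
        ids = tuple(str(i) for i in range(len(points)))
    z = linkage(points, method="ward")
    return Dendrogram(z, tuple(ids))


def ward_cluster(
    scaled: pd.DataFrame, k: int, notch_weight: float = 0.25
) -> tuple[Dendrogram, ClusterAssignment]:
    """Cut the Ward hierarchy of the scaled feature matrix at *k* clusters."""
    n = len(scaled)
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} outside 1..{n}")
    dend = ward_linkage(_weighted(scaled, notch_weight).to_numpy(),
                        tuple(scaled.index.astype(str)))
    labels = dend.cut(k)
    assignment = ClusterAssignment(
        dict(zip(dend.leaf_ids, (int(x) for x in labels))), int(labels.max())
    )
    return dend, assignment


# ---------------------------------------------------------------------------
# cluster-number selection
# ---------------------------------------------------------------------------

def dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum cluster diameter."""
    groups = [np.nonzero(labels == g)[0] for g in np.unique(labels)]
    diam = max((dist[np.ix_(g, g)].max() if g.size > 1 else 0.0) for g in groups)
    sep = min(
        dist[np.ix_(a, b)].min()
        for i, a in enumerate(groups)
        for b in groups[i + 1 :]
    )
    if diam == 0:
        return np.inf
    return float(sep / diam)


#: index name -> (scorer(X, dist, labels), maximize?)
_INDICES = {
    "silhouette": (lambda x, d, l: silhouette_score(x, l, metric="euclidean"), True),
    "calinski_harabasz": (lambda x, d, l: calinski_harabasz_score(x, l), True),
    "davies_bouldin": (lambda x, d, l: davies_bouldin_score(x, l), False),
    "dunn": (lambda x, d, l: dunn_index(d, l), True),
}


@dataclass(frozen=True)
class ClusterNumberReport:
    """Per-index optima, vote counts and the selected number of clusters."""

    k_range: tuple[int, ...]
    per_index_choice: dict[str, int]
    votes: dict[int, int]
    selected_k: int
    silhouette_by_k: dict[int, float]
    index_table: pd.DataFrame          # index values, rows = k


def select_cluster_number(
    scaled: pd.DataFrame,
    k_range: range | tuple[int, ...] = range(2, 11),
    indices: tuple[str, ...] = ("silhouette", "calinski_harabasz",
                                "davies_bouldin", "dunn"),
    notch_weight: float = 0.25,
) -> ClusterNumberReport:
    """Choose k by majority vote of internal validity indices.

    For each k the Ward tree is cut and every index scored on Euclidean
    distances; each index votes for its own optimum. Ties are broken by the
    mean silhouette width at the candidate k, then by the smaller k.
    """
    ks = tuple(k_range)
    x = _weighted(scaled, notch_weight).to_numpy()
    n = len(x)
    if n <= max(ks):
        raise ClusteringError(f"need more than {max(ks)} rows, got {n}")
    if np.allclose(pdist(x), 0):
        raise ClusteringError("all rows identical: cluster structure undefined")
    dist = squareform(pdist(x))
    z = linkage(x, method="ward")
    scores: dict[str, dict[int, float]] = {name: {} for name in indices}
    sil: dict[int, float] = {}
    for k in ks:
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        for name in indices:
            fn, _ = _INDICES[name]
            scores[name][k] = float(fn(x, dist, labels))
        sil[k] = scores.get("silhouette", {}).get(
            k, float(silhouette_score(x, labels)))
    choice = {}
    for name in indices:
        _, maximize = _INDICES[name]
        items = scores[name]
        pick = (max if maximize else min)(items, key=lambda k: (items[k], -k))
        choice[name] = int(pick)
    votes: dict[int, int] = {}
    for k in choice.values():
        votes[k] = votes.get(k, 0) + 1
    top = max(votes.values())
    tied = sorted(k for k, v in votes.items() if v == top)
    selected = min(tied, key=lambda k: (-sil[k], k))
    table = pd.DataFrame(scores).reindex(list(ks))
    table.index.name = "k"
    return ClusterNumberReport(ks, choice, votes, int(selected), sil, table)
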
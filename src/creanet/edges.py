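"""Edge-centric functional connectivity analysis.

From parcellated region-by-time BOLD matrices this module builds edge
co-fluctuation time series (pointwise products of z-scored node signals),
clusters edges into communities with k-means over a range of k, and maps
edge-community structure back onto nodes as

* **overlap** — the normalized entropy of the community labels among a
  node's incident edges (0 = all edges in one community, 1 = edges
  spread uniformly over all k communities), and
* **similarity** — for two nodes, the fraction of other nodes m at which
  their incident edges (m,i) and (m,j) carry the same community label.

The construction has one load-bearing identity: with population-SD
z-scoring, the time average of an edge series equals the Pearson
correlation of its node pair, so edge time series "unwrap" functional
connectivity over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "RegionTimeSeries",
    "EdgeIndex",
    "EdgeTimeSeries",
    "EdgeCommunityAssignment",
    "zscore",
    "concatenate_trials",
    "condition_difference",
    "edge_time_series",
    "group_average",
    "edge_fc",
    "cluster_edges",
    "node_community_matrix",
    "overlap_entropy",
    "community_similarity",
    "within_network_similarity",
    "average_over_k",
]

@dataclass
class RegionTimeSeries:
    """N regions x T time points with atlas network labels."""

    data: np.ndarray
    atlas: list[str] | None = None
    subject: str | None = None
    condition: str | None = None
    trial: int | None = None
    z_scored: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x time)")
        n, t = self.data.shape
        if n < 3 or t < 2:
            raise ValueError(f"need N >= 3 regions and T >= 2 time points, got {n}x{t}")
        if self.atlas is not None and len(self.atlas) != n:
            raise ValueError("atlas length must equal number of regions")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EdgeIndex:
    """Row-major upper-triangle ordering of node pairs (i, j), i < j."""

    n_nodes: int

    @property
    def pairs(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return np.column_stack([iu, ju])

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def edge_of(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("no self-edges")
        i, j = (i, j) if i < j else (j, i)
        n = self.n_nodes
        return i * n - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class EdgeTimeSeries:
    """E x T co-fluctuation matrix; row e(t) = z_i(t) * z_j(t)."""

    data: np.ndarray
    index: EdgeIndex
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != self.index.n_edges:
            raise ValueError("row count must equal number of edges")


@dataclass
class EdgeCommunityAssignment:
    """Edge -> community labels (1..k) for each k, with k-means inertia."""

    labels: dict[int, np.ndarray]
    inertia: dict[int, float]
    index: EdgeIndex
    seed: int


# ---------------------------------------------------------------------------
# time-series construction


def zscore(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Standardize each region with population SD (divisor T).

    The divisor-T convention makes the time mean of every edge series
    equal the node pair's Pearson correlation.
    """
    mu = ts.data.mean(axis=1, keepdims=True)
    sd = ts.data.std(axis=1, keepdims=True)  # ddof=0
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"zero-variance region(s): {bad.tolist()}")
    out = replace(ts)
    out.data = (ts.data - mu) / sd
    out.z_scored = True
    return out


def concatenate_trials(trials: list[RegionTimeSeries]) -> RegionTimeSeries:
    """Column-wise concatenation of per-trial z-scored series, in order."""
    if not trials:
        raise ValueError("no trials to concatenate")
    first = trials[0]
    for t in trials:
        if t.n_regions != first.n_regions:
            raise ValueError("all trials must share the same number of regions")
        if t.atlas != first.atlas:
            raise ValueError("all trials must share the same atlas")
        if not t.z_scored:
            raise ValueError("z-score each trial before concatenation")
    out = replace(first)
    out.data = np.hstack([t.data for t in trials])
    out.trial = None
    out.z_scored = True
    return out


def condition_difference(a: RegionTimeSeries, b: RegionTimeSeries) -> RegionTimeSeries:
    """Elementwise a - b; result is flagged non-z-scored."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    out = replace(a)
    out.data = a.data - b.data
    out.condition = f"{a.condition}-{b.condition}"
    out.z_scored = False
    return out


def edge_time_series(z: RegionTimeSeries) -> EdgeTimeSeries:
    """Pointwise products z_i(t)*z_j(t) over the upper triangle."""
    if not z.z_scored:
        raise ValueError("input must be z-scored")
    idx = EdgeIndex(z.n_regions)
    iu, ju = np.triu_indices(z.n_regions, k=1)
    data = z.data[iu] * z.data[ju]
    prov = "/".join(str(p) for p in (z.subject, z.condition) if p is not None)
    return EdgeTimeSeries(data=data, index=idx, provenance=prov)


def group_average(subjects: list[EdgeTimeSeries]) -> EdgeTimeSeries:
    """Elementwise mean across subjects; shapes must agree exactly."""
    if not subjects:
        raise ValueError("no subjects")
    shapes = [s.data.shape for s in subjects]
    if len(set(shapes)) > 1:
        report = ", ".join(f"{s.provenance or i}: T={sh[1]}" for i, (s, sh) in enumerate(zip(subjects, shapes)))
        raise ValueError(f"mismatched edge-series shapes across subjects ({report})")
    out = EdgeTimeSeries(
        data=np.mean([s.data for s in subjects], axis=0),
        index=subjects[0].index,
        provenance="group-average",
    )
    return out


def edge_fc(ets: EdgeTimeSeries, normalization: str = "inner-product") -> np.ndarray:
    """E x E similarity among edge time series.

    ``inner-product``: (e.f)/sqrt((e.e)(f.f)) — cosine of the raw edge
    rows, the edge-FC convention.  ``pearson``: centered correlation.
    Zero-norm rows yield 0 entries with a warning.
    """
    X = ets.data
    if X.shape[1] < 2:
        raise ValueError("need T >= 2")
    if normalization == "pearson":
        X = X - X.mean(axis=1, keepdims=True)
    elif normalization != "inner-product":
        raise ValueError(f"unknown normalization {normalization!r}")
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm edge rows; their similarities set to 0")
        norms = np.where(zero, 1.0, norms)
    U = X / norms[:, None]
    S = U @ U.T
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, np.where(zero, 0.0, 1.0))
    return np.clip(S, -1.0, 1.0)


# ---------------------------------------------------------------------------
# edge communities


def cluster_edges(
    ets: EdgeTimeSeries,
    k_range: range | list[int] = range(2, 21),
    restarts: int = 10,
    max_iter: int = 5000,
    seed: int = 0,
) -> EdgeCommunityAssignment:
    """k-means (squared Euclidean) on the E x T edge matrix for each k.

    ``max_iter`` caps iterations per restart; ``restarts`` independent
    seeded initializations are run and the lowest-inertia solution kept.
    Labels are 1-based communities.  scikit-learn's k-means relocates
    points into any cluster that empties, so every k yields k nonempty
    or singleton-relocated clusters without manual re-initialization.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k_range")
    E = ets.data.shape[0]
    if E < max(ks):
        raise ValueError(f"E={E} edges < max k={max(ks)}")
    labels: dict[int, np.ndarray] = {}
    inertia: dict[int, float] = {}
    for k in ks:
        km = KMeans(
            n_clusters=k,
            n_init=restarts,
            max_iter=max_iter,
            random_state=seed % (2**32),
            init="k-means++",
        ).fit(ets.data)
        labels[k] = km.labels_.astype(int) + 1
        inertia[k] = float(km.inertia_)
    return EdgeCommunityAssignment(labels=labels, inertia=inertia, index=ets.index, seed=seed)


def node_community_matrix(assignment: EdgeCommunityAssignment, k: int) -> np.ndarray:
    """N x N matrix X with x_ij = community label of edge (i, j).

    The diagonal is empty (self-connections are not considered) and is
    stored as -1 so it can never match a community label.
    """
    if k not in assignment.labels:
        raise ValueError(f"no labels for k={k}")
    n = assignment.index.n_nodes
    X = np.full((n, n), -1, dtype=int)
    iu, ju = np.triu_indices(n, k=1)
    lab = assignment.labels[k]
    X[iu, ju] = lab
    X[ju, iu] = lab
    return X


def overlap_entropy(X: np.ndarray, k: int) -> np.ndarray:
    """Per-node normalized entropy of incident-edge community labels.

    For node i, p_c is the fraction of its N-1 edges carrying label c;
    entropy = -sum p_c ln p_c / ln k, with 0*ln 0 := 0.  Ranges in
    [0, 1]; 1 means edges spread uniformly over all k communities.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (normalizer ln k undefined)")
    n = X.shape[0]
    ent = np.empty(n)
    for i in range(n):
        labels = np.delete(X[:, i], i)
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        ent[i] = float(-(p * np.log(p)).sum() / np.log(k))
    return ent


def community_similarity(X: np.ndarray, include_self_positions: bool = False) -> np.ndarray:
    """N x N similarity: fraction of matching labels between label columns.

    s_ij = fraction of positions m not in {i, j} with x_mi == x_mj (the
    self-positions are excluded because the diagonal is empty).  With
    ``include_self_positions=True`` all N positions are compared, the
    sensitivity-check variant.
    """
    n = X.shape[0]
    if include_self_positions:
        eq = (X[:, :, None] == X[:, None, :]).sum(axis=0)
        return eq / n
    # diagonal sentinel -1 never equals a community label, so matches at
    # positions i and j vanish automatically; denominator is N - 2
    eq = (X[:, :, None] == X[:, None, :]).sum(axis=0)
    S = eq / (n - 2)
    np.fill_diagonal(S, 1.0)
    return S


def within_network_similarity(S: np.ndarray, atlas: list[str]) -> np.ndarray:
    """Per-node mean similarity to the other nodes of its own network.

    Nodes whose network has no other member get NaN.
    """
    n = S.shape[0]
    if len(atlas) != n:
        raise ValueError("atlas length must match similarity matrix size")
    atlas_arr = np.asarray(atlas)
    out = np.full(n, np.nan)
    for i in range(n):
        peers = np.flatnonzero((atlas_arr == atlas_arr[i]) & (np.arange(n) != i))
        if peers.size:
            out[i] = S[i, peers].mean()
    return out


def average_over_k(profiles: dict[int, np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-node profiles over the k grid."""
    if not profiles:
        raise ValueError("no profiles")
    mats = list(profiles.values())
    lengths = {len(m) for m in mats}
    if len(lengths) != 1:
        raise ValueError("profiles must cover the same nodes for every k")
    return np.mean(mats, axis=0)
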
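"""Semantic networks and percolation robustness.

A story's semantic network has its unique words as nodes and the Pearson
correlation between the words' embedding vectors as (signed) edge
weights, giving a fully connected weighted graph.  Robustness is the
percolation integral

    PI = sum over the threshold grid of GC(TH) * TH_res,

where GC(TH) is the size of the giant component after removing every
edge with weight < TH; the grid runs from 0 to 1 in steps of 0.0125 and
evaluation stops at the first threshold where the giant component drops
below 3 nodes (that threshold's term is not added).  A larger PI means
the network stays globally connected under stronger thresholding — the
operational measure of semantic-memory flexibility.

Two significance analyses perturb the network and re-measure PI:

* **noise** — add zero-mean Gaussian noise to every edge weight, with a
  per-realization SD drawn uniformly between 1/E and 10/E (E = number
  of edges), over 500 realizations;
* **link shuffling** — repeatedly swap the weights of randomly chosen
  edge pairs (80% of edges selected per iteration, 20 iterations, PI
  averaged over iterations), which preserves the weight multiset while
  scrambling which pair of words each weight connects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .text import EmbeddingLexicon, TokenSequence

__all__ = [
    "SemanticNetwork",
    "PercolationConfig",
    "PercolationResult",
    "RobustnessResult",
    "build_semantic_network",
    "percolate",
    "noise_robustness",
    "shuffle_robustness",
    "shuffle_weights",
    "edge_touch_probability",
    "subsample_tokens",
]

#: tolerance for "weight >= threshold" comparisons; the grid step 0.0125
#: is not dyadic, so accumulated grid points can overshoot by ~1e-16
_EDGE_TOL = 1e-9


@dataclass
class SemanticNetwork:
    """Unique words as nodes; signed Pearson weights on every pair."""

    nodes: list[str]
    weights: np.ndarray  # condensed upper-triangle vector, length n(n-1)/2

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n * (n - 1) // 2,):
            raise ValueError("weights must be the condensed upper triangle")
        # built networks carry correlations in [-1, 1]; perturbed variants
        # (noise analysis adds unclipped Gaussian noise) may exceed it

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric matrix with zero diagonal (no self-edges)."""
        n = self.n_nodes
        W = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        W[iu, ju] = self.weights
        W[ju, iu] = self.weights
        return W


@dataclass(frozen=True)
class PercolationConfig:
    start_TH: float = 0.0
    end_TH: float = 1.0
    TH_res: float = 0.0125
    gc_min: int = 3
    include_stop_term: bool = False  # sensitivity flag; default excludes it

    def __post_init__(self) -> None:
        if not self.start_TH < self.end_TH:
            raise ValueError("start_TH must be < end_TH")
        if self.TH_res <= 0:
            raise ValueError("TH_res must be positive")

    def grid(self) -> np.ndarray:
        n_steps = int(round((self.end_TH - self.start_TH) / self.TH_res))
        g = self.start_TH + np.arange(n_steps + 1) * self.TH_res
        g[-1] = self.end_TH
        return g


@dataclass
class PercolationResult:
    thresholds: np.ndarray  # evaluated grid points (before the stop)
    gc_sizes: np.ndarray  # giant-component size at each evaluated threshold
    PI: float
    stop_threshold: float | None = None  # first threshold with GC < gc_min


@dataclass
class RobustnessResult:
    PI_mean: float
    PI_values: np.ndarray
    mode: str  # "noise" | "shuffle"
    params: dict
    seed: int


# ---------------------------------------------------------------------------
# construction


def build_semantic_network(tokens: TokenSequence, lexicon: EmbeddingLexicon) -> SemanticNetwork:
    """Fully connected word network weighted by vector Pearson correlation.

    Duplicate words collapse to one node (first-occurrence order);
    out-of-vocabulary words are ignored.
    """
    seen: dict[str, None] = {}
    for t in tokens.tokens:
        if t in lexicon and t not in seen:
            seen[t] = None
    words = list(seen)
    if len(words) < 3:
        raise ValueError(f"{tokens.source_id}: need >= 3 unique in-vocabulary words, got {len(words)}")
    mat = np.array([lexicon[w] for w in words])
    sds = mat.std(axis=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"zero-variance vector for token(s): {[words[i] for i in bad]}")
    corr = np.corrcoef(mat)
    iu, ju = np.triu_indices(len(words), k=1)
    return SemanticNetwork(nodes=words, weights=np.clip(corr[iu, ju], -1.0, 1.0))


# ---------------------------------------------------------------------------
# percolation


class _UnionFind:
    __slots__ = ("parent", "size", "max_size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.max_size = 0  # largest component containing an edge

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            self.max_size = max(self.max_size, self.size[ra])
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.max_size = max(self.max_size, self.size[ra])


def _gc_curve(net_weights: np.ndarray, n_nodes: int, grid: np.ndarray) -> np.ndarray:
    """GC at every grid threshold, via incremental union-find.

    Edges are inserted while sweeping the grid from the highest threshold
    down; components only merge as the threshold drops, so a single pass
    yields the full curve.  Isolated nodes never count toward GC.
    """
    iu, ju = np.triu_indices(n_nodes, k=1)
    order = np.argsort(-net_weights)  # heaviest first
    uf = _UnionFind(n_nodes)
    gc_desc = np.empty(len(grid), dtype=int)
    e = 0
    sorted_w = net_weights[order]
    for gi, th in enumerate(grid[::-1]):
        while e < len(sorted_w) and sorted_w[e] >= th - _EDGE_TOL:
            k = order[e]
            uf.union(int(iu[k]), int(ju[k]))
            e += 1
        gc_desc[gi] = uf.max_size
    return gc_desc[::-1].copy()


def percolate(net: SemanticNetwork, cfg: PercolationConfig = PercolationConfig()) -> PercolationResult:
    """Threshold sweep, giant-component curve, and percolation integral.

    At each grid threshold TH, edges with weight < TH are removed; GC is
    the size of the largest connected component among non-isolated
    nodes.  The sweep stops at the first threshold where GC < gc_min;
    that threshold's term is excluded from PI unless
    ``cfg.include_stop_term`` is set.
    """
    grid = cfg.grid()
    gc = _gc_curve(net.weights, net.n_nodes, grid)
    stop_idx = None
    for i, g in enumerate(gc):
        if g < cfg.gc_min:
            stop_idx = i
            break
    if stop_idx is None:
        evaluated, sizes, stop_th = grid, gc, None
    else:
        end = stop_idx + 1 if cfg.include_stop_term else stop_idx
        evaluated, sizes = grid[:end], gc[:end]
        stop_th = float(grid[stop_idx])
    PI = float(sizes.sum() * cfg.TH_res)
    return PercolationResult(thresholds=evaluated, gc_sizes=sizes, PI=PI, stop_threshold=stop_th)


# ---------------------------------------------------------------------------
# robustness analyses


def noise_robustness(
    net: SemanticNetwork,
    cfg: PercolationConfig = PercolationConfig(),
    n_real: int = 500,
    seed: int = 0,
    sd_range: tuple[float, float] | None = None,
) -> RobustnessResult:
    """Mean PI over noisy realizations of the network.

    Each realization draws one SD uniformly from [1/E, 10/E] and adds
    i.i.d. N(0, SD^2) to every edge weight (no clipping) before
    percolating.  ``sd_range`` overrides the default range (the (0, 0)
    degenerate range reproduces the noiseless PI exactly).
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    E = net.n_edges
    lo, hi = sd_range if sd_range is not None else (1.0 / E, 10.0 / E)
    rng = np.random.default_rng(seed)
    pis = np.empty(n_real)
    for r in range(n_real):
        sd = rng.uniform(lo, hi)
        noisy = net.weights + sd * rng.standard_normal(E)  # no clipping
        pis[r] = percolate(SemanticNetwork(nodes=net.nodes, weights=noisy), cfg).PI
    return RobustnessResult(
        PI_mean=float(pis.mean()),
        PI_values=pis,
        mode="noise",
        params={"n_real": n_real, "sd_range": (lo, hi)},
        seed=seed,
    )


def shuffle_weights(
    weights: np.ndarray, frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One shuffling iteration: pair up selected edges and swap weights.

    round(frac * E) distinct edges are sampled without replacement,
    randomly paired, and each pair's weights exchanged (an odd leftover
    edge is untouched).  Returns the new weight vector and the indices
    of edges that took part in a swap.  The weight multiset is preserved.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    E = len(weights)
    if E < 2:
        raise ValueError("need at least 2 edges to shuffle")
    m = int(round(frac * E))
    m = max(m, 0)
    chosen = rng.choice(E, size=m, replace=False)
    n_pairs = m // 2
    paired = chosen[: 2 * n_pairs]
    out = weights.copy()
    first, second = paired[0::2], paired[1::2]
    out[first], out[second] = weights[second], weights[first]
    return out, paired


def shuffle_robustness(
    net: SemanticNetwork,
    cfg: PercolationConfig = PercolationConfig(),
    n_iter: int = 20,
    frac: float = 0.8,
    seed: int = 0,
) -> RobustnessResult:
    """Mean PI across cumulative link-shuffling iterations.

    Each iteration further shuffles the current network (swapping edge
    weights scrambles structure while preserving the weight multiset)
    and PI is recorded; the result is the mean over the n_iter
    iterations.  At frac=0.8 and n_iter=20 each edge is selected at
    least once with probability 1 - 0.2**20.
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges")
    rng = np.random.default_rng(seed)
    w = net.weights.copy()
    pis = np.empty(n_iter)
    touched = np.zeros(net.n_edges, dtype=bool)
    for it in range(n_iter):
        w, sel = shuffle_weights(w, frac, rng)
        touched[sel] = True
        pis[it] = percolate(SemanticNetwork(nodes=net.nodes, weights=w), cfg).PI
    return RobustnessResult(
        PI_mean=float(pis.mean()),
        PI_values=pis,
        mode="shuffle",
        params={"n_iter": n_iter, "frac": frac, "touched": touched},
        seed=seed,
    )


def edge_touch_probability(
    n_edges: int,
    n_runs: int = 1000,
    n_iter: int = 20,
    frac: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo per-edge probability of being shuffled at least once.

    Runs the same selection-and-swap routine ``shuffle_robustness`` uses
    (``n_iter`` iterations selecting round(frac * E) edges each) over
    ``n_runs`` independently seeded runs, and returns each edge's
    fraction of runs in which it took part in at least one swap.  The
    analytic value at frac=0.8, n_iter=20 is 1 - 0.2**20.
    """
    weights = np.zeros(n_edges)
    hits = np.zeros(n_edges, dtype=int)
    root = np.random.default_rng(seed)
    for _ in range(n_runs):
        rng = np.random.default_rng(root.integers(2**31))
        touched = np.zeros(n_edges, dtype=bool)
        for _ in range(n_iter):
            _, sel = shuffle_weights(weights, frac, rng)
            touched[sel] = True
        hits += touched
    return hits / n_runs


def subsample_tokens(tokens: TokenSequence, n: int, seed: int = 0) -> TokenSequence:
    """Subsample a token stream to length n without replacement, keeping order.

    Used as the word-count control: token streams of different lengths
    yield networks of different sizes, so PI is compared after
    subsampling every stream to a common length (repeated over seeds
    and averaged).
    """
    if n < 2 or n > len(tokens.tokens):
        raise ValueError(f"n must be in [2, {len(tokens.tokens)}]")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(tokens.tokens), size=n, replace=False))
    return TokenSequence(
        tokens=[tokens.tokens[i] for i in keep],
        source_id=tokens.source_id,
        condition=tokens.condition,
    )
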
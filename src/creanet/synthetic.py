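"""Synthetic inputs with controllable ground truth.

Three generators mirror the three data streams the analysis consumes:

* cluster-structured word-embedding lexicons and token streams (stand-ins
  for tokenized creative-writing stories over a pretrained embedding
  corpus);
* multi-subject, multi-trial region-by-time BOLD matrices with planted
  node-block covariance, which induces a recoverable ground-truth
  partition of *edges* by block-pair identity;
* three-variable behavioral tables with a known mediation structure
  (x -> m -> y plus a direct path).

Every generator takes an explicit integer seed and is deterministic; no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .text import EmbeddingLexicon, TokenSequence
from .edges import RegionTimeSeries

__all__ = [
    "LexiconSpec",
    "BoldSpec",
    "MediationSpec",
    "make_lexicon",
    "make_story",
    "make_alternating_story",
    "make_bold",
    "make_mediation_table",
    "block_assignment",
    "edge_block_pair_labels",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class LexiconSpec:
    """Cluster-structured embedding lexicon.

    Vectors are orthonormal cluster means perturbed by isotropic Gaussian
    noise and renormalized to unit length, so with ``within_noise_sd=0``
    within-cluster cosine similarity is exactly 1 and cross-cluster 0.
    """

    n_clusters: int = 8
    words_per_cluster: int = 25
    dim: int = 200  # matches the 200-dim embedding corpus the metrics assume
    within_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.words_per_cluster < 2:
            raise ValueError("words_per_cluster must be >= 2")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.dim < self.n_clusters:
            raise ValueError(
                f"dim={self.dim} < n_clusters={self.n_clusters}: cannot build "
                "orthonormal cluster means"
            )
        if self.within_noise_sd < 0:
            raise ValueError("within_noise_sd must be non-negative")


@dataclass(frozen=True)
class BoldSpec:
    """Parcellated BOLD emulation: block-latent signals plus noise.

    Each node belongs to one latent covariance block; its signal is the
    block's shared standard-normal time course plus independent Gaussian
    noise.  Two conditions are generated with distinct block assignments
    so condition-specific edge structure exists.  Defaults mirror the
    acquisition layout the edge analysis expects (400 regions in 17
    networks, 10 trials per condition).
    """

    n_nodes: int = 400
    n_networks: int = 17
    network_sizes: tuple[int, ...] | None = None
    n_blocks: int = 4
    block_sizes: tuple[int, ...] | None = None  # default: near-equal contiguous
    T_trial: int = 30
    n_trials: int = 10
    n_subjects: int = 10
    noise_sd: float = 0.1
    seed: int = 0
    conditions: tuple[str, str] = ("imagery", "semantic")

    def __post_init__(self) -> None:
        if self.network_sizes is None:
            base = self.n_nodes // self.n_networks
            sizes = [base] * self.n_networks
            for i in range(self.n_nodes - base * self.n_networks):
                sizes[i] += 1
            object.__setattr__(self, "network_sizes", tuple(sizes))
        if sum(self.network_sizes) != self.n_nodes:
            raise ValueError("network_sizes must sum to n_nodes")
        if len(self.network_sizes) != self.n_networks:
            raise ValueError("network_sizes length must equal n_networks")
        if self.n_blocks > self.n_nodes:
            raise ValueError("n_blocks must be <= n_nodes")
        if self.block_sizes is not None:
            if len(self.block_sizes) != self.n_blocks:
                raise ValueError("block_sizes length must equal n_blocks")
            if sum(self.block_sizes) != self.n_nodes:
                raise ValueError("block_sizes must sum to n_nodes")
        if self.T_trial < 2:
            raise ValueError("T_trial must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def atlas(self) -> list[str]:
        """Node -> network label, contiguous by construction."""
        labels = []
        for i, size in enumerate(self.network_sizes):
            labels.extend([f"Net{i + 1:02d}"] * size)
        return labels


@dataclass(frozen=True)
class MediationSpec:
    """x -> m -> y generator with a direct path.

    ``m = a*x + eps_m`` and ``y = c'*x + b*m + eps_y`` with independent
    N(0, noise_sd^2) errors; population indirect effect is ``a*b``.
    """

    n: int = 100
    a_path: float = 0.5
    b_path: float = 0.4
    c_prime: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# lexicon and stories


def _orthonormal_means(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Random orthonormal cluster means via QR of a Gaussian matrix."""
    gauss = rng.standard_normal((dim, n))
    q, r = np.linalg.qr(gauss)
    # fix signs so the decomposition is unique given the draw
    q = q * np.sign(np.diag(r))
    return q[:, :n].T


def make_lexicon(spec: LexiconSpec) -> EmbeddingLexicon:
    """Build a cluster-structured lexicon with unit-norm vectors.

    Tokens are ``c{cluster}_w{index}`` so cluster membership is trivially
    recoverable from the token string.
    """
    rng = np.random.default_rng(spec.seed)
    means = _orthonormal_means(spec.n_clusters, spec.dim, rng)
    vectors: dict[str, np.ndarray] = {}
    for c in range(spec.n_clusters):
        for w in range(spec.words_per_cluster):
            v = means[c] + spec.within_noise_sd * rng.standard_normal(spec.dim)
            v = v / np.linalg.norm(v)
            vectors[f"c{c}_w{w}"] = v
    return EmbeddingLexicon(vectors=vectors, dim=spec.dim)


def lexicon_clusters(lexicon: EmbeddingLexicon) -> dict[str, int]:
    """Recover the planted cluster id from each synthetic token string."""
    return {tok: int(tok.split("_")[0][1:]) for tok in lexicon.vocab}


def make_story(
    lexicon: EmbeddingLexicon,
    n_tokens: int,
    cluster_weights,
    seed: int,
    source_id: str = "story",
    condition: str | None = None,
) -> TokenSequence:
    """Sample a token stream cluster-first, then word-within-cluster."""
    if n_tokens < 2:
        raise ValueError("n_tokens must be >= 2")
    weights = np.asarray(cluster_weights, dtype=float)
    clusters = sorted({c for c in lexicon_clusters(lexicon).values()})
    if len(weights) != len(clusters):
        raise ValueError(
            f"cluster_weights length {len(weights)} != n_clusters {len(clusters)}"
        )
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("cluster_weights must sum to 1")
    by_cluster: dict[int, list[str]] = {c: [] for c in clusters}
    for tok in sorted(lexicon.vocab):
        by_cluster[int(tok.split("_")[0][1:])].append(tok)
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(clusters), size=n_tokens, p=weights)
    tokens = []
    for c in draws:
        words = by_cluster[clusters[c]]
        tokens.append(words[rng.integers(len(words))])
    return TokenSequence(tokens=tokens, source_id=source_id, condition=condition)


def make_alternating_story(
    lexicon: EmbeddingLexicon,
    n_tokens: int,
    clusters: tuple[int, int] = (0, 1),
    seed: int = 0,
    source_id: str = "story",
    condition: str | None = None,
) -> TokenSequence:
    """Token stream strictly alternating between two clusters.

    Word identity within the active cluster is still sampled, so repeated
    seeds give distinct stories with the same cluster rhythm.
    """
    if n_tokens < 2:
        raise ValueError("n_tokens must be >= 2")
    by_cluster: dict[int, list[str]] = {}
    for tok in sorted(lexicon.vocab):
        by_cluster.setdefault(int(tok.split("_")[0][1:]), []).append(tok)
    rng = np.random.default_rng(seed)
    tokens = []
    for t in range(n_tokens):
        words = by_cluster[clusters[t % 2]]
        tokens.append(words[rng.integers(len(words))])
    return TokenSequence(tokens=tokens, source_id=source_id, condition=condition)


# ---------------------------------------------------------------------------
# BOLD


def block_assignment(spec: BoldSpec, condition: str) -> np.ndarray:
    """Node -> latent block map for one condition.

    The first condition uses contiguous equal blocks; the second rolls the
    assignment by half a block so the two conditions plant different edge
    structure.
    """
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if spec.block_sizes is not None:
        base = np.repeat(np.arange(spec.n_blocks), spec.block_sizes)
    else:
        base = np.repeat(np.arange(spec.n_blocks), int(np.ceil(spec.n_nodes / spec.n_blocks)))
        base = base[: spec.n_nodes]
    if condition == spec.conditions[0]:
        return base
    shift = max(1, spec.n_nodes // (2 * spec.n_blocks))
    return np.roll(base, shift)


def edge_block_pair_labels(assignment: np.ndarray) -> np.ndarray:
    """Ground-truth edge groups: unordered block-pair identity per edge.

    Edges are ordered row-major over the upper triangle; labels enumerate
    the distinct unordered block pairs actually present (same-block pairs
    included), so ``n_blocks=3`` yields up to 6 groups.
    """
    n = len(assignment)
    iu, ju = np.triu_indices(n, k=1)
    pairs = [tuple(sorted((int(assignment[i]), int(assignment[j])))) for i, j in zip(iu, ju)]
    uniq = {p: k for k, p in enumerate(sorted(set(pairs)))}
    return np.array([uniq[p] for p in pairs])


def make_bold(spec: BoldSpec) -> list[RegionTimeSeries]:
    """Generate raw (not yet z-scored) region time series.

    Returns one ``RegionTimeSeries`` per (subject, condition, trial).
    Node signal = block latent (standard normal over time, fresh per
    trial) + independent N(0, noise_sd^2) noise.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = spec.atlas
    out: list[RegionTimeSeries] = []
    for subject in range(spec.n_subjects):
        for condition in spec.conditions:
            blocks = block_assignment(spec, condition)
            for trial in range(spec.n_trials):
                latents = rng.standard_normal((spec.n_blocks, spec.T_trial))
                data = latents[blocks]
                if spec.noise_sd > 0:
                    data = data + spec.noise_sd * rng.standard_normal(data.shape)
                out.append(
                    RegionTimeSeries(
                        data=data.copy(),
                        atlas=list(atlas),
                        subject=f"sub{subject + 1:02d}",
                        condition=condition,
                        trial=trial,
                        z_scored=False,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# behavior


def make_mediation_table(spec: MediationSpec) -> pd.DataFrame:
    """Simulate an x/m/y table with known standardized-ish path structure."""
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(spec.n)
    m = spec.a_path * x + spec.noise_sd * rng.standard_normal(spec.n)
    y = spec.c_prime * x + spec.b_path * m + spec.noise_sd * rng.standard_normal(spec.n)
    return pd.DataFrame({"x": x, "m": m, "y": y})
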
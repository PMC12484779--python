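"""Text-level semantic creativity metrics.

Two scores are computed from a story's word representations:

* **Global semantic distance (GSD)** — the objective creative-writing
  score.  The token stream is cut into sliding windows (10 words, step
  5 by default), each window is represented by the mean of its word
  embeddings, and the score is the mean cosine distance (1 - cosine
  similarity) between adjacent window means.

* **Divergent semantic integration (DSI)** — the mean cosine distance
  over every unordered pair of word representations pooled across the
  whole story, for each of two designated contextual-embedding layers.
  The contextual embedder is an injected provider satisfying
  :class:`ContextualEmbedder`; any model exposing two fixed layers of
  per-token vectors can back it.

Both scores live on the cosine-distance scale [0, 2].
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

__all__ = [
    "EmbeddingLexicon",
    "TokenSequence",
    "SentenceSet",
    "ContextualEmbedder",
    "LexiconEmbedder",
    "SemanticScore",
    "tokenize",
    "global_semantic_distance",
    "divergent_semantic_integration",
]

logger = logging.getLogger(__name__)

#: characters stripped before whitespace tokenization; covers ASCII and
#: common CJK punctuation so the default tokenizer works on either script
DEFAULT_PUNCT = r"[\.,;:!\?\"'`~@#\$%\^&\*\(\)\[\]\{\}<>/\\\|\-=\+，。！？、；：“”‘’（）《》【】…—·]"


@dataclass
class EmbeddingLexicon:
    """Token -> fixed-dimension vector map; the semantic substrate."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        for tok, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has shape {v.shape}, expected ({self.dim},)")
            self.vectors[tok] = v

    @property
    def vocab(self) -> set[str]:
        return set(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class TokenSequence:
    """Ordered tokens of one story after cleaning."""

    tokens: list[str]
    source_id: str = "story"
    condition: str | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("token list is empty after cleaning")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class SentenceSet:
    """Story segmented into sentences (token lists) for contextual embedding."""

    sentences: list[list[str]]
    source_id: str = "story"
    condition: str | None = None

    def __post_init__(self) -> None:
        if not self.sentences or any(len(s) == 0 for s in self.sentences):
            raise ValueError("every sentence must be nonempty")

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


class ContextualEmbedder(Protocol):
    """Contract for providers of two-layer contextual token embeddings."""

    def embed(self, sentence: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Return (layer_a, layer_b) arrays of shape (len(sentence), dim)."""
        ...


class LexiconEmbedder:
    """Deterministic embedder: static lexicon lookup duplicated to two layers.

    Useful as a test double and as a degenerate context-free provider;
    with it DSI reduces to mean pairwise cosine distance over static
    word vectors.
    """

    def __init__(self, lexicon: EmbeddingLexicon):
        self.lexicon = lexicon

    def embed(self, sentence: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        mat = np.array([self.lexicon[t] for t in sentence])
        return mat, mat.copy()


@dataclass(frozen=True)
class SemanticScore:
    value: float
    n_units: int  # windows for gsd, pairs (per layer) for dsi
    metric: str
    source_id: str = "story"
    condition: str | None = None


def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


def tokenize(
    text: str,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenizer,
    lexicon: EmbeddingLexicon | None = None,
    punct_pattern: str = DEFAULT_PUNCT,
    source_id: str = "story",
    condition: str | None = None,
) -> TokenSequence:
    """Strip punctuation, tokenize, and drop out-of-vocabulary tokens.

    The tokenizer is pluggable (whitespace split by default; a Chinese
    segmenter can be injected for real corpora).  Tokens absent from the
    supplied lexicon are dropped and the drop count is logged and kept
    on the result.
    """
    if text is None:
        raise ValueError("text is None")
    cleaned = re.sub(punct_pattern, " ", text)
    tokens = tokenizer(cleaned)
    n_dropped = 0
    if lexicon is not None:
        kept = [t for t in tokens if t in lexicon]
        n_dropped = len(tokens) - len(kept)
        if n_dropped:
            logger.info("%s: dropped %d out-of-vocabulary tokens", source_id, n_dropped)
        tokens = kept
    if not tokens:
        raise ValueError(f"{source_id}: no tokens left after cleaning")
    return TokenSequence(tokens=tokens, source_id=source_id, condition=condition, n_dropped=n_dropped)


def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm vector in cosine distance")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def global_semantic_distance(
    tokens: TokenSequence,
    lexicon: EmbeddingLexicon,
    window: int = 10,
    step: int = 5,
    keep_partial: bool = True,
) -> SemanticScore:
    """Mean cosine distance between adjacent sliding-window mean vectors.

    Windows start at 0, step, 2*step, ...; each window's vector is the
    mean of its token embeddings.  A trailing partial window is kept if
    it holds at least 2 tokens (``keep_partial=False`` drops it).  At
    least two windows are required.
    """
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    toks = [t for t in tokens.tokens if t in lexicon]
    n_oov = len(tokens.tokens) - len(toks)
    if n_oov:
        logger.info("%s: %d tokens not in lexicon ignored for gsd", tokens.source_id, n_oov)
    vecs = np.array([lexicon[t] for t in toks]) if toks else np.empty((0, lexicon.dim))
    n = len(toks)
    # full windows at starts 0, step, 2*step, ...
    starts = list(range(0, max(n - window, 0) + 1, step)) if n >= window else []
    means = [vecs[s : s + window].mean(axis=0) for s in starts]
    # one trailing partial window if tokens remain beyond the last full window
    if starts and keep_partial:
        tail = starts[-1] + step
        if tail < n and n - tail >= 2 and starts[-1] + window < n:
            means.append(vecs[tail:n].mean(axis=0))
    if len(means) < 2:
        raise ValueError(
            f"{tokens.source_id}: text too short for gsd "
            f"(need at least {window + step} tokens for 2 full windows, got {len(toks)})"
        )
    dists = [_cosine_distance(means[i], means[i + 1]) for i in range(len(means) - 1)]
    return SemanticScore(
        value=float(np.mean(dists)),
        n_units=len(means),
        metric="gsd",
        source_id=tokens.source_id,
        condition=tokens.condition,
    )


def divergent_semantic_integration(
    sentences: SentenceSet,
    embedder: ContextualEmbedder,
    average_layers_first: bool = False,
) -> SemanticScore:
    """Mean pairwise cosine distance over a story's word representations.

    Per-token vectors from two designated embedding layers are pooled
    across all sentences of the story; cosine distance is computed for
    every unordered token pair within each layer and the score is the
    mean over all pairs and both layers.  With
    ``average_layers_first=True`` the two layers' vectors are averaged
    per token before a single pass of pairwise distances (the alternate
    reading of averaging "across" layers).
    """
    layer_a: list[np.ndarray] = []
    layer_b: list[np.ndarray] = []
    for sent in sentences.sentences:
        out = embedder.embed(sent)
        if len(out) != 2:
            raise ValueError(f"embedder must return exactly 2 layers, got {len(out)}")
        a, b = (np.asarray(m, dtype=float) for m in out)
        if a.shape != b.shape or a.shape[0] != len(sent):
            raise ValueError("embedder layers disagree in token count or dimension")
        layer_a.append(a)
        layer_b.append(b)
    A = np.vstack(layer_a)
    B = np.vstack(layer_b)
    n = A.shape[0]
    if n < 2:
        raise ValueError("dsi needs at least 2 tokens in the story")

    def _mean_pairwise(mat: np.ndarray) -> tuple[float, int]:
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm token vector")
        unit = mat / norms[:, None]
        sims = unit @ unit.T
        iu = np.triu_indices(len(mat), k=1)
        d = 1.0 - sims[iu]
        return float(d.mean()), len(d)

    if average_layers_first:
        value, n_pairs = _mean_pairwise((A + B) / 2.0)
    else:
        da, n_pairs = _mean_pairwise(A)
        db, _ = _mean_pairwise(B)
        value = (da + db) / 2.0
    return SemanticScore(
        value=value,
        n_units=n_pairs,
        metric="dsi",
        source_id=sentences.source_id,
        condition=sentences.condition,
    )
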
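"""Word embeddings, lexicon retrofitting, and the word semantic score.

A generic embedding table (word2vec text format) is specialised to the
mental-health domain by *retrofitting*: word vectors are iteratively
pulled toward their neighbors in a lexicon-derived word graph, so that
words that share a depression-lexicon phrase or category end up closer in
the vector space (e.g. "feeling" and "lethargic"). The word semantic
score WSS(w) is then the maximum cosine similarity of w's (retrofitted)
vector with any word of the lexicon, clamped to [0, 1]; it is the
knowledge signal injected into language-model scoring and word importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .lexicon import DepressionLexicon

log = logging.getLogger(__name__)

__all__ = [
    "EmbeddingStore",
    "RetrofitConfig",
    "cosine",
    "read_word2vec",
    "write_word2vec",
    "build_lexicon_graph",
    "retrofit",
    "wss",
    "make_wss_fn",
]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two same-dimension nonzero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


class EmbeddingStore:
    """word -> dense vector table with explicit misses.

    Lookup of an absent word raises ``KeyError`` (via ``[]``) or returns
    ``None`` (via :meth:`get`); it is never silently a zero vector.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding table")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {dims}")
        self._vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dimension = next(iter(dims))[0]

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def get(self, word: str) -> np.ndarray | None:
        return self._vectors.get(word)

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def words(self) -> Iterable[str]:
        return self._vectors.keys()

    def mean_vector(self, words: Sequence[str]) -> np.ndarray | None:
        """Unweighted mean of in-vocabulary word vectors; ``None`` when all
        words are out of vocabulary or the mean degenerates to zero."""
        vecs = [self._vectors[w] for w in words if w in self._vectors]
        if not vecs:
            return None
        mean = np.mean(vecs, axis=0)
        return None if np.linalg.norm(mean) == 0.0 else mean

    @staticmethod
    def cosine_vec(u: np.ndarray, v: np.ndarray) -> float:
        return cosine(u, v)

    def copy(self) -> "EmbeddingStore":
        return EmbeddingStore({w: v.copy() for w, v in self._vectors.items()})


def read_word2vec(path: str | Path) -> EmbeddingStore:
    """Read a word2vec-text embedding file (optional count header line)."""
    vectors: dict[str, np.ndarray] = {}
    with Path(path).open(encoding="utf-8") as fh:
        first = fh.readline().split()
        # header line is "<count> <dim>"; otherwise it is already a vector
        if len(first) != 2 or not _all_floats(first[1:]):
            if first:
                vectors[first[0]] = np.array([float(x) for x in first[1:]])
        for line in fh:
            parts = line.split()
            if parts:
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return EmbeddingStore(vectors)


def _all_floats(items: Sequence[str]) -> bool:
    try:
        [float(x) for x in items]
        return True
    except ValueError:
        return False


def write_word2vec(store: EmbeddingStore, path: str | Path, header: bool = True) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(store)} {store.dimension}\n")
        for word in sorted(store.words):
            vec = " ".join(repr(float(x)) for x in store[word])
            fh.write(f"{word} {vec}\n")


@dataclass(frozen=True)
class RetrofitConfig:
    """Parameters of the retrofitting update.

    alpha weights attachment to the original vector; each edge (i, j)
    carries weight 1/degree(i); iterations >= 1 Jacobi rounds.
    """

    alpha: float = 1.0
    iterations: int = 10

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def build_lexicon_graph(lexicon: DepressionLexicon) -> nx.Graph:
    """Undirected word graph induced by the lexicon.

    Edges connect (a) distinct words co-occurring in one phrase and
    (b) head words (first tokens) of phrases in the same category. No
    self-loops.
    """
    graph = nx.Graph()
    for cat in sorted(lexicon.categories):
        phrases = sorted(lexicon.categories[cat])
        heads = []
        for phrase in phrases:
            words = phrase.split()
            graph.add_nodes_from(words)
            heads.append(words[0])
            for i, a in enumerate(words):
                for b in words[i + 1 :]:
                    if a != b:
                        graph.add_edge(a, b)
        for i, a in enumerate(heads):
            for b in heads[i + 1 :]:
                if a != b:
                    graph.add_edge(a, b)
    return graph


def retrofit(
    embeddings: EmbeddingStore,
    graph: nx.Graph,
    config: RetrofitConfig | None = None,
    edge_weights: Mapping[tuple[str, str], float] | None = None,
) -> EmbeddingStore:
    """Retrofit vectors toward lexicon-graph neighbors (Jacobi updates).

    Each round updates every in-vocabulary graph node i synchronously:

        q_i <- (alpha * q_hat_i + sum_j beta_ij * q_j) / (alpha + sum_j beta_ij)

    where q_hat_i is the original vector, j ranges over in-vocabulary
    neighbors, and beta_ij = 1/degree(i) unless ``edge_weights`` overrides
    it. Words outside the graph keep their exact original vectors; graph
    nodes absent from the vocabulary are skipped (logged). Deterministic.
    """
    config = config or RetrofitConfig()
    if graph.number_of_nodes() == 0:
        log.warning("retrofit called with empty lexicon graph; returning input")
        return embeddings.copy()

    nodes = [n for n in graph.nodes if n in embeddings]
    skipped = graph.number_of_nodes() - len(nodes)
    if skipped:
        log.info("retrofit: %d lexicon-graph words absent from embeddings", skipped)
    if not nodes:
        return embeddings.copy()

    def beta(i: str, j: str) -> float:
        if edge_weights is not None:
            w = edge_weights.get((i, j), edge_weights.get((j, i)))
            if w is not None:
                return w
        return 1.0 / graph.degree(i)

    original = {n: embeddings[n].copy() for n in nodes}
    current = {n: embeddings[n].copy() for n in nodes}
    for _ in range(config.iterations):
        nxt = {}
        for i in nodes:
            neigh = [j for j in graph.neighbors(i) if j in current]
            if not neigh:
                nxt[i] = current[i]
                continue
            num = config.alpha * original[i]
            den = config.alpha
            for j in neigh:
                b = beta(i, j)
                num = num + b * current[j]
                den += b
            nxt[i] = num / den
        current = nxt

    out = {w: embeddings[w].copy() for w in embeddings.words}
    out.update(current)
    return EmbeddingStore(out)


def wss(
    word: str, embeddings: EmbeddingStore, lexicon: DepressionLexicon
) -> float:
    """Word semantic score: clamped max cosine with any lexicon word.

    Out-of-vocabulary words (and lexicon entries with no vector) score 0;
    negative maxima are clamped to 0 so the score composes multiplicatively
    with probabilities.
    """
    if not lexicon.categories:
        raise ValueError("wss requires a non-empty lexicon")
    vec = embeddings.get(word)
    if vec is None or not np.any(vec):
        return 0.0
    best = 0.0
    for lw in sorted(lexicon.vocabulary):
        lvec = embeddings.get(lw)
        if lvec is None or not np.any(lvec):
            continue
        best = max(best, cosine(vec, lvec))
    return min(best, 1.0)


def make_wss_fn(embeddings: EmbeddingStore, lexicon: DepressionLexicon):
    """Memoized word -> WSS callable over a fixed store and lexicon."""
    cache: dict[str, float] = {}

    def fn(word: str) -> float:
        if word not in cache:
            cache[word] = wss(word, embeddings, lexicon)
        return cache[word]

    return fn
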
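"""Extrinsic evaluation metrics for generated summaries.

Because clinical interviews lack gold human summaries, the pruned
conversation doubles as the reference summary (RS), and summaries are
judged extrinsically: readability (Flesch Reading Ease), distributional
fidelity of topical content (Jensen--Shannon divergence between LDA topic
posteriors, base 2), contextual similarity (cosine between mean word
embeddings), thematic overlap (shared top terms of dominant topics), and
ROUGE-1/2/L recall and F1. The LDA reference model is chosen by scanning
topic counts and keeping the model with the highest C_V-style coherence.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from ._text import tokenize
from .embeddings import EmbeddingStore, cosine

__all__ = [
    "EvalReport",
    "TopicModel",
    "fre",
    "count_syllables",
    "fit_topic_model",
    "jsd",
    "contextual_similarity",
    "thematic_overlap",
    "rouge",
    "evaluate_summary",
]


# ---------------------------------------------------------------------------
# Readability

_VOWEL_GROUP = re.compile(r"[aeiouy]+")


def count_syllables(word: str) -> int:
    """Deterministic vowel-group syllable heuristic with a silent-e
    correction; at least one syllable per word."""
    word = word.lower().strip("'")
    if not word:
        return 0
    groups = _VOWEL_GROUP.findall(word)
    n = len(groups)
    if n > 1 and word.endswith("e") and not word.endswith(("le", "ee", "ye")):
        n -= 1
    return max(n, 1)


def fre(text: str) -> float:
    """Flesch Reading Ease:
    206.835 - 1.015 * (words/sentences) - 84.6 * (syllables/words).

    Sentences are delimited by line breaks and terminal punctuation
    (templated summaries are one statement per line); at least one
    sentence is assumed.
    """
    words = tokenize(text)
    if not words:
        raise ValueError("fre requires at least one word")
    sentences = [s for s in re.split(r"[.!?\n]+", text) if s.strip()]
    n_sent = max(len(sentences), 1)
    n_syll = sum(count_syllables(w) for w in words)
    return 206.835 - 1.015 * (len(words) / n_sent) - 84.6 * (n_syll / len(words))


# ---------------------------------------------------------------------------
# Topic modelling

@dataclass
class TopicModel:
    """Fitted LDA model with its vectorizer and coherence score."""

    n_topics: int
    vectorizer: CountVectorizer
    lda: LatentDirichletAllocation
    coherence: float
    topic_word: np.ndarray  # rows sum to 1
    doc_token_sets: list[set] = field(default_factory=list, repr=False)

    def infer(self, text: str) -> np.ndarray:
        """Posterior topic distribution of one text."""
        X = self.vectorizer.transform([text])
        return self.lda.transform(X)[0]

    def top_terms(self, topic: int, top_n: int = 10) -> list[str]:
        vocab = self.vectorizer.get_feature_names_out()
        order = np.argsort(self.topic_word[topic])[::-1][:top_n]
        return [vocab[i] for i in order]


def _doc_npmi_matrix(terms: Sequence[str], doc_sets: Sequence[set]) -> np.ndarray:
    """Pairwise NPMI of terms from boolean document co-occurrence."""
    D = len(doc_sets)
    eps = 1e-12
    p = np.array([sum(t in d for d in doc_sets) / D for t in terms])
    M = np.zeros((len(terms), len(terms)))
    for i, ti in enumerate(terms):
        for j, tj in enumerate(terms):
            if i == j:
                M[i, j] = 1.0
                continue
            p_ij = sum(ti in d and tj in d for d in doc_sets) / D
            if p_ij <= 0 or p[i] <= 0 or p[j] <= 0:
                M[i, j] = -1.0
                continue
            pmi = math.log((p_ij + eps) / (p[i] * p[j]))
            M[i, j] = pmi / (-math.log(p_ij + eps))
    return M


def coherence_cv(
    topic_terms: Sequence[Sequence[str]], doc_sets: Sequence[set]
) -> float:
    """C_V-style coherence: for each topic, embed each top term as its
    NPMI vector against the topic's term set and average the cosine with
    the summed set vector; topics are then averaged."""
    scores = []
    for terms in topic_terms:
        terms = [t for t in terms if any(t in d for d in doc_sets)]
        if len(terms) < 2:
            continue
        M = _doc_npmi_matrix(terms, doc_sets)
        set_vec = M.sum(axis=0)
        sims = []
        for i in range(len(terms)):
            if np.linalg.norm(M[i]) == 0 or np.linalg.norm(set_vec) == 0:
                continue
            sims.append(cosine(M[i], set_vec))
        if sims:
            scores.append(float(np.mean(sims)))
    return float(np.mean(scores)) if scores else float("nan")


def fit_topic_model(
    reference_corpus: Sequence[str],
    k_range: Iterable[int] = range(2, 101, 2),
    seed: int = 0,
    top_n: int = 10,
) -> TopicModel:
    """Fit one LDA model per candidate topic count and keep the most
    coherent one. Reproducible for a fixed seed."""
    corpus = list(reference_corpus)
    k_range = sorted(set(k_range))
    if not k_range:
        raise ValueError("k_range must be non-empty")
    vectorizer = CountVectorizer(analyzer=tokenize)
    X = vectorizer.fit_transform(corpus)
    doc_sets = [set(tokenize(doc)) for doc in corpus]
    degenerate = len({frozenset(d) for d in doc_sets}) == 1
    if degenerate:
        import logging

        logging.getLogger(__name__).warning(
            "degenerate corpus (all documents identical); using smallest k"
        )
        k_range = k_range[:1]

    best: TopicModel | None = None
    for k in k_range:
        if k > max(2, X.shape[0]):
            continue
        lda = LatentDirichletAllocation(
            n_components=k, random_state=seed, max_iter=30
        )
        lda.fit(X)
        topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
        vocab = vectorizer.get_feature_names_out()
        terms = [
            [vocab[i] for i in np.argsort(topic_word[t])[::-1][:top_n]]
            for t in range(k)
        ]
        coh = coherence_cv(terms, doc_sets)
        model = TopicModel(k, vectorizer, lda, coh, topic_word, doc_sets)
        if best is None or (not math.isnan(coh) and coh > best.coherence):
            best = model
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Distribution and overlap metrics

def jsd(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen--Shannon divergence, log base 2, bounded [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    for name, vec in (("p", p), ("q", q)):
        if abs(vec.sum() - 1.0) > 1e-6 or (vec < -1e-12).any():
            raise ValueError(f"{name} is not a probability distribution")
    return float(jensenshannon(p, q, base=2) ** 2)


def contextual_similarity(
    summary: str, reference: str, embeddings: EmbeddingStore
) -> float | None:
    """Cosine of the unweighted mean word vectors of the two texts;
    ``None`` when either text has no in-vocabulary words."""
    u = embeddings.mean_vector(tokenize(summary))
    v = embeddings.mean_vector(tokenize(reference))
    if u is None or v is None:
        return None
    return cosine(u, v)


def _dominant_term_set(
    model: TopicModel, text: str, top_n: int
) -> set[str] | None:
    post = model.infer(text)
    dominant = [t for t in range(model.n_topics) if post[t] > 1.0 / model.n_topics]
    if not dominant:
        return None
    terms: set[str] = set()
    for t in dominant:
        terms.update(model.top_terms(t, top_n))
    return terms


def thematic_overlap(
    summary: str, reference: str, model: TopicModel, top_n: int = 10
) -> float | None:
    """Share of the reference's dominant-topic top terms also covered by
    the summary's dominant topics; ``None`` if either side has no
    dominant topic."""
    s_terms = _dominant_term_set(model, summary, top_n)
    r_terms = _dominant_term_set(model, reference, top_n)
    if s_terms is None or r_terms is None or not r_terms:
        return None
    return len(s_terms & r_terms) / len(r_terms)


# ---------------------------------------------------------------------------
# ROUGE

def _ngram_counts(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    dp = [0] * (len(b) + 1)
    for x in a:
        prev = 0
        for j, y in enumerate(b, start=1):
            cur = dp[j]
            dp[j] = prev + 1 if x == y else max(dp[j], dp[j - 1])
            prev = cur
    return dp[len(b)]


def rouge(candidate: str, reference: str, variant: str = "1") -> dict[str, float]:
    """ROUGE-1/2 (n-gram overlap) or ROUGE-L (longest common subsequence);
    returns recall and F1. Tokenization is the shared normalizer; no
    stemming or stopword removal."""
    cand = tokenize(candidate)
    ref = tokenize(reference)
    if not ref:
        raise ValueError("rouge requires a non-empty reference")
    if variant in ("1", "2", 1, 2):
        n = int(variant)
        c_counts = _ngram_counts(cand, n)
        r_counts = _ngram_counts(ref, n)
        overlap = sum((c_counts & r_counts).values())
        n_cand = max(sum(c_counts.values()), 0)
        n_ref = sum(r_counts.values())
    elif variant in ("L", "l"):
        overlap = _lcs_length(cand, ref)
        n_cand = len(cand)
        n_ref = len(ref)
    else:
        raise ValueError(f"unknown ROUGE variant {variant!r}")
    recall = overlap / n_ref if n_ref else 0.0
    precision = overlap / n_cand if n_cand else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"recall": recall, "f1": f1}


# ---------------------------------------------------------------------------
# Report

@dataclass
class EvalReport:
    conversation_id: str
    fre: float | None = None
    jsd: float | None = None
    contextual_similarity: float | None = None
    thematic_overlap: float | None = None
    rouge: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "conversation_id": self.conversation_id,
            "fre": self.fre,
            "jsd": self.jsd,
            "contextual_similarity": self.contextual_similarity,
            "thematic_overlap": self.thematic_overlap,
            "rouge": self.rouge,
        }


def evaluate_summary(
    conversation_id: str,
    summary_text: str,
    reference_text: str,
    embeddings: EmbeddingStore | None = None,
    topic_model: TopicModel | None = None,
    top_n: int = 10,
) -> EvalReport:
    """Compute all metrics for one (summary, reference) pair; metrics whose
    resources are missing are left as None (explicitly not computed)."""
    report = EvalReport(conversation_id)
    if tokenize(summary_text):
        report.fre = fre(summary_text)
    if embeddings is not None:
        report.contextual_similarity = contextual_similarity(
            summary_text, reference_text, embeddings
        )
    if topic_model is not None:
        p = topic_model.infer(summary_text)
        q = topic_model.infer(reference_text)
        report.jsd = jsd(p / p.sum(), q / q.sum())
        report.thematic_overlap = thematic_overlap(
            summary_text, reference_text, topic_model, top_n
        )
    for variant in ("1", "2", "L"):
        report.rouge[f"r{variant.lower()}"] = rouge(
            summary_text, reference_text, variant
        )
    return report
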
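"""Depression lexicon loading, n-gram statistics, and phrase matching.

The lexicon follows the nine-item Patient Health Questionnaire (PHQ-9):
nine signal categories S1..S9, each a set of indicative phrases (e.g.
"trouble sleeping" under the sleep-disorder signal S3). Matching a
statement against the lexicon is the knowledge source for pruning: a
statement is clinically informative evidence if it contains a lexicon
phrase verbatim (exact match) or an n-gram whose embedding is close to a
lexicon phrase's embedding (semantic match). The matcher prefers recall
over precision, since a phrase like "nobody likes me" said once is a
signal a frequency-based method would miss.
"""

from __future__ import annotations

import csv
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from ._text import tokenize

if TYPE_CHECKING:  # pragma: no cover
    from .embeddings import EmbeddingStore
    from .transcripts import Statement

__all__ = [
    "VALID_CATEGORIES",
    "CATEGORY_LABELS",
    "DepressionLexicon",
    "PhraseMatch",
    "LexiconError",
    "load_lexicon",
    "save_lexicon",
    "extract_ngrams",
    "NgramCounts",
    "npmi",
    "match_statement",
]

VALID_CATEGORIES = tuple(f"S{i}" for i in range(1, 10))

#: The nine PHQ-9 signal categories.
CATEGORY_LABELS: dict[str, str] = {
    "S1": "decreased pleasure in most activities",
    "S2": "feeling down",
    "S3": "sleep disorders",
    "S4": "loss of energy",
    "S5": "significant change in appetite",
    "S6": "feeling worthless",
    "S7": "concentration problems",
    "S8": "hyper or lower activity",
    "S9": "suicidal thoughts",
}


class LexiconError(ValueError):
    """Invalid lexicon content (unknown category, empty phrase, ...)."""


@dataclass
class DepressionLexicon:
    """Map from signal category (S1..S9) to its indicative phrases."""

    categories: dict[str, set[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=lambda: dict(CATEGORY_LABELS))

    def __post_init__(self) -> None:
        bad = sorted(set(self.categories) - set(VALID_CATEGORIES))
        if bad:
            raise LexiconError(f"unknown lexicon categories: {bad}")
        for cat, phrases in self.categories.items():
            self.categories[cat] = {
                " ".join(tokenize(p)) for p in phrases if p.strip()
            }

    @property
    def vocabulary(self) -> set[str]:
        """Every word occurring in any phrase."""
        return {w for ph in self.iter_phrases() for w in ph.split()}

    def iter_phrases(self) -> Iterable[str]:
        for phrases in self.categories.values():
            yield from phrases

    def items(self) -> Iterable[tuple[str, str]]:
        """Yield (category, phrase) pairs in deterministic order."""
        for cat in sorted(self.categories):
            for phrase in sorted(self.categories[cat]):
                yield cat, phrase

    def __len__(self) -> int:
        return sum(len(p) for p in self.categories.values())


@dataclass(frozen=True)
class PhraseMatch:
    pair_index: int
    matched_ngram: str
    lexicon_phrase: str
    category: str
    kind: str  # "exact" | "semantic"
    score: float


def load_lexicon(path: str | Path) -> DepressionLexicon:
    """Load a lexicon from CSV (``category,phrase`` rows) or JSON
    (``{category: [phrases]}``)."""
    path = Path(path)
    categories: dict[str, set[str]] = {}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise LexiconError(f"{path}: expected a JSON object")
        for cat, phrases in data.items():
            categories.setdefault(cat, set()).update(map(str, phrases))
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() == "category":
                    continue
                if len(row) < 2:
                    raise LexiconError(f"{path}: malformed row {row!r}")
                categories.setdefault(row[0].strip(), set()).add(row[1])
    return DepressionLexicon(categories)


def save_lexicon(lexicon: DepressionLexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", "phrase"])
        for cat, phrase in lexicon.items():
            writer.writerow([cat, phrase])


def extract_ngrams(text: str | Sequence[str], n: int) -> list[str]:
    """Contiguous n-grams (space-joined) in order; [] if fewer than n tokens."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    tokens = tokenize(text) if isinstance(text, str) else list(text)
    return [" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


@dataclass
class NgramCounts:
    """Corpus frequency table for NPMI: unigram counts, n-gram counts per
    order, and the corresponding totals."""

    unigrams: Counter = field(default_factory=Counter)
    ngrams: dict[int, Counter] = field(default_factory=dict)
    total_unigrams: int = 0
    total_ngrams: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_texts(cls, texts: Iterable[str], orders: Iterable[int] = (2, 3)) -> "NgramCounts":
        counts = cls()
        orders = list(orders)
        counts.ngrams = {n: Counter() for n in orders}
        counts.total_ngrams = {n: 0 for n in orders}
        for text in texts:
            tokens = tokenize(text)
            counts.unigrams.update(tokens)
            counts.total_unigrams += len(tokens)
            for n in orders:
                grams = extract_ngrams(tokens, n)
                counts.ngrams[n].update(grams)
                counts.total_ngrams[n] += len(grams)
        return counts

    def mean_npmi(self, n: int, min_count: int = 1) -> float:
        """Count-weighted mean NPMI over all stored n-grams of order n."""
        table = self.ngrams[n]
        num = den = 0.0
        for gram, c in table.items():
            if c < min_count:
                continue
            num += c * npmi(gram, self)
            den += c
        return num / den if den else float("nan")


def npmi(ngram: str, counts: NgramCounts) -> float:
    """Normalized pointwise mutual information of an n-gram, in [-1, 1].

    npmi = pmi / (-log p(ngram)), with pmi = log[p(ngram) / prod p(w_i)]
    (natural log). Word probabilities use the unigram total; the n-gram
    probability uses the total number of n-grams of its order. The
    degenerate p(ngram) = 1 returns 1 by continuity.
    """
    words = ngram.split()
    n = len(words)
    c_ngram = counts.ngrams.get(n, Counter()).get(ngram, 0)
    if c_ngram <= 0:
        raise ValueError(f"n-gram {ngram!r} has zero count")
    p_ngram = c_ngram / counts.total_ngrams[n]
    if p_ngram >= 1.0:
        return 1.0
    p_words = 1.0
    for w in words:
        c_w = counts.unigrams.get(w, 0)
        if c_w <= 0:
            raise ValueError(f"word {w!r} has zero count")
        p_words *= c_w / counts.total_unigrams
    pmi = math.log(p_ngram / p_words)
    return max(-1.0, min(1.0, pmi / (-math.log(p_ngram))))


def _contains_phrase(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> bool:
    m = len(phrase_tokens)
    return any(
        list(tokens[i : i + m]) == list(phrase_tokens)
        for i in range(len(tokens) - m + 1)
    )


def match_statement(
    statement: "Statement | str",
    lexicon: DepressionLexicon,
    embeddings: "EmbeddingStore | None" = None,
    tau: float = 0.6,
) -> list[PhraseMatch]:
    """Find exact and semantic lexicon matches in a templated statement.

    Exact: a lexicon phrase occurs as a contiguous token subsequence
    (score 1). Semantic: a statement bigram/trigram whose mean word vector
    has cosine >= ``tau`` with some lexicon phrase's mean word vector; each
    matched n-gram is reported once with its best-scoring lexicon phrase.
    Without an embedding store only exact matching runs.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    from .transcripts import Statement  # local import to avoid cycle

    if isinstance(statement, Statement):
        tokens = statement.tokens()
        pair_index = statement.source_pair_index
    else:
        tokens = tokenize(statement)
        pair_index = -1

    matches: list[PhraseMatch] = []
    matched_ngrams: set[str] = set()

    for cat, phrase in lexicon.items():
        ptoks = phrase.split()
        if ptoks and _contains_phrase(tokens, ptoks):
            if phrase not in matched_ngrams:
                matches.append(
                    PhraseMatch(pair_index, phrase, phrase, cat, "exact", 1.0)
                )
                matched_ngrams.add(phrase)

    if embeddings is not None:
        phrase_vecs = [
            (cat, phrase, embeddings.mean_vector(phrase.split()))
            for cat, phrase in lexicon.items()
        ]
        phrase_vecs = [(c, p, v) for c, p, v in phrase_vecs if v is not None]
        for n in (2, 3):
            for gram in dict.fromkeys(extract_ngrams(tokens, n)):
                if gram in matched_ngrams:
                    continue
                gvec = embeddings.mean_vector(gram.split())
                if gvec is None:
                    continue
                best: tuple[float, str, str] | None = None
                for cat, phrase, pvec in phrase_vecs:
                    score = float(embeddings.cosine_vec(gvec, pvec))
                    if best is None or score > best[0]:
                        best = (score, cat, phrase)
                if best is not None and best[0] >= tau:
                    matches.append(
                        PhraseMatch(
                            pair_index, gram, best[2], best[1], "semantic",
                            min(best[0], 1.0),
                        )
                    )
                    matched_ngrams.add(gram)
    return matches
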
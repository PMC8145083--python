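"""Seeded synthetic interviews, toy lexicons, embeddings, and language
models.

The generator emulates the structure of Wizard-of-Oz clinical diagnostic
interviews without using any real patient text: ~50-60 question--answer
turns arranged in a neutral -> clinical -> cool-down arc, depression-
lexicon phrases planted in a minority of clinical-phase answers,
occasional anaphoric answers that respond to an earlier question, and
speech disfluencies ("uh", "um", unrecognizable "xxx"). A ground-truth
sidecar records which pairs are clinical and which are anaphoric so that
recovery can be measured.

It deliberately does *not* model realistic patient language: answers are
drawn from small template banks, so lexical diversity, grammar errors and
topic drift of real interviews are absent. Passing tests on this corpus
demonstrates that the pipeline surfaces planted clinical content under
controlled conditions, not clinical validity on real data.
"""

from __future__ import annotations

import json
import math
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._text import STOPWORDS, tokenize
from .embeddings import EmbeddingStore
from .lexicon import DepressionLexicon
from .lm import BOS, EOS, UNK, TrigramLM
from .transcripts import Transcript, Utterance

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "make_toy_lexicon",
    "generate_interview",
    "make_embeddings",
    "make_toy_lm",
]


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_pairs: int = 58
    clinical_rate: float = 0.3
    anaphora_rate: float = 0.1
    disfluency_rate: float = 0.2
    #: proportions of the neutral / clinical / cool-down phases
    phases: tuple[float, float, float] = (0.25, 0.55, 0.20)

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for name in ("clinical_rate", "anaphora_rate", "disfluency_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.phases) - 1.0) > 1e-9:
            raise ValueError("phase proportions must sum to 1")


@dataclass
class GroundTruth:
    """Planted structure of a generated interview."""

    clinical_pair_indices: list[int] = field(default_factory=list)
    anaphoric_pair_indices: list[int] = field(default_factory=list)
    planted_phrases: dict[int, str] = field(default_factory=dict)
    phase_of_pair: dict[int, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clinical_pair_indices": self.clinical_pair_indices,
            "anaphoric_pair_indices": self.anaphoric_pair_indices,
            "planted_phrases": {str(k): v for k, v in self.planted_phrases.items()},
            "phase_of_pair": {str(k): v for k, v in self.phase_of_pair.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Toy lexicon

#: Built-in phrase bank keyed to the nine PHQ-9 signal categories. Phrases
#: use content words only, so function words never carry category signal.
_LEXICON_BANK: dict[str, list[str]] = {
    "S1": ["lost interest", "joyless days", "stopped enjoying hobbies"],
    "S2": ["feeling down", "feeling hopeless", "deep sadness"],
    "S3": ["trouble sleeping", "insomnia", "sleepless nights"],
    "S4": ["low energy", "feeling lethargic", "constantly exhausted"],
    "S5": ["poor appetite", "overeating constantly", "skipping meals"],
    "S6": ["feeling worthless", "nobody likes me", "total failure"],
    "S7": ["trouble concentrating", "cannot focus", "scattered thoughts"],
    "S8": ["moving sluggishly", "restless and fidgety", "pacing endlessly"],
    "S9": ["suicidal thoughts", "better off dead", "hurting myself"],
}


def make_toy_lexicon(seed: int = 0) -> DepressionLexicon:
    """Nine-category toy depression lexicon drawn from the built-in bank.

    The bank itself is fixed; the seed only fixes iteration order, so the
    same seed always yields the same lexicon.
    """
    rng = random.Random(seed)
    categories = {cat: set(phrases) for cat, phrases in _LEXICON_BANK.items()}
    rng.random()  # reserved draw: keeps parity with earlier versions
    return DepressionLexicon(categories)


# ---------------------------------------------------------------------------
# Interview generator

_NEUTRAL_QUESTIONS = [
    "okay what'd you study at school",
    "that's good where are you from originally",
    "how do you like l.a.",
    "what are some things you enjoy doing for fun",
    "do you travel much",
    "tell me about where you grew up",
    "who lives with you at home",
    "what did you do last weekend",
]

_NEUTRAL_ANSWERS = [
    "i studied engineering at college",
    "i am from portland originally",
    "i really like the weather",
    "we go hiking most weekends",
    "i grew up near chicago",
    "my sister lives with me",
    "we visited the coast recently",
    "i play guitar with friends",
]

_CLINICAL_QUESTIONS = [
    "is there anything you regret",
    "have you been diagnosed with depression",
    "have you been diagnosed with ptsd",
    "when did you last see a therapist",
    "how have you been doing emotionally",
    "what got you to seek help",
    "how has your mood been recently",
    "do you find it hard to unwind",
]

_CLINICAL_FILLER_ANSWERS = [
    "yeah a while ago",
    "i guess so maybe",
    "hmm possibly yeah",
    "it is hard to say",
    "yeah that happens sometimes",
    "i think so yeah",
]

_PLANTED_TEMPLATES = [
    "yeah {phrase} recently",
    "well {phrase} mostly",
    "honestly {phrase} these days",
    "{phrase} almost daily",
]

_COOLDOWN_QUESTIONS = [
    "okay when was the last time you felt really happy",
    "cool how would your best friend describe you",
    "who has been a positive influence in your life",
    "what are you looking forward to",
]

_COOLDOWN_ANSWERS = [
    "probably last summer i think",
    "they would say i am kind",
    "my grandmother definitely",
    "seeing my family next month",
]

_ANAPHORA_ANSWERS = [
    "about what you asked earlier yeah",
    "like i said before not really",
    "going back to your question yes",
]

_DISFLUENCIES = ["uh", "um", "xxx"]


def _phase_lengths(n_pairs: int, phases: Sequence[float]) -> tuple[int, int, int]:
    n1 = round(phases[0] * n_pairs)
    n3 = round(phases[2] * n_pairs)
    n2 = n_pairs - n1 - n3
    if n2 < 0:  # tiny interviews: give everything to the clinical phase
        n1, n2, n3 = 0, n_pairs, 0
    return n1, n2, n3


def generate_interview(
    config: GeneratorConfig, lexicon: DepressionLexicon
) -> tuple[Transcript, GroundTruth]:
    """Generate one synthetic interview transcript plus its ground truth.

    Clinical-phase answers embed a lexicon phrase with probability
    ``clinical_rate``; with probability ``anaphora_rate`` an answer
    instead responds to a question asked at least two pairs earlier;
    disfluencies are prepended at ``disfluency_rate``. Deterministic for
    a fixed (seed, config, lexicon).
    """
    if config.clinical_rate > 0 and not lexicon.categories:
        raise ValueError("clinical_rate > 0 requires a non-empty lexicon")
    rng = random.Random(config.seed)
    phrases = [phrase for _, phrase in lexicon.items()]
    n1, n2, _ = _phase_lengths(config.n_pairs, config.phases)

    truth = GroundTruth()
    utterances: list[Utterance] = []
    turn = 0

    def emit(speaker: str, text: str) -> None:
        nonlocal turn
        utterances.append(Utterance(speaker, text, turn))
        turn += 1

    for pair_index in range(config.n_pairs):
        if pair_index < n1:
            phase = "neutral"
            question = rng.choice(_NEUTRAL_QUESTIONS)
            answer = rng.choice(_NEUTRAL_ANSWERS)
        elif pair_index < n1 + n2:
            phase = "clinical"
            question = rng.choice(_CLINICAL_QUESTIONS)
            if phrases and rng.random() < config.clinical_rate:
                phrase = rng.choice(phrases)
                answer = rng.choice(_PLANTED_TEMPLATES).format(phrase=phrase)
                truth.clinical_pair_indices.append(pair_index)
                truth.planted_phrases[pair_index] = phrase
            else:
                answer = rng.choice(_CLINICAL_FILLER_ANSWERS)
        else:
            phase = "cooldown"
            question = rng.choice(_COOLDOWN_QUESTIONS)
            answer = rng.choice(_COOLDOWN_ANSWERS)

        # anaphoric answers point back >= 2 pairs; never overwrite a plant
        if (
            pair_index >= 2
            and pair_index not in truth.planted_phrases
            and rng.random() < config.anaphora_rate
        ):
            answer = rng.choice(_ANAPHORA_ANSWERS)
            truth.anaphoric_pair_indices.append(pair_index)

        if rng.random() < config.disfluency_rate:
            answer = f"{rng.choice(_DISFLUENCIES)} {answer}"

        truth.phase_of_pair[pair_index] = phase
        emit("interviewer", question)
        emit("participant", answer)
        # occasional second participant turn, exercising answer merging
        if rng.random() < 0.15:
            emit("participant", "yeah")

    transcript = Transcript(f"synthetic-{config.seed}", utterances)
    return transcript, truth


# ---------------------------------------------------------------------------
# Toy embeddings

def make_embeddings(
    vocab: Sequence[str] | set[str],
    dim: int,
    lexicon: DepressionLexicon,
    seed: int = 0,
) -> EmbeddingStore:
    """Random unit vectors with planted category structure.

    Content words of the same lexicon category share an anchor direction
    (pairwise cosine >= 0.7 by construction: each vector deviates from
    its anchor by at most arcsin(0.2)); all other words are independent
    random unit vectors, so unrelated pairs have expected cosine ~ 0.
    Function words never receive category anchors — they would leak
    clinical similarity into every sentence.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    anchors = {
        cat: unit(rng.standard_normal(dim))
        for cat in sorted(lexicon.categories)
    }
    word_category: dict[str, str] = {}
    for cat in sorted(lexicon.categories):
        for phrase in sorted(lexicon.categories[cat]):
            for w in phrase.split():
                if w not in STOPWORDS:
                    word_category.setdefault(w, cat)

    vectors: dict[str, np.ndarray] = {}
    for word in sorted(set(vocab) | set(word_category)):
        if word in word_category:
            noise = unit(rng.standard_normal(dim))
            vectors[word] = unit(anchors[word_category[word]] + 0.2 * noise)
        else:
            vectors[word] = unit(rng.standard_normal(dim))
    return EmbeddingStore(vectors)


# ---------------------------------------------------------------------------
# Toy language model

def make_toy_lm(
    corpus: Sequence[str], smoothing_k: float = 0.1, log_floor: float = -10.0
) -> TrigramLM:
    """Add-k maximum-likelihood trigram model with proper back-off weights.

    For each stored context, observed continuations get add-k conditional
    probabilities and the leftover mass is redistributed over unobserved
    continuations via a Katz-style back-off weight, so probabilities at
    every order sum to 1 over the closed vocabulary (words + sentence
    markers + <unk>).
    """
    if not corpus:
        raise ValueError("make_toy_lm requires a non-empty corpus")
    k = smoothing_k
    sentences = [tokenize(text) for text in corpus]
    sentences = [s for s in sentences if s]
    if not sentences:
        raise ValueError("corpus contains no tokens")

    vocab = sorted({w for s in sentences for w in s} | {EOS, UNK})
    V = len(vocab)  # <s> is context-only and excluded from smoothing mass
    uni = Counter()
    bi = Counter()
    tri = Counter()
    bi_ctx = Counter()
    tri_ctx = Counter()
    for s in sentences:
        padded = [BOS, BOS, *s, EOS]
        uni.update(padded[2:])
        for i in range(1, len(padded)):
            bi[(padded[i - 1], padded[i])] += 1
            bi_ctx[padded[i - 1]] += 1
        for i in range(2, len(padded)):
            tri[(padded[i - 2], padded[i - 1], padded[i])] += 1
            tri_ctx[(padded[i - 2], padded[i - 1])] += 1

    N = sum(uni.values())
    p_uni = {w: (uni.get(w, 0) + k) / (N + k * V) for w in vocab}

    def p_bi(u: str, w: str) -> float:
        if (u, w) in bi:
            return (bi[(u, w)] + k) / (bi_ctx[u] + k * V)
        return bo_uni.get(u, 1.0) * p_uni[w]

    lm = TrigramLM(log_floor=log_floor)
    for w, p in p_uni.items():
        lm.unigrams[w] = math.log10(p)
    lm.unigrams[BOS] = -99.0  # conventional: <s> is context-only

    # bigram section and unigram back-off weights
    bo_uni: dict[str, float] = {}
    contexts1 = sorted(bi_ctx)
    for u in contexts1:
        observed = [w for (uu, w) in bi if uu == u]
        mass_obs = sum((bi[(u, w)] + k) / (bi_ctx[u] + k * V) for w in observed)
        uni_obs = sum(p_uni[w] for w in observed if w in p_uni)
        denom = 1.0 - uni_obs
        bo_uni[u] = (1.0 - mass_obs) / denom if denom > 1e-12 else 0.0
    for (u, w), c in sorted(bi.items()):
        lm.bigrams[(u, w)] = math.log10((c + k) / (bi_ctx[u] + k * V))
    for u, b in bo_uni.items():
        if u in lm.unigrams:
            lm.unigram_backoff[u] = math.log10(b) if b > 0 else -99.0

    # trigram section and bigram back-off weights
    for (u, v), _ in sorted(tri_ctx.items()):
        observed = [w for (uu, vv, w) in tri if (uu, vv) == (u, v)]
        mass_obs = sum(
            (tri[(u, v, w)] + k) / (tri_ctx[(u, v)] + k * V) for w in observed
        )
        low_obs = sum(p_bi(v, w) for w in observed)
        denom = 1.0 - low_obs
        b = (1.0 - mass_obs) / denom if denom > 1e-12 else 0.0
        if (u, v) in lm.bigrams:
            lm.bigram_backoff[(u, v)] = math.log10(b) if b > 0 else -99.0
    for (u, v, w), c in sorted(tri.items()):
        lm.trigrams[(u, v, w)] = math.log10((c + k) / (tri_ctx[(u, v)] + k * V))
    return lm
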
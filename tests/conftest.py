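"""Shared fixtures: toy lexicon, embeddings, language model, interviews."""

from __future__ import annotations

import numpy as np
import pytest

from kias.lexicon import DepressionLexicon
from kias.embeddings import EmbeddingStore
from kias.summarizer import Resources, SummarizerConfig
from kias.synthetic import (
    GeneratorConfig,
    generate_interview,
    make_embeddings,
    make_toy_lexicon,
    make_toy_lm,
)
from kias.transcripts import transcript_to_statements


@pytest.fixture(scope="session")
def toy_lexicon() -> DepressionLexicon:
    return make_toy_lexicon(seed=0)


@pytest.fixture()
def mini_lexicon() -> DepressionLexicon:
    return DepressionLexicon(
        {
            "S2": {"feeling down"},
            "S3": {"trouble sleeping", "insomnia"},
            "S6": {"nobody likes me"},
        }
    )


@pytest.fixture()
def unit_embeddings() -> EmbeddingStore:
    """Hand-chosen orthogonal/near vectors for deterministic cosine tests."""
    e1 = np.array([1.0, 0.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0, 0.0])
    e3 = np.array([0.0, 0.0, 1.0, 0.0])
    e4 = np.array([0.0, 0.0, 0.0, 1.0])
    return EmbeddingStore(
        {
            "trouble": e1,
            "sleeping": (e1 + 0.2 * e2) / np.linalg.norm(e1 + 0.2 * e2),
            "insomnia": (e1 + 0.1 * e3) / np.linalg.norm(e1 + 0.1 * e3),
            "feeling": e2,
            "down": (e2 + 0.2 * e3) / np.linalg.norm(e2 + 0.2 * e3),
            "nobody": e3,
            "likes": e3,
            "me": e3,
            "pilgrimage": e4,
            "israel": (e4 + 0.1 * e1) / np.linalg.norm(e4 + 0.1 * e1),
            "went": e4,
        }
    )


@pytest.fixture(scope="session")
def interview(toy_lexicon):
    """One synthetic interview plus its derived statements and resources."""
    config = GeneratorConfig(seed=7, n_pairs=58, clinical_rate=0.3)
    transcript, truth = generate_interview(config, toy_lexicon)
    pairs, statements = transcript_to_statements(transcript)
    vocab = {w for s in statements for w in s.tokens()}
    embeddings = make_embeddings(vocab, dim=50, lexicon=toy_lexicon, seed=7)
    lm = make_toy_lm([s.text for s in statements])
    resources = Resources(toy_lexicon, embeddings, lm, SummarizerConfig())
    return {
        "transcript": transcript,
        "truth": truth,
        "pairs": pairs,
        "statements": statements,
        "embeddings": embeddings,
        "lm": lm,
        "resources": resources,
    }
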
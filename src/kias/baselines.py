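"""Comparison systems: SumBasic extraction, plain abstraction, and
abstraction-over-extraction.

SumBasic is the frequency-based extractive baseline: sentences are scored
by the mean unigram probability of their words, the sentence containing
the currently most probable word is taken, and the probabilities of its
words are squared to discourage redundant picks. Plain abstractive
summarization (AS) is the full fusion/ILP pipeline with the word semantic
score switched off — a generic language model and no retrofitted
knowledge. AoES runs SumBasic as a prefilter and abstracts over the
surviving statements; it inherits extraction's blindness to rare but
clinically crucial phrases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from ._text import tokenize
from .pruning import prune
from .summarizer import Resources, Summary, summarize_statements
from .transcripts import Statement, Transcript, transcript_to_statements

__all__ = ["SumBasicState", "sumbasic", "sumbasic_select", "plain_as", "aoes"]


@dataclass
class SumBasicState:
    word_probabilities: dict[str, float] = field(default_factory=dict)
    selected: list[Statement] = field(default_factory=list)
    N: int = 0


def sumbasic_select(
    statements: Sequence[Statement], n_out: int
) -> tuple[list[Statement], SumBasicState]:
    """Greedy SumBasic selection; returns picks in selection order."""
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    statements = list(statements)
    if not statements:
        return [], SumBasicState()

    tokens_per = [s.tokens() for s in statements]
    N = sum(len(t) for t in tokens_per)
    probs: dict[str, float] = {}
    for toks in tokens_per:
        for w in toks:
            probs[w] = probs.get(w, 0.0) + 1.0 / N

    state = SumBasicState(word_probabilities=probs, N=N)
    remaining = list(range(len(statements)))
    while remaining and len(state.selected) < n_out:
        # highest-probability word currently present in any remaining statement
        candidate_words = {w for i in remaining for w in tokens_per[i]}
        if not candidate_words:
            break
        top_word = max(sorted(candidate_words), key=lambda w: probs[w])
        holders = [i for i in remaining if top_word in tokens_per[i]]
        best = max(
            holders,
            key=lambda i: (
                sum(probs[w] for w in tokens_per[i]) / len(tokens_per[i])
                if tokens_per[i]
                else 0.0,
                -i,  # earlier statement wins ties
            ),
        )
        state.selected.append(statements[best])
        remaining.remove(best)
        for w in set(tokens_per[best]):
            probs[w] = probs[w] ** 2
    return state.selected, state


def sumbasic(
    statements: Sequence[Statement],
    n_out: int | None = None,
    window: int = 7,
    conversation_id: str = "",
) -> Summary:
    """SumBasic extractive summary. ``n_out`` defaults to
    ceil(n_statements / window) so summary lengths are comparable with the
    abstractive systems."""
    statements = list(statements)
    if not statements:
        return Summary(conversation_id, status="empty input")
    if n_out is None:
        n_out = math.ceil(len(statements) / window)
    picks, _ = sumbasic_select(statements, n_out)
    summary = Summary(conversation_id)
    summary.sentences = [s.text for s in picks]
    return summary


def plain_as(transcript: Transcript, resources: Resources) -> Summary:
    """Plain abstractive summarization: the identical pipeline with the
    word semantic score identically zero (generic LM, no retrofitting).
    Operates on the same pruned conversations as the knowledge-infused
    system."""
    from dataclasses import replace

    cfg = replace(resources.config, use_wss=False)
    plain = Resources(resources.lexicon, resources.embeddings, resources.lm, cfg)
    _, statements = transcript_to_statements(transcript)
    summary, _, _ = summarize_statements(
        transcript.conversation_id, statements, plain
    )
    return summary


def aoes(
    transcript: Transcript,
    resources: Resources,
    es_fraction: float = 0.5,
    on_pruned: bool = True,
) -> Summary:
    """Abstraction over extraction: SumBasic keeps the top ``es_fraction``
    of statements, then plain abstraction runs on that subset (original
    order preserved). ``es_fraction=1`` reduces to plain AS."""
    if not 0.0 < es_fraction <= 1.0:
        raise ValueError("es_fraction must be in (0, 1]")
    from dataclasses import replace

    _, statements = transcript_to_statements(transcript)
    if on_pruned:
        pruned = prune(
            statements,
            resources.lexicon,
            embeddings=resources.embeddings,
            tau=resources.config.tau,
            r=resources.config.context_radius,
            conversation_id=transcript.conversation_id,
        )
        pool = pruned.statements
    else:
        pool = statements
    if not pool:
        return Summary(transcript.conversation_id, status="no clinical content")
    n_keep = max(1, math.ceil(es_fraction * len(pool)))
    picks, _ = sumbasic_select(pool, n_keep)
    picked_ids = {id(s) for s in picks}
    subset = [s for s in pool if id(s) in picked_ids]

    cfg = replace(resources.config, use_wss=False)
    plain = Resources(resources.lexicon, resources.embeddings, resources.lm, cfg)
    summary, _, _ = summarize_statements(
        transcript.conversation_id, subset, plain
    )
    return summary
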
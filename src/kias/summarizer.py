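"""Per-slice ILP selection and the end-to-end summarization pipeline.

Each slice contributes exactly one sentence to the summary: among the K
candidate fusion paths of the slice's word graph, a binary program

    maximize   sum_i x_i * (I_i + Q_i) / |W(p_i)|
    subject to sum_i x_i = 1,   x_i in {0, 1}

selects the path with the best length-normalized sum of informativeness
and linguistic quality; the 1/|W(p)| factor rewards concise paths. With a
single selection constraint the program reduces to an argmax, but the
binary formulation is kept (and cross-checked against the argmax) so that
additional inter-slice constraints can be added later.

Knowledge infusion enters in two places: word importance is elevated to
Imp(w) * (1 + WSS(w)) before informativeness is summed, and the language
model probabilities inside Q are boosted by the same word semantic score.
Setting WSS to zero everywhere recovers the plain abstractive baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .embeddings import EmbeddingStore, make_wss_fn
from .lexicon import DepressionLexicon
from .lm import TrigramLM, linguistic_quality
from .pruning import PrunedConversation, Slice, prune, slice_statements
from .transcripts import Statement, Transcript, transcript_to_statements
from .wordgraph import PathCandidate, build_graph, enumerate_paths, informativeness, textrank

log = logging.getLogger(__name__)

__all__ = [
    "SummarizerConfig",
    "Resources",
    "SliceSelection",
    "Summary",
    "score_path",
    "solve_slice",
    "argmax_select",
    "summarize_statements",
    "summarize",
]


@dataclass(frozen=True)
class SummarizerConfig:
    """Tunables of the summarization pipeline (defaults as used throughout)."""

    window: int = 7            # max Q&A pairs per slice
    d: float = 0.78            # TextRank damping factor
    tau: float = 0.6           # semantic-match cosine threshold
    context_radius: int = 1    # pruning keeps neighbors within this radius
    K: int = 100               # candidate paths per slice
    min_len: int = 8           # minimum words in a candidate path
    use_wss: bool = True       # False => plain abstractive baseline


@dataclass
class Resources:
    """Loaded model resources shared by the summarizers."""

    lexicon: DepressionLexicon
    embeddings: EmbeddingStore
    lm: TrigramLM
    config: SummarizerConfig = field(default_factory=SummarizerConfig)

    @classmethod
    def build(
        cls,
        lexicon: DepressionLexicon,
        embeddings: EmbeddingStore,
        lm: TrigramLM,
        config: SummarizerConfig | None = None,
        retrofit_config=None,
    ) -> "Resources":
        """Assemble resources, retrofitting the embeddings to the lexicon.

        The retrofitted store is shared by pruning and by WSS, so the
        knowledge-infused system and the plain baseline see the same
        pruned conversations (the baseline simply ignores WSS).
        """
        from .embeddings import RetrofitConfig, build_lexicon_graph, retrofit

        graph = build_lexicon_graph(lexicon)
        fitted = retrofit(embeddings, graph, retrofit_config or RetrofitConfig())
        return cls(lexicon, fitted, lm, config or SummarizerConfig())


@dataclass
class SliceSelection:
    slice_index: int
    candidates: list[PathCandidate]
    chosen: int
    objective_value: float

    @property
    def chosen_path(self) -> PathCandidate:
        return self.candidates[self.chosen]


@dataclass
class Summary:
    conversation_id: str
    selections: list[SliceSelection] = field(default_factory=list)
    sentences: list[str] = field(default_factory=list)
    status: str = "ok"

    @property
    def text(self) -> str:
        return "\n".join(self.sentences)


def score_path(path: PathCandidate) -> float:
    """Length-normalized combined score (I + Q) / |W(p)|."""
    if path.n_words == 0:
        raise ValueError("cannot score an empty path")
    return path.combined


def argmax_select(candidates: Sequence[PathCandidate]) -> int:
    """Direct argmax of the combined score with deterministic tie-breaks:
    ties go to the path with fewer words, then to the earlier candidate."""
    best = 0
    for i in range(1, len(candidates)):
        a, b = candidates[i], candidates[best]
        if a.combined > b.combined + 1e-12:
            best = i
        elif abs(a.combined - b.combined) <= 1e-12 and a.n_words < b.n_words:
            best = i
    return best


def solve_slice(
    candidates: Sequence[PathCandidate], slice_index: int = 0
) -> SliceSelection:
    """Solve the one-path-per-slice binary program.

    The MILP result is reconciled with the direct argmax: among candidates
    attaining the optimal objective (within 1e-9), ties are broken by
    fewer words, then earlier candidate rank.
    """
    if not candidates:
        raise ValueError("solve_slice requires at least one candidate")
    scores = np.array([score_path(c) for c in candidates], dtype=float)
    n = len(candidates)
    res = milp(
        c=-scores,  # milp minimizes
        constraints=LinearConstraint(np.ones((1, n)), lb=1, ub=1),
        integrality=np.ones(n),
        bounds=None,
    )
    if not res.success:  # pragma: no cover - tiny feasible program
        raise RuntimeError(f"ILP solver failed: {res.message}")
    optimum = float(scores @ res.x)
    # deterministic tie resolution at the optimum
    tied = [i for i in range(n) if scores[i] >= optimum - 1e-9]
    chosen = min(tied, key=lambda i: (candidates[i].n_words, i))
    assert chosen == argmax_select(candidates) or abs(
        scores[chosen] - scores[argmax_select(candidates)]
    ) <= 1e-9
    return SliceSelection(
        slice_index=slice_index,
        candidates=list(candidates),
        chosen=chosen,
        objective_value=float(scores[chosen]),
    )


def render_sentence(path: PathCandidate) -> str:
    """Render a fused path in question/answer display form, splitting at
    the template boundary '(the) participant said'."""
    words = list(path.words)
    split = None
    for i in range(1, len(words) - 1):
        if words[i] == "participant" and words[i + 1] == "said":
            split = i
    if split is None:
        return " ".join(words).capitalize()
    q_part = words[:split]
    if q_part and q_part[-1] == "the":
        q_part = q_part[:-1]
    a_part = words[split + 2 :]
    # strip the leading "participant was asked" for display
    if q_part[:3] == ["participant", "was", "asked"]:
        q_part = q_part[3:]
    q = " ".join(q_part).capitalize()
    a = " ".join(a_part).capitalize()
    return f"Participant was asked: {q} Participant said: {a}"


def _score_candidates(
    candidates: Sequence[PathCandidate],
    importance: dict,
    lm: TrigramLM,
    wss_fn: Callable[[str], float],
) -> None:
    """Attach I and Q to each candidate in place. Word importance is
    elevated by (1 + WSS) before summation, so lexicon-related words raise
    a path's informativeness as well as its quality."""
    elevated = {
        node: imp * (1.0 + wss_fn(node[1]))
        for node, imp in importance.items()
    }
    for pid, cand in enumerate(candidates):
        cand.I = informativeness(cand, elevated)
        cand.Q = linguistic_quality(cand.words, lm, wss_fn, path_id=pid).q


def summarize_statements(
    conversation_id: str,
    statements: Sequence[Statement],
    resources: Resources,
) -> tuple[Summary, PrunedConversation, list[Slice]]:
    """prune -> slice -> per-slice fuse/score/select. Returns the summary
    together with the pruned conversation and slices for inspection."""
    cfg = resources.config
    pruned = prune(
        statements,
        resources.lexicon,
        embeddings=resources.embeddings,
        tau=cfg.tau,
        r=cfg.context_radius,
        conversation_id=conversation_id,
    )
    if not pruned.statements:
        return (
            Summary(conversation_id, status="no clinical content"),
            pruned,
            [],
        )
    slices = slice_statements(pruned, window=cfg.window)
    wss_fn: Callable[[str], float]
    if cfg.use_wss:
        wss_fn = make_wss_fn(resources.embeddings, resources.lexicon)
    else:
        wss_fn = lambda w: 0.0  # noqa: E731 - plain abstractive baseline

    summary = Summary(conversation_id)
    for sl in slices:
        graph = build_graph(sl.statements)
        importance = textrank(graph, d=cfg.d)
        min_len = min(
            cfg.min_len, min(len(s.tokens()) for s in sl.statements)
        )
        candidates = enumerate_paths(graph, K=cfg.K, min_len=min_len)
        if not candidates:
            log.warning(
                "%s: slice %d produced no candidate paths; skipped",
                conversation_id,
                sl.slice_index,
            )
            continue
        _score_candidates(candidates, importance, resources.lm, wss_fn)
        selection = solve_slice(candidates, slice_index=sl.slice_index)
        summary.selections.append(selection)
        summary.sentences.append(render_sentence(selection.chosen_path))
    if not summary.sentences:
        summary.status = "no candidates"
    return summary, pruned, slices


def summarize(transcript: Transcript, resources: Resources) -> Summary:
    """End-to-end knowledge-infused summarization of one transcript."""
    _, statements = transcript_to_statements(transcript)
    summary, _, _ = summarize_statements(
        transcript.conversation_id, statements, resources
    )
    return summary
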
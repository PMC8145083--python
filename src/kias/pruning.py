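"""Lexicon-driven pruning and fixed-window slicing of statements.

Most of a diagnostic interview is rapport-building small talk; pruning
keeps only the templated statements that carry clinical evidence (a
depression-lexicon match) together with their immediate neighbors, which
supply context for anaphoric answers. The retained statements are then
partitioned into contiguous slices of at most ``window`` question--answer
pairs (7 by default, the context horizon estimated by clinicians); each
slice later yields exactly one summary sentence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

from .lexicon import DepressionLexicon, PhraseMatch, match_statement
from .transcripts import Statement

if TYPE_CHECKING:  # pragma: no cover
    from .embeddings import EmbeddingStore

__all__ = ["PrunedConversation", "Slice", "prune", "slice_statements", "slice_sizes"]


@dataclass
class PrunedConversation:
    conversation_id: str
    statements: list[Statement] = field(default_factory=list)
    matches: list[PhraseMatch] = field(default_factory=list)
    kept_indices: list[int] = field(default_factory=list)

    @property
    def text(self) -> str:
        return "\n".join(s.text for s in self.statements)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "conversation_id": self.conversation_id,
            "statements": [s.text for s in self.statements],
            "kept_indices": self.kept_indices,
            "matches": [
                {
                    "pair_index": m.pair_index,
                    "matched_ngram": m.matched_ngram,
                    "lexicon_phrase": m.lexicon_phrase,
                    "category": m.category,
                    "kind": m.kind,
                    "score": m.score,
                }
                for m in self.matches
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


@dataclass
class Slice:
    slice_index: int
    statements: list[Statement]


def prune(
    statements: Sequence[Statement],
    lexicon: DepressionLexicon,
    embeddings: "EmbeddingStore | None" = None,
    tau: float = 0.6,
    r: int = 1,
    conversation_id: str = "",
) -> PrunedConversation:
    """Keep statement i iff some statement j with ``|i - j| <= r`` has at
    least one lexicon match.

    Statements from pairs with empty answers never count as matching
    evidence themselves, but may be retained as context of a neighbor's
    match. An empty statement list yields an empty pruned conversation.
    """
    if r < 0:
        raise ValueError("context radius r must be >= 0")
    statements = list(statements)
    per_statement: list[list[PhraseMatch]] = []
    for s in statements:
        if not s.has_answer:
            per_statement.append([])
            continue
        per_statement.append(
            match_statement(s, lexicon, embeddings=embeddings, tau=tau)
        )
    has_match = [bool(m) for m in per_statement]
    keep = [
        any(has_match[j] for j in range(max(0, i - r), min(len(statements), i + r + 1)))
        for i in range(len(statements))
    ]
    kept = [i for i, k in enumerate(keep) if k]
    return PrunedConversation(
        conversation_id=conversation_id,
        statements=[statements[i] for i in kept],
        matches=[m for i in kept for m in per_statement[i]],
        kept_indices=[statements[i].source_pair_index for i in kept],
    )


def slice_sizes(n: int, window: int) -> list[int]:
    """Even partition of n into k = ceil(n/window) parts, larger first.

    Sizes differ by at most one and never exceed ``window``; e.g. 20 pairs
    at window 7 -> [7, 7, 6], and 15 -> [5, 5, 5].
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if n == 0:
        return []
    k = math.ceil(n / window)
    base, extra = divmod(n, k)
    return [base + 1] * extra + [base] * (k - extra)


def slice_statements(pruned: PrunedConversation, window: int = 7) -> list[Slice]:
    """Partition the pruned statements into balanced contiguous slices."""
    sizes = slice_sizes(len(pruned.statements), window)
    slices: list[Slice] = []
    start = 0
    for idx, size in enumerate(sizes):
        slices.append(Slice(idx, pruned.statements[start : start + size]))
        start += size
    return slices
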
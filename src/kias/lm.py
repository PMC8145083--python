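"""Back-off trigram language model and the linguistic-quality score Q.

The model is a standard ARPA back-off trigram LM (log base 10). The
linguistic quality of a candidate word path combines two signals:
fluency, via the trigram conditional probabilities, and clinical
relevance, via the word semantic score (WSS). Each word's probability is
boosted multiplicatively by (1 + WSS) and capped at 1; the mean log
probability is normalized to [0, 1] against a log-probability floor, and

    Q = 1 - LL_norm

so Q is 1 for a perfectly fluent, fully boosted path and 0 when every
word sits at the floor. With WSS identically zero, Q reduces to a pure
length-normalized fluency score (the plain abstractive baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

__all__ = [
    "BOS",
    "EOS",
    "UNK",
    "DEFAULT_LOG_FLOOR",
    "TrigramLM",
    "QualityScore",
    "ArpaParseError",
    "load_arpa",
    "write_arpa",
    "logprob",
    "sentence_logprob",
    "linguistic_quality",
]

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"

#: Default floor on per-word log10 probability (also the OOV score).
DEFAULT_LOG_FLOOR = -10.0


class ArpaParseError(ValueError):
    pass


@dataclass
class TrigramLM:
    """ARPA-style back-off model: log10 probabilities for orders 1-3 and
    back-off weights for orders 1-2."""

    unigrams: dict[str, float] = field(default_factory=dict)
    bigrams: dict[tuple[str, str], float] = field(default_factory=dict)
    trigrams: dict[tuple[str, str, str], float] = field(default_factory=dict)
    unigram_backoff: dict[str, float] = field(default_factory=dict)
    bigram_backoff: dict[tuple[str, str], float] = field(default_factory=dict)
    log_floor: float = DEFAULT_LOG_FLOOR

    @property
    def vocabulary(self) -> set[str]:
        return set(self.unigrams)

    def __contains__(self, word: str) -> bool:
        return word in self.unigrams


@dataclass(frozen=True)
class QualityScore:
    path_id: int
    L: int
    ll_norm: float
    q: float


def load_arpa(path: str | Path, log_floor: float = DEFAULT_LOG_FLOOR) -> TrigramLM:
    """Parse an ARPA file with \\1-grams .. \\3-grams sections.

    The counts declared in the ``\\data\\`` header must match the section
    lengths; a missing ``\\end\\`` marker or malformed line is a parse
    error reporting the line number.
    """
    lm = TrigramLM(log_floor=log_floor)
    declared: dict[int, int] = {}
    seen: dict[int, int] = {1: 0, 2: 0, 3: 0}
    section = None
    ended = False
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "\\data\\":
                section = "data"
                continue
            if line == "\\end\\":
                ended = True
                break
            m = line.split("=")
            if section == "data" and line.startswith("ngram"):
                try:
                    order = int(m[0].split()[1])
                    declared[order] = int(m[1])
                except (IndexError, ValueError):
                    raise ArpaParseError(f"line {lineno}: bad ngram count {line!r}")
                continue
            if line.endswith("-grams:") and line.startswith("\\"):
                try:
                    section = int(line[1])
                except ValueError:
                    raise ArpaParseError(f"line {lineno}: bad section {line!r}")
                continue
            if not isinstance(section, int):
                raise ArpaParseError(f"line {lineno}: unexpected content {line!r}")
            parts = line.split()
            n = section
            if len(parts) < n + 1:
                raise ArpaParseError(f"line {lineno}: truncated {n}-gram entry")
            try:
                lp = float(parts[0])
                has_backoff = len(parts) == n + 2
                backoff = float(parts[-1]) if has_backoff else 0.0
            except ValueError:
                raise ArpaParseError(f"line {lineno}: non-numeric field in {line!r}")
            words = tuple(parts[1 : n + 1])
            seen[n] += 1
            if n == 1:
                lm.unigrams[words[0]] = lp
                if has_backoff:
                    lm.unigram_backoff[words[0]] = backoff
            elif n == 2:
                lm.bigrams[words] = lp
                if has_backoff:
                    lm.bigram_backoff[words] = backoff
            elif n == 3:
                lm.trigrams[words] = lp
            else:
                raise ArpaParseError(f"line {lineno}: unsupported order {n}")
    if not ended:
        raise ArpaParseError(f"{path}: missing \\end\\ marker")
    for order, count in declared.items():
        if seen.get(order, 0) != count:
            raise ArpaParseError(
                f"{path}: declared {count} {order}-grams, found {seen.get(order, 0)}"
            )
    return lm


def write_arpa(lm: TrigramLM, path: str | Path) -> None:
    """Write the model back to ARPA; full float precision so that a
    write/load round-trip scores identically."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        fh.write(f"ngram 1={len(lm.unigrams)}\n")
        fh.write(f"ngram 2={len(lm.bigrams)}\n")
        fh.write(f"ngram 3={len(lm.trigrams)}\n")
        fh.write("\n\\1-grams:\n")
        for w in sorted(lm.unigrams):
            bo = lm.unigram_backoff.get(w)
            tail = f"\t{bo!r}" if bo is not None else ""
            fh.write(f"{lm.unigrams[w]!r}\t{w}{tail}\n")
        fh.write("\n\\2-grams:\n")
        for bg in sorted(lm.bigrams):
            bo = lm.bigram_backoff.get(bg)
            tail = f"\t{bo!r}" if bo is not None else ""
            fh.write(f"{lm.bigrams[bg]!r}\t{bg[0]} {bg[1]}{tail}\n")
        fh.write("\n\\3-grams:\n")
        for tg in sorted(lm.trigrams):
            fh.write(f"{lm.trigrams[tg]!r}\t{tg[0]} {tg[1]} {tg[2]}\n")
        fh.write("\n\\end\\\n")


def logprob(word: str, context: Sequence[str], lm: TrigramLM) -> float:
    """log10 P(word | context) with Katz-style back-off.

    Exact trigram if stored; otherwise back off trigram -> bigram ->
    unigram, adding the back-off weights of the skipped contexts. A word
    with no unigram entry scores the floor.
    """
    ctx = tuple(context)[-2:]
    if word not in lm.unigrams:
        return lm.log_floor
    if len(ctx) == 2:
        tri = (ctx[0], ctx[1], word)
        if tri in lm.trigrams:
            return lm.trigrams[tri]
        bo = lm.bigram_backoff.get((ctx[0], ctx[1]), 0.0)
        return bo + logprob(word, ctx[1:], lm)
    if len(ctx) == 1:
        bg = (ctx[0], word)
        if bg in lm.bigrams:
            return lm.bigrams[bg]
        bo = lm.unigram_backoff.get(ctx[0], 0.0)
        return bo + lm.unigrams[word]
    return lm.unigrams[word]


def sentence_logprob(words: Sequence[str], lm: TrigramLM) -> float:
    """Total log10 probability of a word sequence with <s> padding."""
    padded = [BOS, BOS, *words]
    return sum(
        logprob(padded[t], padded[t - 2 : t], lm) for t in range(2, len(padded))
    )


def linguistic_quality(
    words: Sequence[str],
    lm: TrigramLM,
    wss_fn: Callable[[str], float] | None = None,
    path_id: int = 0,
) -> QualityScore:
    """Knowledge-modulated linguistic quality Q of a word path.

    For each position t (contexts padded with <s>):

        p_t = 10 ** logprob(w_t | w_{t-1}, w_{t-2})
        b_t = min(1, p_t * (1 + wss(w_t)))

    LL_norm = sum_t log10(b_t) / (L * floor) with L = len(words), each
    log10(b_t) clamped at the floor; Q = 1 - LL_norm, in [0, 1].
    """
    if not words:
        raise ValueError("linguistic_quality requires at least one word")
    wss_fn = wss_fn or (lambda w: 0.0)
    padded = [BOS, BOS, *words]
    total = 0.0
    for t in range(2, len(padded)):
        lp = logprob(padded[t], padded[t - 2 : t], lm)
        p = 10.0 ** lp
        boosted = min(1.0, p * (1.0 + wss_fn(padded[t])))
        log_b = math.log10(boosted) if boosted > 0 else lm.log_floor
        total += max(log_b, lm.log_floor)
    L = len(words)
    ll_norm = total / (L * lm.log_floor)
    ll_norm = min(max(ll_norm, 0.0), 1.0)
    return QualityScore(path_id=path_id, L=L, ll_norm=ll_norm, q=1.0 - ll_norm)
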
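"""Shared tokenization helpers.

Transcripts are spontaneous, largely unpunctuated speech, so the tokenizer
is deliberately simple: lowercase, strip punctuation except apostrophes,
split on whitespace. Every module that compares words (lexicon matching,
word graphs, the language model, ROUGE) goes through this single tokenizer
so scores are computed over one shared vocabulary.
"""

from __future__ import annotations

import re

_PUNCT = re.compile(r"[^\w\s']", flags=re.UNICODE)
_WS = re.compile(r"\s+")

#: Small closed-class stopword list used only for the guarded node-merging
#: rule in the word graph. Kept tiny and fixed so graph construction is
#: reproducible without any external resource.
STOPWORDS = frozenset(
    """a an the and or but if then than as of at by for with to in on from
    is are was were be been being am do does did have has had not no so
    that this these those it its he she they them his her their i me my we
    us our you your what which who whom when where why how there here
    """.split()
)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation (keeping apostrophes), split on space."""
    text = _PUNCT.sub(" ", text.lower())
    return [t for t in _WS.split(text) if t]


def is_stopword(token: str) -> bool:
    return token in STOPWORDS
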
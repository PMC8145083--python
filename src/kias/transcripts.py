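"""Reading and restructuring of clinical interview transcripts.

Interviews arrive as a sequence of timed speaker turns (interviewer /
participant, in the style of Wizard-of-Oz clinical interviews). They are
restructured into question--answer pairs and then templated into single
declarative statements of the form

    "participant was asked X, the participant said Y"

which is the unit every downstream stage (pruning, slicing, word graphs)
operates on. Templating preserves the question--answer association so that
graph-based ranking can measure the statistical relevance of an answer to
its question.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from ._text import tokenize

log = logging.getLogger(__name__)

__all__ = [
    "Utterance",
    "Transcript",
    "QAPair",
    "Statement",
    "TranscriptDialect",
    "TranscriptError",
    "read_transcript",
    "write_transcript",
    "normalize_utterance",
    "pair_qa",
    "to_statement",
    "transcript_to_statements",
    "write_statements",
]

#: Second-person -> third-person rewrites applied to the question slot of
#: the statement template. Deliberately a small fixed table.
PRONOUN_REWRITE: dict[str, str] = {
    "you": "they",
    "your": "their",
    "yours": "theirs",
    "yourself": "themselves",
    "you're": "they are",
    "you've": "they have",
}

#: Marker for words the transcriber could not recognize.
UNK_TOKEN = "xxx"


class TranscriptError(ValueError):
    """Structural problem in a transcript file (e.g. no interviewer turns)."""


@dataclass(frozen=True)
class Utterance:
    speaker: str  # "interviewer" or "participant"
    text: str
    turn_index: int


@dataclass
class Transcript:
    conversation_id: str
    utterances: list[Utterance] = field(default_factory=list)

    def __iter__(self):
        return iter(self.utterances)

    def __len__(self) -> int:
        return len(self.utterances)


@dataclass(frozen=True)
class QAPair:
    question_text: str
    answer_text: str
    pair_index: int

    @property
    def has_answer(self) -> bool:
        return bool(self.answer_text.strip())


@dataclass(frozen=True)
class Statement:
    """One templated sentence; the summarization unit."""

    text: str
    source_pair_index: int
    has_answer: bool = True

    def tokens(self) -> list[str]:
        return tokenize(self.text)


@dataclass(frozen=True)
class TranscriptDialect:
    """Column layout of a tab-separated transcript file."""

    speaker_column: str = "speaker"
    text_column: str = "value"
    interviewer_label: str = "Ellie"
    delimiter: str = "\t"


def read_transcript(
    path: str | Path,
    dialect: TranscriptDialect | None = None,
    conversation_id: str | None = None,
) -> Transcript:
    """Read a tab-separated transcript (header: start_time, stop_time,
    speaker, value; only speaker and value are used).

    Rows with empty text are skipped. Raises :class:`TranscriptError` if
    the file contains no interviewer turn at all.
    """
    dialect = dialect or TranscriptDialect()
    path = Path(path)
    utterances: list[Utterance] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise TranscriptError(f"{path}: empty transcript file")
        for col in (dialect.speaker_column, dialect.text_column):
            if col not in reader.fieldnames:
                raise TranscriptError(f"{path}: missing column {col!r}")
        for i, row in enumerate(reader):
            text = (row.get(dialect.text_column) or "").strip()
            if not text:
                continue
            raw_speaker = (row.get(dialect.speaker_column) or "").strip()
            speaker = (
                "interviewer"
                if raw_speaker == dialect.interviewer_label
                else "participant"
            )
            utterances.append(Utterance(speaker, text, turn_index=i))
    if not any(u.speaker == "interviewer" for u in utterances):
        raise TranscriptError(f"{path}: no interviewer turns found")
    return Transcript(conversation_id or path.stem, utterances)


def write_transcript(
    transcript: Transcript,
    path: str | Path,
    dialect: TranscriptDialect | None = None,
) -> None:
    """Write a transcript in the tab-separated dialect (inverse of read)."""
    dialect = dialect or TranscriptDialect()
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(
            ["start_time", "stop_time", dialect.speaker_column, dialect.text_column]
        )
        for u in transcript.utterances:
            speaker = (
                dialect.interviewer_label
                if u.speaker == "interviewer"
                else "Participant"
            )
            writer.writerow([u.turn_index, u.turn_index + 1, speaker, u.text])


def normalize_utterance(
    text: str, completion_map: Mapping[str, str] | None = None
) -> str:
    """Lowercase, collapse whitespace, and complete truncated words.

    ``completion_map`` maps incomplete transcription fragments to their
    full forms (e.g. ``peop -> people``); mapping a token to the empty
    string or to ``xxx`` marks it unrecognizable, rendered literally as
    ``xxx``. Total function: never raises.
    """
    completion_map = completion_map or {}
    out: list[str] = []
    for tok in tokenize(text):
        mapped = completion_map.get(tok, tok)
        out.append(UNK_TOKEN if not mapped else mapped)
    return " ".join(out)


def pair_qa(transcript: Transcript) -> list[QAPair]:
    """Group turns into question--answer pairs.

    Each interviewer turn opens a pair; the consecutive participant turns
    that follow (until the next interviewer turn) are concatenated with
    single spaces as its answer. Interviewer turns with no following
    participant turn yield a pair with an empty answer (flagged downstream
    so it is never counted as clinical evidence). Participant turns before
    the first question have no question to attach to and are dropped.
    """
    pairs: list[QAPair] = []
    question: str | None = None
    answer_parts: list[str] = []

    def flush() -> None:
        nonlocal question, answer_parts
        if question is not None:
            pairs.append(
                QAPair(question, " ".join(answer_parts), pair_index=len(pairs))
            )
        question, answer_parts = None, []

    for utt in transcript.utterances:
        if utt.speaker == "interviewer":
            flush()
            question = utt.text
        elif question is None:
            log.info(
                "%s: dropping leading participant turn %d (no preceding question)",
                transcript.conversation_id,
                utt.turn_index,
            )
        else:
            answer_parts.append(utt.text)
    flush()
    return pairs


#: Inverted be-auxiliary + "you" sequences are un-inverted when reported
#: ("how long ago were you diagnosed" -> "... they were diagnosed").
_INVERSION_REWRITE: dict[tuple[str, str], tuple[str, str]] = {
    ("were", "you"): ("they", "were"),
    ("are", "you"): ("they", "are"),
}


def _rewrite_pronouns(text: str) -> str:
    tokens = tokenize(text)
    out: list[str] = []
    i = 0
    while i < len(tokens):
        pair = tuple(tokens[i : i + 2])
        if len(pair) == 2 and pair in _INVERSION_REWRITE:
            out.extend(_INVERSION_REWRITE[pair])
            i += 2
            continue
        out.append(PRONOUN_REWRITE.get(tokens[i], tokens[i]))
        i += 1
    return " ".join(out)


def to_statement(pair: QAPair) -> Statement:
    """Fill the statement template for one question--answer pair.

    Second-person pronouns in the question are rewritten to third person
    ("how long ago were you diagnosed" -> "... were they diagnosed").
    """
    if not pair.question_text.strip():
        raise ValueError("QAPair with empty question cannot be templated")
    q = _rewrite_pronouns(pair.question_text)
    a = " ".join(tokenize(pair.answer_text))
    text = f"participant was asked {q}, the participant said {a}".strip()
    return Statement(
        text=text, source_pair_index=pair.pair_index, has_answer=pair.has_answer
    )


def transcript_to_statements(
    transcript: Transcript, completion_map: Mapping[str, str] | None = None
) -> tuple[list[QAPair], list[Statement]]:
    """normalize -> pair -> template, the standard front of the pipeline."""
    normalized = Transcript(
        transcript.conversation_id,
        [
            Utterance(u.speaker, normalize_utterance(u.text, completion_map), u.turn_index)
            for u in transcript.utterances
            if normalize_utterance(u.text, completion_map)
        ],
    )
    pairs = pair_qa(normalized)
    return pairs, [to_statement(p) for p in pairs]


def write_statements(
    pairs: Iterable[QAPair],
    statements: Iterable[Statement],
    txt_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write statements one per line and/or as JSON records."""
    statements = list(statements)
    pairs = list(pairs)
    if txt_path is not None:
        Path(txt_path).write_text(
            "".join(s.text + "\n" for s in statements), encoding="utf-8"
        )
    if json_path is not None:
        records = [
            {
                "pair_index": p.pair_index,
                "question": p.question_text,
                "answer": p.answer_text,
                "statement": s.text,
            }
            for p, s in zip(pairs, statements)
        ]
        Path(json_path).write_text(
            json.dumps(records, indent=2) + "\n", encoding="utf-8"
        )
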
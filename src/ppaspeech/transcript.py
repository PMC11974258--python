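"""Annotated picture-description transcripts: data model, JSON dialect, validation.

A transcript is the finished product of human annotation of an audio-recorded
picture description (e.g. the WAB "Picnic Scene"): utterances of typed tokens,
sentence and self-correction spans over those tokens, and two timing scalars
(total duration and summed pause duration).  Nothing here detects anything from
raw text — annotations are input.

Conventions
-----------
* Token indices are 0-based; all spans are half-open ``[start, end)`` intervals
  into one utterance's token list.
* Timing is the minimal sufficient statistic for the rate measures: total
  duration and pause duration (filled + unfilled), both in seconds.
* Lexicon lookup case-folds with :meth:`str.lower` but never strips diacritics
  (Italian lemmas are diacritic-significant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TokenKind",
    "WordClass",
    "Pos",
    "TokenFlag",
    "SubjectType",
    "Token",
    "Utterance",
    "SentenceSpan",
    "SCSSpan",
    "Timing",
    "Transcript",
    "Lexicon",
    "TranscriptError",
    "ValidationError",
    "read_transcript",
    "write_transcript",
    "read_lexicon",
    "write_lexicon",
    "write_token_table",
    "validate_transcript",
]


class TranscriptError(ValueError):
    """Malformed transcript file (parse-level problem)."""


class ValidationError(ValueError):
    """A structurally parseable transcript violated data-model invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "transcript failed validation:\n" + "\n".join(f"  - {v}" for v in violations)
        )


class TokenKind(str, Enum):
    WORD = "word"
    FILLED_PAUSE = "filled_pause"
    FALSE_START = "false_start"


class WordClass(str, Enum):
    OPEN = "open"
    CLOSED = "closed"
    NONE = "none"


class Pos(str, Enum):
    NOUN = "noun"
    VERB = "verb"
    AUXILIARY_BE_HAVE = "auxiliary_be_have"
    ADJECTIVE = "adjective"
    ADVERB = "adverb"
    FUNCTION = "function"
    OTHER = "other"


class TokenFlag(str, Enum):
    PHONOLOGICAL_ERROR = "phonological_error"
    SEMANTIC_ERROR = "semantic_error"
    PHONOTACTIC_DISTORTION = "phonotactic_distortion"


class SubjectType(str, Enum):
    EXPRESSED = "expressed"
    IMPLIED = "implied"


#: open-class parts of speech: nouns, lexical verbs, qualifying adjectives,
#: derived adverbs.  Auxiliaries "to be"/"to have" and function words are closed.
_OPEN_POS = {Pos.NOUN, Pos.VERB, Pos.ADJECTIVE, Pos.ADVERB}
_CLOSED_POS = {Pos.AUXILIARY_BE_HAVE, Pos.FUNCTION}


@dataclass(frozen=True)
class Token:
    surface: str
    kind: TokenKind = TokenKind.WORD
    word_class: WordClass = WordClass.NONE
    pos: Pos = Pos.OTHER
    lemma: str | None = None
    flags: frozenset[TokenFlag] = frozenset()

    @property
    def is_word(self) -> bool:
        return self.kind == TokenKind.WORD


@dataclass(frozen=True)
class Utterance:
    id: int
    tokens: tuple[Token, ...]


@dataclass(frozen=True)
class SentenceSpan:
    utterance_id: int
    start: int
    end: int
    subject_type: SubjectType = SubjectType.EXPRESSED
    is_embedding: bool = False
    is_incomplete: bool = False
    msyn_error_count: int = 0


@dataclass(frozen=True)
class SCSSpan:
    utterance_id: int
    start: int
    end: int


@dataclass(frozen=True)
class Timing:
    total_duration: float
    pause_duration: float


@dataclass(frozen=True)
class Transcript:
    subject_id: str
    session_id: str
    language_tag: str
    utterances: tuple[Utterance, ...]
    sentence_spans: tuple[SentenceSpan, ...] = ()
    scs_spans: tuple[SCSSpan, ...] = ()
    timing: Timing = Timing(1.0, 0.0)

    def utterance(self, uid: int) -> Utterance:
        for u in self.utterances:
            if u.id == uid:
                return u
        raise KeyError(f"no utterance with id {uid}")


class Lexicon:
    """Lemma → frequency of use (occurrences per million), case-folded keys."""

    def __init__(self, entries: Mapping[str, float]):
        folded: dict[str, float] = {}
        for lemma, freq in entries.items():
            key = lemma.lower()
            if key in folded:
                raise ValueError(f"duplicate lemma after case-folding: {lemma!r}")
            f = float(freq)
            if not f > 0:
                raise ValueError(f"non-positive frequency for lemma {lemma!r}: {freq}")
            folded[key] = f
        self._entries = folded

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, lemma: str) -> bool:
        return lemma.lower() in self._entries

    def __getitem__(self, lemma: str) -> float:
        return self._entries[lemma.lower()]

    def get(self, lemma: str, default: float | None = None) -> float | None:
        return self._entries.get(lemma.lower(), default)

    def items(self):
        return self._entries.items()


# ---------------------------------------------------------------------------
# validation

def validate_transcript(t: Transcript) -> list[str]:
    """Return a list of invariant violations (empty iff ``t`` is valid).

    Never raises on structurally parseable input: violations are data.
    """
    v: list[str] = []

    if not t.utterances:
        v.append("utterances: transcript has no utterances")
    last_id = None
    for u in t.utterances:
        if not u.tokens:
            v.append(f"utterance {u.id}: empty token list")
        if last_id is not None and u.id <= last_id:
            v.append(f"utterance {u.id}: ids not strictly increasing (follows {last_id})")
        last_id = u.id
        for i, tok in enumerate(u.tokens):
            where = f"utterance {u.id} token {i}"
            if tok.kind != TokenKind.WORD:
                if tok.word_class != WordClass.NONE:
                    v.append(f"{where}: non-word token must have word_class 'none'")
                if tok.flags:
                    v.append(f"{where}: non-word token must carry no flags")
            else:
                if tok.word_class == WordClass.NONE:
                    v.append(f"{where}: word token must be open or closed class")
                if tok.pos in _OPEN_POS and tok.word_class != WordClass.OPEN:
                    v.append(f"{where}: pos {tok.pos.value} must be open class")
                if tok.pos in _CLOSED_POS and tok.word_class != WordClass.CLOSED:
                    v.append(f"{where}: pos {tok.pos.value} must be closed class")

    ids = {u.id for u in t.utterances}
    lengths = {u.id: len(u.tokens) for u in t.utterances}

    def check_span(span, name: str, idx: int) -> None:
        where = f"{name} span {idx} (utterance {span.utterance_id})"
        if span.utterance_id not in ids:
            v.append(f"{where}: references a missing utterance")
            return
        n = lengths[span.utterance_id]
        if not (0 <= span.start < span.end <= n):
            v.append(f"{where}: range [{span.start}, {span.end}) invalid for {n} tokens")

    for i, s in enumerate(t.sentence_spans):
        check_span(s, "sentence", i)
        if s.msyn_error_count < 0:
            v.append(f"sentence span {i}: negative msyn_error_count")
    for i, s in enumerate(t.scs_spans):
        check_span(s, "scs", i)
        if s.utterance_id in ids:
            u = t.utterance(s.utterance_id)
            end = min(s.end, len(u.tokens))
            if 0 <= s.start < end and not any(
                tok.is_word for tok in u.tokens[s.start:end]
            ):
                v.append(f"scs span {i}: contains no word token")

    def overlaps(spans: Iterable, name: str) -> None:
        by_utt: dict[int, list[tuple[int, int, int]]] = {}
        for i, s in enumerate(spans):
            by_utt.setdefault(s.utterance_id, []).append((s.start, s.end, i))
        for uid, ss in by_utt.items():
            ss.sort()
            for (a_start, a_end, a_i), (b_start, b_end, b_i) in zip(ss, ss[1:]):
                if b_start < a_end:
                    v.append(
                        f"{name} spans {a_i} and {b_i} overlap in utterance {uid}"
                    )

    overlaps(t.sentence_spans, "sentence")
    overlaps(t.scs_spans, "scs")

    if not t.timing.total_duration > 0:
        v.append("timing: total_duration must be positive")
    if not (0 <= t.timing.pause_duration <= t.timing.total_duration):
        v.append("timing: pause_duration must lie in [0, total_duration]")

    return v


# ---------------------------------------------------------------------------
# on-disk dialect (JSON)

def _token_to_json(tok: Token) -> dict:
    d: dict = {"surface": tok.surface, "kind": tok.kind.value}
    if tok.kind == TokenKind.WORD:
        d["word_class"] = tok.word_class.value
        d["pos"] = tok.pos.value
    if tok.lemma is not None:
        d["lemma"] = tok.lemma
    if tok.flags:
        d["flags"] = sorted(f.value for f in tok.flags)
    return d


def _token_from_json(d: dict, where: str) -> Token:
    try:
        kind = TokenKind(d.get("kind", "word"))
        wc = WordClass(d.get("word_class", "none" if kind != TokenKind.WORD else d["word_class"]))
        pos = Pos(d.get("pos", "other"))
        flags = frozenset(TokenFlag(f) for f in d.get("flags", []))
        return Token(
            surface=str(d["surface"]),
            kind=kind,
            word_class=wc,
            pos=pos,
            lemma=d.get("lemma"),
            flags=flags,
        )
    except (KeyError, ValueError) as e:
        raise TranscriptError(f"{where}: malformed token {d!r} ({e})") from e


def transcript_to_dict(t: Transcript) -> dict:
    return {
        "subject_id": t.subject_id,
        "session_id": t.session_id,
        "language": t.language_tag,
        "timing": {
            "total_duration_s": t.timing.total_duration,
            "pause_duration_s": t.timing.pause_duration,
        },
        "utterances": [
            {"id": u.id, "tokens": [_token_to_json(tok) for tok in u.tokens]}
            for u in t.utterances
        ],
        "sentences": [
            {
                "utterance_id": s.utterance_id,
                "start": s.start,
                "end": s.end,
                "subject_type": s.subject_type.value,
                "is_embedding": s.is_embedding,
                "is_incomplete": s.is_incomplete,
                "msyn_errors": s.msyn_error_count,
            }
            for s in t.sentence_spans
        ],
        "scs": [
            {"utterance_id": s.utterance_id, "start": s.start, "end": s.end}
            for s in t.scs_spans
        ],
    }


def transcript_from_dict(doc: dict) -> Transcript:
    try:
        timing = Timing(
            total_duration=float(doc["timing"]["total_duration_s"]),
            pause_duration=float(doc["timing"]["pause_duration_s"]),
        )
        utterances = tuple(
            Utterance(
                id=int(u["id"]),
                tokens=tuple(
                    _token_from_json(tok, f"utterance {u.get('id')}")
                    for tok in u["tokens"]
                ),
            )
            for u in doc["utterances"]
        )
        sentences = tuple(
            SentenceSpan(
                utterance_id=int(s["utterance_id"]),
                start=int(s["start"]),
                end=int(s["end"]),
                subject_type=SubjectType(s.get("subject_type", "expressed")),
                is_embedding=bool(s.get("is_embedding", False)),
                is_incomplete=bool(s.get("is_incomplete", False)),
                msyn_error_count=int(s.get("msyn_errors", 0)),
            )
            for s in doc.get("sentences", [])
        )
        scs = tuple(
            SCSSpan(int(s["utterance_id"]), int(s["start"]), int(s["end"]))
            for s in doc.get("scs", [])
        )
        t = Transcript(
            subject_id=str(doc["subject_id"]),
            session_id=str(doc["session_id"]),
            language_tag=str(doc.get("language", "it")),
            utterances=utterances,
            sentence_spans=sentences,
            scs_spans=scs,
            timing=timing,
        )
    except TranscriptError:
        raise
    except (KeyError, TypeError, ValueError) as e:
        raise TranscriptError(f"malformed transcript document: {e}") from e

    violations = validate_transcript(t)
    if violations:
        raise ValidationError(violations)
    return t


def read_transcript(path: str | Path) -> Transcript:
    """Read a transcript from its JSON dialect and validate it."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise TranscriptError(f"{path}: line {e.lineno} column {e.colno}: {e.msg}") from e
    return transcript_from_dict(doc)


def write_transcript(t: Transcript, path: str | Path) -> Path:
    """Write a valid transcript to ``path``; round-trips field-for-field."""
    violations = validate_transcript(t)
    if violations:
        raise ValidationError(violations)
    path = Path(path)
    path.write_text(
        json.dumps(transcript_to_dict(t), ensure_ascii=False, indent=1, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )
    return path


# ---------------------------------------------------------------------------
# lexicon (headered TSV: lemma<TAB>per_million)

def read_lexicon(path: str | Path) -> Lexicon:
    path = Path(path)
    entries: dict[str, float] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["lemma", "per_million"]:
            raise TranscriptError(
                f"{path}: expected header 'lemma<TAB>per_million', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TranscriptError(f"{path}: line {lineno}: expected 2 columns")
            lemma, freq_s = parts
            try:
                freq = float(freq_s)
            except ValueError:
                raise TranscriptError(
                    f"{path}: line {lineno}: non-numeric frequency {freq_s!r}"
                ) from None
            if not freq > 0:
                raise TranscriptError(
                    f"{path}: line {lineno}: non-positive frequency for {lemma!r}"
                )
            if lemma.lower() in entries:
                raise TranscriptError(f"{path}: line {lineno}: duplicate lemma {lemma!r}")
            entries[lemma.lower()] = freq
    return Lexicon(entries)


def write_token_table(t: Transcript, path: str | Path) -> Path:
    """Flat TSV of the token table (one row per token) for spreadsheet users."""
    path = Path(path)
    lines = ["utterance_id\tposition\tsurface\tkind\tword_class\tpos\tlemma\tflags"]
    for u in t.utterances:
        for i, tok in enumerate(u.tokens):
            flags = ",".join(sorted(f.value for f in tok.flags))
            lines.append(
                f"{u.id}\t{i}\t{tok.surface}\t{tok.kind.value}\t"
                f"{tok.word_class.value}\t{tok.pos.value}\t{tok.lemma or ''}\t{flags}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_lexicon(lex: Lexicon, path: str | Path) -> Path:
    path = Path(path)
    lines = ["lemma\tper_million"]
    lines += [f"{lemma}\t{freq:g}" for lemma, freq in sorted(lex.items())]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
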
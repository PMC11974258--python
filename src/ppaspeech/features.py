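"""Quantitative speech parameters from an annotated picture-description sample.

Each validated :class:`~ppaspeech.transcript.Transcript` yields one
:class:`SpeechFeatureVector` of 44 named parameters covering four domains:
speech rate and speech-sound errors, other disruptions to fluency, lexical
content, and syntactic structure/complexity.  All parameters are simple
closed-form functions of the annotation (counts, durations and their
quotients); nothing is estimated.

Zero-denominator conventions (kept total so cohorts never lose rows):

* no sentences ⇒ ``sl = 0`` and ``r_msyn_e = 0``;
* ``ses + sis = 0`` ⇒ ``pr_ses = 0``; ``verbs + nouns = 0`` ⇒ ``pr_v = 0``;
* no closed-class words ⇒ ``r_oc = 0`` (warning), symmetrically for ``r_cc``;
* no nouns ⇒ ``mean_freq``/``log_freq`` are NaN;
* no words at all ⇒ the per-word ratios (``aos``, ``pew``, ``sem_ew``,
  ``sp_rate``) are 0.

Two noun/verb rate variants are exposed: the per-second definition
(``noun_rate``, ``verb_rate`` — counts over total duration) and the per-word
variant (``noun_rate_word``, ``verb_rate_word`` — counts over total words),
because published group profiles for "noun rate" are on the per-word scale
while the formula table defines the per-second one.  Both are carried in the
feature table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dc_fields

import pandas as pd

from .transcript import (
    Lexicon,
    Pos,
    SubjectType,
    TokenFlag,
    TokenKind,
    Transcript,
    ValidationError,
    validate_transcript,
)

__all__ = [
    "SpeechFeatureVector",
    "FEATURE_NAMES",
    "COUNT_FEATURES",
    "RATE_FEATURES",
    "MissingLemmaError",
    "count_words",
    "extract_features",
    "feature_table",
]


class MissingLemmaError(KeyError):
    """A noun token's lemma is absent from the frequency lexicon (strict mode)."""

    def __init__(self, lemmas: list[str]):
        self.lemmas = lemmas
        super().__init__(f"lemmas missing from lexicon: {sorted(set(lemmas))}")


@dataclass(frozen=True)
class SpeechFeatureVector:
    # speech rate and speech sound errors
    total_duration: float
    duration_no_pauses: float
    total_words: int
    wps: float
    wps_np: float
    distortions: int
    aos: float
    pe: int
    pew: float
    # other disruptions to fluency
    false_starts: int
    false_start_rate: float
    filled_pauses: int
    filled_pause_rate: float
    scs: int
    scs_rate: float
    is_count: int
    is_rate: float
    # lexical content
    open_class: int
    closed_class: int
    verbs: int
    verb_rate: float
    nouns: int
    noun_rate: float
    r_oc: float
    r_cc: float
    pr_v: float
    mean_freq: float
    log_freq: float
    sem_e: int
    sem_ew: float
    # syntactic structure and complexity
    utterances: int
    ul: float
    sentences: int
    sentence_rate: float
    nws: int
    sl: float
    r_sentences: float
    embeddings: int
    ses: int
    sis: int
    pr_ses: float
    sp_rate: float
    msyn_e: int
    r_msyn_e: float
    # per-word rate variants (supplementary, outside the canonical 44)
    noun_rate_word: float = 0.0
    verb_rate_word: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


#: canonical 44-parameter order (the on-disk column order)
FEATURE_NAMES: tuple[str, ...] = tuple(
    f.name for f in dc_fields(SpeechFeatureVector)
)[:44]

#: parameters that are integer counts of annotation events
COUNT_FEATURES: tuple[str, ...] = (
    "total_words", "distortions", "pe", "false_starts", "filled_pauses",
    "scs", "is_count", "open_class", "closed_class", "verbs", "nouns",
    "sem_e", "utterances", "sentences", "nws", "embeddings", "ses", "sis",
    "msyn_e",
)

#: derived quotients (everything in the canonical 44 that is not a count
#: and not a raw duration)
RATE_FEATURES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES
    if n not in COUNT_FEATURES and n not in ("total_duration", "duration_no_pauses")
)


def count_words(t: Transcript) -> int:
    """Words in the sample: tokens of kind ``word``.

    Filled pauses and false starts (partially pronounced words) are not words
    and never enter the total word count.
    """
    return sum(1 for u in t.utterances for tok in u.tokens if tok.is_word)


def _ratio(num: float, den: float, zero: float = 0.0) -> float:
    return num / den if den else zero


def extract_features(
    t: Transcript, lex: Lexicon, *, strict_lexicon: bool = True
) -> SpeechFeatureVector:
    """Compute the full speech-parameter vector for one validated transcript.

    Parameters
    ----------
    t : Transcript
        A transcript that passes :func:`validate_transcript`.
    lex : Lexicon
        Lemma-frequency norms (occurrences per million) for noun scoring.
    strict_lexicon : bool
        If True (default) a noun lemma absent from ``lex`` raises
        :class:`MissingLemmaError`; if False the noun is skipped from the
        frequency average with a warning (NaN if no noun can be scored).
    """
    violations = validate_transcript(t)
    if violations:
        raise ValidationError(violations)

    words = [tok for u in t.utterances for tok in u.tokens if tok.is_word]
    total_words = len(words)
    total_duration = t.timing.total_duration
    duration_np = total_duration - t.timing.pause_duration

    distortions = sum(1 for w in words if TokenFlag.PHONOTACTIC_DISTORTION in w.flags)
    pe = sum(1 for w in words if TokenFlag.PHONOLOGICAL_ERROR in w.flags)
    sem_e = sum(1 for w in words if TokenFlag.SEMANTIC_ERROR in w.flags)
    false_starts = sum(
        1 for u in t.utterances for tok in u.tokens if tok.kind == TokenKind.FALSE_START
    )
    filled_pauses = sum(
        1 for u in t.utterances for tok in u.tokens if tok.kind == TokenKind.FILLED_PAUSE
    )

    open_class = sum(1 for w in words if w.word_class.value == "open")
    closed_class = total_words - open_class
    verbs = sum(1 for w in words if w.pos == Pos.VERB)
    nouns = sum(1 for w in words if w.pos == Pos.NOUN)

    # token-weighted mean lemma frequency over produced nouns
    noun_freqs: list[float] = []
    missing: list[str] = []
    for w in words:
        if w.pos != Pos.NOUN:
            continue
        if w.lemma is None or w.lemma not in lex:
            missing.append(w.lemma if w.lemma is not None else w.surface)
        else:
            noun_freqs.append(lex[w.lemma])
    if missing:
        if strict_lexicon:
            raise MissingLemmaError(missing)
        warnings.warn(
            f"{len(missing)} noun(s) missing from lexicon, skipped from mean_freq: "
            f"{sorted(set(missing))}",
            stacklevel=2,
        )
    if noun_freqs:
        mean_freq = sum(noun_freqs) / len(noun_freqs)
        log_freq = math.log10(mean_freq)
    else:
        mean_freq = float("nan")
        log_freq = float("nan")

    if open_class == 0 or closed_class == 0:
        if total_words:
            warnings.warn(
                "one word class is empty; r_oc/r_cc use the 0 sentinel",
                stacklevel=2,
            )
    r_oc = _ratio(open_class, closed_class)
    r_cc = _ratio(closed_class, open_class)

    n_utt = len(t.utterances)
    sentences = len(t.sentence_spans)
    is_count = sum(1 for s in t.sentence_spans if s.is_incomplete)
    embeddings = sum(1 for s in t.sentence_spans if s.is_embedding)
    ses = sum(1 for s in t.sentence_spans if s.subject_type == SubjectType.EXPRESSED)
    sis = sentences - ses
    msyn_e = sum(s.msyn_error_count for s in t.sentence_spans)

    # words in sentences, excluding words that form self-corrected sequences
    scs_index: dict[int, set[int]] = {}
    for s in t.scs_spans:
        scs_index.setdefault(s.utterance_id, set()).update(range(s.start, s.end))
    nws = 0
    for s in t.sentence_spans:
        u = t.utterance(s.utterance_id)
        excluded = scs_index.get(s.utterance_id, set())
        nws += sum(
            1
            for i in range(s.start, s.end)
            if u.tokens[i].is_word and i not in excluded
        )

    return SpeechFeatureVector(
        total_duration=total_duration,
        duration_no_pauses=duration_np,
        total_words=total_words,
        wps=total_words / total_duration,
        wps_np=_ratio(total_words, duration_np),
        distortions=distortions,
        aos=_ratio(distortions, total_words) * 100.0,
        pe=pe,
        pew=_ratio(pe, total_words),
        false_starts=false_starts,
        false_start_rate=false_starts / total_duration,
        filled_pauses=filled_pauses,
        filled_pause_rate=filled_pauses / total_duration,
        scs=len(t.scs_spans),
        scs_rate=len(t.scs_spans) / total_duration,
        is_count=is_count,
        is_rate=is_count / total_duration,
        open_class=open_class,
        closed_class=closed_class,
        verbs=verbs,
        verb_rate=verbs / total_duration,
        nouns=nouns,
        noun_rate=nouns / total_duration,
        r_oc=r_oc,
        r_cc=r_cc,
        pr_v=_ratio(verbs, verbs + nouns),
        mean_freq=mean_freq,
        log_freq=log_freq,
        sem_e=sem_e,
        sem_ew=_ratio(sem_e, total_words),
        utterances=n_utt,
        ul=total_words / n_utt,
        sentences=sentences,
        sentence_rate=sentences / total_duration,
        nws=nws,
        sl=_ratio(nws, sentences),
        r_sentences=sentences / n_utt,
        embeddings=embeddings,
        ses=ses,
        sis=sis,
        pr_ses=_ratio(ses, sentences),
        sp_rate=_ratio(nws, total_words),
        msyn_e=msyn_e,
        r_msyn_e=_ratio(msyn_e, nws),
        noun_rate_word=_ratio(nouns, total_words),
        verb_rate_word=_ratio(verbs, total_words),
    )


def feature_table(
    transcripts: list[Transcript], lex: Lexicon, *, strict_lexicon: bool = True
) -> pd.DataFrame:
    """One row per transcript, indexed by (subject_id, session_id).

    Columns are the canonical 44 parameters followed by the per-word rate
    variants; row order follows the input order.
    """
    keys = [(t.subject_id, t.session_id) for t in transcripts]
    if len(set(keys)) != len(keys):
        seen: set[tuple[str, str]] = set()
        dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate (subject_id, session_id): {dup}")
    rows = [
        extract_features(t, lex, strict_lexicon=strict_lexicon).as_dict()
        for t in transcripts
    ]
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(keys, names=["subject_id", "session_id"]))
    return df
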
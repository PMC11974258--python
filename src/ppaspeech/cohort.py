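"""Synthetic cohorts with the statistical structure of published group profiles.

Three generators:

* :func:`generate_feature_cohort` — subject-level feature rows for one
  diagnostic group, each variable drawn from a range-respecting distribution
  calibrated to the profile's published mean / SD / range;
* :func:`generate_transcript` — a fully annotated transcript whose extracted
  count features hit a requested target exactly (round-trip construction);
* :func:`generate_longitudinal` — follow-up visits obtained by adding a
  Gaussian per-variable delta to each baseline record.

Marginal model
--------------
Published per-group profiles give mean, SD and the observed range per
variable.  Speech-error counts in this population are heavily zero-inflated
(e.g. a mean a third of the SD with a range starting at 0), which no
truncated normal can reproduce: on a bounded support with the mean close to
an edge, the truncated-normal family caps the coefficient of variation near
the exponential limit.  The default marginal is therefore a scaled Beta on
[min, max] matched to the published mean and SD by moments — the Beta family
covers J- and U-shaped (zero-inflation-like) as well as bell shapes, so every
published (mean, SD, range) triple is attainable up to the universal
bounded-support variance limit.  A truncated-normal marginal (parameters used
as the parent's) remains available via ``family="truncnorm"`` for users who
prefer the classical choice and accept its moment bias.  Count-valued
variables are stochastically rounded (round up with probability equal to the
fractional part), which preserves the mean exactly.

Optional correlation is induced with a Gaussian copula over a user-supplied
correlation matrix; marginals are untouched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .features import COUNT_FEATURES
from .transcript import (
    Lexicon,
    Pos,
    SCSSpan,
    SentenceSpan,
    SubjectType,
    Timing,
    Token,
    TokenFlag,
    TokenKind,
    Transcript,
    Utterance,
    WordClass,
    read_lexicon,
)

__all__ = [
    "VariableSpec",
    "CohortProfile",
    "DeltaProfile",
    "TranscriptTarget",
    "InfeasibleTargetError",
    "GROUPS",
    "PATIENT_GROUPS",
    "SPEECH_BLOCK",
    "STANDARD_LANGUAGE_BLOCK",
    "GMV_BLOCK",
    "load_default_profiles",
    "load_default_deltas",
    "packaged_lexicon",
    "generate_feature_cohort",
    "generate_cohorts",
    "generate_longitudinal",
    "generate_transcript",
    "random_feasible_target",
]

GROUPS = ("HC", "nfvPPA", "svPPA", "lvPPA")
PATIENT_GROUPS = ("nfvPPA", "svPPA", "lvPPA")

STANDARD_LANGUAGE_BLOCK = ("naming", "repetition", "single_word_comprehension")
GMV_BLOCK = (
    "l_sma",
    "l_insula",
    "l_middle_temporal",
    "l_middle_temporal_pole",
    "l_hippocampus",
    "r_pars_opercularis",
)


@dataclass(frozen=True)
class VariableSpec:
    """Published summary of one variable: mean, SD, and observed range."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"mean {self.mean} outside range [{self.min}, {self.max}]"
            )


@dataclass
class CohortProfile:
    """Per-group generative parameters for a synthetic cohort."""

    group: str
    n_default: int
    variables: dict[str, VariableSpec]
    age: VariableSpec | None = None
    education: VariableSpec | None = None
    sex_female_prop: float | None = None
    n_followup: int | None = None


@dataclass
class DeltaProfile:
    """Per-group per-variable follow-up change and the inter-visit interval."""

    interval_months: VariableSpec
    deltas: dict[str, dict[str, tuple[float, float]]]  # group -> var -> (mean, sd)
    n_followup: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.interval_months.mean > 0:
            raise ValueError("inter-visit interval must be positive")


# ---------------------------------------------------------------------------
# packaged defaults

def _data_path(*parts: str) -> Path:
    return Path(resources.files("ppaspeech").joinpath("data", *parts))  # type: ignore[arg-type]


def packaged_lexicon() -> Lexicon:
    """The packaged 50-lemma toy lexicon (frequencies per million)."""
    return read_lexicon(_data_path("toy_lexicon.tsv"))


def _load_yaml(name: str) -> dict:
    return yaml.safe_load(_data_path("profiles", name).read_text(encoding="utf-8"))


def load_default_profiles(*, include_auxiliary: bool = False) -> dict[str, CohortProfile]:
    """Shipped per-group profiles (speech parameters + demographics).

    With ``include_auxiliary=True`` the clearly-labelled synthetic
    standard-language and gray-matter-volume blocks are appended to each
    group's variable set (those numbers are illustrative placeholders, not
    published values).
    """
    speech = _load_yaml("speech_baseline.yaml")["groups"]
    demo = _load_yaml("demographics.yaml")["groups"]
    aux = _load_yaml("auxiliary_synthetic.yaml")["groups"] if include_auxiliary else {}

    profiles: dict[str, CohortProfile] = {}
    for group in GROUPS:
        variables = {
            name: VariableSpec(**spec)
            for name, spec in speech[group]["variables"].items()
        }
        if group in aux:
            for block in ("standard_language", "gmv"):
                for name, spec in aux[group][block].items():
                    variables[name] = VariableSpec(**spec)
        d = demo[group]
        profiles[group] = CohortProfile(
            group=group,
            n_default=int(speech[group]["n"]),
            variables=variables,
            age=VariableSpec(**d["age"]),
            education=VariableSpec(**d["education"]),
            sex_female_prop=d["sex_female"] / (d["sex_female"] + d["sex_male"]),
        )
    return profiles


def load_default_deltas() -> DeltaProfile:
    """Shipped per-group longitudinal delta profile."""
    doc = _load_yaml("deltas.yaml")
    return DeltaProfile(
        interval_months=VariableSpec(**doc["interval_months"]),
        deltas={
            g: {
                var: (spec["delta_mean"], spec["delta_sd"])
                for var, spec in entry["deltas"].items()
            }
            for g, entry in doc["groups"].items()
        },
        n_followup={g: int(entry["n_followup"]) for g, entry in doc["groups"].items()},
    )


# ---------------------------------------------------------------------------
# marginal sampling

def _beta_params(spec: VariableSpec) -> tuple[float, float]:
    """Method-of-moments Beta parameters on the unit interval.

    The variance is capped just under the bounded-support maximum
    m(1-m); published SDs computed with the n-1 divisor can exceed that
    population bound by a hair.
    """
    width = spec.max - spec.min
    m = (spec.mean - spec.min) / width
    s2 = (spec.sd / width) ** 2
    cap = 0.999
    if s2 >= cap * 0.25:
        # SD above the bounded-support maximum altogether
        s2 = cap * 0.25
        m = 0.5
    elif s2 >= cap * m * (1.0 - m):
        # published mean too close to the range edge for the published SD
        # (possible for ANY distribution only up to rounding); shift the mean
        # minimally toward the center so the SD is preserved
        root = np.sqrt(1.0 - 4.0 * s2 / cap)
        m = (1.0 - root) / 2.0 if m < 0.5 else (1.0 + root) / 2.0
    nu = m * (1.0 - m) / s2 - 1.0
    return max(m * nu, 1e-6), max((1.0 - m) * nu, 1e-6)


def _marginal_ppf(u: np.ndarray, spec: VariableSpec, family: str) -> np.ndarray:
    if spec.sd == 0 or spec.max == spec.min:
        return np.full_like(u, spec.mean, dtype=float)
    if family == "beta":
        a, b = _beta_params(spec)
        x = stats.beta.ppf(u, a, b)
        return spec.min + (spec.max - spec.min) * x
    if family == "truncnorm":
        lo = (spec.min - spec.mean) / spec.sd
        hi = (spec.max - spec.mean) / spec.sd
        return stats.truncnorm.ppf(u, lo, hi, loc=spec.mean, scale=spec.sd)
    raise ValueError(f"unknown marginal family {family!r}")


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer rounding that is unbiased in expectation."""
    floor = np.floor(x)
    return floor + (rng.random(x.shape) < (x - floor))


def _correlated_uniforms(
    rng: np.random.Generator,
    n: int,
    names: list[str],
    correlation: pd.DataFrame | None,
) -> pd.DataFrame:
    """n x len(names) uniforms; a Gaussian copula ties the listed subset."""
    u = pd.DataFrame(rng.random((n, len(names))), columns=names)
    if correlation is None:
        return u
    corr_names = list(correlation.index)
    missing = set(corr_names) - set(names)
    if missing:
        raise ValueError(f"correlation names not in profile: {sorted(missing)}")
    c = correlation.loc[corr_names, corr_names].to_numpy(dtype=float)
    if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
        raise ValueError("correlation matrix must be symmetric with unit diagonal")
    eigmin = np.linalg.eigvalsh(c).min()
    if eigmin < -1e-10:
        raise ValueError(f"correlation matrix not positive semidefinite (min eig {eigmin:.3g})")
    root = np.linalg.cholesky(c + 1e-12 * np.eye(len(c)))
    z = rng.standard_normal((n, len(corr_names))) @ root.T
    u[corr_names] = stats.norm.cdf(z)
    return u


def generate_feature_cohort(
    profile: CohortProfile,
    n: int,
    seed: int | np.random.Generator,
    *,
    correlation: pd.DataFrame | None = None,
    family: str = "beta",
    subject_prefix: str | None = None,
) -> pd.DataFrame:
    """Baseline subject records for one group.

    Returns a DataFrame with columns ``subject_id, group, sex, age,
    education, visit, months_since_baseline`` followed by every profile
    variable.  ``sex`` is a 0/1 indicator (1 = female).  Deterministic under
    a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prefix = subject_prefix or profile.group
    names = list(profile.variables)
    u = _correlated_uniforms(rng, n, names, correlation)

    data: dict[str, np.ndarray] = {}
    for name in names:
        spec = profile.variables[name]
        x = _marginal_ppf(u[name].to_numpy(), spec, family)
        if name in COUNT_FEATURES:
            x = np.clip(_stochastic_round(x, rng), spec.min, spec.max)
        data[name] = x

    out = pd.DataFrame(
        {
            "subject_id": [f"{prefix}-{i:04d}" for i in range(n)],
            "group": profile.group,
            "sex": (
                (rng.random(n) < profile.sex_female_prop).astype(int)
                if profile.sex_female_prop is not None
                else 0
            ),
            "age": (
                _marginal_ppf(rng.random(n), profile.age, family)
                if profile.age is not None
                else np.nan
            ),
            "education": (
                _marginal_ppf(rng.random(n), profile.education, family)
                if profile.education is not None
                else np.nan
            ),
            "visit": 0,
            "months_since_baseline": 0.0,
        }
    )
    for name in names:
        out[name] = data[name]
    return out


def generate_cohorts(
    seed: int,
    *,
    n_per_group: dict[str, int] | None = None,
    include_auxiliary: bool = False,
    correlation: pd.DataFrame | None = None,
    family: str = "beta",
) -> pd.DataFrame:
    """Baseline cohorts for all four groups at the published sample sizes."""
    profiles = load_default_profiles(include_auxiliary=include_auxiliary)
    rng = np.random.default_rng(seed)
    frames = []
    for group in GROUPS:
        p = profiles[group]
        n = (n_per_group or {}).get(group, p.n_default)
        frames.append(
            generate_feature_cohort(p, n, rng, correlation=correlation, family=family)
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# longitudinal follow-up

def generate_longitudinal(
    baseline: pd.DataFrame,
    deltas: DeltaProfile,
    seed: int | np.random.Generator,
    *,
    variables: list[str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One follow-up record per baseline subject.

    Each requested variable is incremented by a draw from
    N(delta_mean, delta_sd) for the subject's group; the inter-visit interval
    is drawn from the profile's truncated-normal interval distribution.
    Values are clipped to ``bounds`` when given.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iv = deltas.interval_months
    followups = []
    for group, block in baseline.groupby("group", sort=False):
        if group not in deltas.deltas:
            raise KeyError(f"no delta profile for group {group!r}")
        gdeltas = deltas.deltas[group]
        req = variables if variables is not None else [
            v for v in block.columns if v in gdeltas
        ]
        missing = [v for v in req if v not in gdeltas]
        if missing:
            raise KeyError(f"no delta for variables {missing} in group {group!r}")
        fu = block.copy()
        n = len(fu)
        fu["visit"] = 1
        lo = (iv.min - iv.mean) / iv.sd if iv.sd else 0.0
        hi = (iv.max - iv.mean) / iv.sd if iv.sd else 0.0
        months = (
            stats.truncnorm.rvs(lo, hi, loc=iv.mean, scale=iv.sd, size=n, random_state=rng)
            if iv.sd
            else np.full(n, iv.mean)
        )
        fu["months_since_baseline"] = months
        for var in req:
            dm, ds = gdeltas[var]
            x = fu[var].to_numpy(dtype=float) + rng.normal(dm, ds, size=n)
            if bounds and var in bounds:
                x = np.clip(x, *bounds[var])
            fu[var] = x
        followups.append(fu)
    return pd.concat(followups, ignore_index=True)


# ---------------------------------------------------------------------------
# transcript-level generation (round-trip by construction)

class InfeasibleTargetError(ValueError):
    """A transcript target violates one of its internal consistency relations."""


@dataclass(frozen=True)
class TranscriptTarget:
    """Count targets for one synthetic transcript.

    ``nws=None`` means "all non-self-corrected words in sentences", i.e.
    ``total_words - scs``.  Every self-corrected sequence occupies one word
    inside a sentence.  ``ses`` is derived as ``sentences - sis``.
    """

    total_words: int = 12
    nouns: int = 3
    verbs: int = 2
    other_open: int = 0
    utterances: int = 2
    sentences: int = 2
    duration_s: float = 10.0
    pause_s: float = 2.0
    nws: int | None = None
    scs: int = 0
    filled_pauses: int = 0
    false_starts: int = 0
    distortions: int = 0
    pe: int = 0
    sem_e: int = 0
    is_count: int = 0
    embeddings: int = 0
    sis: int = 0
    msyn_e: int = 0


def _check_target(t: TranscriptTarget) -> int:
    """Validate consistency relations; return the resolved nws."""
    if t.nws is None:
        nws = (t.total_words - t.scs) if t.sentences > 0 else 0
    else:
        nws = t.nws

    def bad(relation: str):
        raise InfeasibleTargetError(f"infeasible target: violated relation {relation}")

    if t.total_words < 0 or t.utterances < 1 or t.duration_s <= 0:
        bad("total_words >= 0, utterances >= 1, duration > 0")
    if not (0 <= t.pause_s <= t.duration_s):
        bad("0 <= pause <= duration")
    if t.nouns + t.verbs + t.other_open > t.total_words:
        bad("nouns + verbs + other_open <= total_words")
    if t.sentences > t.utterances:
        bad("sentences <= utterances")
    if nws > t.total_words:
        bad("nws <= total_words")
    if nws + t.scs > t.total_words:
        bad("nws + scs <= total_words")
    if t.sentences > 0 and nws < t.sentences:
        bad("nws >= sentences (each sentence needs a counted word)")
    if t.sentences == 0 and (nws > 0 or t.scs > 0):
        bad("nws = scs = 0 when there are no sentences")
    if max(t.distortions, t.pe, t.sem_e) > t.total_words:
        bad("per-word error counts <= total_words")
    if max(t.is_count, t.embeddings, t.sis) > t.sentences:
        bad("sentence-level counts <= sentences")
    # every utterance needs at least one token
    leftover_words = t.total_words - nws - t.scs
    spare_tokens = leftover_words + t.filled_pauses + t.false_starts
    if t.utterances - t.sentences > spare_tokens:
        bad("enough words/pauses/false starts to populate every utterance")
    return nws


def generate_transcript(
    target: TranscriptTarget,
    seed: int = 0,
    *,
    lexicon: Lexicon | None = None,
    subject_id: str = "synthetic",
    session_id: str = "v0",
) -> Transcript:
    """Build a valid transcript whose extracted count features equal ``target``.

    Vocabulary (noun lemmas in particular) is drawn from the packaged toy
    lexicon, so the result can be fed straight back through feature
    extraction; all count features round-trip exactly and the ratio features
    equal the implied quotients.
    """
    nws = _check_target(target)
    lex = lexicon or packaged_lexicon()
    rng = np.random.default_rng(seed)
    lemmas = sorted(dict(lex.items()))
    start = int(rng.integers(len(lemmas)))

    # word tokens in a fixed POS order; flags assigned to leading words
    words: list[Token] = []
    lemma_cycle = itertools.islice(itertools.cycle(lemmas), start, start + target.nouns)
    for lemma in lemma_cycle:
        words.append(Token(lemma, word_class=WordClass.OPEN, pos=Pos.NOUN, lemma=lemma))
    for i in range(target.verbs):
        words.append(Token(f"verbo{i}", word_class=WordClass.OPEN, pos=Pos.VERB))
    for i in range(target.other_open):
        pos = Pos.ADJECTIVE if i % 2 == 0 else Pos.ADVERB
        words.append(Token(f"aperto{i}", word_class=WordClass.OPEN, pos=pos))
    n_closed = target.total_words - len(words)
    for i in range(n_closed):
        words.append(Token(f"di{i}", word_class=WordClass.CLOSED, pos=Pos.FUNCTION))

    flagged: list[Token] = []
    for i, w in enumerate(words):
        flags = set()
        if i < target.distortions:
            flags.add(TokenFlag.PHONOTACTIC_DISTORTION)
        if i < target.pe:
            flags.add(TokenFlag.PHONOLOGICAL_ERROR)
        if i < target.sem_e:
            flags.add(TokenFlag.SEMANTIC_ERROR)
        flagged.append(replace(w, flags=frozenset(flags)) if flags else w)
    word_iter = iter(flagged)

    def split_even(total: int, parts: int, minimum: int = 0) -> list[int]:
        if parts == 0:
            return []
        base = [total // parts] * parts
        for i in range(total % parts):
            base[i] += 1
        assert all(b >= minimum for b in base)
        return base

    utterances: list[Utterance] = []
    sentence_spans: list[SentenceSpan] = []
    scs_spans: list[SCSSpan] = []

    # sentence utterances: counted words + self-corrected words (in utt 1)
    per_sentence = split_even(nws, target.sentences, minimum=1 if target.sentences else 0)
    for si in range(target.sentences):
        uid = si + 1
        toks = [next(word_iter) for _ in range(per_sentence[si])]
        n_scs_here = target.scs if si == 0 else 0
        for k in range(n_scs_here):
            toks.append(next(word_iter))
            scs_spans.append(SCSSpan(uid, per_sentence[si] + k, per_sentence[si] + k + 1))
        utterances.append(Utterance(uid, tuple(toks)))
        sentence_spans.append(
            SentenceSpan(
                utterance_id=uid,
                start=0,
                end=len(toks),
                subject_type=(
                    SubjectType.IMPLIED
                    if si >= target.sentences - target.sis
                    else SubjectType.EXPRESSED
                ),
                is_embedding=si < target.embeddings,
                is_incomplete=si < target.is_count,
                msyn_error_count=target.msyn_e if si == 0 else 0,
            )
        )

    # remaining utterances take the leftover (non-sentence) words, then the
    # filled pauses / false starts; with no spare utterance everything left
    # lands after the last sentence span (outside it, so nws is unaffected)
    n_rest = target.utterances - target.sentences
    leftover_words = list(word_iter)
    fillers = [
        Token("eh", kind=TokenKind.FILLED_PAUSE) for _ in range(target.filled_pauses)
    ] + [
        Token(f"fa{i}-", kind=TokenKind.FALSE_START) for i in range(target.false_starts)
    ]
    if n_rest:
        rest_tokens: list[list[Token]] = [[] for _ in range(n_rest)]
        pool = leftover_words + fillers
        for i, tok in enumerate(pool[:n_rest]):  # one token per utterance first
            rest_tokens[i].append(tok)
        rest_tokens[-1].extend(pool[n_rest:])
        for i, toks in enumerate(rest_tokens):
            utterances.append(Utterance(target.sentences + i + 1, tuple(toks)))
    elif leftover_words or fillers:
        last = utterances[-1]
        utterances[-1] = Utterance(
            last.id, last.tokens + tuple(leftover_words) + tuple(fillers)
        )

    return Transcript(
        subject_id=subject_id,
        session_id=session_id,
        language_tag="it",
        utterances=tuple(utterances),
        sentence_spans=tuple(sentence_spans),
        scs_spans=tuple(scs_spans),
        timing=Timing(target.duration_s, target.pause_s),
    )


def random_feasible_target(seed: int) -> TranscriptTarget:
    """A random target satisfying every consistency relation (for testing)."""
    rng = np.random.default_rng(seed)
    utterances = int(rng.integers(1, 12))
    sentences = int(rng.integers(0, utterances + 1))
    total_words = int(rng.integers(max(2 * sentences, 4), 60))
    nouns = int(rng.integers(0, total_words // 3 + 1))
    verbs = int(rng.integers(0, total_words // 3 + 1))
    other_open = int(rng.integers(0, total_words - nouns - verbs + 1))
    scs = int(rng.integers(0, max(total_words // 6, 1))) if sentences else 0
    max_nws = total_words - scs
    nws = int(rng.integers(sentences, max_nws + 1)) if sentences else 0
    filled_pauses = int(rng.integers(0, 8))
    false_starts = int(rng.integers(0, 5))
    # guarantee every non-sentence utterance can be populated
    spare = (total_words - nws - scs) + filled_pauses + false_starts
    need = utterances - sentences
    if need > spare:
        filled_pauses += need - spare
    duration = float(rng.uniform(20, 180))
    return TranscriptTarget(
        total_words=total_words,
        nouns=nouns,
        verbs=verbs,
        other_open=other_open,
        utterances=utterances,
        sentences=sentences,
        duration_s=duration,
        pause_s=float(rng.uniform(0, duration / 2)),
        nws=nws,
        scs=scs,
        filled_pauses=filled_pauses,
        false_starts=false_starts,
        distortions=int(rng.integers(0, 3)),
        pe=int(rng.integers(0, 4)),
        sem_e=int(rng.integers(0, 3)),
        is_count=int(rng.integers(0, sentences + 1)),
        embeddings=int(rng.integers(0, sentences + 1)),
        sis=int(rng.integers(0, sentences + 1)),
        msyn_e=int(rng.integers(0, 4)) if sentences else 0,
    )
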
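# Methods

`ppaspeech` quantifies connected speech in primary progressive aphasia (PPA)
from annotated picture-description transcripts and implements the three
statistical stages built on those measurements: covariate-adjusted group
comparison with candidate preparation, group discrimination by forward
sequential feature selection (SFS) under ridge logistic regression with
McNemar model comparison, and longitudinal linear-trend estimation with
random subject effects. A synthetic-cohort generator reproduces the
statistical structure of published group profiles so that every stage is
testable without access to patient data.

## Transcript model and speech parameters

A transcript is the finished product of human annotation: utterances
(prosodically bounded token sequences) of typed tokens (word / filled pause /
false start, with word class, part of speech, optional lemma, and error
flags), sentence spans (half-open token ranges carrying subject type,
embedding, incompleteness, and a morphosyntactic-error count), self-corrected
sequence (SCS) spans, and two timing scalars — total duration and summed
pause duration. Two scalars are the minimal sufficient statistic for every
rate measure; individual pause events are never needed. All span indexing is
0-based and half-open. Nothing is inferred from raw text: the package
consumes annotations, it does not produce them.

From one validated transcript, 44 parameters are computed in closed form
across four domains: speech rate and speech-sound errors (durations, words
per second with and without pauses, phonotactic distortions and their
per-100-word rate, phonological errors and per-word rate), fluency
disruptions (false starts, filled pauses, SCS, incomplete sentences, each
with a per-second rate), lexical content (open/closed class counts and
ratios, verbs, nouns, verb proportion, token-weighted mean lemma frequency
of nouns and its log10, semantic errors), and syntactic structure
(utterances, utterance length, sentences, words-in-sentences excluding SCS
words, sentence length, sentence/utterance ratio, embeddings,
expressed/implied-subject sentences and their proportion, syntax production
rate, morphosyntactic errors and their ratio).

Decisions where the published definitions leave room:

* **Zero denominators.** Vectors stay total: `sl`, `r_msyn_e`, `pr_ses`,
  `pr_v` fall back to 0 when their denominators vanish (published group
  ranges include 0.00 minima, so such samples occur); an empty word class
  yields a 0 sentinel for `r_oc`/`r_cc` with a warning; no nouns gives NaN
  frequency measures.
* **Noun/verb rate.** The formula table defines the per-second quotient,
  while the published group values for "noun rate" are on the per-word scale
  (a control mean of 0.44 against 32.4 nouns in 74.4 s only works as
  nouns/words). Both variants are computed; the canonical `noun_rate` is
  per-second, `noun_rate_word` is per-word and is the variable the shipped
  profiles parameterize.
* **Noun frequency** is token-weighted (a repeated noun counts each time),
  matching a measure over produced words. Lexicon lookup lower-cases but
  never strips diacritics — Italian lemmas are diacritic-significant.
* **Incomplete sentences** count as sentences (they are annotated as
  sentence spans) and contribute to words-in-sentences.
* A word carries at most one phonological-error flag; words inside false
  starts are not words and enter no lexical count.

## Synthetic cohorts

The generator's defaults are the published study conditions: group sizes
23/40/35/20 (controls, nonfluent, semantic, logopenic), the per-group
mean ± SD (range) of every speech parameter, the demographic profiles (age,
education, female/male split), and the per-group follow-up deltas at a mean
inter-visit interval of 10.2 months (range 5.50–24.80; the unpublished
interval SD is set to 4.0 months).

**Marginals.** Each variable is drawn from a scaled Beta on its observed
[min, max], with shape parameters matched by moments to the published
mean and SD. The Beta family is used instead of a truncated normal because
speech-error counts in these cohorts are strongly zero-inflated — e.g. a
mean a third of the SD on a support starting at 0 — and on a bounded support
with the mean near an edge the truncated-normal family cannot exceed a
coefficient of variation near the exponential limit, so it cannot reproduce
the published moments at all. The Beta family covers J-, U- and bell-shaped
densities and attains every published (mean, SD, range) triple up to the
universal bounded-support variance limit `s² < (m−a)(b−m)`; published SDs
computed with the n−1 divisor occasionally exceed that bound by a hair and
are capped just inside it. A published mean lying exactly on the range edge
(printed as 0.00 to two decimals) is shifted minimally toward the interior,
because no distribution on the range can hold both that mean and a nonzero
SD. A truncated-normal marginal remains available (`family="truncnorm"`)
for users who accept its moment bias. Count-valued parameters are
stochastically rounded (round up with probability equal to the fractional
part), which preserves means exactly and inflates variance by at most 1/12.

**Dependence.** Marginal profiles say nothing about correlation, yet speech
measures are strongly inter-correlated in reality; a Gaussian copula over a
user-supplied correlation matrix (symmetric PSD, unit diagonal) induces
dependence without touching the marginals. The default is independence, so
downstream null-calibration results are exact; the true correlation
structure is unknowable from group summaries and its effect on
discrimination accuracy is an experiment, not an assumption.

**Transcript-level generation** builds a fully annotated transcript whose
extracted count features equal a requested target exactly (words, POS
composition, utterances, sentences, error counts, SCS, words-in-sentences,
timing), drawing noun lemmas from the packaged 50-lemma frequency lexicon.
Every consistency relation among targets is checked up front and violations
are reported with the failed relation. This gives the extraction pipeline an
exact round-trip oracle: ratios must equal the implied quotients to
floating-point precision.

**Follow-up visits** add a per-variable Gaussian delta (published
mean ± SD per patient group) to each baseline record, draw the interval from
a truncated normal, and clip to the variable's observed range when bounds
are supplied.

**What the generator does not emulate**: inter-feature correlation (unless
supplied), within-subject coupling between a subject's counts and durations
(a subject's WPS is drawn, not recomputed from drawn words and time), visit-
to-visit correlation beyond the shared baseline, and any linguistic content.
Passing tests therefore demonstrate that the statistical machinery behaves
correctly under the published group-level structure — not that it would
attain the published discrimination accuracies on real, correlated data.
Auxiliary blocks (standard language scores, regional gray-matter volumes)
ship as clearly-labelled synthetic placeholder profiles whose only purpose
is to exercise the model grid; their group values are not published.

## Cross-sectional statistics and candidate preparation

Group comparisons use a linear model `variable ~ group + age + sex +
education` (sex as a 0/1 indicator); the omnibus test is the type-II F for
the group factor, pairwise contrasts use the full model's pooled error, and
Bonferroni multiplies by the **number of groups** — the published rule,
kept literal — with the conventional contrast-count rule selectable.
Categorical tables use the exact conditional test: scipy's 2×2 Fisher test,
and for 2×k a direct log-multinomial enumeration over tables with the
observed margins (scipy does not cover k > 2; the enumeration is
cross-checked against full hypergeometric oracles in the tests).

Candidate preparation for the discrimination models runs three steps:
(1) an outlier audit (robust z from median/MAD, normal-consistent scale,
threshold 3.0) that reports but never removes — the source procedure
describes an "evaluation", not exclusion; (2) a significance screen keeping
variables whose covariate-adjusted omnibus effect is significant either
patients-vs-controls or among the patient groups (α = 0.05); (3) a
multicollinearity prune computing Pearson correlations **among controls**
and, within each pair with |r| ≥ 0.8, dropping the member with the smaller
between-group omnibus F (partner and r recorded). All three thresholds are
configurable; the result records every variable exactly once with its fate.

## Discrimination: forward SFS under ridge logistic regression

For each pair of groups, a greedy forward search adds, one at a time, the
candidate feature that most improves the stratified 10-fold
cross-validated score of an L2-penalized logistic regression
(regularization strength parameter 1.0, i.e. `C = 1`), stopping at 6
features or when no candidate improves. Features are z-scored with
training-fold statistics only. The selection score is the mean CV
**log-loss**: it is a proper scoring rule and continuous, whereas 0/1
accuracy plateaus stall the greedy search and let chance features win steps
(accuracy remains selectable and is always the reported evaluation metric).
Ties break by candidate order, so the path is a deterministic function of
(data, seed).

Reported accuracy and the pooled out-of-fold predictions are **nested**:
the full selection is re-run inside every training fold before predicting
its held-out fold. Reusing the selection folds for evaluation inflates
accuracy far above chance even on pure noise (≈ 0.62 at n = 75 with 8 noise
candidates); nested evaluation is unbiased, which the null-calibration
tests verify (≈ 0.50). The optimistic path score is exposed separately.
The inner loops run on a dedicated Newton/IRLS solver for the identical
penalized objective (intercept unpenalized), making nested selection
affordable; the reported full-data refit uses scikit-learn.

Goodness of fit is Nagelkerke's R², computed from an unpenalized
maximum-likelihood refit of the selected set: the statistic is defined on
maximized likelihoods, a penalized likelihood biases it downward, and only
the unpenalized version reaches 1.00 under perfect separation (values the
source analysis reports). McFadden's variant is available. Each model's
significance is a likelihood-ratio test against the intercept-only model —
the source does not state its model-significance test; this is the standard
reading.

Models are compared with McNemar's test on the 2×2 correct/incorrect table
of the two models' pooled cross-validated predictions over the same
subjects: exact two-sided binomial on the discordant pairs when they number
fewer than 25, chi-square with continuity correction otherwise (method
recorded). The model grid runs speech-only models against controls and all
seven block combinations (speech, standard language, volumes) for patient
pairs, with demographics joining every candidate set.

## Longitudinal models

Per group and variable, a linear mixed-effects model
`variable ~ visit + age + sex + education + interval` with a random
intercept per subject, fit by REML; the visit coefficient (visit coded
0/1) is the predicted per-interval delta and its Wald z test is the test
for linear trend, Bonferroni-corrected by the number of patient groups (3).
The inter-visit interval enters as a subject-level covariate (the subject's
gap in months, constant across that subject's rows); coding it as
months-since-baseline would duplicate the visit indicator. The
group-by-time model adds group and group×visit terms and reports the
omnibus Wald test of the interaction block. Wald z (not Satterthwaite t)
is used because statsmodels' mixed models do not implement Satterthwaite
degrees of freedom; at the cohort sizes involved the difference is
negligible. Non-convergent or singular fits fall back to OLS with
cluster-robust (by subject) standard errors and are flagged.

## Numerical conventions and problem sizes

All randomness flows through explicit integer seeds (`numpy` Generator);
identical (config, seed) pairs give byte-identical pipeline outputs.
Calibration and power checks in the test suite run at the sizes a laptop
handles comfortably: cohort calibration at n = 1000 per group against CLT
bands (the SD band uses the fitted marginal's analytic kurtosis, since
rare-event counts make a flat relative band meaningless); SFS behaviour at
n = 40 + 35 over 50–200 seeds; longitudinal type-I error at n = 40 over 200
seeds; the demo at the published group sizes. The McNemar exact p is
verified against full binomial-tail enumeration for all discordant
configurations up to 20.

## Known limitations

* The generator's independence default understates the difficulty of real
  discrimination problems; supplying a realistic correlation matrix is the
  user's responsibility.
* Published discrimination accuracies derive from non-deposited patient
  data and are not reproduction targets; the package reproduces the
  machinery and its calibration, not those numbers.
* Clipping follow-up values to the observed baseline range slightly biases
  injected deltas for variables whose distribution hugs a bound.
* Only two visits are modelled; no dropout, no nonlinear trajectories.
* Exact outlier and collinearity rules of the source analysis are not
  published; the defaults here (robust z > 3, |r| ≥ 0.8, larger-F
  tie-break) are documented and configurable.
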
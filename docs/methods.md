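# Methods

`dismol` implements a disease-specific ontology-learning pipeline for
daytime impairment in insomnia disorder, together with a synthetic-EHR
generator that makes every stage testable offline. This note records the
models, the parameters that matter, the numerical conventions, and what the
synthetic study does and does not demonstrate.

## Pipeline overview

1. **Corpus preparation.** Physician notes arrive as encounters with named
   sections. Only five section types are retained — chief complaint, review
   of systems, physical exam, assessment, history of present illness — and
   the past-medical-history section is dropped, because it can describe
   conditions unrelated to the disorder under study. Text is lowercased,
   sentence-split on terminal punctuation and tokenized on
   whitespace/punctuation with intra-token hyphens kept. Lemma keys come
   from rule-based suffix stripping (`-ies/-ing/-ed/-es/-s`, doubling and
   `i -> y` repairs, a small exception table) iterated to a fixpoint, which
   makes the key idempotent by construction. The key is a grouping label,
   not a display form: "fatigue", "fatigued" and "fatigues" share one key.

2. **Disease-specific embedding.** Skip-gram with negative sampling,
   implemented in numpy with minibatched SGD: dynamic window (uniform in
   `1..window`), unigram^0.75 negative-sampling distribution, linear
   learning-rate decay, a seeded generator for initialization, window
   draws, pair shuffling and negative draws, so a fixed (corpus, config,
   seed) is exactly reproducible on one worker. Hyperparameters are chosen
   by random search over a configurable space, scored with the seed-pair
   metric below; ties break toward the earliest-sampled configuration. The
   final model is an ensemble of 8 members (configurable) trained on
   sentence-level bootstrap resamples (resample size = corpus size, member
   seed = base seed + index); the token-pair distance is the mean cosine
   distance across members, restricted to the intersection of member
   vocabularies. Averaging damps the neighbour instability of any single
   stochastic run; a dedicated test checks that the across-seed variance of
   ensemble distances is below that of single-model distances.

3. **Seed-pair metric.** A model is scored by the fraction of
   known-relationship symptom pairs whose cosine similarity strictly
   exceeds the 95th percentile (nearest-rank) of a null similarity sample
   built from random daytime-impairment-supertype tokens drawn from the
   vocabulary; the reported score is the median over 5 re-draws of the
   null. Under random geometry a pair beats the threshold with probability
   0.05, so 0.05 is the chance floor — the calibration test checks this on
   an isotropic Gaussian model. Pairs with an out-of-vocabulary member are
   skipped and reported, not scored as failures, so vocabulary coverage is
   not conflated with geometric quality. When the supertype pool is smaller
   than the requested 10,000 tokens the whole pool is used (logged), and
   pairwise similarities are subsampled once they exceed a configurable
   pair budget (default 10^6); the threshold estimate error at that budget
   is negligible.

4. **Ontology enrichment.** Candidates are tokens whose ensemble distance
   to a seed term falls in the closest 3.7% of a reference distribution of
   ensemble distances over random shared-vocabulary token pairs (the 0.963
   percentile of similarity). The reference population is a global random
   pair sample rather than seed-restricted pairs — the only scale-free
   choice, and the same construction the metric's null uses. Retrieval is
   strict (`distance < threshold`), deduplicates tokens at the minimal
   distance while keeping all contributing seeds, and never returns a seed
   as its own candidate. The four filters then run in order: semantic
   supertype (unknown tokens fail closed), patient frequency (at least
   0.24% of all patients, ceiling at the boundary: 82,672 patients demand
   199), directionality clarity, and explicit expert review from an
   accept/reject file — the pipeline never auto-accepts a term. Finally
   lexical consistency requires that terms sharing a lemma key carry
   identical domain sets; `union` resolution assigns the class the union
   of its members' domains.

5. **Directionality (ConText-style).** Trigger phrases in six categories
   (negation, pseudo-negation, hypothetical, historical, family,
   termination) project scopes over sentence tokens: forward, backward or
   bidirectional, up to `max_scope` tokens (0 = sentence boundary), cut
   short by the first termination trigger. Triggers match longest-first and
   non-overlapping; a pseudo-negation claims its tokens before any shorter
   negation can, which implements the suppression rule. Scopes never cross
   sentence boundaries, and double negation stays a single flag (ConText
   family semantics, not algebraic cancellation). A mention is a confirmed
   impairment event iff its polarity agrees with its negation status:
   ordinary symptom terms count when asserted, positive-state terms such as
   "happy" or "energy" count exactly when negated. Hypothetical and
   family-attributed mentions never confirm. Historical mentions confirm by
   default (config-switchable): history is excluded upstream by dropping
   the past-medical-history section, not by the modifier. A token has
   "clear directionality" when at least 80% of its corpus occurrences
   resolve to asserted or negated (not hypothetical/family); the 0.8 share
   is a package choice, config-exposed, since no operational constant is
   established for this criterion.

6. **Inference and evaluation.** An encounter's domain is flagged present
   when at least one confirmed event of that domain occurs in its retained
   sections; the flag is binary by design (mention counts do not change
   it), but every confirmed event is kept for rate counting. ICD baselines
   flag an encounter from same-patient, same-calendar-date claims through
   editable domain -> code maps with prefix-aware matching ("F32" matches
   "F32.1"). Scoring uses sensitivity, precision and F1 over either
   encounter-level or encounter x domain units; zero-denominator ratios are
   reported as undefined rather than zero. Reported metrics round to whole
   percent; internal values keep full precision.

7. **Treatment effects.** Per drug class (trazodone; benzodiazepines:
   estazolam, flurazepam, lorazepam, quazepam, temazepam, triazolam;
   non-BzRAs: eszopiclone, zaleplon, zolpidem) the index date t0 is the
   first dispensing. Inclusion: an insomnia claim strictly inside
   (t0 - 183 d, t0) and age >= 18 at t0 (calendar-year arithmetic; the
   feed has no birth date). Exclusion: palliative-care, active-malignancy
   or pregnancy codes on or before t0, each logged with its rule. Events
   are counted in [t0 - 182 d, t0) and (t0, t0 + follow-up]; t0 itself is
   censored. Follow-up ends at the last dispensing plus a 30-day
   days-supply allowance. Rates are pooled events per 100 patient-years
   (365.25-day years). Two percent-change quantities coexist and are
   reported under separate labels: `aggregate_pct` = 100 * ATE /
   rate_before (the ratio of pooled rates), and `within_subject_pct` =
   mean +- SD of per-patient relative changes in annualized rates.
   Patients with zero baseline events are excluded from the within-subject
   ratio (division by zero) but retained everywhere else; the exclusion
   count is reported. Annualizing per-patient rates neutralizes unequal
   window lengths. Significance is a two-sided paired t-test on per-patient
   annualized-rate differences; the 95% CI uses the t distribution on the
   same differences; zero-variance families report p as undefined.
   Benjamini-Hochberg step-up q-values are computed across the full
   (representation x class x domain) family of one run; the family
   definition is config-exposed. A domain-spanning term contributes one
   event to each of its domains but only once to the all-domains count, so
   multi-domain terms are not double-counted in the overall row.

## The synthetic study

The generator emulates the seven inputs of the real feed: sectioned notes,
claims, dispensings, demographics, the seed ontology, the semantic-type
lexicon, known-relationship seed pairs and gold annotations. Its defaults
define the study conditions and were fixed once:

* **Seed ontology**: 14 item-stem terms over cognition/emotional/physical
  plus five expert-style synonyms. Item texts are paraphrased stand-ins for
  a licensed questionnaire, not its wording. "happy" and "energy" carry
  negated polarity.
* **Planted synonyms** (default six, e.g. fatigue -> weariness) co-occur
  in-sentence with their seeds in 60% of their assertions, which is what
  makes them embeddable neighbours.
* **Emission**: 0.4 events per domain per note (Poisson), negated surface
  forms at rate 0.15, ~6 baseline and ~3 on-treatment visits per treated
  patient over 182 / 91 observed days. Visit counts are untruncated
  Poisson draws so expected visit density is identical pre/post and the
  planted rate ratio equals the class multiplier exactly.
* **Planted treatment effect**: per-class multiplier on the emission rate
  after the first dispensing (defaults 1.05 / 1.2 / 1.15 for trazodone /
  benzodiazepine / non-BzRA, echoing the direction of the motivating
  findings).
* **Claims**: insomnia diagnoses placed inside the inclusion window (5% of
  treated patients deliberately violate one cohort rule each), domain
  symptom codes emitted for only 20% of truly impaired encounter-domains —
  the under-coding that makes ICD baselines insensitive — plus comorbidity
  and exclusion codes.
* **Background text**: template filler sentences over a synthetic
  vocabulary partitioned into 10-token topics; 80 background tokens carry
  the daytime-impairment supertype so the metric's null pool is non-trivial.
  Without topic structure every background token shares every context and
  the embedding geometry degenerates into a single cluster.

Gold annotations mark, per note and domain, whether a correctly-directed
(impairment-direction) planted mention was emitted into a retained section.

**What passing tests show — and do not show.** The synthetic corpus is a
template grammar: it validates the mechanics (section filtering, scope
resolution, filter arithmetic, window censoring, estimator calibration and
parameter recovery), not clinical-language robustness. Real notes have
misspellings, abbreviations, section-header noise and negation patterns
outside any trigger list; absolute synthetic scores (e.g. near-perfect
inference accuracy against gold) say nothing about accuracy on real notes.
The treatment-effect recovery shows the estimator is unbiased for a planted
multiplicative effect under uninformative visit timing; it cannot speak to
confounding, indication bias or carry-over, which the within-subject design
does not control.

## Numerical choices

* Percentiles are nearest-rank (ceil(q*n)-th order statistic) with a 1e-9
  tolerance inside the ceiling against float round-off; no interpolation.
* "Within the 95th percentile" counts strictly-greater similarities;
  candidate retrieval keeps strictly-smaller distances.
* Cosine computations guard zero vectors with a 1e-12 norm floor.
* Nearest-neighbour ties break lexicographically; vocabulary order is by
  descending count then token, so training is order-deterministic.
* Problem sizes in the test suite and acceptance script (corpora of
  120–300 patients, 2,000-patient effect cohorts, 200 replicate nulls,
  3-member ensembles in tests) are chosen as the smallest studies at which
  the checked quantities are statistically decidable at 3 Monte-Carlo SE.
* The boundary example 82,672 x 0.24% = ceil(198.41) = 199 is enforced in
  tests; ceiling (not rounding) because the rule is a lower bound.

## Known limitations

* The trainer is a faithful but compact SGNS; it has no hierarchical
  softmax, no CBOW variant and one worker (by design, for determinism).
* The bundled trigger lexicon (~60 phrases) is a compact set modelled on
  the published ConText categories and is fully replaceable via TSV; it is
  not a complete clinical trigger inventory.
* The suffix-stripping lemma key over-merges rare forms ("bring"/"br");
  this is harmless for grouping but the keys are not citable lemmas.
* Age uses calendar-year arithmetic at t0; day-precision ages would need
  birth dates the feed does not carry.
* Expert review is an input file; the package deliberately has no
  auto-accept path.
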
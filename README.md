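# dismol — disease-specific medical ontology learning

Mental-health disorders are poorly served by general-purpose coding systems:
daytime impairment is a required feature of an insomnia diagnosis, yet its
symptoms (fatigue, poor concentration, irritability, sleepiness, ...) are
rarely coded in claims. `dismol` learns a disease-specific symptom ontology
directly from physician notes and uses it to turn free text into structured
encounter-level data, so that disease burden and treatment effects can be
measured where ICD codes under-report them.

The package is aimed at clinical-NLP and real-world-evidence researchers.
It implements the full pipeline:

* **Corpus preparation** — keep the five clinically current note sections
  (chief complaint, review of systems, physical exam, assessment, history of
  present illness; past medical history is dropped), tokenize, lemmatize,
  and compute per-token patient frequencies.
* **Disease-specific embedding** — skip-gram with negative sampling,
  hyperparameter search, and an 8-model bootstrap ensemble whose token-pair
  distance is the mean cosine distance across members,
  `D(a,b) = (1/8) Σᵢ (1 − cosᵢ(a,b))`.
* **Seed-pair evaluation** — a model's score is the fraction of
  known-relationship symptom pairs whose similarity exceeds the 95th
  percentile of a null built from random daytime-impairment-supertype
  tokens (chance floor 0.05), median across 5 null re-draws.
* **Ontology enrichment** — retrieve tokens in the closest 3.7% of the
  ensemble-distance distribution (the 0.963 similarity percentile), then
  filter by semantic supertype, patient frequency (≥ 0.24% of patients,
  ceiling at the boundary), directionality clarity, and an explicit expert
  accept/reject file; finally enforce lexical consistency (same lemma ⇒
  same domain set).
* **Directionality inference** — a ConText-style trigger/scope algorithm
  (negation, pseudo-negation, hypothetical, historical, family,
  termination) decides whether a mention is a confirmed impairment event:
  "being happy" is no impairment, "not being happy" is one.
* **Evaluation vs ICD baselines** — encounter-level sensitivity, precision
  and F1 against gold annotations, for the learned ontology and for two
  expert ICD-10 code maps.
* **Treatment effects** — within-subject pre/post rates per 100
  patient-years around the first dispensing of trazodone, benzodiazepines
  or non-BzRA hypnotics, with paired t-tests and Benjamini–Hochberg FDR.
* **Synthetic EHR generator** — a first-class module that emits notes,
  claims, dispensings, demographics, seed ontology, lexicon, seed pairs and
  gold annotations with planted synonyms and a planted treatment effect, so
  every stage above is testable offline.

## Worked example

```python
import dismol as dm
from dismol.ontology_enrichment import (
    retrieve_candidates, apply_supertype_filter,
    apply_frequency_filter, apply_directionality_filter,
)

cfg = dm.GenerationConfig(n_patients=150, rng_seed=1)
bundle = dm.generate_bundle(cfg)
corpus = dm.corpus_stats(dm.select_sections(e) for e in bundle.encounters)
print(f"corpus: {len(corpus.sentences)} sentences, "
      f"{len(corpus.token_stats)} tokens, {corpus.n_patients_total} patients")

tc = dm.TrainConfig(dim=40, window=4, min_count=3, epochs=3)
ens = dm.build_ensemble(corpus, tc, n_models=3, base_seed=1)
res = dm.evaluate_model(ens.members[0], bundle.seed_pairs,
                        bundle.semantic_lexicon, n_runs=5)
print(f"seed-pair metric (median of 5 runs): {res.median_fraction:.2f}")

cands = retrieve_candidates(ens, bundle.seed_ontology, seed=0)
stage = apply_supertype_filter(cands, bundle.semantic_lexicon)
stage = apply_frequency_filter(stage, corpus)
stage = apply_directionality_filter(stage, corpus.sentences)
print(f"candidates: {len(cands)} retrieved -> "
      f"{len(stage)} after the three automatic filters")
print("surviving:", sorted(c.token for c in stage))
```

prints

```
corpus: 10600 sentences, 258 tokens, 150 patients
seed-pair metric (median of 5 runs): 0.64
candidates: 19 retrieved -> 6 after the three automatic filters
surviving: ['crankiness', 'distractibility', 'groggy', 'jittery', 'somnolence', 'weariness']
```

The metric's 0.64 is far above its 0.05 chance floor — the planted
co-occurrence structure is detected — and the six survivors are exactly the
six synonyms the generator planted; they would now go to expert review
(`apply_expert_review`), which is an explicit input, never automatic.

Treatment effects on a larger bundle (the generator plants a 1.2×
post-treatment emission multiplier for benzodiazepines):

```python
cfg = dm.GenerationConfig(n_patients=1000, rng_seed=1)
bundle = dm.generate_bundle(cfg)
imps = dm.infer_encounters(bundle.encounters, dm.planted_ontology(cfg))
recs, excluded = dm.build_cohort(bundle.claims, bundle.dispensings,
                                 bundle.patients,
                                 dm.CohortSpec(drug_class="benzodiazepine"))
dm.count_events(recs, imps)
r = dm.estimate_effect(recs, dm.ALL_DOMAINS)
```

```
benzodiazepine cohort: 202 patients (6 excluded)
rate before 1381.0, during 1590.4 per 100 patient-years
ATE 209.4 [7.3, 437.8], change 15.2%, p = 0.0427
```

The +15.2% aggregate change estimates the planted +20% within this cohort's
Monte-Carlo error; the excluded patients are the generator's deliberate
cohort-rule violators (late diagnosis, underage, exclusion codes).

A `dismol` console script wraps the stages (`synth`, `prep`, `train`,
`eval-model`, `enrich`, `infer`, `score`, `effects`); run
`dismol <command> --help` for the file formats.

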
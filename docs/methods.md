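# Methods

`notelex` implements a complete, testable pipeline for a common study
design in clinical-documentation research: detect negative patient
descriptors ("noncompliant", "agitated", "refused", ...) in
history-and-physical (H&P) notes, reduce sentence-level detections to a
note-level binary outcome, and model that outcome as a function of
patient race/ethnicity and covariates with a three-level mixed-effects
logistic regression (notes nested in encounters nested in patients).
Because real H&P corpora and chart-review labels are private, every
experiment here runs on synthetic data with known ground truth; the
generator is a first-class, tested module.

## Descriptor lexicon and matching

The lexicon holds fifteen descriptors, each with a lowercase stem that
captures its grammatical family (`adher` → adherent / adhere / adhered /
adherence). Matching is case-insensitive, word-initial, and restricted
to a closed list of grammatical suffixes; the suffix list is what keeps
look-alike tokens ("resistor", "complicated", "challenger") from
matching. Fused or hyphenated negation morphemes (`non`, `non-`, `un`,
`in`) are recognized during matching and carried on the hit;
free-standing negators ("not", "poorly") are the classifier's business.
Each descriptor is classed either *inherently negative* (aggressive,
agitated, angry, challenging, combative, confront, defensive,
exaggerate, hysterical, refuse, resist) or *polarity-by-negation*
(adherent, compliant, cooperative, pleasant — positive words that become
negative only under negation).

## Sentence segmentation

Notes are normalized (whitespace collapsed, non-printing characters
dropped, casing and punctuation untouched) and split by an explicit rule
system: sentence-final punctuation with an abbreviation guard (Dr., Mr.,
Mrs., Ms., vs., e.g., i.e., a.m./p.m., single-letter initials), bullet
markers, and ALL-CAPS section headers ("ASSESSMENT:") as their own
segments. "pt." is treated as non-final only when it runs into a
lowercase continuation, since in clinical text it commonly ends a
fragment. The splitter is deliberately simple and is pinned by a
50-line hand-annotated fixture (`tests/data/sentence_fixture.tsv`); one
consequence of the single-initial guard is that a capital-letter
abbreviation like "98.6 F." does not end a sentence.

## Context classification

Every descriptor-containing sentence gets one of three labels:
`negative`, `positive`, or `out_of_context` (descriptor applied to a
non-patient entity, e.g. "non-compliant balloon"). Two classifiers
share this contract:

* **Rules.** In order: (1) out-of-context if a non-patient-entity cue
  noun (balloon, bandage, dressing, airway, organism(s), bacteria,
  tourniquet, valve, catheter) lies within ±2 tokens of the hit, or
  "resistant" is preceded within 3 tokens by a microbiology collocate
  (methicillin, vancomycin, drug, multi, antibiotic, MRSA, VRE);
  (2) a polarity-by-negation descriptor is negative iff negated — by a
  fused prefix or a free-standing negator ("not", "non", "poorly",
  "never", "no longer") within a 4-token window — and positive
  otherwise; an inherently negative descriptor is negative unless a
  denial cue ("denies", "denied", "without") or negation flips it to a
  benign reading. Multi-hit sentences are negative if any hit is
  negative, else positive if any is positive, else out-of-context. The
  cue check is symmetric (±2 tokens) rather than following-only because
  clinical usage puts the entity on either side ("airway
  semi-cooperative" vs "non-adherent bandage"). The window sizes are
  fixture-calibrated constants.
* **Trained model.** A multinomial logistic regression over sparse
  features: lowercased uni-/bi-grams within ±6 tokens of each hit plus
  indicators for descriptor identity, fused negation, and cue
  proximity. The vocabulary is built on the training fold only. It is a
  scikit-learn estimator (`fit`/`predict`), serialized as a flat JSON
  file (feature spec + weights), with a fixed prediction tie-break
  (negative > positive > out_of_context). Evaluation follows the
  standard protocol for this task: stratified two-thirds / one-third
  split, per-class precision/recall/F1 and their unweighted macro mean.

## Cohort construction

The analytic cohort is produced by an ordered exclusion cascade with
per-stage accounting: (1) drop patients carrying any dementia-prefix
ICD-10 code (prefix list configurable; default F00–F03, G30), (2) drop
patients missing race/ethnicity, (3) drop patients missing any model
covariate. Missing values are explicit sentinels (`NA` in files,
`None` in memory) and never imputed. Covariates are coded against
fixed reference levels — race White, age 65+, male, married,
English-speaking, private insurance, inpatient, encounter before
2020-03-01 — with the Charlson Comorbidity Index and encounter length
consumed as numeric inputs (the CCI is never computed from diagnoses
here). A note is outcome-positive iff at least one of its sentences is
classified negative; per-patient counts of negative notes feed the
patient-level sensitivity model.

## The three-level model

With note *k* in encounter *j* of patient *i*,

    logit P(y_ijk = 1 | u_i, w_ij) = x_ijk' β + u_i + w_ij,
    u_i ~ N(0, σ²_pat),   w_ij ~ N(0, σ²_enc),

and the marginal likelihood integrates both intercepts out of each
patient block. Two evaluations are implemented:

* **Laplace**: joint Newton mode-finding over all random effects. The
  per-patient Hessian blocks are arrow matrices (the patient intercept
  couples to the diagonal of its encounter intercepts), so each Newton
  step and the log-determinant come from a closed-form Schur
  factorization, fully vectorized across patients.
* **Nested adaptive Gauss–Hermite (AGQ, the default)**: outer
  quadrature per patient, centred at the Laplace mode and scaled by the
  Schur curvature; inner quadrature per encounter at its conditional
  mode given the outer node. Default order 7 (configurable).

AGQ is the default because the realistic nesting here has ~1.2 notes
per encounter: with a binary outcome and mostly singleton clusters the
Laplace objective is not just inaccurate but *unbounded-increasing* in
σ²_enc, so a Laplace fit runs the encounter variance to the boundary
and corrupts the fixed effects. Order-15 AGQ agrees with brute-force
dense two-level integration to ~1e-8 on toy data and is the package's
own integration cross-check.

Optimization is L-BFGS-B on (β, log σ_pat, log σ_enc), started from the
plain IRLS logistic solution and σ = 0.5, with bounds log σ ∈ [−10, 3]
(the lower bound is effectively σ = 0; at that limit the objective
reduces exactly to the ordinary logistic likelihood). Convergence is
relative log-likelihood change below `tol` (default 1e-8) with gradient
norm checks; hitting the iteration cap sets `converged=False` rather
than raising. Inference is Wald throughout: standard errors from the
numerically differentiated observed information at the optimum, odds
ratios `exp(β)` with `exp(β ± z·se)` intervals. Known identifiability
limits: with one note per encounter per patient the two variances (and
their total, jointly with β) sit on a flat ridge — the fit terminates
with finite boundary-ish values, which is the documented behaviour, and
even in well-posed designs σ²_enc is weakly identified (only multi-note
encounters inform it), so its estimate is noisy while the fixed effects
remain well behaved.

The patient-level sensitivity analysis is an ordinary least-squares
regression of each patient's negative-note count on covariates with
HC1 heteroskedasticity-robust standard errors, reported per 100
patients.

## Synthetic-data generator

The generating model is exactly the analysis model, so parameter
recovery is well posed. Defaults live in a version-controlled config
file (`src/notelex/data/sim_defaults.yaml`), not code:

* Patient covariate marginals follow the emulated study population
  (race 29.7/60.6/6.2/3.5% White/Black/Hispanic-Latino/other; five age
  bands; 56% female; 67.8% unmarried; 2.2% non-English; insurance
  32.2/32.7/35.1% Medicaid/Medicare/private; 8.2% COVID-positive).
* Encounters per patient are 1 + Poisson(0.795) and notes per encounter
  1 + Poisson(0.21), matching ~1.8 encounters and ~2.2 notes per
  patient; encounter location 46.6/51.8/1.6% inpatient/outpatient/ED,
  80.7% after the 2020-03-01 cutoff, exponential lengths (mean 4.4
  days), Poisson CCI (mean 1.4).
* The true conditional log-odds effects are the natural logs of the
  adjusted odds ratios being recovered (e.g. 2.54 for Black vs White,
  2.66 for Medicaid vs private).
* Random-intercept variances default to σ²_pat = 1.0, σ²_enc = 0.5 —
  moderate within-patient clustering of the kind such outcomes show;
  neither is externally reported, so they are declared constants.
* The baseline intercept (−5.13) was calibrated once, by bisection on
  large simulations, so that the defaults yield the emulated study's
  8.2% patient-level prevalence of at least one negative note.

Note text is rendered from a template bank covering all 15 descriptors
× 3 labels, validated at construction: every instantiated template
contains exactly one lexicon hit and is classified by the rules as its
intended label. Notes whose true indicator is 1 get one
negative-context sentence; positive and out-of-context distractor
sentences are injected at rates 0.30 and 0.10 per note; neutral
descriptor-free filler pads every note. Because templates are
rule-consistent and the cohort path applies no lexical noise, the
detection pipeline recovers the generating indicators exactly — by
design, so end-to-end recovery error reflects the estimator, not the
text layer. The labeled-corpus path (classifier training) additionally
applies lexical noise: random filler phrases plus 5% dropout of
non-signal tokens (descriptor forms, negators, and cue nouns are never
dropped — labels must remain consistent with the text). The default
class mix is 0.35/0.45/0.20 negative/positive/out-of-context, a
declared assumption. What passing on this corpus does *not* show:
robustness to real clinical prose (typos, templated EHR boilerplate,
section structure, copy-forward text) or to descriptors outside the
fifteen-term lexicon.

## Reported quantities and problem sizes

`scripts/acceptance.py` recomputes, from scratch at run time: the
held-out macro-F1 on a 6,818-sentence surrogate corpus, and the
adjusted ORs for Black-vs-White race and Medicaid-vs-private insurance
recovered by the full pipeline. A single 2,000-patient replicate
carries only ~220 outcome events, so its log-OR estimate has a sampling
SD near 0.25–0.28; the script therefore runs 30 seeded replicates and
reports the exponentiated 10%-trimmed mean of the replicate log ORs
(trimming guards against occasional variance-boundary solutions). The
same sampling arithmetic means no estimator could land inside the
reported CI band — half-width ≈ 0.24 on the log scale, about one
per-replicate SD — in ≥90% of replicates at this cohort size; the
corresponding acceptance test states that bar faithfully and documents
the shortfall rather than relaxing it.

## Numerical choices, degeneracies, limitations

* Classifier ties broken by fixed label priority; identical texts map
  to identical features (pure functions throughout the text path).
* Singular designs are rejected with the collinear columns named;
  constant outcomes are rejected.
* The quadrature order trades accuracy for time: 7 for reported fits,
  5 inside replicate sweeps, 15 for oracle comparisons.
* The sentence splitter and rule classifier are English-only and tuned
  to short clinical prose; no de-identification, spelling correction,
  or section-aware logic is attempted.
* No crossed random effects, random slopes, survey weights, or Bayesian
  estimation; Wald (not profile) intervals only.
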
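# Methods

## Problem setting

Patients with fluctuating Parkinson's disease alternate between ON
periods (high dopaminergic medication effect: elevated mood, energy,
talkativeness, sometimes euphoria) and OFF periods (fatigue, low mood,
anxiety, lack of initiative).  The Neuropsychiatric Fluctuations Scale
(NFS) is a 20-item momentary self-report instrument — 10 items phrased
as typical ON feelings, 10 as typical OFF feelings — from which a
neuropsychiatric state score in [0, 60] is derived (0 = very low mood,
60 = very high mood).  `nfspeech` asks how much of this state is
recoverable from *what patients say* in a short free-speech monologue:
it classifies the medication state and regresses the state score from
an English transcript, using three complementary approaches, and
evaluates everything with leave-one-subject-out cross-validation
(LOSO: both recordings of the held-out patient form the test set, so no
model component ever sees the test subject).

## The three approaches

**1. Semantic search against the NFS items** (`semsearch`).  Transcripts
and items are normalized identically (lowercase; punctuation stripped;
pronouns, conjunctions, articles and prepositions removed; negations
always kept, with n't-contractions expanded first so "don't" survives as
"do not").  Each transcript, used as a query, is ranked against the 20
item embeddings by cosine similarity; the predicted state is the
majority polarity of the top-k items (k odd, default 5 — an odd voter
count cannot tie).  The fraction of ON voters serves as the
probability-of-ON for ROC and calibration analysis.  The state score is
predicted separately by kNN over the *other* patients' transcripts: the
similarity-weighted mean score of the top-k (default 5) most similar
training transcripts, with negative similarities clamped to zero
(negative weights could leave the convex hull of neighbour scores and
hence the scale), an unweighted-mean fallback when all weights vanish,
and a final clip to [0, 60].

**2. ML on reduced embeddings** (`ml_models`).  Embeddings are reduced
per training fold by PCA on standardized columns (truncated SVD for
sparse counts), keeping the smallest leading component count whose
cumulative explained variance reaches 0.9.  Classifiers: Gaussian naive
Bayes, SVM (with Platt-scaled probabilities), random forest.
Regressors: random forest, ridge, SVR, LightGBM and XGBoost behind one
contract.  Hyperparameters come from a seeded grid search with inner
3-fold CV (stratified for classification; accuracy / RMSE as the
selection score) on training rows only; grids are deliberately small
(≤ 24 points) and config-exposed.  Regression outputs are clipped to
[0, 60]; `bagging_ensemble` uniformly averages aligned predictions of
two or more base regressors and re-clips.

**3. Few-shot prompting of a generative model** (`llm_harness`).  A
prompt is an instruction paraphrase, then k labelled in-context examples
("Transcript: …\nClass: ON"), then the open query slot.  Examples are
the k most cosine-similar transcripts from other patients (k = 6 for
classification, 9 for regression by default).  Nine instruction
paraphrases — all embedding the identical example set and query — are
run per query; the final class is the modal parsed label (ties go to
the label with the higher mean first-token confidence, else OFF) and
the final score is the mean of parsed values, clipped.  Output parsing
is deliberately strict: a single standalone ON/OFF token, or the first
numeric literal inside [0, 60]; anything else counts as a parse
failure, and a query where all nine paraphrases fail raises an abstain
error rather than guessing.  First-token confidence is the mean
probability mass the backend places on the "ON"/"OFF" answer tokens
across the nine prompts; it feeds the calibration analysis (Brier, ECE,
MCE over 10 equal-width bins on the probability-of-ON, ON being the
positive class throughout).

## Backends and the offline simulators

Embedding and generation go through registries.  Always available:

* `ngram` — bag of word n-grams (n = 1–3), raw counts or tf-idf, fitted
  per training fold;
* `mock` — deterministic dense embeddings: each token is hashed (keyed
  by a seed) to one of 256 coordinates with a ±1 sign and the signed
  counts are L2-normalized, so cosine similarity tracks token overlap
  and the entire pipeline is bit-reproducible offline;
* `stub` — a keyword-scoring simulator of an instruction-following
  model.  It reads the prompt exactly as written (examples + query),
  computes each text's ON fraction over the pole-symptom vocabularies
  that the instruction itself describes, and blends a logistic in the
  query's ON fraction with a proximity-weighted vote over the in-context
  example labels — a deterministic caricature of in-context learning.
  Regression answers map the ON fraction onto the 0–60 scale with a
  small seed-keyed per-prompt jitter so the paraphrase ensemble is
  non-trivial.

Adapters for real sentence-embedding checkpoints or locally hosted LLMs
can be registered at runtime (`register_dense_backend`,
`register_llm_backend`); nothing in the package downloads models.

## Synthetic cohort generator

Clinical recordings of this kind cannot be shared, so `synthetic_data`
generates cohorts carrying the structure the analysis assumes.  Defaults
are the emulated study conditions: 33 patients, each with one OFF and
one ON recording; latent scores drawn from normals with ON 48.2 ± 8.7
and OFF 17.2 ± 12.0, clipped to [0, 60] (clipping rather than
resampling — the emulated cohort's observed ranges touch both bounds).
Transcript text is template-based: each sentence frame has three
content slots, filled from the ON-pole vocabulary with probability
`w·separation`, the OFF-pole vocabulary with probability
`(1−w)·separation`, and neutral vocabulary otherwise, where
`w = score/60`.  Text therefore correlates linearly with the score, and
`lexicon_separation` dials the task from fully informative (1.0) to
pure noise (0.0).  Transcripts default to 6–10 sentences (~60–90
words), matching the order of magnitude of a ~45-second monologue.

A configurable fraction of patients (default 3/33) are
**nonfluctuators**: their (ON, OFF) pair is rejection-sampled from the
same marginals conditioned on |ON − OFF| < 10, while all other patients
are conditioned on the complement, so the realised nonfluctuator count
is exactly binomial in the configured rate.  About 20% of patients can
be given a second OFF recording drawn from the same latent state plus
measurement noise (`generate_repeat_trial`), emulating a repeat-trial
design.

**What the generator does and does not emulate.**  It reproduces the
paired design, the score distributions, a lexical text–score link, and
rare nonfluctuators.  It does not emulate disfluencies, ASR errors,
translation artefacts, topic drift, or any semantics beyond vocabulary
choice — so passing recovery tests shows the pipeline's machinery is
sound, not that real speech is this separable.

**An intrinsic accuracy ceiling.**  Because text tracks the *score*
(not the label), recordings whose score falls on the wrong side of the
optimal decision boundary (~33.6 under the default distributions) are
genuinely misleading: about 8.6% of OFF and 4.7% of ON recordings.
This caps per-recording classification at ~0.93 even with unlimited
text, and an oracle that counts pole terms directly on the generated
transcripts measures ~0.89–0.90 averaged over seeds.  The observed
accuracies of the item-vote (~0.85) and stub-LLM (~0.88) pipelines sit
close to that oracle; the residual gap is retrieval noise.  This
mirrors the real phenomenon the emulated study reports: its one
misclassified recording came from a nonfluctuating patient whose OFF
score exceeded the ON score.

## Numerical and design choices

* Ranking and retrieval ties break by ascending target id —
  deterministic and order-independent.
* The variance threshold keeps the *smallest* component count reaching
  ≥ 0.9; an unreachable threshold keeps everything and flags the model.
* Reductions, vocabularies, grids and retrieval pools are refit inside
  every LOSO fold by default; `reduce_global_fit` reproduces a
  corpus-wide fit for comparison with analyses that fitted once.
* Quartiles of absolute errors use linear interpolation (type 7);
  Spearman uses average ranks on ties; MAE's spread is the sample SD.
* A constant truth vector flags Spearman/R² as degenerate instead of
  raising; all other metrics are still computed.
* Flagged-empty normalized documents (every token removable) are the
  caller's decision; the LOSO driver surfaces the affected fold as
  failed rather than silently dropping rows.
* All randomness flows from explicit seeds (generator config, mock
  hashing key, model seeds, stub jitter key); two runs with equal seeds
  produce byte-identical reports.

## Problem sizes used in the shipped checks

Recovery checks average 20 cohorts per condition; generator-fidelity
checks use 200 cohorts; oracle-equivalence checks use 100 seeded random
instances per operation; the acceptance script pools 3 evaluation
cohorts (198 LOSO predictions per approach) and 50 generator cohorts.

## Known limitations

* The packaged NFS item file contains only the six item texts that are
  publicly quoted; the other fourteen are theme-consistent synthetic
  stand-ins (marked in the file), so item-level frequency profiles are
  illustrative, not clinical.
* The stub LLM and mock embeddings are lexical simulators; none of the
  reported synthetic-cohort numbers transfer to real checkpoints.
* The stop-word sub-lists are a package decision (the four classes are
  fixed, their membership is not canonical); results shift slightly
  with the list.
* Scores are consumed as data; the NFS-to-score formula is out of
  scope.
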
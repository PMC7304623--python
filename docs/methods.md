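# Methods

This note documents the models, the evaluation protocol, the synthetic
data generator, and the numerical and design choices behind them.

## Text preprocessing

Cleaning removes configurable boilerplate lines (site headers, signature
lines; regex list, user-replaceable), collapses separator art (runs of
the same character among `=-_*~#+` of length ≥ 3), lowercases, and maps
punctuation to spaces. Sentence terminators `.!?` are kept attached to
the preceding word until sentence splitting, and a space is enforced
after them so dictation artifacts like `stroke.Impression` cannot fuse
two words into one token. Cleaning is idempotent; tokens contain only
`[a-z0-9]`.

Multi-word medical phrases are merged into single tokens via an ordered
lexicon (longest phrase first, left-to-right, word-boundary anchored).
The default lexicon holds ~35 neurovascular phrases (cerebral arteries,
diffusion terms, grey-white matter wording, hemorrhage types); it is a
two-column CSV and fully user-extensible, since boilerplate formats and
phrase inventories are site-specific. Stop words are retained
deliberately: tf-idf is the mechanism that down-weights them, and
removing them would change the bag-of-words counts that the featurizer
definitions are stated in terms of. Negation is *not* parsed; the
classifiers must learn negated mentions from context, which is exactly
what the synthetic negation templates exercise.

## Featurization

- **BOW**: absolute token counts over a vocabulary fitted on the
  training split only (`min_df` configurable, benchmark default 2).
  Out-of-vocabulary tokens at test time are dropped — the vocabulary is
  a training-corpus artifact.
- **tf-idf**: `tf · idf` with the smoothed inverse document frequency
  `idf(t) = ln((1+N)/(1+df(t))) + 1`. This dialect keeps every weight at
  or above the raw count (a token present in every training document
  keeps its tf), and cannot divide by zero for tokens unseen in
  training. No document-length normalization by default; an L2 flag
  exists because practice varies.
- **Document embedding**: elementwise sum of the word vectors of
  in-vocabulary tokens; an empty or fully-OOV document maps to the zero
  vector rather than an error, so degenerate reports flow through
  scoring.

## GloVe trainer

Co-occurrence accumulates `1/distance` for every ordered pair within a
symmetric window (default 10 tokens). Windows are sentence-bounded by
default (a `cross_sentence` flag removes the restriction): radiology
sentences are short, telegraphic units and cross-sentence counts mix
unrelated findings. Same-token pairs are skipped entirely, so the
diagonal of X is exactly zero.

Training minimizes the weighted least-squares objective with
`f(x) = min((x/x_max)^α, 1)`, `x_max = 100`, `α = 0.75` — the standard
weighting constants — by AdaGrad with accumulators initialized to 1 and
per-epoch seeded shuffling of the nonzero entries. Parameters initialize
uniformly in `(−0.5/d, 0.5/d)`. Updates are applied in vectorized chunks
(default 1024 entries); within a chunk, updates for a repeated row use
the accumulator state from the chunk start, which is a deterministic
approximation of fully sequential AdaGrad and indistinguishable from it
in the recovery experiments. The raw error term is clipped to ±100 for
numerical safety. "Iterations" are epochs (full passes over the nonzero
entries). The per-epoch loss `Σ f·diff²` is recorded; training is
single-threaded and bitwise reproducible given the seed. The exported
vector per token is `w + w̃`.

Defaults: d=100, 50 epochs, window 10, learning rate 0.05.

## Classifiers

Lasso logistic regression (penalty weight λ, max 1000 iterations,
tolerance 0.01, unpenalized intercept), k-NN (Euclidean, probability =
vote fraction, default grid {5, 10, 15, 20}), CART (depth and minimum
bucket each in 1–10, gini by default with entropy available), and random
forest (200 trees) are fitted through scikit-learn behind the module's
own interface. Logistic regression and k-NN standardize features
internally with statistics from the training rows only — both are
scale-sensitive, and tf-idf columns span orders of magnitude.

The recurrent model is a hierarchical LSTM written in numpy: a
word-level LSTM (forget/input/output gates, forget bias 1) reads each
sentence's embedded tokens and its final hidden state becomes the
sentence vector; a sentence-level LSTM reads the sentence-vector
sequence into a document vector; an affine + logistic head produces the
probability. Embedding rows are frozen (an unfreeze option was
considered and rejected: on desk-scale corpora fine-tuning overfits the
embedding table before the recurrent weights converge). Training is
mini-batch Adam on the binary log-loss; batches pad and mask sequences,
so the whole batch's sentences go through one vectorized pass.
Backpropagation through both levels is hand-derived and checked against
finite differences in the test suite. Default widths 64/64, 20 epochs,
batch 32; the benchmark and acceptance runs use 32/32 and 8 epochs,
which reach the same discrimination on the synthetic cohort in a
fraction of the time. All randomness (init, shuffling) comes from one
seed, and sentences are truncated at 60 tokens / documents at 30
sentences to bound padding cost.

Hyperparameter tuning uses stratified 10-fold grid-search CV maximizing
mean validation AUC; exact ties go to the simpler specification (larger
λ, smaller depth, smaller k).

## Evaluation protocol

- **Splits**: five seeded random 75/25 partitions ("bootstrapped"
  splits in the sense of repeated random resampling of the partition,
  not sampling with replacement). By default splits are grouped by
  patient — patients contribute several reports, and report-level
  splitting leaks near-duplicate text across the boundary; a flag
  restores report-level splitting. Grouped stratification is
  best-effort: among 50 seeded random greedy allocations the one closest
  to the target test size and prevalence is kept, with a logged warning
  if one patient exceeds the test fraction.
- **AUC**: Mann–Whitney form from midranks; ties credit 1/2. ROC points
  sweep all distinct scores. Equivalence to brute-force pair counting is
  a test invariant.
- **CI**: mean ± 1.96·SD/√k over the k=5 split AUCs, clipped to [0,1].
  Percentile intervals were rejected: at five values they are determined
  by the extremes.
- **Threshold**: the decision rule is `positive iff p ≥ t` everywhere.
  Among distinct scores with sensitivity ≥ 0.90, the threshold with the
  highest specificity wins (ties → largest t); if none qualifies, the
  maximal-sensitivity threshold is used and logged. Thresholds are
  chosen on each split's test predictions — the protocol reports the
  operating point achievable on the evaluated set, so the threshold
  metrics are in-sample with respect to the threshold (not the model).
- **Calibration**: bins `[0,10%], (10,20%], …, (90,100%]` (first bin
  closed at both ends so p=0 is counted); per bin count, events and
  event rate, with empty bins reported as missing rather than 0.
- **McNemar**: b and c are the discordant correct/incorrect counts,
  χ² = (b−c)²/(b+c) against χ²(1), two-sided; continuity correction
  `(|b−c|−1)²/(b+c)` by flag; b+c=0 degenerates to χ²=0, p=1.

## Synthetic data generator

The generator is the stand-in for a hand-labeled hospital cohort, and
its defaults mirror a realistic derivation cohort: 1,359 reports,
stroke prevalence 0.68, MCA fraction 0.38 and acute fraction 0.56 among
strokes, a ~65:35 CT/CTA:MRI/MRA mix, and a mean of ~4.5 reports per
patient (geometric). Reports are assembled from templated sections
(exam header, clinical history, findings, impression) with a separator
line so the cleaning stage is always exercised.

The templates deliberately encode the documented hard cases:

- **Negation**: stroke-negative reports carry explicit negated stroke
  sentences ("no evidence of acute infarct") at `negation_rate`
  (default 0.5). These appear *only* in negatives pre-noise, which is a
  generator contract the tests enforce.
- **Chronic infarcts**: encephalomalacia/volume-loss templates yield
  stroke=1, acute=0 — presence without acuity.
- **Indeterminate age**: ~35% of stroke reports use timing-neutral
  wording ("subacute infarct", "infarct of indeterminate age") drawn
  from one shared pool regardless of the true acuity label. This is the
  structural reason acuity is the hardest task: a fraction of reports
  is lexically uninformative about timing, as in real radiology.
- **Distractors** (`distractor_rate`, default 0.3): prior-imaging
  references and chronic microvascular-change sentences that put
  infarct and territory vocabulary into reports of either label, and
  stroke-code indications that precede ~30% of scans regardless of
  outcome. Raising the rate measurably lowers attainable AUC (a tested
  property).
- **Label noise** (default 0.02): independent flips applied after
  template-derived labels, so noisy labels may violate the
  mca⇒stroke hierarchy — as adjudicated human labels can.
- **Template jitter** (default 0.3): synonym swaps within template
  slots (infarct/infarction/ischemic stroke, etc.).

The unchosen rates (negation, distractor, noise, jitter) have no
counterpart in any published count; they were fixed once at values that
make the synthetic task behave like the real one qualitatively
(presence easiest, acuity hardest, high-but-imperfect AUCs) and are
exposed as configuration.

The embedding-corpus generator plants synonym pairs: each pair owns a
disjoint slice of context vocabulary and its sentence frames are filled
by either member with equal probability, so pair members see identical
context distributions. Background sentences draw from a Zipf-like
distribution. Recovery (within-pair cosine exceeding across-pair cosine
by a wide margin) validates the embedding trainer end to end.

**What the generator does not emulate**: real reports' institutional
variety, typographical errors, hedging language, longitudinal
correlation of a patient's findings across reports, and findings beyond
the phrase level. Passing tests on this corpus show the pipeline's
machinery is correct and its protocol behaves as specified; they do not
certify the discrimination figures on any real hospital population.

## Problem sizes used in checks

The bundled verification runs use the default 1,359-report cohort, a
separate 3,000-report unlabeled corpus for embedding training
(vocabulary min_df 5), 150-document planted-synonym corpora across 20
seeds, and a 32/32-unit, 8-epoch LSTM — sizes chosen so a full
from-scratch run completes in a few minutes on one CPU while leaving
every measured effect far from its decision boundary.

## Known limitations

- The tree learners are greedy (CART/RF); globally optimized decision
  trees are out of scope.
- The evaluation offers no DeLong variance for a single-split AUC; the
  CI quantifies between-split variability only.
- Dates are parsed and carried for provenance but never modeled.
- The hierarchical LSTM is CPU-bound numpy; it is sized for corpora of
  thousands of reports, not millions.
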
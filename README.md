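# radstroke

NLP phenotyping of neuroradiology reports: given the free text of a head
CT/CTA/MRI/MRA report, classify three binary outcomes — **ischemic stroke
presence**, **middle cerebral artery (MCA) territory involvement**, and
**acuity** (recent vs chronic infarct). The package is aimed at clinical
NLP researchers and stroke registries who need report-level labels at
scale, where billing codes are unreliable and manual review does not
scale.

## What it does

The pipeline has four stages, each usable on its own:

1. **Preprocessing** — boilerplate and separator removal ("`= = = = =`"),
   lowercasing, punctuation-to-space normalization, sentence splitting,
   and merging of multi-word medical phrases into single n-gram tokens
   ("middle cerebral artery" → `middlecerebralartery`).
2. **Featurization** — bag-of-words counts `tf(d,t)`; tf-idf weights
   `tf(d,t) · idf(t)` with the smoothed form
   `idf(t) = ln((1+N)/(1+df(t))) + 1`; or document embeddings as the sum
   of word vectors, `v(d) = Σ_{t∈d} w_t`.
3. **Embedding training** — a GloVe trainer: inverse-distance-weighted
   co-occurrence counts `X_ij` within a 10-token window, then AdaGrad
   minimization of

       J = Σ_{ij: X_ij>0} f(X_ij) (w_i·w̃_j + b_i + b̃_j − ln X_ij)²,
       f(x) = min((x/x_max)^0.75, 1)

   with defaults d=100, 50 epochs, learning rate 0.05. Exported vectors
   are `w_i + w̃_i`.
4. **Classification & evaluation** — lasso logistic regression, k-NN,
   CART, random forest (200 trees), and a hierarchical LSTM (word-level
   LSTM → sentence vectors → sentence-level LSTM → document vector →
   logistic head) implemented in numpy with full backpropagation.
   Validation follows a fixed protocol: five seeded 75/25
   patient-grouped splits, Mann–Whitney AUC with a normal-approximation
   95% CI over the splits, an operating threshold chosen as the one with
   sensitivity ≥ 0.90 and maximal specificity, ten-bin calibration
   tables, and McNemar comparison of paired classifiers,
   χ² = (b−c)²/(b+c).

Real stroke reports are protected health information, so the package
ships a synthetic report generator that emulates the hard cases of the
task (negated stroke language, chronic infarcts, non-MCA strokes,
prior-imaging references, infarcts of indeterminate age) with known
labels, plus a planted-synonym corpus generator for validating the
embedding trainer.

## Worked example

```python
import radstroke as rs
from radstroke import evaluation as ev

reports, labels = rs.generate_reports(rs.GeneratorConfig(n_reports=600, seed=3))
docs = rs.preprocess_corpus(reports)
results = rs.run_benchmark(
    reports, labels, docs, featurizers=["bow"],
    classifier_specs=[rs.LogRegSpec()],
    cfg=rs.BenchmarkConfig(split=ev.SplitConfig(seed=3)),
)
for task, cells in results.items():
    rep = cells["bow"]["logreg_l1"]
    print(task, round(rep.mean_auc, 3), (round(rep.ci_low, 3), round(rep.ci_high, 3)))
```

prints (see `examples/04_benchmark.py` for the full script):

```
stroke: AUC 0.965 (0.947:0.983)  sens 0.90  spec 0.96  acc 0.92  prec 0.98  thr 0.92
   mca: AUC 0.981 (0.971:0.991)  sens 0.92  spec 0.99  acc 0.97  prec 0.96  thr 0.80
 acute: AUC 0.954 (0.944:0.964)  sens 0.91  spec 0.86  acc 0.88  prec 0.80  thr 0.37
```

Each line is one classification task: the mean test AUC over the five
splits with its 95% CI, then sensitivity/specificity/accuracy/precision
at the sensitivity-first threshold. Acuity is the hardest task — the
generator (like real radiology) produces infarcts whose age cannot be
determined from wording alone.

The `examples/` directory has one short script per capability:
simulation, featurization, embedding training, the benchmark, and the
LSTM-vs-logreg McNemar comparison. A thin CLI mirrors the same stages:

```
radstroke simulate --n 1359 --seed 7 --out-dir data/
radstroke train-embeddings --corpus corpus.txt --out emb.csv
radstroke benchmark --config config.json --out-dir out/
```

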
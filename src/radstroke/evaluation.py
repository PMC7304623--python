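"""Validation protocol: bootstrapped splits, ROC/AUC, sensitivity-first
thresholds, confusion metrics, calibration tables and McNemar comparison.

The study design evaluated here: five seeded random 75/25 train/test
partitions; per-split AUC with a normal-approximation confidence interval
over the five values; an operating threshold chosen as the one achieving
sensitivity >= 0.90 with the highest specificity; ten-bin calibration
tables with intervals [0,10%], (10,20%], ..., (90,100%]; and a two-sided
McNemar test on discordant correct/incorrect pairs for model comparison.

The decision rule everywhere is "positive iff p >= t". AUC is the
Mann-Whitney form (ties credited 1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .featurize import FeatureMatrix, bow_matrix, doc_embedding_matrix, fit_vocabulary, tfidf_transform
from .io import EmbeddingFile, LabelSet, Report, labels_frame
from .preprocess import TokenDoc

logger = logging.getLogger(__name__)

TASKS = ("stroke", "mca", "acute")


@dataclass
class SplitConfig:
    n_splits: int = 5
    test_frac: float = 0.25
    seed: int = 0
    group_by_patient: bool = True
    stratify_on: str = "stroke"


@dataclass
class SplitPlan:
    """Per split: disjoint train/test report-id sets at 75%/25%."""

    train_ids: list[list[str]]
    test_ids: list[list[str]]
    cfg: SplitConfig

    @property
    def n_splits(self) -> int:
        return len(self.train_ids)


@dataclass
class EvalReport:
    """Aggregate discrimination, threshold and calibration for one model."""

    per_split_auc: list[float]
    mean_auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float | None
    calibration: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        cal = d.pop("calibration")
        if cal is not None:
            d["calibration"] = self.calibration.where(
                pd.notna(self.calibration), None
            ).to_dict(orient="records")
        return d


@dataclass
class McNemarResult:
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    chi2: float
    p: float


def make_splits(
    reports: list[Report], labels: list[LabelSet], cfg: SplitConfig | None = None
) -> SplitPlan:
    """Five (by default) seeded random 75/25 partitions, stratified on one task.

    With ``group_by_patient`` no patient contributes reports to both sides
    of a split; stratification is then best-effort (chosen among seeded
    random allocations), and a warning is logged if a single patient group
    exceeds the test fraction.
    """
    if cfg is None:
        cfg = SplitConfig()
    n = len(reports)
    if n < 8:
        raise ValueError("need at least 8 reports to split")
    lab = labels_frame(labels)
    ids = [r.report_id for r in reports]
    y = lab.loc[ids, cfg.stratify_on].to_numpy()
    n_train = round((1 - cfg.test_frac) * n)
    n_test = n - n_train

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_splits)
    train_sets, test_sets = [], []
    if not cfg.group_by_patient:
        idx_pos = np.array([i for i, v in enumerate(y) if v == 1])
        idx_neg = np.array([i for i, v in enumerate(y) if v == 0])
        n_test_pos = int(round(len(idx_pos) * n_test / n))
        n_test_neg = n_test - n_test_pos
        for ss in children:
            rng = np.random.default_rng(ss)
            test = set(rng.choice(idx_pos, size=n_test_pos, replace=False)) | set(
                rng.choice(idx_neg, size=n_test_neg, replace=False)
            )
            test_sets.append([ids[i] for i in sorted(test)])
            train_sets.append([ids[i] for i in range(n) if i not in test])
    else:
        by_patient: dict[str, list[int]] = {}
        for i, r in enumerate(reports):
            by_patient.setdefault(r.patient_id, []).append(i)
        groups = sorted(by_patient)
        if max(len(v) for v in by_patient.values()) > cfg.test_frac * n:
            logger.warning(
                "a single patient holds more than the test fraction; "
                "stratification relaxed"
            )
        target_pos = len(y[y == 1]) * n_test / n
        for ss in children:
            rng = np.random.default_rng(ss)
            best = None
            for _ in range(50):  # seeded random greedy allocations; keep the best
                order = rng.permutation(len(groups))
                test_idx: list[int] = []
                for gi in order:
                    if len(test_idx) >= n_test:
                        break
                    test_idx.extend(by_patient[groups[gi]])
                score = abs(len(test_idx) - n_test) + abs(
                    float(np.sum(y[test_idx])) - target_pos
                )
                if best is None or score < best[0]:
                    best = (score, set(test_idx))
            test = best[1]
            test_sets.append([ids[i] for i in sorted(test)])
            train_sets.append([ids[i] for i in range(n) if i not in test])
    return SplitPlan(train_ids=train_sets, test_ids=test_sets, cfg=cfg)


def roc_and_auc(y, p) -> tuple[pd.DataFrame, float]:
    """ROC points over all distinct score thresholds and Mann-Whitney AUC.

    AUC is the probability a random positive outscores a random negative,
    with ties credited 1/2 (computed from midranks).
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC")
    ranks = stats.rankdata(p)
    auc = (float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.unique(p)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = p >= t
        tpr.append(float(np.sum(pred & (y == 1))) / n_pos)
        fpr.append(float(np.sum(pred & (y == 0))) / n_neg)
    roc = pd.DataFrame(
        {
            "threshold": np.concatenate(([np.inf], thresholds)),
            "fpr": fpr,
            "tpr": tpr,
        }
    )
    return roc, float(auc)


def auc_ci(per_split_aucs) -> tuple[float, float, float]:
    """Mean and normal-approximation 95% CI over the per-split AUCs."""
    a = np.asarray(per_split_aucs, dtype=float)
    if len(a) < 2:
        raise ValueError("confidence interval needs at least two split AUCs")
    mean = float(np.mean(a))
    half = 1.96 * float(np.std(a, ddof=1)) / np.sqrt(len(a))
    return mean, max(0.0, mean - half), min(1.0, mean + half)


def select_threshold(y, p, min_sens: float = 0.90) -> float:
    """Sensitivity-first operating point.

    Among candidate thresholds (the distinct scores, rule ``p >= t``) with
    sensitivity >= min_sens, return the one maximizing specificity,
    breaking ties toward the largest threshold. If no candidate reaches
    min_sens, fall back (with a log message) to the threshold of maximal
    sensitivity.
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to select a threshold")
    n_pos = np.sum(y == 1)
    n_neg = np.sum(y == 0)
    candidates = np.unique(p)
    best = None  # (spec, t)
    fallback = None  # (sens, spec, t)
    for t in candidates:
        pred = p >= t
        sens = np.sum(pred & (y == 1)) / n_pos
        spec = np.sum(~pred & (y == 0)) / n_neg
        if sens >= min_sens and (best is None or (spec, t) > best):
            best = (spec, t)
        if fallback is None or (sens, spec, t) > fallback:
            fallback = (sens, spec, t)
    if best is not None:
        return float(best[1])
    logger.info(
        "no threshold reaches sensitivity %.2f; falling back to max-sensitivity point",
        min_sens,
    )
    return float(fallback[2])


def confusion_metrics(y, p, t: float) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy and precision at threshold t.

    Precision is None (missing, not zero) when nothing is predicted
    positive.
    """
    y = np.asarray(y, dtype=int)
    pred = np.asarray(p, dtype=float) >= t
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "accuracy": (tp + tn) / len(y),
        "precision": tp / (tp + fp) if tp + fp else None,
    }


def calibration_table(y, p) -> pd.DataFrame:
    """Ten-bin reliability table over [0,10%], (10,20%], ..., (90,100%].

    Per bin: sample count, event count and event rate (NaN for empty
    bins). The first interval is closed on both ends, so p=0 lands in it.
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    # (k-1)/10 < p <= k/10 for bin k>=1; p <= 0.1 -> bin 1
    idx = np.clip(np.ceil(np.round(p * 10, 9)).astype(int) - 1, 0, 9)
    rows = []
    for b in range(10):
        sel = idx == b
        n = int(np.sum(sel))
        events = int(np.sum(y[sel]))
        rows.append(
            {
                "bin_low": b / 10,
                "bin_high": (b + 1) / 10,
                "midpoint": (b + 0.5) / 10,
                "n": n,
                "events": events,
                "event_rate": events / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mcnemar_test(y, pred_a, pred_b, continuity: bool = False) -> McNemarResult:
    """Two-sided McNemar test on the discordant pairs of two classifiers.

    b counts cases A classifies correctly and B misses; c the converse.
    chi2 = (b-c)^2/(b+c) (with the optional continuity correction
    (|b-c|-1)^2/(b+c)); p is the upper chi-square(1) tail. b+c=0 gives
    chi2=0, p=1.
    """
    y = np.asarray(y, dtype=int)
    a = np.asarray(pred_a, dtype=int)
    bb = np.asarray(pred_b, dtype=int)
    if not (len(y) == len(a) == len(bb)):
        raise ValueError("y, pred_a, pred_b must have equal length")
    a_ok = a == y
    b_ok = bb == y
    b_count = int(np.sum(a_ok & ~b_ok))
    c_count = int(np.sum(~a_ok & b_ok))
    total = b_count + c_count
    if total == 0:
        return McNemarResult(b=b_count, c=c_count, chi2=0.0, p=1.0)
    num = (abs(b_count - c_count) - 1) ** 2 if continuity else (b_count - c_count) ** 2
    chi2 = num / total
    return McNemarResult(
        b=b_count, c=c_count, chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1))
    )


# ---------------------------------------------------------------------------
# Benchmark orchestration


@dataclass
class BenchmarkConfig:
    tasks: tuple[str, ...] = TASKS
    split: SplitConfig = field(default_factory=SplitConfig)
    min_df: int = 2
    min_sens: float = 0.90
    grids: dict | None = None  # classifier kind -> list of specs to tune over
    cv_folds: int = 10
    external_docs: list | None = None  # fixed external validation corpus (TokenDocs)
    external_labels: list | None = None


def _featurize(kind, train_docs, test_docs, emb, min_df):
    if kind == "bow":
        vocab = fit_vocabulary(train_docs, min_df=min_df)
        return bow_matrix(train_docs, vocab), bow_matrix(test_docs, vocab)
    if kind == "tfidf":
        vocab = fit_vocabulary(train_docs, min_df=min_df)
        return tfidf_transform(train_docs, vocab), tfidf_transform(test_docs, vocab)
    if kind == "glove":
        if emb is None:
            raise ValueError("glove featurizer requires an embedding file")
        return doc_embedding_matrix(train_docs, emb), doc_embedding_matrix(test_docs, emb)
    raise ValueError(f"unknown featurizer {kind!r}")


def evaluate_split_predictions(y_test, p_test, min_sens: float = 0.90):
    """Threshold + confusion metrics for one split's test predictions."""
    t = select_threshold(y_test, p_test, min_sens=min_sens)
    return t, confusion_metrics(y_test, p_test, t)


def run_benchmark(
    reports: list[Report],
    labels: list[LabelSet],
    docs: list[TokenDoc],
    featurizers: list[str],
    classifier_specs: list,
    cfg: BenchmarkConfig | None = None,
    emb: EmbeddingFile | None = None,
) -> dict:
    """Full task x featurizer x classifier grid over the split plan.

    Per cell and split: fit on the training side (optionally grid-search
    CV-tuned), score the held-out side, select the sensitivity-first
    threshold on the test predictions and record confusion metrics; then
    aggregate AUCs (mean + CI) and average the threshold metrics across
    splits. Calibration is tabulated on the pooled test predictions. In
    external mode the entire external corpus is scored by the model from
    each training split.

    Returns {task: {featurizer: {classifier_kind: EvalReport}}}.
    """
    if cfg is None:
        cfg = BenchmarkConfig()
    lab = labels_frame(labels)
    doc_by_id = {d.report_id: d for d in docs}
    plan = make_splits(reports, labels, cfg.split)

    external = cfg.external_docs is not None
    if external:
        ext_lab = labels_frame(cfg.external_labels)
        ext_docs = cfg.external_docs

    results: dict = {}
    for task in cfg.tasks:
        if task not in lab.columns or lab[task].isna().any():
            logger.warning("task %r skipped: labels missing", task)
            continue
        results[task] = {}
        for feat in featurizers:
            results[task][feat] = {}
            for spec in classifier_specs:
                per_auc, per_thr, per_metrics = [], [], []
                pooled_y, pooled_p = [], []
                for s in range(plan.n_splits):
                    tr_ids, te_ids = plan.train_ids[s], plan.test_ids[s]
                    tr_docs = [doc_by_id[i] for i in tr_ids]
                    y_tr = lab.loc[tr_ids, task].to_numpy()
                    if external:
                        te_docs = ext_docs
                        y_te = ext_lab.loc[[d.report_id for d in ext_docs], task].to_numpy()
                    else:
                        te_docs = [doc_by_id[i] for i in te_ids]
                        y_te = lab.loc[te_ids, task].to_numpy()

                    if spec.kind == "rnn":
                        from .classifiers import train_rnn_document_model

                        model = train_rnn_document_model(tr_docs, emb, y_tr, spec)
                        p_te = model.predict_proba(te_docs)
                    else:
                        from .classifiers import grid_search_cv, predict_proba, train

                        X_tr, X_te = _featurize(feat, tr_docs, te_docs, emb, cfg.min_df)
                        used = spec
                        if cfg.grids and spec.kind in cfg.grids:
                            used, _ = grid_search_cv(
                                X_tr, y_tr, cfg.grids[spec.kind], folds=cfg.cv_folds,
                                seed=cfg.split.seed,
                            )
                        model = train(X_tr, y_tr, used)
                        p_te = predict_proba(model, X_te)

                    _, auc = roc_and_auc(y_te, p_te)
                    thr, metrics = evaluate_split_predictions(y_te, p_te, cfg.min_sens)
                    per_auc.append(auc)
                    per_thr.append(thr)
                    per_metrics.append(metrics)
                    pooled_y.append(y_te)
                    pooled_p.append(p_te)

                mean_auc, lo, hi = auc_ci(per_auc)
                avg = {
                    k: (
                        float(np.mean([m[k] for m in per_metrics if m[k] is not None]))
                        if any(m[k] is not None for m in per_metrics)
                        else None
                    )
                    for k in ("sensitivity", "specificity", "accuracy", "precision")
                }
                results[task][feat][spec.kind] = EvalReport(
                    per_split_auc=[float(a) for a in per_auc],
                    mean_auc=mean_auc,
                    ci_low=lo,
                    ci_high=hi,
                    threshold=float(np.mean(per_thr)),
                    sensitivity=avg["sensitivity"],
                    specificity=avg["specificity"],
                    accuracy=avg["accuracy"],
                    precision=avg["precision"],
                    calibration=calibration_table(
                        np.concatenate(pooled_y), np.concatenate(pooled_p)
                    ),
                )
    return results
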
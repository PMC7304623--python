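import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import radstroke as rs
from radstroke import evaluation as ev


def _brute_force_auc(y, p):
    """Pair-counting oracle: P(pos outscores neg), ties credit 1/2."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _brute_force_threshold(y, p, min_sens):
    """Exhaustive enumeration over all distinct-score thresholds."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    best = None
    fallback = None
    for t in np.unique(p):
        pred = p >= t
        sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
        spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
        if sens >= min_sens and (best is None or (spec, t) > best):
            best = (spec, t)
        if fallback is None or (sens, spec, t) > fallback:
            fallback = (sens, spec, t)
    return best[1] if best is not None else fallback[2]


class TestSplits:
    def _mk(self, n, n_pos, n_patients=None):
        reports = [
            rs.Report(f"r{i}", f"p{i if n_patients is None else i % n_patients}",
                      "CT", None, "text")
            for i in range(n)
        ]
        labels = [
            rs.LabelSet(f"r{i}", int(i < n_pos), 0, 0) for i in range(n)
        ]
        return reports, labels

    def test_sizes_are_75_25(self):
        reports, labels = self._mk(100, 40)
        plan = rs.make_splits(reports, labels, ev.SplitConfig(group_by_patient=False))
        for s in range(plan.n_splits):
            assert len(plan.train_ids[s]) == 75
            assert len(plan.test_ids[s]) == 25
            assert not set(plan.train_ids[s]) & set(plan.test_ids[s])

    def test_same_seed_same_plan(self):
        reports, labels = self._mk(60, 20)
        cfg = ev.SplitConfig(seed=5)
        p1 = rs.make_splits(reports, labels, cfg)
        p2 = rs.make_splits(reports, labels, cfg)
        assert p1.train_ids == p2.train_ids and p1.test_ids == p2.test_ids

    def test_stratified_prevalence_n40(self):
        reports, labels = self._mk(40, 10)
        plan = rs.make_splits(reports, labels, ev.SplitConfig(group_by_patient=False))
        positives = {l.report_id for l in labels if l.stroke == 1}
        for s in range(plan.n_splits):
            n_pos_test = len(positives & set(plan.test_ids[s]))
            assert 2 <= n_pos_test <= 3

    def test_grouped_split_keeps_patients_on_one_side(self):
        reports, labels = self._mk(80, 30, n_patients=20)
        plan = rs.make_splits(reports, labels, ev.SplitConfig(group_by_patient=True))
        pat = {r.report_id: r.patient_id for r in reports}
        for s in range(plan.n_splits):
            tr = {pat[i] for i in plan.train_ids[s]}
            te = {pat[i] for i in plan.test_ids[s]}
            assert not tr & te

    def test_too_few_reports_rejected(self):
        reports, labels = self._mk(5, 2)
        with pytest.raises(ValueError):
            rs.make_splits(reports, labels)


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = rs.roc_and_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = rs.roc_and_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_hand_counted_pairs(self):
        _, auc = rs.roc_and_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rs.roc_and_auc([1, 1], [0.2, 0.3])

    def test_roc_monotone_and_spans_unit_square(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=50)
        p = rng.random(50)
        roc, _ = rs.roc_and_auc(y, p)
        assert (np.diff(roc["fpr"]) >= 0).all()
        assert (np.diff(roc["tpr"]) >= 0).all()
        assert roc["fpr"].iloc[0] == 0 and roc["tpr"].iloc[0] == 0
        assert roc["fpr"].iloc[-1] == 1 and roc["tpr"].iloc[-1] == 1

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.integers(0, 10)), min_size=2, max_size=60)
    )
    def test_matches_pair_counting_oracle(self, pairs):
        y = np.array([a for a, _ in pairs])
        p = np.array([b / 10 for _, b in pairs])
        if len(np.unique(y)) < 2:
            return
        _, auc = rs.roc_and_auc(y, p)
        assert auc == pytest.approx(_brute_force_auc(y, p), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=200)
        p = np.round(rng.random(200), 2)  # force ties
        _, auc = rs.roc_and_auc(y, p)
        assert auc == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestAucCI:
    def test_constant_values_zero_width(self):
        mean, lo, hi = rs.auc_ci([0.9] * 5)
        assert mean == lo == hi == 0.9

    def test_hand_computed_interval(self):
        mean, lo, hi = rs.auc_ci([0.9, 0.92, 0.94, 0.96, 0.98])
        assert mean == pytest.approx(0.94)
        assert lo == pytest.approx(0.94 - 1.96 * 0.014142, abs=1e-4)
        assert hi == pytest.approx(0.94 + 1.96 * 0.014142, abs=1e-4)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            rs.auc_ci([0.9])


class TestThreshold:
    def test_separable_scores(self):
        y = [1, 1, 1, 0, 0, 0]
        p = [0.9, 0.85, 0.8, 0.3, 0.2, 0.1]
        t = rs.select_threshold(y, p, min_sens=0.90)
        assert t == 0.8
        m = rs.confusion_metrics(y, p, t)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_min_sens_zero_maximizes_specificity(self):
        y = [1, 1, 0, 0]
        p = [0.9, 0.6, 0.5, 0.1]
        t = rs.select_threshold(y, p, min_sens=0.0)
        m = rs.confusion_metrics(y, p, t)
        assert m["specificity"] == 1.0

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.integers(0, 8)), min_size=4, max_size=40),
        st.sampled_from([0.0, 0.5, 0.9, 1.0]),
    )
    def test_matches_exhaustive_enumeration(self, pairs, min_sens):
        y = np.array([a for a, _ in pairs])
        p = np.array([b / 8 for _, b in pairs])
        if len(np.unique(y)) < 2:
            return
        assert rs.select_threshold(y, p, min_sens) == pytest.approx(
            _brute_force_threshold(y, p, min_sens)
        )


class TestConfusionMetrics:
    def test_threshold_zero_catches_everything(self):
        m = rs.confusion_metrics([1, 0], [0.4, 0.6], 0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_hand_arithmetic(self):
        y = [1] * 10 + [0] * 10
        p = [0.9] * 9 + [0.1] + [0.9] * 2 + [0.1] * 8
        m = rs.confusion_metrics(y, p, 0.5)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(9 / 11)

    def test_threshold_above_max_score(self):
        m = rs.confusion_metrics([1, 0], [0.4, 0.6], 0.99)
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0
        assert m["precision"] is None


class TestCalibration:
    def test_last_bin_event_rate_80_percent(self):
        y = [1, 1, 1, 1, 0]
        p = [0.95, 0.92, 0.99, 0.91, 0.97]
        table = rs.calibration_table(y, p)
        last = table.iloc[-1]
        assert last["n"] == 5 and last["events"] == 4
        assert last["event_rate"] == pytest.approx(0.80)

    def test_zero_lands_in_first_closed_bin(self):
        table = rs.calibration_table([0], [0.0])
        assert table.iloc[0]["n"] == 1

    def test_bin_edges_follow_left_open_intervals(self):
        # 0.1 belongs to [0,10%]; 0.1000...1 would belong to (10,20%]
        table = rs.calibration_table([0, 0], [0.1, 0.11])
        assert table.iloc[0]["n"] == 1 and table.iloc[1]["n"] == 1

    def test_bernoulli_simulation_is_calibrated(self):
        rng = np.random.default_rng(12)
        p = rng.random(10000)
        y = (rng.random(10000) < p).astype(int)
        table = rs.calibration_table(y, p)
        occupied = table.dropna(subset=["event_rate"])
        assert (abs(occupied["event_rate"] - occupied["midpoint"]) <= 0.05).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    def test_bins_partition_the_sample(self, probs):
        y = [0] * len(probs)
        table = rs.calibration_table(y, probs)
        assert table["n"].sum() == len(probs)


class TestMcNemar:
    def test_balanced_discordance_is_null(self):
        y = np.zeros(20, dtype=int)
        a = np.array([0] * 6 + [1] * 7 + [0] * 7)
        b = np.array([0] * 6 + [0] * 7 + [1] * 7)
        res = rs.mcnemar_test(y, a, b)
        assert res.b == res.c == 7
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_closed_form_15_5(self):
        y = np.zeros(30, dtype=int)
        a = np.array([0] * 10 + [0] * 15 + [1] * 5)
        b = np.array([0] * 10 + [1] * 15 + [0] * 5)
        res = rs.mcnemar_test(y, a, b)
        assert res.b == 15 and res.c == 5
        assert res.chi2 == pytest.approx(5.0)
        assert res.p == pytest.approx(0.0253, abs=1e-3)

    def test_symmetric_in_model_order(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 50)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        r1 = rs.mcnemar_test(y, a, b)
        r2 = rs.mcnemar_test(y, b, a)
        assert r1.chi2 == r2.chi2 and r1.p == r2.p

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        ours = rs.mcnemar_test(y, a, b)
        table = np.array(
            [
                [np.sum((a == y) & (b == y)), np.sum((a == y) & (b != y))],
                [np.sum((a != y) & (b == y)), np.sum((a != y) & (b != y))],
            ]
        )
        ref = sm_mcnemar(table, exact=False, correction=False)
        assert ours.chi2 == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_no_discordance_degenerate(self):
        y = np.array([0, 1])
        res = rs.mcnemar_test(y, y, y)
        assert res.chi2 == 0.0 and res.p == 1.0


class TestBenchmark:
    def test_single_cell_produces_eval_report(self, default_corpus):
        reports, labels, docs = default_corpus
        res = rs.run_benchmark(
            reports[:400], labels[:400], docs[:400], ["bow"], [rs.LogRegSpec()],
            rs.BenchmarkConfig(
                tasks=("stroke",),
                split=ev.SplitConfig(seed=1, group_by_patient=False),
            ),
        )
        rep = res["stroke"]["bow"]["logreg_l1"]
        assert len(rep.per_split_auc) == 5
        assert rep.ci_low <= rep.mean_auc <= rep.ci_high
        assert 0 <= rep.sensitivity <= 1
        assert rep.calibration["n"].sum() == 5 * 100  # pooled test predictions

    def test_signal_dial_auc_increases_with_signal(self):
        """Distractor-free corpora are easier than distractor-heavy ones."""
        means = []
        for rate in (0.0, 0.5):
            aucs = []
            for seed in range(5):
                cfg = rs.GeneratorConfig(
                    n_reports=400, distractor_rate=rate, seed=100 + seed
                )
                reports, labels = rs.generate_reports(cfg)
                docs = rs.preprocess_corpus(reports)
                res = rs.run_benchmark(
                    reports, labels, docs, ["bow"], [rs.LogRegSpec()],
                    rs.BenchmarkConfig(
                        tasks=("stroke",),
                        split=ev.SplitConfig(seed=seed, n_splits=2),
                    ),
                )
                aucs.append(res["stroke"]["bow"]["logreg_l1"].mean_auc)
            means.append(np.mean(aucs))
        assert means[0] > means[1]

    def test_external_mode_scores_fixed_corpus_each_split(self, default_corpus):
        reports, labels, docs = default_corpus
        ext_reports, ext_labels = rs.generate_reports(
            rs.GeneratorConfig(n_reports=120, seed=777)
        )
        ext_docs = rs.preprocess_corpus(ext_reports)
        cfg = rs.BenchmarkConfig(
            tasks=("stroke",),
            split=ev.SplitConfig(seed=2),
            external_docs=ext_docs,
            external_labels=ext_labels,
        )
        res = rs.run_benchmark(
            reports[:400], labels[:400], docs[:400], ["bow"], [rs.LogRegSpec()], cfg
        )
        rep = res["stroke"]["bow"]["logreg_l1"]
        # every split scores the full external corpus
        assert rep.calibration["n"].sum() == 5 * len(ext_docs)
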
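import numpy as np
import pandas as pd
import pytest

from prognet import (
    ExpressionMatrix,
    GroupLabels,
    PrognetError,
    SurvivalTable,
    classify_cohort,
    km_estimate,
    logrank_test,
    simulate_survival,
    size_sweep,
)
from prognet.types import CohortConfig


def _expr(rows, label="c"):
    n = len(next(iter(rows.values())))
    return ExpressionMatrix(
        pd.DataFrame(rows, index=[f"{label}{i}" for i in range(n)]).T.astype(float), label)


def _separable(rng, n=60, shift=2.0, label="c"):
    group = np.where(np.arange(n) % 2 == 0, "good", "poor")
    sign = np.where(group == "good", 1.0, -1.0)
    rows = {f"m{j}": 7 + sign * shift / 2 + rng.normal(scale=0.3, size=n)
            for j in range(5)}
    expr = _expr(rows, label)
    labels = GroupLabels(dict(zip(expr.sample_ids, group.tolist())))
    return expr, labels


class TestClassifier:
    def test_resubstitution_accuracy_on_separable_groups(self, rng):
        expr, labels = _separable(rng)
        pred = classify_cohort(expr, labels, expr, [f"m{j}" for j in range(5)])
        agree = np.mean([pred.assignments[s] == labels.assignments[s]
                         for s in expr.sample_ids])
        assert agree >= 0.95

    def test_held_out_cohort_accuracy_with_planted_shift(self):
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            train, train_labels = _separable(r, n=80, shift=1.0, label="tr")
            test, test_labels = _separable(r, n=80, shift=1.0, label="te")
            pred = classify_cohort(train, train_labels, test, [f"m{j}" for j in range(5)])
            accs.append(np.mean([pred.assignments[s] == test_labels.assignments[s]
                                 for s in test.sample_ids]))
        assert np.median(accs) >= 0.9

    def test_single_class_training_rejected(self, rng):
        expr, _ = _separable(rng)
        labels = GroupLabels({s: "good" for s in expr.sample_ids})
        with pytest.raises(PrognetError):
            classify_cohort(expr, labels, expr, ["m0"])

    def test_empty_marker_overlap_rejected(self, rng):
        expr, labels = _separable(rng)
        with pytest.raises(PrognetError):
            classify_cohort(expr, labels, expr, ["nope"])


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        surv = SurvivalTable([("s1", 5.0, 0), ("s2", 9.0, 0)])
        groups = GroupLabels({"s1": "good", "s2": "good"})
        curve = km_estimate(surv, groups)["good"]
        assert (curve["survival"] == 1.0).all()

    def test_product_limit_hand_computation(self):
        surv = SurvivalTable([("a", 1.0, 1), ("b", 2.0, 1), ("c", 3.0, 1)])
        groups = GroupLabels({k: "good" for k in "abc"})
        curve = km_estimate(surv, groups)["good"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(1 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    def test_censoring_reduces_risk_set_without_drop(self):
        surv = SurvivalTable([("a", 1.0, 1), ("b", 1.5, 0), ("c", 3.0, 1)])
        groups = GroupLabels({k: "good" for k in "abc"})
        curve = km_estimate(surv, groups)["good"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[1.5] == pytest.approx(2 / 3)  # no drop at censoring
        assert curve.loc[3.0] == pytest.approx(0.0)  # risk set of 1 at t=3

    def test_unknown_labeled_sample_rejected(self):
        surv = SurvivalTable([("a", 1.0, 1)])
        with pytest.raises(PrognetError):
            km_estimate(surv, GroupLabels({"zz": "good"}))


class TestLogRank:
    def test_hand_computed_small_example(self):
        """A: events at 1, 2; B: events at 3, 4 -> chi2 ~ 2.882, p ~ 0.0896."""
        surv = SurvivalTable([("a1", 1.0, 1), ("a2", 2.0, 1),
                              ("b1", 3.0, 1), ("b2", 4.0, 1)])
        groups = GroupLabels({"a1": "good", "a2": "good", "b1": "poor", "b2": "poor"})
        res = logrank_test(surv, groups)
        assert res.chi_square == pytest.approx(2.8824, abs=1e-3)
        assert res.p_value == pytest.approx(0.0896, abs=1e-3)
        o, e = res.observed_expected["good"]
        assert o == pytest.approx(2.0) and e == pytest.approx(5 / 6, abs=1e-9)

    def test_identical_groups_give_zero(self):
        surv = SurvivalTable(
            [(f"a{i}", float(t), 1) for i, t in enumerate([1, 2, 3])]
            + [(f"b{i}", float(t), 1) for i, t in enumerate([1, 2, 3])])
        groups = GroupLabels({f"a{i}": "good" for i in range(3)}
                             | {f"b{i}": "poor" for i in range(3)})
        res = logrank_test(surv, groups)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance_and_oe_balance(self, rng):
        surv = SurvivalTable([(f"s{i}", float(rng.exponential(10)),
                               int(rng.random() < 0.8)) for i in range(40)])
        groups = GroupLabels({f"s{i}": ("good" if i % 2 else "poor") for i in range(40)})
        swapped = GroupLabels({s: ("poor" if g == "good" else "good")
                               for s, g in groups.assignments.items()})
        a, b = logrank_test(surv, groups), logrank_test(surv, swapped)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)
        diff = sum(o - e for o, e in a.observed_expected.values())
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_lifelines_on_random_data(self):
        """Independent oracle: lifelines' log-rank on 100 random datasets."""
        from lifelines.statistics import logrank_test as ll_logrank

        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(6, 30))
            times = r.exponential(10, size=n)
            events = (r.random(n) < 0.7).astype(int)
            if events.sum() == 0:
                events[0] = 1
            grp = np.array(["good" if r.random() < 0.5 else "poor" for _ in range(n)])
            if len(set(grp)) < 2:
                grp[0] = "good" if grp[1] == "poor" else "poor"
            surv = SurvivalTable([(f"s{i}", float(times[i]), int(events[i]))
                                  for i in range(n)])
            groups = GroupLabels({f"s{i}": grp[i] for i in range(n)})
            mine = logrank_test(surv, groups)
            ref = ll_logrank(times[grp == "good"], times[grp == "poor"],
                             events[grp == "good"], events[grp == "poor"])
            assert mine.chi_square == pytest.approx(ref.test_statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_no_events_rejected(self):
        surv = SurvivalTable([("a", 1.0, 0), ("b", 2.0, 0)])
        groups = GroupLabels({"a": "good", "b": "poor"})
        with pytest.raises(PrognetError, match="no events"):
            logrank_test(surv, groups)


class TestSimulatedSurvivalMonotonicity:
    def test_poor_group_has_shorter_median_time(self):
        cfg = CohortConfig(n_samples=200, hazard_good=0.01, hazard_poor=0.03,
                           censor_time=1e9, seed=3)
        labels = GroupLabels({f"s{i}": ("good" if i < 100 else "poor")
                              for i in range(200)})
        surv = simulate_survival(labels, cfg)
        frame = surv.to_frame().set_index("sample")
        med_good = frame.loc[[f"s{i}" for i in range(100)], "time"].median()
        med_poor = frame.loc[[f"s{i}" for i in range(100, 200)], "time"].median()
        assert med_poor < med_good

    def test_zero_censor_time_yields_no_events_error(self):
        cfg = CohortConfig(censor_time=0.0, seed=1)
        labels = GroupLabels({"s1": "good", "s2": "poor"})
        surv = simulate_survival(labels, cfg)
        assert all(t == 0.0 and e == 0 for _, t, e in surv.records)
        with pytest.raises(PrognetError, match="no events"):
            logrank_test(surv, labels)


class TestSizeSweep:
    def _study(self, seed=0):
        r = np.random.default_rng(seed)
        train, train_labels = _separable(r, n=100, shift=1.0, label="tr")
        test, test_labels = _separable(r, n=100, shift=1.0, label="te")
        cfg = CohortConfig(n_samples=100, hazard_good=0.01, hazard_poor=0.04, seed=seed)
        surv = simulate_survival(test_labels, cfg)
        return train, train_labels, test, surv

    def test_full_size_matches_direct_evaluation(self):
        train, train_labels, test, surv = self._study()
        markers = [f"m{j}" for j in range(5)]
        sweep = size_sweep({"m": markers}, [5], train, train_labels, test, surv)
        pred = classify_cohort(train, train_labels, test, markers)
        direct = logrank_test(surv, pred).p_value
        assert sweep.loc[5, "m"] == pytest.approx(direct, rel=1e-12)

    def test_oversized_prefix_truncated_with_warning(self, caplog):
        train, train_labels, test, surv = self._study()
        with caplog.at_level("WARNING"):
            sweep = size_sweep({"m": ["m0", "m1"]}, [2, 99], train, train_labels,
                               test, surv)
        assert "truncating" in caplog.text
        assert sweep.loc[99, "m"] == pytest.approx(sweep.loc[2, "m"], rel=1e-12)

    def test_informative_prefixes_reach_significance(self):
        """With a planted prognostic structure the p-value trajectory reaches
        its minimum at or before the full size and the full model is strong."""
        fulls, mins = [], []
        for seed in range(10):
            train, train_labels, test, surv = self._study(seed)
            sweep = size_sweep({"m": [f"m{j}" for j in range(5)]}, [1, 3, 5],
                               train, train_labels, test, surv)
            ps = sweep["m"].to_numpy()
            fulls.append(ps[-1])
            mins.append(ps.min())
        assert np.median(fulls) < 0.05
        assert all(m <= f + 1e-12 for m, f in zip(mins, fulls))
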
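"""Metrics: MAE, subscore accuracy, pair counting, trend consistency."""

import itertools
import math

import numpy as np
import pytest

from pasivision.core import VisitAssessment, write_visits_csv
from pasivision.evaluate import (
    EvalInputError,
    count_pairs,
    evaluate,
    mae,
    subscore_accuracy,
    trend_consistency,
)

from conftest import CONSISTENT_SCORE_TABLES, make_visit_regions


# -- brute-force oracles ----------------------------------------------------

def brute_mae(p, t):
    return sum(abs(a - b) for a, b in zip(p, t)) / len(p)


def brute_trend(truth, pred):
    """Naive pair loop: concordant / usable, with strata on |truth gap|."""
    ok = used = 0
    strata = {"band_0_5": [0, 0], "band_6_10": [0, 0], "band_gt10": [0, 0]}
    for i, j in itertools.combinations(range(len(truth)), 2):
        dt = truth[i] - truth[j]
        if dt == 0:
            continue
        used += 1
        good = math.copysign(1, pred[i] - pred[j]) == math.copysign(1, dt) and pred[i] != pred[j]
        ok += good
        g = abs(dt)
        key = "band_0_5" if g <= 5 else ("band_6_10" if g <= 10 else "band_gt10")
        strata[key][0] += good
        strata[key][1] += 1
    return ok / used if used else None, strata, used


# -- mae / accuracy ---------------------------------------------------------

def test_mae_examples_and_oracle(rng):
    assert mae([1, 2], [2, 4]) == 1.5
    assert mae([18.4], [17.2]) == pytest.approx(1.2)
    assert mae([3, 3], [3, 3]) == 0.0
    p = rng.uniform(0, 72, 50)
    t = rng.uniform(0, 72, 50)
    assert mae(p, t) == pytest.approx(brute_mae(p, t), abs=1e-9)


def test_mae_input_errors():
    with pytest.raises(EvalInputError):
        mae([1], [1, 2])
    with pytest.raises(EvalInputError):
        mae([], [])


def test_subscore_accuracy_examples_and_oracle(rng):
    assert subscore_accuracy([0, 1, 2, 3], [0, 1, 2, 4], 5) == 0.75
    assert subscore_accuracy([1, 1], [1, 1], 5) == 1.0
    p = rng.integers(0, 7, 100)
    t = rng.integers(0, 7, 100)
    assert subscore_accuracy(p, t, 7) == pytest.approx(np.mean(p == t), abs=1e-12)


def test_subscore_accuracy_rejects_empty_and_out_of_range():
    with pytest.raises(EvalInputError):
        subscore_accuracy([], [], 5)
    with pytest.raises(EvalInputError):
        subscore_accuracy([5], [1], 5)


# -- pair counting ----------------------------------------------------------

def test_count_pairs_matches_enumeration_and_printed_value():
    assert count_pairs(429) == 91806
    assert count_pairs(2) == 1
    for n in range(12):
        assert count_pairs(n) == len(list(itertools.combinations(range(n), 2)))
    with pytest.raises(EvalInputError):
        count_pairs(-1)


# -- trend consistency ------------------------------------------------------

def test_trend_perfect_predictor_is_100_percent_everywhere(rng):
    truth = rng.uniform(0, 40, 30)
    rep = trend_consistency(truth, truth)
    assert rep.overall == 1.0
    assert all(v in (None, 1.0) for v in rep.per_band.values())


def test_trend_reversed_predictor_is_0_percent(rng):
    truth = rng.uniform(0, 40, 30)
    rep = trend_consistency(truth, -truth)
    assert rep.overall == 0.0


def test_trend_three_visit_worked_example():
    rep = trend_consistency([1, 4, 12], [2, 3, 20])
    assert rep.overall == 1.0
    assert rep.pairs_per_band == {"band_0_5": 1, "band_6_10": 1, "band_gt10": 1}


def test_trend_matches_brute_force_on_random_fixtures(rng):
    for _ in range(5):
        truth = np.round(rng.uniform(0, 30, 25), 1)
        pred = np.round(truth + rng.normal(0, 4, 25), 1)
        rep = trend_consistency(truth, pred)
        expect, strata, used = brute_trend(list(truth), list(pred))
        assert rep.overall == pytest.approx(expect, abs=1e-9)
        assert rep.n_pairs_used == used
        for key, (good, tot) in strata.items():
            assert rep.pairs_per_band[key] == tot
            if tot:
                assert rep.per_band[key] == pytest.approx(good / tot, abs=1e-9)


def test_trend_invariant_under_strictly_increasing_transform(rng):
    truth = rng.uniform(0, 30, 20)
    pred = rng.uniform(0, 30, 20)
    base = trend_consistency(truth, pred)
    for f in (lambda x: 3 * x + 7, np.exp, lambda x: x**3):
        rep = trend_consistency(truth, f(pred))
        assert rep.overall == pytest.approx(base.overall)
        for key, val in base.per_band.items():
            if val is None:
                assert rep.per_band[key] is None
            else:
                assert rep.per_band[key] == pytest.approx(val)


def test_trend_strata_partition_the_untied_pairs(rng):
    truth = rng.integers(0, 20, 40).astype(float)  # many ties
    pred = rng.uniform(0, 20, 40)
    rep = trend_consistency(truth, pred)
    assert sum(rep.pairs_per_band.values()) == rep.n_pairs_used
    assert rep.n_pairs_total == count_pairs(40)


def test_trend_predicted_ties_on_ordered_truth_count_incorrect():
    # three strictly ordered truths, all predictions tied -> 3 usable pairs
    rep = trend_consistency([1.0, 8.0, 15.0], [4.0, 4.0, 4.0])
    assert rep.overall == 0.0
    rep_half = trend_consistency([1.0, 8.0, 15.0], [4.0, 4.0, 4.0], tie_policy="half")
    assert rep_half.overall == 0.5


def test_trend_insufficient_pairs():
    rep = trend_consistency([5.0, 5.0], [1.0, 2.0])
    assert rep.insufficient and rep.overall is None


# -- evaluate (report assembly) --------------------------------------------

def _visits(n, rng, prefix="p"):
    out = []
    for i in range(n):
        rows = [(int(rng.integers(0, 7)),) + tuple(int(rng.integers(0, 5)) for _ in range(3))
                for _ in range(4)]
        out.append(VisitAssessment(f"{prefix}{i}", "v0", make_visit_regions(rows)))
    return out


def test_evaluate_identity_gives_perfect_report(tmp_path, rng):
    visits = _visits(8, rng)
    p = tmp_path / "pred.csv"
    t = tmp_path / "truth.csv"
    write_visits_csv(visits, p)
    write_visits_csv(visits, t)
    rep = evaluate(p, t)
    assert rep.pasi_mae == 0.0
    assert all(v == 1.0 for v in rep.subscore_accuracy.values())
    assert rep.trend.overall == 1.0
    assert all(v is None or v == 0.0 for v in rep.mae_by_severity.values())


def test_evaluate_single_visit_reports_insufficient_pairs(tmp_path, rng):
    visits = _visits(1, rng)
    p = tmp_path / "pred.csv"
    write_visits_csv(visits, p)
    rep = evaluate(p, p)
    assert rep.pasi_mae == 0.0 and rep.trend.insufficient


def test_evaluate_pair_bookkeeping_matches_count_pairs(tmp_path, rng):
    truth = _visits(10, rng)
    pred = _visits(10, rng)
    tp = tmp_path / "t.csv"
    pp = tmp_path / "p.csv"
    write_visits_csv(truth, tp)
    write_visits_csv(pred, pp)
    rep = evaluate(pp, tp)
    tied = sum(
        1 for a, b in itertools.combinations([v.pasi for v in truth], 2) if a == b
    )
    assert rep.trend.n_pairs_used == count_pairs(10) - tied
    assert sum(rep.trend.pairs_per_band.values()) == rep.trend.n_pairs_used


def test_evaluate_unmatched_keys_are_an_error(tmp_path, rng):
    a = _visits(3, rng)
    b = _visits(4, rng)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_visits_csv(a, pa)
    write_visits_csv(b, pb)
    with pytest.raises(EvalInputError, match="keys differ"):
        evaluate(pa, pb)


def test_evaluate_severity_stratified_mae(tmp_path):
    rows_low = [(1, 1, 0, 0), (1, 1, 0, 0), (0, 0, 0, 0), (1, 1, 1, 0)]
    truth = [VisitAssessment("a", "v", make_visit_regions(rows_low)),
             VisitAssessment("b", "v", make_visit_regions(CONSISTENT_SCORE_TABLES[0][1]))]
    pred = [VisitAssessment("a", "v", make_visit_regions([(0, 0, 0, 0)] * 4)),
            VisitAssessment("b", "v", make_visit_regions(CONSISTENT_SCORE_TABLES[1][1]))]
    tp, pp = tmp_path / "t.csv", tmp_path / "p.csv"
    write_visits_csv(truth, tp)
    write_visits_csv(pred, pp)
    rep = evaluate(pp, tp)
    assert rep.mae_by_severity["low"] == pytest.approx(truth[0].pasi)
    assert rep.mae_by_severity["high"] == pytest.approx(abs(18.4 - 17.2))
    assert rep.mae_by_severity["medium"] is None
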
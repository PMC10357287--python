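"""Statistical machinery against brute-force and closed-form oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iliorisk.cohort_stats import (CalibrationResult, ConfusionMatrix,
                                   aic_forward_selection, best_split,
                                   calibration_slope, confusion_metrics,
                                   correlations, fit_threshold_tree,
                                   logistic_fit, max_accuracy_threshold,
                                   predict_tree, propensity_match, roc_auc,
                                   univariate_screen)
from iliorisk.errors import (CollinearityError, InvalidInputError)


# ---------------------------------------------------------------------------
# confusion metrics (exact rational arithmetic)


def test_design_cohort_worked_example():
    """172 complication / 344 control patients, 4 missed and 9 false
    alarms: sensitivity 97.7% as printed."""
    m = confusion_metrics(ConfusionMatrix(tp=168, fn=4, fp=9, tn=335))
    assert m.sensitivity == Fraction(168, 172)
    assert m.as_percent()["sensitivity"] == 97.7
    assert m.accuracy == Fraction(168 + 335, 516)


def test_ppv_worked_example():
    m = confusion_metrics(ConfusionMatrix(tp=66, fp=2, tn=0, fn=0))
    assert m.ppv == Fraction(66, 68)
    assert m.as_percent()["ppv"] == 97.1


def test_zero_denominator_is_undefined_not_zero():
    m = confusion_metrics(ConfusionMatrix(tp=0, fn=0, fp=3, tn=7))
    assert m.sensitivity is None
    assert m.specificity == Fraction(7, 10)
    assert m.as_percent()["sensitivity"] is None


@given(tp=st.integers(0, 40), fp=st.integers(0, 40),
       tn=st.integers(0, 40), fn=st.integers(0, 40))
@settings(max_examples=200, deadline=None)
def test_confusion_identities(tp, fp, tn, fn):
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    m = confusion_metrics(cm)
    if cm.total:
        assert m.accuracy == Fraction(tp + tn, cm.total)
        p, n = tp + fn, tn + fp
        if m.sensitivity is not None and m.specificity is not None:
            assert m.sensitivity * p + m.specificity * n == tp + tn


# ---------------------------------------------------------------------------
# ROC / concordance


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_perfect_separation():
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)


def test_roc_three_quarters():
    assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc == pytest.approx(0.75)


def test_roc_all_ties_is_half():
    assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)


def test_roc_rejects_single_class():
    with pytest.raises(InvalidInputError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_roc_curve_monotone_and_ci_ordered(cohort_small):
    r = roc_auc(cohort_small["csi"].to_numpy(),
                cohort_small["outcome"].to_numpy())
    fpr = [p[0] for p in r.curve]
    tpr = [p[1] for p in r.curve]
    assert all(b >= a for a, b in zip(fpr, fpr[1:]))
    assert all(b >= a for a, b in zip(tpr, tpr[1:]))
    assert r.ci95[0] <= r.auc <= r.ci95[1]


@given(st.data())
@settings(max_examples=120, deadline=None)
def test_roc_equals_brute_force_concordance(data):
    n = data.draw(st.integers(4, 50))
    scores = data.draw(st.lists(st.integers(0, 10), min_size=n, max_size=n))
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if len(set(labels)) < 2:
        labels[0], labels[1] = 0, 1
    assert roc_auc(scores, labels).auc == pytest.approx(
        brute_force_auc(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# max-accuracy threshold


def brute_force_max_accuracy(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cands = np.concatenate([[-math.inf], (uniq[:-1] + uniq[1:]) / 2,
                            [math.inf]])
    best = None
    for t in cands:
        pred = scores > t
        acc = np.mean(pred == labels)
        sens = (pred & (labels == 1)).sum() / max(1, (labels == 1).sum())
        key = (acc, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, acc)
    return best[1], best[2]


def test_max_accuracy_perfect_separation_midpoint():
    t, sens, spec, acc = max_accuracy_threshold([1, 2, 10, 11],
                                                [0, 0, 1, 1])
    assert acc == 1.0 and sens == 1.0 and spec == 1.0
    assert t == pytest.approx(6.0)


def test_max_accuracy_exhaustive_example():
    scores = [1, 2, 3, 4, 5, 6]
    labels = [0, 0, 0, 1, 0, 1]
    t, sens, spec, acc = max_accuracy_threshold(scores, labels)
    bt, bacc = brute_force_max_accuracy(scores, labels)
    assert t == pytest.approx(bt)
    assert acc == pytest.approx(bacc)


def test_max_accuracy_shift_invariance():
    scores = np.array([1.0, 2, 3, 4, 5, 6])
    labels = [0, 1, 0, 1, 0, 1]
    t0, se0, sp0, a0 = max_accuracy_threshold(scores, labels)
    t1, se1, sp1, a1 = max_accuracy_threshold(scores + 100.0, labels)
    assert t1 == pytest.approx(t0 + 100.0)
    assert (se1, sp1, a1) == (se0, sp0, a0)


@given(st.data())
@settings(max_examples=80, deadline=None)
def test_max_accuracy_matches_brute_force(data):
    n = data.draw(st.integers(4, 30))
    scores = data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n))
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if len(set(labels)) < 2:
        labels[0], labels[1] = 0, 1
    t, sens, spec, acc = max_accuracy_threshold(scores, labels)
    bt, bacc = brute_force_max_accuracy(scores, labels)
    assert acc == pytest.approx(bacc, abs=1e-12)
    assert t == pytest.approx(bt, abs=1e-12)


# ---------------------------------------------------------------------------
# logistic regression


def test_intercept_only_closed_form():
    y = np.array([1] * 30 + [0] * 70)
    fit = logistic_fit(pd.DataFrame(index=range(100)), y)
    assert fit.params["const"] == pytest.approx(math.log(30 / 70), abs=1e-6)
    assert fit.aic == pytest.approx(fit.deviance + 2.0)


def test_duplicated_column_raises_collinearity():
    rng = np.random.default_rng(0)
    x = rng.normal(size=80)
    y = (x + rng.normal(size=80) > 0).astype(int)
    X = pd.DataFrame({"a": x, "b": x})
    with pytest.raises(CollinearityError) as err:
        logistic_fit(X, y)
    assert "b" in str(err.value)


def test_parameter_recovery_large_sample():
    """Known-coefficient simulation: estimates land within 3 SE."""
    rng = np.random.default_rng(42)
    n = 5000
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    truth = {"const": -1.0, "x1": 0.8, "x2": -0.5}
    lp = truth["const"] + truth["x1"] * X.x1 + truth["x2"] * X.x2
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    fit = logistic_fit(X, y)
    for name, b in truth.items():
        assert abs(fit.params[name] - b) < 3 * fit.bse[name]


# ---------------------------------------------------------------------------
# univariate screening + AIC forward selection


def _toy_cohort(n=400, seed=3):
    rng = np.random.default_rng(seed)
    signal = rng.normal(size=n)
    noise1 = rng.normal(size=n)
    noise2 = rng.normal(size=n)
    flag = rng.integers(0, 2, size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 2.0 * signal)))).astype(int)
    return pd.DataFrame({"signal": signal, "noise1": noise1,
                         "noise2": noise2, "flag": flag, "outcome": y})


def test_univariate_screen_flags_signal():
    table = _toy_cohort()
    screen = univariate_screen(table, ["signal", "noise1", "noise2",
                                       "flag"])
    assert screen.loc["signal", "selected"]
    assert screen.loc["signal", "test"] == "ttest"
    assert screen.loc["flag", "test"] in ("chi2", "fisher")


def test_aic_forward_selects_predictive_feature():
    """Greedy forward AIC agrees with exhaustive subset search on a small
    candidate set with one real predictor."""
    table = _toy_cohort()
    candidates = ["signal", "noise1", "noise2", "flag"]
    selected, fit = aic_forward_selection(table, candidates)
    assert "signal" in selected

    best_subset, best_aic = None, math.inf
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(sorted(candidates), r):
            aic = logistic_fit(table[list(subset)], table["outcome"]).aic
            if aic < best_aic - 1e-12:
                best_subset, best_aic = set(subset), aic
    assert set(selected) == best_subset
    assert fit.aic == pytest.approx(best_aic)


def test_aic_never_adds_duplicate():
    table = _toy_cohort()
    table["signal_copy"] = table["signal"]
    selected, _ = aic_forward_selection(
        table, ["signal", "signal_copy", "noise1"])
    assert not ("signal" in selected and "signal_copy" in selected)


def test_aic_all_noise_usually_selects_nothing():
    """A null candidate at n = 2,000 joins the model only when its chance
    deviance gain beats the AIC penalty of 2 — probability
    P(χ²₁ > 2) ≈ 15.7% — so the empty model wins in at least 80% of 100
    replicates."""
    empty = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        table = pd.DataFrame({
            "n1": rng.normal(size=2000),
            "outcome": rng.integers(0, 2, size=2000)})
        selected, _ = aic_forward_selection(table, ["n1"])
        empty += not selected
    assert empty >= 80


def test_aic_empty_candidates_gives_intercept_only():
    table = _toy_cohort()
    selected, fit = aic_forward_selection(table, [])
    assert selected == []
    assert list(fit.params.index) == ["const"]


# ---------------------------------------------------------------------------
# propensity matching


def brute_force_greedy_match(ps, y, ratio, caliper):
    """Independent restatement of the greedy rule: cases by descending
    score, nearest unused controls within the caliper."""
    cases = sorted((i for i in ps.index if y[i] == 1),
                   key=lambda i: -ps[i])
    pool = {i for i in ps.index if y[i] == 0}
    out = {}
    for cid in cases:
        ranked = sorted(pool, key=lambda j: (abs(ps[j] - ps[cid]), j))
        take = [j for j in ranked if abs(ps[j] - ps[cid]) <= caliper][:ratio]
        if take:
            out[cid] = take
            pool -= set(take)
    return out


def _match_cohort(n=80, seed=11):
    rng = np.random.default_rng(seed)
    age = rng.normal(80, 8, n)
    sex = rng.integers(0, 2, n)
    lp = -2.2 + 0.04 * (age - 80) + 0.3 * sex
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    y[:6] = 1  # ensure enough cases
    return pd.DataFrame({"age": age, "sex": sex, "outcome": y})


def test_identical_covariates_match_at_zero_distance():
    table = pd.DataFrame({
        "age": [80.0] * 9, "sex": [1] * 9,
        "outcome": [1, 0, 0, 0, 0, 0, 0, 0, 1]})
    res = propensity_match(table, ["age", "sex"], ratio=2, caliper=0.10)
    assert len(res.matches) == 2
    for cid, ctrls in res.matches.items():
        assert len(ctrls) == 2
        for j in ctrls:
            assert abs(res.propensity[j] - res.propensity[cid]) < 1e-12


def test_match_agrees_with_brute_force_on_toy_table():
    """13-patient table (3 cases / 10 controls): pairing equals the
    brute-force enumeration of the stated greedy rule."""
    table = _match_cohort(n=13, seed=29)
    table["outcome"] = [1, 1, 1] + [0] * 10
    res = propensity_match(table, ["age", "sex"], ratio=2, caliper=0.10)
    oracle = brute_force_greedy_match(res.propensity,
                                      table["outcome"], 2, 0.10)
    assert res.matches == oracle


def test_zero_caliper_drops_every_case():
    table = _match_cohort(n=40, seed=3)
    res = propensity_match(table, ["age", "sex"], ratio=2, caliper=0.0)
    assert res.matches == {} or all(
        abs(res.propensity[j] - res.propensity[c]) == 0
        for c, js in res.matches.items() for j in js)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_match_invariants_never_violated(seed):
    table = _match_cohort(n=120, seed=seed)
    res = propensity_match(table, ["age", "sex"], ratio=2, caliper=0.10)
    used = res.matched_control_ids
    assert len(used) == len(set(used))
    for cid, ctrls in res.matches.items():
        assert 1 <= len(ctrls) <= 2
        for j in ctrls:
            assert abs(res.propensity[j] - res.propensity[cid]) <= 0.10
    assert set(res.dropped_cases).isdisjoint(res.matches)
    assert {"smd_before", "smd_after"} <= set(res.balance.columns)


# ---------------------------------------------------------------------------
# threshold tree


def brute_force_best_split(X, y):
    best = None
    n = len(y)

    def gini(yy):
        if len(yy) == 0:
            return 0.0
        p = np.mean(yy)
        return 2 * p * (1 - p)

    parent = gini(y)
    for feat in sorted(X.columns):
        vals = np.unique(X[feat])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2
            mask = X[feat].to_numpy() <= thr
            gain = parent - (mask.sum() * gini(y[mask])
                             + (~mask).sum() * gini(y[~mask])) / n
            key = (-gain, feat, thr)
            if gain > 1e-12 and (best is None or key < best[0]):
                best = (key, (feat, thr, gain))
    return None if best is None else best[1]


def test_best_split_matches_brute_force_20_rows():
    rng = np.random.default_rng(5)
    X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
    y = rng.integers(0, 2, size=20)
    y[0], y[1] = 0, 1
    got = best_split(X, y)
    want = brute_force_best_split(X, y)
    assert got[0] == want[0]
    assert got[1] == pytest.approx(want[1])
    assert got[2] == pytest.approx(want[2])


def test_pure_node_never_splits():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    assert best_split(X, np.array([1, 1, 1])) is None


def _planted_rule_table(n=2000, seed=8, flip=0.0,
                        sfar_margin=0.05, csi_margin=5.0):
    """Cohort labelled by the two-step rule with empty margin gaps around
    both thresholds.

    Points just below each gap are forced negative on the *other*
    feature (buffer regions): without them the data cannot identify the
    planted threshold — a Gini split at the gap's lower edge, swallowing
    neighbours that are positive through the other rule, separates the
    labels equally well.
    """
    rng = np.random.default_rng(seed)
    sfar = rng.uniform(0.7, 1.3, n)
    sfar = np.where(np.abs(sfar - 1.0) < sfar_margin,
                    1.0 + np.sign(sfar - 1.0 + 1e-12) * sfar_margin
                    + rng.uniform(0, 0.1, n), sfar)
    csi = rng.uniform(50.0, 150.0, n)
    csi = np.where(np.abs(csi - 100.0) < csi_margin,
                   100.0 + np.sign(csi - 100.0 + 1e-12) * csi_margin
                   + rng.uniform(0, 10, n), csi)
    near_sfar_gap = (sfar > 1.0 - 2 * sfar_margin) & (sfar <= 1.0)
    csi[near_sfar_gap] = rng.uniform(50.0, 100.0 - 2 * csi_margin,
                                     int(near_sfar_gap.sum()))
    near_csi_gap = (csi > 100.0 - 2 * csi_margin) & (csi <= 100.0)
    sfar[near_csi_gap] = rng.uniform(0.7, 1.0 - 2 * sfar_margin,
                                     int(near_csi_gap.sum()))
    y = ((sfar > 1.0) | (csi > 100.0)).astype(int)
    if flip:
        flips = rng.random(n) < flip
        y = np.where(flips, 1 - y, y)
    return pd.DataFrame({"sfar": sfar, "csi": csi, "outcome": y})


def test_tree_recovers_planted_rule():
    table = _planted_rule_table()
    model, root = fit_threshold_tree(table[["sfar", "csi"]],
                                     table["outcome"])
    thresholds = {f: t for f, t, d in model.rules}
    assert set(thresholds) == {"sfar", "csi"}
    assert abs(thresholds["sfar"] - 1.0) < 0.025  # half the 0.05 margin
    assert abs(thresholds["csi"] - 100.0) < 2.5  # half the 5 margin
    assert all(d == ">" for _, _, d in model.rules)
    pred = predict_tree(model, table)
    assert np.array_equal(pred, table["outcome"].to_numpy())


def test_tree_prediction_consistent_with_own_confusion():
    """Quadrant counts implied by the fitted rules reproduce the model's
    own confusion matrix on the training table."""
    table = _planted_rule_table(flip=0.05, seed=9)
    model, _ = fit_threshold_tree(table[["sfar", "csi"]], table["outcome"])
    pred = predict_tree(model, table)
    thresholds = {f: t for f, t, _ in model.rules}
    if set(thresholds) == {"sfar", "csi"}:
        manual = ((table["sfar"] > thresholds["sfar"])
                  | (table["csi"] > thresholds["csi"])).astype(int)
        assert np.array_equal(pred, manual.to_numpy())


# ---------------------------------------------------------------------------
# correlations


def test_pearson_linear():
    x = np.arange(10.0)
    assert correlations(x, 2 * x, "pearson") == pytest.approx(1.0)


def test_rank_correlations_under_monotone_transform():
    x = np.linspace(0.1, 5, 25)
    y = np.exp(x)  # strictly monotone, nonlinear
    assert correlations(x, y, "spearman") == pytest.approx(1.0)
    assert correlations(x, y, "kendall") == pytest.approx(1.0)


def test_kendall_matches_pair_counting():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 5])
    conc = disc = 0
    for i in range(5):
        for j in range(i + 1, 5):
            s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
            conc += s > 0
            disc += s < 0
    tau = (conc - disc) / (5 * 4 / 2)
    assert correlations(x, y, "kendall") == pytest.approx(tau)


def test_zero_variance_undefined():
    assert correlations([1, 1, 1, 1], [1, 2, 3, 4]) is None


# ---------------------------------------------------------------------------
# calibration slope


def test_calibration_self_consistency():
    """Outcomes drawn exactly from the stated probabilities: slope ≈ 1."""
    rng = np.random.default_rng(0)
    n = 10_000
    p = 1 / (1 + np.exp(-rng.normal(-2.0, 1.0, n)))
    y = (rng.random(n) < p).astype(int)
    res = calibration_slope(p, y, n_boot=100, seed=1)
    assert isinstance(res, CalibrationResult)
    assert res.corrected == pytest.approx(1.0, abs=0.05)


def test_calibration_overdispersed_logits():
    """Doubling the logits halves the recalibration slope."""
    rng = np.random.default_rng(2)
    n = 10_000
    logit = rng.normal(-2.0, 1.0, n)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    p_over = 1 / (1 + np.exp(-2.0 * logit))
    res = calibration_slope(p_over, y, n_boot=100, seed=1)
    assert res.corrected == pytest.approx(0.5, abs=0.05)


def test_calibration_rejects_degenerate_probabilities():
    with pytest.raises(InvalidInputError):
        calibration_slope([0.2, 0.2, 0.2], [0, 1, 0])
    with pytest.raises(InvalidInputError):
        calibration_slope([0.0, 0.5, 0.9], [0, 1, 0])
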
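"""Cohort-level statistics for risk-model derivation and validation.

Everything needed to derive and evaluate the two-step risk model on a
patient table lives here: exact-rational confusion metrics, ROC area by
pairwise concordance with a DeLong confidence interval, the
maximum-accuracy operating point, logistic regression (IRLS via
statsmodels) with collinearity and separation diagnostics, univariate
screening, greedy minimum-AIC forward selection, 2:1 caliper
propensity-score matching, a depth-limited Gini classification tree
emitted as an ordered rule list, correlation coefficients and the
optimism-corrected calibration slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, InvalidInputError, SeparationError
from .risk_score import TreeModel

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")

    @classmethod
    def from_predictions(cls, predicted, labels) -> "ConfusionMatrix":
        predicted = np.asarray(predicted, dtype=bool)
        labels = np.asarray(labels, dtype=bool)
        if predicted.shape != labels.shape:
            raise InvalidInputError("predicted and labels differ in length")
        return cls(tp=int(np.sum(predicted & labels)),
                   fp=int(np.sum(predicted & ~labels)),
                   tn=int(np.sum(~predicted & ~labels)),
                   fn=int(np.sum(~predicted & labels)))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Exact rational metrics; a field is None when its denominator is 0."""

    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    accuracy: Optional[Fraction]
    ppv: Optional[Fraction]
    npv: Optional[Fraction]
    f1: Optional[Fraction]

    def as_percent(self, ndigits: int = 1) -> dict:
        """Rounded percentages (one decimal, as printed in clinical
        tables); undefined metrics stay None."""
        out = {}
        for name in ("sensitivity", "specificity", "accuracy",
                     "ppv", "npv", "f1"):
            v = getattr(self, name)
            out[name] = None if v is None else round(float(v) * 100, ndigits)
        return out


def _ratio(num: int, den: int) -> Optional[Fraction]:
    return None if den == 0 else Fraction(num, den)


def confusion_metrics(cm: ConfusionMatrix) -> ConfusionMetrics:
    """Standard confusion metrics in exact rational arithmetic.

    Zero-denominator metrics are reported as undefined (None) rather
    than zero.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    f1 = _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    return ConfusionMetrics(sensitivity=sens, specificity=spec, accuracy=acc,
                            ppv=ppv, npv=npv, f1=f1)


# ---------------------------------------------------------------------------
# ROC / concordance


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple
    curve: tuple  # ((fpr, tpr, threshold), ...) monotone in both axes
    se: float


def _check_two_classes(labels: np.ndarray):
    if labels.min() == labels.max():
        raise InvalidInputError("both outcome classes must be present")


def roc_auc(scores, labels) -> ROCResult:
    """ROC area as the pairwise concordance probability (ties count ½),
    with a DeLong 95% confidence interval.

    Equivalent to trapezoidal integration of the empirical ROC curve;
    fully deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise InvalidInputError("scores and labels differ in length")
    if not np.all(np.isin(labels, (0, 1))):
        raise InvalidInputError("labels must be binary 0/1")
    _check_two_classes(labels)

    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = math.sqrt(var)
    ci = (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))

    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(1 - labels[order])
    distinct = np.append(np.flatnonzero(np.diff(scores[order]) != 0),
                         len(scores) - 1)
    curve = [(0.0, 0.0, math.inf)]
    curve += [(fps[i] / n, tps[i] / m, float(scores[order][i]))
              for i in distinct]
    return ROCResult(auc=float(auc), ci95=ci, curve=tuple(curve),
                     se=float(se))


def max_accuracy_threshold(scores, labels):
    """Operating point maximizing accuracy for the rule ``score > t``.

    Scans the midpoints between adjacent distinct scores plus ±infinity;
    ties are broken toward higher sensitivity, then lower threshold.
    Returns ``(threshold, sensitivity, specificity, accuracy)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    cands = np.concatenate([[-math.inf], (uniq[:-1] + uniq[1:]) / 2.0,
                            [math.inf]])
    m = int(labels.sum())
    n = len(labels) - m
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    cum_pos = np.concatenate([[0], np.cumsum(labels[order])])
    best = None
    for t in cands:
        k = int(np.searchsorted(sorted_scores, t, side="right"))
        tp = m - cum_pos[k]
        fp = (len(labels) - k) - tp
        tn = n - fp
        sens = tp / m
        spec = tn / n
        acc = (tp + tn) / len(labels)
        key = (acc, sens, -t)
        if best is None or key > best[0]:
            best = (key, (float(t), sens, spec, acc))
    return best[1]


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    deviance: float
    aic: float
    llf: float
    converged: bool
    nobs: int
    _result: object = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        design = _design_matrix(X)
        return np.asarray(self._result.predict(design[self.params.index]))


def _design_matrix(X) -> pd.DataFrame:
    if X is None:
        X = pd.DataFrame()
    X = pd.DataFrame(X).astype(float)
    return sm.add_constant(X, has_constant="add")


def _find_collinear(design: pd.DataFrame) -> list:
    """Columns that add no rank to the preceding ones (greedy scan)."""
    culprits = []
    kept = []
    arr = design.to_numpy()
    for j, name in enumerate(design.columns):
        trial = arr[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            culprits.append(name)
    return culprits


def logistic_fit(X, outcome, tol: float = 1e-8,
                 maxiter: int = 200) -> LogisticFit:
    """Binomial GLM fitted by iteratively reweighted least squares.

    An intercept ('const') is always added.  Rank-deficient designs raise
    :class:`CollinearityError` naming the redundant column(s); apparent
    separation or non-convergence raises :class:`SeparationError` naming
    the feature with the most extreme coefficient.  ``aic`` equals
    ``deviance + 2 × n_parameters``.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InvalidInputError("outcome must be binary 0/1")
    design = _design_matrix(X)
    if len(design) != len(y):
        raise InvalidInputError("design and outcome differ in length")
    culprits = _find_collinear(design)
    if culprits:
        raise CollinearityError(
            f"collinear feature(s): {', '.join(map(str, culprits))}",
            features=culprits)
    model = sm.GLM(y, design, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=tol)
    params = pd.Series(res.params, index=design.columns)
    bse = pd.Series(res.bse, index=design.columns)
    nonconst = params.drop("const", errors="ignore")
    suspect = None
    if len(nonconst):
        suspect = nonconst.abs().idxmax()
    if not res.converged or np.any(np.abs(params.to_numpy()) > 30) \
            or np.any(~np.isfinite(bse.to_numpy())) \
            or np.any(bse.to_numpy() > 1e4):
        raise SeparationError(
            "logistic fit did not converge to finite estimates "
            f"(suspect feature: {suspect})", feature=suspect)
    return LogisticFit(params=params, bse=bse, deviance=float(res.deviance),
                       aic=float(res.deviance + 2 * len(params)),
                       llf=float(res.llf), converged=bool(res.converged),
                       nobs=int(res.nobs), _result=res)


# ---------------------------------------------------------------------------
# univariate screening + AIC forward selection


def univariate_screen(table: pd.DataFrame, features: Sequence[str],
                      outcome: str = "outcome", alpha: float = 0.05,
                      nonparametric: bool = False) -> pd.DataFrame:
    """Per-feature two-group tests against the binary outcome.

    Continuous features use Welch's t-test (Mann-Whitney U when
    ``nonparametric``); binary features use the chi-square test, falling
    back to Fisher's exact test when an expected cell count is below 5.
    Returns a table of p-values with a ``selected`` flag at ``alpha``.
    """
    y = table[outcome].astype(int).to_numpy()
    _check_two_classes(y)
    rows = []
    for feat in features:
        x = table[feat].to_numpy(dtype=float)
        values = np.unique(x[np.isfinite(x)])
        if len(values) <= 2 and np.all(np.isin(values, (0.0, 1.0))):
            ct = pd.crosstab(x, y).reindex(index=[0.0, 1.0],
                                           columns=[0, 1], fill_value=0)
            obs = ct.to_numpy()
            expected = stats.contingency.expected_freq(obs + 0.0) \
                if obs.sum() else obs
            if obs.sum() and expected.min() < 5:
                _, p = stats.fisher_exact(obs)
                test = "fisher"
            else:
                _, p, _, _ = stats.chi2_contingency(obs, correction=False)
                test = "chi2"
        else:
            g1, g0 = x[y == 1], x[y == 0]
            if nonparametric:
                _, p = stats.mannwhitneyu(g1, g0, alternative="two-sided")
                test = "mannwhitney"
            else:
                _, p = stats.ttest_ind(g1, g0, equal_var=False)
                test = "ttest"
        rows.append({"feature": feat, "p_value": float(p), "test": test})
    out = pd.DataFrame(rows).set_index("feature")
    out["selected"] = out["p_value"] < alpha
    return out


def aic_forward_selection(table: pd.DataFrame, candidates: Sequence[str],
                          outcome: str = "outcome"):
    """Greedy forward feature selection by minimum AIC.

    Starting from the intercept-only model, repeatedly adds the candidate
    that lowers the AIC the most (ties broken alphabetically by scanning
    candidates in sorted order and requiring a strict improvement); stops
    when no addition lowers it.  Returns ``(selected, fit)``.
    """
    y = table[outcome].astype(int)
    selected: list = []
    current = logistic_fit(table[selected], y)
    remaining = sorted(dict.fromkeys(candidates))
    while remaining:
        best_feat, best_fit = None, None
        for feat in remaining:
            if feat in selected:
                continue
            try:
                fit = logistic_fit(table[selected + [feat]], y)
            except CollinearityError:
                continue
            if fit.aic < (best_fit.aic if best_fit else current.aic) - 1e-12:
                best_feat, best_fit = feat, fit
        if best_feat is None:
            break
        selected.append(best_feat)
        current = best_fit
        remaining.remove(best_feat)
    return selected, current


# ---------------------------------------------------------------------------
# propensity-score matching


@dataclass
class MatchResult:
    """Greedy nearest-neighbor caliper matching output.

    ``matches`` maps each matched case id to its control ids (at most the
    requested ratio, no control reused); ``dropped_cases`` had no control
    within the caliper.  ``balance`` holds standardized mean differences
    per covariate before and after matching.
    """

    matches: dict
    propensity: pd.Series
    caliper: float
    ratio: int
    dropped_cases: list
    balance: pd.DataFrame

    @property
    def matched_case_ids(self) -> list:
        return list(self.matches.keys())

    @property
    def matched_control_ids(self) -> list:
        return [c for ctrls in self.matches.values() for c in ctrls]


def _smd(x1: np.ndarray, x0: np.ndarray) -> float:
    v = (np.var(x1, ddof=1) + np.var(x0, ddof=1)) / 2.0 \
        if len(x1) > 1 and len(x0) > 1 else 0.0
    if v == 0:
        return 0.0 if np.mean(x1) == np.mean(x0) else math.inf
    return float((np.mean(x1) - np.mean(x0)) / math.sqrt(v))


def propensity_match(cohort: pd.DataFrame, covariates: Sequence[str],
                     outcome: str = "outcome", ratio: int = 2,
                     caliper: float = 0.10,
                     caliper_scale: str = "ps") -> MatchResult:
    """Nearest-neighbor propensity matching with a caliper, ratio 1:k.

    The propensity score is a logistic fit of the outcome on the
    covariates.  Cases are processed in descending score order; each
    receives its (up to) ``ratio`` nearest unused controls within the
    caliper; cases with none in range are dropped and reported.  The
    caliper is taken on the propensity scale by default, or as a multiple
    of the SD of the logit score with ``caliper_scale='logit_sd'``.
    """
    y = cohort[outcome].astype(int)
    _check_two_classes(y.to_numpy())
    # constant covariates carry no information and would break the fit
    informative = [c for c in covariates if cohort[c].nunique() > 1]
    if informative:
        fit = logistic_fit(cohort[informative], y)
        ps = pd.Series(fit.predict(cohort[informative]),
                       index=cohort.index, name="propensity")
    else:
        ps = pd.Series(float(y.mean()), index=cohort.index,
                       name="propensity")
    if caliper_scale == "logit_sd":
        logit = np.log(ps / (1 - ps))
        width = caliper * float(np.std(logit, ddof=1))
        dist_scores = logit
    elif caliper_scale == "ps":
        width = caliper
        dist_scores = ps
    else:
        raise InvalidInputError(f"unknown caliper scale {caliper_scale!r}")

    case_ids = [i for i in ps.sort_values(ascending=False).index
                if y.loc[i] == 1]
    control_pool = {i for i in cohort.index if y.loc[i] == 0}
    matches, dropped = {}, []
    for cid in case_ids:
        cand = sorted(control_pool,
                      key=lambda j: (abs(dist_scores.loc[j] - dist_scores.loc[cid]), j))
        chosen = [j for j in cand
                  if abs(dist_scores.loc[j] - dist_scores.loc[cid]) <= width][:ratio]
        if not chosen:
            dropped.append(cid)
            continue
        matches[cid] = chosen
        control_pool.difference_update(chosen)

    # invariants asserted on every run
    used = [c for ctrls in matches.values() for c in ctrls]
    assert len(used) == len(set(used)), "a control was reused"
    for cid, ctrls in matches.items():
        for j in ctrls:
            assert abs(dist_scores.loc[j] - dist_scores.loc[cid]) <= width + 1e-12

    rows = []
    m_cases = list(matches.keys())
    m_controls = used
    for cov in covariates:
        x1 = cohort.loc[y == 1, cov].to_numpy(dtype=float)
        x0 = cohort.loc[y == 0, cov].to_numpy(dtype=float)
        row = {"covariate": cov, "smd_before": _smd(x1, x0)}
        if m_cases and m_controls:
            row["smd_after"] = _smd(
                cohort.loc[m_cases, cov].to_numpy(dtype=float),
                cohort.loc[m_controls, cov].to_numpy(dtype=float))
        else:
            row["smd_after"] = math.nan
        rows.append(row)
    balance = pd.DataFrame(rows).set_index("covariate")
    return MatchResult(matches=matches, propensity=ps, caliper=width,
                       ratio=ratio, dropped_cases=dropped, balance=balance)


# ---------------------------------------------------------------------------
# Gini classification tree → ordered rules


@dataclass
class TreeNode:
    prediction: int  # majority class
    n: int
    n_pos: int
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None  # feature <= threshold
    right: Optional["TreeNode"] = None  # feature > threshold

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _gini(n_pos: int, n: int) -> float:
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


def best_split(X: pd.DataFrame, y: np.ndarray):
    """Exhaustive best Gini split over midpoints of every feature.

    Returns ``(feature, threshold, impurity_decrease)`` or None for a
    pure node or when no split reduces impurity.  Ties break toward the
    alphabetically first feature, then the lower threshold.
    """
    n = len(y)
    n_pos = int(np.sum(y))
    if n_pos in (0, n):
        return None
    parent = _gini(n_pos, n)
    best = None
    for feat in sorted(X.columns):
        x = X[feat].to_numpy(dtype=float)
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        cum_pos = np.cumsum(ys)
        boundary = np.flatnonzero(np.diff(xs) != 0)
        for b in boundary:
            thr = (xs[b] + xs[b + 1]) / 2.0
            nl = b + 1
            pl = int(cum_pos[b])
            nr, pr = n - nl, n_pos - pl
            gain = parent - (nl * _gini(pl, nl) + nr * _gini(pr, nr)) / n
            key = (-gain, feat, thr)
            if gain > 1e-12 and (best is None or key < best[0]):
                best = (key, (feat, thr, gain))
    return None if best is None else best[1]


def _grow(X: pd.DataFrame, y: np.ndarray, depth: int,
          max_depth: int) -> TreeNode:
    n, n_pos = len(y), int(np.sum(y))
    node = TreeNode(prediction=int(n_pos * 2 > n), n=n, n_pos=n_pos)
    if depth >= max_depth:
        return node
    split = best_split(X, y)
    if split is None:
        return node
    feat, thr, _ = split
    mask = X[feat].to_numpy(dtype=float) <= thr
    node.feature, node.threshold = feat, thr
    node.left = _grow(X[mask], y[mask], depth + 1, max_depth)
    node.right = _grow(X[~mask], y[~mask], depth + 1, max_depth)
    return node


def _uniform_class(node: TreeNode) -> Optional[int]:
    """The single class every leaf under ``node`` predicts, or None."""
    if node.is_leaf:
        return node.prediction
    left = _uniform_class(node.left)
    if left is None:
        return None
    return left if left == _uniform_class(node.right) else None


def _flatten(node: TreeNode) -> list:
    """Ordered high-risk rules from a tree whose high-risk regions hang
    off a rule chain (the shape the two-step model takes); exact for such
    trees, best-effort otherwise.  Subtrees whose leaves all agree are
    treated as leaves."""
    cls = _uniform_class(node)
    if cls is not None:
        if cls == 1:
            return [("__always__", -math.inf, ">")]
        return []
    right_high = _uniform_class(node.right) == 1
    left_high = _uniform_class(node.left) == 1
    if right_high:
        return [(node.feature, node.threshold, ">")] + _flatten(node.left)
    if left_high:
        return [(node.feature, node.threshold, "<=")] + _flatten(node.right)
    return _flatten(node.right) + _flatten(node.left)


def fit_threshold_tree(X: pd.DataFrame, labels, max_depth: int = 2):
    """Binary recursive partitioning on (typically) SFAR and CSI.

    Greedy exhaustive Gini splits to ``max_depth``; leaves take their
    majority class.  Returns ``(model, root)`` where ``model`` is the
    ordered-rule :class:`~iliorisk.risk_score.TreeModel` read off the
    tree and ``root`` the raw tree for inspection.
    """
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    X = pd.DataFrame(X)
    root = _grow(X.reset_index(drop=True), y, 0, max_depth)
    rules = [r for r in _flatten(root) if r[0] != "__always__"]
    return TreeModel(rules=tuple(rules)), root


def predict_tree(model: TreeModel, table: pd.DataFrame) -> np.ndarray:
    """Vectorized ordered-rule prediction (1 = high risk) on a table whose
    columns include every feature the model names."""
    pred = np.zeros(len(table), dtype=bool)
    undecided = np.ones(len(table), dtype=bool)
    for feat, thr, direction in model.rules:
        if feat not in table.columns:
            raise InvalidInputError(f"missing feature {feat!r}")
        v = table[feat].to_numpy(dtype=float)
        hit = v > thr if direction == ">" else v <= thr
        pred |= undecided & hit
        undecided &= ~hit
    return pred.astype(int)


# ---------------------------------------------------------------------------
# correlations & calibration


def correlations(x, y, method: str = "pearson") -> Optional[float]:
    """Pearson, Spearman or Kendall correlation; None when undefined
    (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InvalidInputError("x and y differ in length")
    if len(x) < 3:
        raise InvalidInputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "kendall":
        return float(stats.kendalltau(x, y).statistic)
    raise InvalidInputError(f"unknown correlation method {method!r}")


@dataclass(frozen=True)
class CalibrationResult:
    apparent: float
    optimism: float
    corrected: float
    n_boot: int


def calibration_slope(predicted_probabilities, labels, n_boot: int = 200,
                      seed: int = 0) -> CalibrationResult:
    """Logistic recalibration slope with bootstrap optimism correction.

    The apparent slope is the coefficient of logit(p) in a logistic
    refit of the outcome; a slope of 1 is perfect calibration, below 1
    overconfident predictions.  Optimism is estimated by refitting the
    recalibration on ``n_boot`` bootstrap resamples and measuring the
    slope shrinkage back on the original data (Harrell's procedure);
    ``corrected = apparent − optimism``.
    """
    p = np.asarray(predicted_probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise InvalidInputError("probabilities and labels differ in length")
    if np.any((p <= 0) | (p >= 1)):
        raise InvalidInputError("probabilities must lie strictly in (0, 1)")
    if np.ptp(p) == 0:
        raise InvalidInputError("constant probabilities: slope undefined")
    _check_two_classes(y)
    logit = np.log(p / (1.0 - p))

    def slope_of(lp: np.ndarray, yy: np.ndarray) -> float:
        design = sm.add_constant(lp)
        res = sm.GLM(yy, design, family=sm.families.Binomial()).fit()
        return float(res.params[1])

    apparent = slope_of(logit, y)
    rng = np.random.default_rng(seed)
    optimisms = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].min() == y[idx].max() or np.ptp(logit[idx]) == 0:
            continue
        b_boot = slope_of(logit[idx], y[idx])
        if abs(b_boot) < 1e-12:
            continue
        # refit slope is 1 on its own sample by construction; on the
        # original data the bootstrap model's slope is apparent / b_boot
        optimisms.append(1.0 - apparent / b_boot)
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return CalibrationResult(apparent=apparent, optimism=optimism,
                             corrected=apparent - optimism, n_boot=n_boot)
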
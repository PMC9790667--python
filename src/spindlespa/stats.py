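"""Cohort statistics: group comparisons, stepwise logistic selection,
ROC/AUC and cut-off diagnostics.

The statistical stage mirrors a conventional small-cohort biomarker
workflow: Shapiro-Wilk as a normality gate (logged, not branching),
Mann-Whitney U per index, chi-square for binary demographics, forward
stepwise ("forward conditional") binary logistic regression with score-test
entry at p <= 0.05 and likelihood-ratio removal at p >= 0.1, nonparametric
AUC with an asymptotic confidence interval, confusion-table diagnostics at
an SPA cut-off of 0.65, and Grubbs single-outlier screening.

Mann-Whitney, AUC, Grubbs, Nagelkerke R-squared and the stepwise driver are
implemented here; maximum-likelihood logistic fits use statsmodels and the
separation fallback uses a small-ridge scikit-learn fit.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "LogisticSelectionResult",
    "ROCResult",
    "DiagnosticMetrics",
    "GrubbsResult",
    "shapiro_wilk",
    "mann_whitney_u",
    "chi_square_binary",
    "forward_conditional_logistic",
    "nagelkerke_r2",
    "roc_auc",
    "diagnostic_metrics",
    "grubbs_test",
    "grubbs_critical_value",
    "holm_adjust",
]

#: enumerate the exact Mann-Whitney null when the number of group-label
#: assignments C(n, n1) is at most this
_EXACT_COMB_LIMIT = 20_000


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    index_name: str
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    n_a: int
    n_b: int
    u: float
    p: float
    method: str  # "exact" | "normal"


@dataclass
class LogisticSelectionResult:
    candidates: list[str]
    selected: list[str]                      # in entry order
    coef: dict[str, float] = field(default_factory=dict)
    wald: dict[str, float] = field(default_factory=dict)
    wald_p: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    nagelkerke_r2: float = 0.0
    classification_accuracy: float = 0.0
    n: int = 0
    separation_warning: bool = False
    steps: list[str] = field(default_factory=list)


@dataclass
class ROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    orientation: str = "lower score => positive class"
    curve: pd.DataFrame | None = None


@dataclass
class DiagnosticMetrics:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")


@dataclass
class GrubbsResult:
    index_name: str
    group: str
    n: int
    g: float
    critical: float
    outlier_id: str | None
    outlier_value: float | None


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------

def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test, valid for 3 <= n <= 50 here.

    Used as a logged gate motivating the nonparametric comparisons; the
    pipeline never branches on it.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= x.size <= 50:
        raise ValueError(f"Shapiro-Wilk gate requires 3 <= n <= 50, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a via mid-rank sums."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def _iqr(x: np.ndarray) -> float:
    return float(np.percentile(x, 75) - np.percentile(x, 25))


def mann_whitney_u(group_a, group_b, index_name: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    U is reported as min(U_a, U_b). The two-tailed p is exact — obtained by
    enumerating every assignment of group labels to the pooled sample — when
    C(n, n_a) <= 20000 (all cases with n_a, n_b <= 6 and more), and is
    otherwise the tie-corrected normal approximation without continuity
    correction, as used by standard clinical statistics software.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    ua = _u_statistic(a, b)
    ub = n1 * n2 - ua
    u = min(ua, ub)
    mu = n1 * n2 / 2.0

    if math.comb(n1 + n2, n1) <= _EXACT_COMB_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        obs_dev = abs(ua - mu)
        count = 0
        total = 0
        base = n1 * (n1 + 1) / 2.0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u_perm = ranks[list(comb)].sum() - base
            if abs(u_perm - mu) >= obs_dev - 1e-9:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        pooled = np.concatenate([a, b])
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (ua - mu) / math.sqrt(var)
            p = float(2 * sps.norm.sf(abs(z)))
        method = "normal"
    return GroupComparison(
        index_name=index_name,
        median_a=float(np.median(a)), iqr_a=_iqr(a),
        median_b=float(np.median(b)), iqr_b=_iqr(b),
        n_a=n1, n_b=n2, u=float(u), p=min(float(p), 1.0), method=method,
    )


def chi_square_binary(table) -> tuple[float, float]:
    """Pearson chi-square with 1 df on a 2x2 count table, two-sided p."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(row, col) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def holm_adjust(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (reported for transparency only)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


# ---------------------------------------------------------------------------
# Logistic selection
# ---------------------------------------------------------------------------

def _fit_logit(X: np.ndarray, y: np.ndarray):
    """MLE logistic fit; returns (params, loglik, cov, separated)."""
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            cov = np.asarray(res.cov_params(), dtype=float)
            ll = float(res.llf)
            if not res.mle_retvals.get("converged", True) or np.max(np.abs(params)) > 50:
                separated = True
        except Exception:
            separated = True
            params = cov = None
            ll = float("nan")
    if separated:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=2000)
        if X.shape[1] == 0:
            p0 = y.mean()
            params = np.array([math.log(p0 / (1 - p0)) if 0 < p0 < 1 else 0.0])
            cov = np.array([[np.nan]])
            ll = _bernoulli_ll(y, np.full_like(y, p0, dtype=float))
        else:
            clf.fit(X, y)
            params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
            eta = params[0] + X @ params[1:]
            ll = _bernoulli_ll(y, 1.0 / (1.0 + np.exp(-eta)))
            cov = np.full((params.size, params.size), np.nan)
    return params, ll, cov, separated


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _predict(params: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = np.full(X.shape[0], params[0])
    if X.shape[1]:
        eta = eta + X @ params[1:]
    return 1.0 / (1.0 + np.exp(-eta))


def _score_test_p(X_in: np.ndarray, x_new: np.ndarray, y: np.ndarray,
                  params_in: np.ndarray) -> float:
    """Rao score test (1 df) for adding x_new to the fitted current model."""
    p_hat = _predict(params_in, X_in)
    w = p_hat * (1 - p_hat)
    n = y.size
    X_ext = np.column_stack([np.ones(n), X_in, x_new])
    u = X_ext.T @ (y - p_hat)           # only the new column is non-zero
    info = X_ext.T @ (X_ext * w[:, None])
    try:
        s = float(u @ np.linalg.solve(info, u))
    except np.linalg.LinAlgError:
        return 1.0
    return float(sps.chi2.sf(max(s, 0.0), df=1))


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Cox-Snell R-squared rescaled by its maximum; in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_model < loglik_null - 1e-9:
        raise ValueError("model log-likelihood must be >= null log-likelihood")
    cox_snell = 1.0 - math.exp(2.0 * (loglik_null - loglik_model) / n)
    max_cs = 1.0 - math.exp(2.0 * loglik_null / n)
    if max_cs <= 0:
        return 0.0
    return float(min(1.0, max(0.0, cox_snell / max_cs)))


def forward_conditional_logistic(data: pd.DataFrame, candidates: list[str],
                                 outcome: str, p_enter: float = 0.05,
                                 p_remove: float = 0.1) -> LogisticSelectionResult:
    """Forward stepwise binary logistic regression with backward elimination.

    Starts from the constant model. Each step enters the candidate with the
    smallest score-test p if it is <= p_enter; after each entry every
    included predictor is re-examined with a likelihood-ratio test and
    removed if its removal p is >= p_remove. Rows with a missing value in
    any candidate or the outcome are dropped (listwise deletion, logged in
    steps). Complete separation is flagged and handled with a lightly
    ridge-penalized fit.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    cols = list(candidates) + [outcome]
    d = data[cols].dropna()
    y = np.asarray(d[outcome], dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n = y.size
    res = LogisticSelectionResult(candidates=list(candidates), selected=[], n=n)
    res.steps.append(f"listwise-complete n={n} of {len(data)}")

    X_of = lambda names: np.asarray(d[names], dtype=float) if names else np.empty((n, 0))
    params, ll, cov, sep = _fit_logit(X_of([]), y)
    ll_null = ll
    selected: list[str] = []
    visited: set[tuple[str, ...]] = set()

    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            scores = {c: _score_test_p(X_of(selected), np.asarray(d[c], float), y, params)
                      for c in remaining}
            best = min(scores, key=scores.get)
            if scores[best] <= p_enter:
                selected.append(best)
                params, ll, cov, sep_i = _fit_logit(X_of(selected), y)
                sep = sep or sep_i
                res.steps.append(f"enter {best} (score p={scores[best]:.4g})")
                changed = True

        # backward elimination by likelihood-ratio removal tests
        removed = True
        while removed and selected:
            removed = False
            worst, worst_p = None, -1.0
            for c in selected:
                reduced = [s for s in selected if s != c]
                _, ll_red, _, _ = _fit_logit(X_of(reduced), y)
                p_rm = float(sps.chi2.sf(max(2 * (ll - ll_red), 0.0), df=1))
                if p_rm > worst_p:
                    worst, worst_p = c, p_rm
            if worst is not None and worst_p >= p_remove:
                selected.remove(worst)
                params, ll, cov, _ = _fit_logit(X_of(selected), y)
                res.steps.append(f"remove {worst} (LR p={worst_p:.4g})")
                changed = removed = True

        key = tuple(selected)
        if not changed or key in visited:
            break
        visited.add(key)

    res.selected = selected
    res.separation_warning = sep
    res.intercept = float(params[0])
    for i, c in enumerate(selected):
        beta = float(params[i + 1])
        se = float(np.sqrt(cov[i + 1, i + 1])) if cov is not None and np.isfinite(
            cov[i + 1, i + 1]) else float("nan")
        res.coef[c] = beta
        res.wald[c] = (beta / se) ** 2 if se and np.isfinite(se) and se > 0 else float("nan")
        res.wald_p[c] = float(sps.chi2.sf(res.wald[c], df=1)) if np.isfinite(
            res.wald[c]) else float("nan")
    res.nagelkerke_r2 = nagelkerke_r2(ll_null, ll, n)
    pred = _predict(params, X_of(selected)) >= 0.5
    res.classification_accuracy = float(np.mean(pred == (y == 1)))
    if sep:
        res.steps.append("separation detected: ridge-penalized fallback fit used")
    return res


# ---------------------------------------------------------------------------
# ROC, cut-off diagnostics, outliers
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, positive_low: bool = True,
            with_curve: bool = False) -> ROCResult:
    """Nonparametric AUC by pair counting with tie correction.

    positive_low orients the score so that lower SPA predicts the positive
    (UCP) class. SE is the Hanley-McNeil asymptotic estimate; the 95% CI is
    the normal interval clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if positive_low:
        pos, neg = -pos, -neg
    # AUC = P(score_pos > score_neg) + 0.5 P(equal), via mid-ranks
    diff = pos[:, None] - neg[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (pos.size * neg.size))
    n1, n2 = pos.size, neg.size
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc)
           + (n2 - 1) * (q2 - auc * auc)) / (n1 * n2)
    se = math.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)
    curve = None
    if with_curve:
        thr = np.unique(np.concatenate([pos, neg]))
        rows = [(float(np.mean(neg >= t)), float(np.mean(pos >= t))) for t in
                np.concatenate([[-np.inf], thr, [np.inf]])]
        curve = pd.DataFrame(rows, columns=["fpr", "tpr"])
    return ROCResult(auc=auc, se=se, ci95=(lo, hi), n_pos=n1, n_neg=n2,
                     orientation="lower SPA => positive class" if positive_low
                     else "higher score => positive class", curve=curve)


def diagnostic_metrics(scores, labels, cutoff: float = 0.65) -> DiagnosticMetrics:
    """Confusion-table diagnostics predicting positive iff score < cutoff.

    A score exactly at the cut-off is classified negative (typical).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both classes must be present")
    pred = s < cutoff
    return DiagnosticMetrics(
        cutoff=cutoff,
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def grubbs_critical_value(n: int, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Grubbs critical value from the Student t quantile."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    a = alpha / (2 * n) if two_sided else alpha / n
    t = sps.t.ppf(1 - a, n - 2)
    return float((n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t)))


def grubbs_test(values, alpha: float = 0.05, two_sided: bool = True,
                ids: list[str] | None = None, index_name: str = "",
                group: str = "") -> GrubbsResult:
    """Single-outlier Grubbs test: G = max |x - mean| / sd vs the t-based
    critical value. At most one outlier is reported per call; iterate after
    removal for sequential screening."""
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    x = x[ok]
    if ids is not None:
        ids = [i for i, k in zip(ids, ok) if k]
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / sd)
    crit = grubbs_critical_value(x.size, alpha, two_sided)
    is_out = g > crit
    return GrubbsResult(
        index_name=index_name, group=group, n=x.size, g=g, critical=crit,
        outlier_id=(ids[i] if ids is not None else str(i)) if is_out else None,
        outlier_value=float(x[i]) if is_out else None,
    )
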
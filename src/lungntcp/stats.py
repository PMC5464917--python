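"""Cohort statistics: 2x2 tests, t tests, logistic regression, ROC analysis.

This is the univariate/multivariate battery a dose-response study runs
around the NTCP model: chi-square association tests on categorical
covariates, two-sample t tests on dosimetric summaries, a multivariable
logistic model with odds ratios, and ROC curves with Youden cut-off
selection plus the derived 2x2 classification metrics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import expit, ndtr

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
    RankError,
)


# ---------------------------------------------------------------------------
# contingency tables


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts: rows are exposure levels, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("cell counts must be nonnegative")
        if self.total < 1:
            raise ParameterError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = True
) -> tuple[float, float]:
    """Chi-square test of association on a 2x2 table (1 df).

    With the Yates continuity correction (the default),
    ``chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))``; without it,
    the Pearson form. The corrected statistic never exceeds the uncorrected
    one. Returns ``(statistic, p_value)``.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    marginals = [(a + b), (c + d), (a + c), (b + d)]
    if min(marginals) <= 0:
        raise DegenerateDataError("a marginal total is zero")
    cross = abs(a * d - b * c)
    if continuity_correction:
        cross = max(cross - n / 2.0, 0.0)
    stat = n * cross**2 / np.prod(marginals)
    return float(stat), float(sps.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# t tests


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    variant: str


def two_sample_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Two-sample t test from summary statistics (pooled or Welch)."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs at least two observations")
    if sd1 <= 0 or sd2 <= 0:
        raise InsufficientDataError("standard deviations must be positive")
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        a1, a2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(a1 + a2)
        df = (a1 + a2) ** 2 / (a1**2 / (n1 - 1) + a2**2 / (n2 - 1))
    else:
        raise ParameterError("variant must be 'pooled' or 'welch'")
    t = (mean1 - mean2) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, variant)


def two_sample_t_from_samples(x1, x2, variant: str = "pooled") -> TTestResult:
    """Two-sample t test from raw samples (delegates to the summary form)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise InsufficientDataError("each group needs at least two observations")
    return two_sample_t(
        float(x1.mean()), float(x1.std(ddof=1)), x1.size,
        float(x2.mean()), float(x2.std(ddof=1)), x2.size,
        variant,
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticResult:
    """IRLS logistic fit: coefficients with Wald inference on the OR scale."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    separation: bool
    n_iter: int
    condition_number: float


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(y @ np.log(p) + (1 - y) @ np.log1p(-p))


def logistic_fit(
    X,
    y,
    names: list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticResult:
    """Maximum-likelihood logit fit by iteratively reweighted least squares.

    Converges when the score's sup-norm drops below ``tol``; the
    log-likelihood is nondecreasing across iterations (step-halving).
    Quasi-complete separation (a coefficient drifting past 15 in absolute
    value) is flagged in the result, never silently returned as a finite
    estimate. A singular weighted design raises :class:`RankError`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ParameterError("X and y lengths differ")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ParameterError("y must be binary 0/1")
    if np.any(np.all(X == 0, axis=0)):
        raise RankError("design has an all-zero column")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + (names or [f"x{i}" for i in range(1, X.shape[1])])
    else:
        names = names or [f"x{i}" for i in range(X.shape[1])]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    ll = _bernoulli_ll(y, expit(X @ beta))
    converged = False
    separation = False
    it = 0
    xtwx = None
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        xtwx = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:
            raise RankError("weighted design became singular") from exc
        s = 1.0
        for _ in range(30):  # keep the log-likelihood nondecreasing
            cand = beta + s * delta
            ll_new = _bernoulli_ll(y, expit(X @ cand))
            if ll_new >= ll - 1e-12:
                break
            s *= 0.5
        beta = beta + s * delta
        ll = ll_new
        if np.max(np.abs(beta)) > 15:
            separation = True
            break

    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-10, None)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise RankError("information matrix is singular") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * ndtr(-np.abs(zval))
    return LogisticResult(
        names=names,
        coef=beta,
        se=se,
        odds_ratios=np.exp(beta),
        ci_low=np.exp(beta - 1.96 * se),
        ci_high=np.exp(beta + 1.96 * se),
        p_values=pvals,
        log_likelihood=ll,
        converged=converged,
        separation=separation,
        n_iter=it,
        condition_number=float(np.linalg.cond(xtwx)),
    )


# ---------------------------------------------------------------------------
# ROC analysis and classification metrics


@dataclass
class RocAnalysis:
    """ROC curve with trapezoid AUC, Hanley-McNeil CI and the Youden cut-off."""

    thresholds: np.ndarray  # decreasing; +/-inf anchors included
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    best_cutoff: float
    youden_j: float


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise DegenerateDataError("ROC needs both outcome classes present")


def roc_curve(scores, labels) -> RocAnalysis:
    """ROC analysis of a risk score (higher score = higher risk).

    Thresholds sit at midpoints between adjacent distinct scores plus
    +/-inf anchors; a subject is called positive when ``score >= cutoff``.
    The trapezoid AUC then equals the Mann-Whitney pair statistic (ties
    count half). The best cut-off maximises Youden's J = sens + spec - 1,
    ties breaking toward higher specificity (the higher threshold). The
    AUC confidence interval uses the Hanley-McNeil variance approximation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.size != labels.size or scores.size == 0:
        raise ParameterError("scores and labels must be equal-length and nonempty")
    _check_two_classes(labels)

    uniq = np.unique(scores)  # ascending
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(scores.size - n_pos)

    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = scores >= thr
        tp = int(np.sum(pred & pos))
        fp = int(np.sum(pred & ~pos))
        sens[i] = tp / n_pos
        spec[i] = (n_neg - fp) / n_neg

    fpr = 1.0 - spec  # ascending along decreasing thresholds
    auc = float(np.trapezoid(sens, fpr))

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    half = 1.96 * float(np.sqrt(max(var, 0.0)))
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))

    j = sens + spec - 1.0
    best_i = 0
    for i in range(thresholds.size):  # descending thresholds: first max wins ties
        if j[i] > j[best_i]:
            best_i = i
    return RocAnalysis(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci=ci,
        best_cutoff=float(thresholds[best_i]),
        youden_j=float(j[best_i]),
    )


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 classification counts and the five derived fractions.

    Metrics with a zero denominator are ``None`` (absent), never 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionMetrics:
    """Classify ``score >= cutoff`` as positive and tabulate against labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    pred = scores >= cutoff
    pos = labels == 1
    return ConfusionMetrics(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


@dataclass(frozen=True)
class StratifiedIncidence:
    rate_below: float
    rate_above: float
    events_below: int
    n_below: int
    events_above: int
    n_above: int
    p_value: float
    test: str  # "fisher" or "chi2_yates"


def stratified_incidence(scores, labels, cutoff: float) -> StratifiedIncidence:
    """Event rate below vs at/above a score cut-off, with an association test.

    Uses Fisher's exact test when any expected cell count is below 5,
    otherwise the Yates-corrected chi-square.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    above = scores >= cutoff
    n_above = int(above.sum())
    n_below = int(scores.size - n_above)
    if n_above == 0 or n_below == 0:
        raise DegenerateDataError("both strata must be nonempty")
    ev_above = int(labels[above].sum())
    ev_below = int(labels[~above].sum())
    table = np.array(
        [[ev_below, n_below - ev_below], [ev_above, n_above - ev_above]], dtype=float
    )
    rowsums = table.sum(axis=1, keepdims=True)
    colsums = table.sum(axis=0, keepdims=True)
    expected = rowsums * colsums / table.sum()
    if (expected < 5).any():
        _, p = sps.fisher_exact(table)
        test = "fisher"
    else:
        _, p = chi_square_2x2(
            ContingencyTable2x2(int(table[0, 0]), int(table[0, 1]),
                                int(table[1, 0]), int(table[1, 1]))
        )
        test = "chi2_yates"
    return StratifiedIncidence(
        rate_below=ev_below / n_below,
        rate_above=ev_above / n_above,
        events_below=ev_below,
        n_below=n_below,
        events_above=ev_above,
        n_above=n_above,
        p_value=float(p),
        test=test,
    )
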
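"""Inferential machinery: logistic MLE, AUC, DeLong, NRI, calibration, power.

Everything here is implemented from first principles against the standard
definitions — iteratively reweighted least squares for the logistic MLE,
the midrank Mann-Whitney AUC with DeLong placement-component variances, the
category-free net reclassification improvement, the Hosmer-Lemeshow
chi-square on predicted-risk quantile groups, and a Hanley-McNeil /
Monte-Carlo sample-size calculation for a single-ROC hypothesis test.
Established packages (statsmodels, scikit-learn) serve only as independent
cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "RocComparison",
    "NriResult",
    "CalibrationResult",
    "AucResult",
    "fit_logistic",
    "auc",
    "delong_test",
    "nri",
    "categorical_nri",
    "hosmer_lemeshow",
    "sample_size_auc",
]


# ---------------------------------------------------------------------------
# Logistic regression by IRLS

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``ci95`` is on the odds-ratio scale; separation is flagged and the
    affected intervals reported as unbounded.
    """

    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    ci95: np.ndarray            # (k, 2) odds-ratio scale
    loglik: float
    aic: float
    converged: bool
    separated: bool
    n_iter: int
    deviance_trace: np.ndarray
    fitted: np.ndarray

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "OR": self.odds_ratios,
                "OR 2.5%": self.ci95[:, 0],
                "OR 97.5%": self.ci95[:, 1],
                "p": self.p_values,
            },
            index=self.names,
        )

    def __str__(self) -> str:
        head = f"LogisticFit  loglik={self.loglik:.3f}  AIC={self.aic:.3f}"
        if self.separated:
            head += "  [separation detected]"
        elif not self.converged:
            head += "  [did not converge]"
        return head + "\n" + self.summary().to_string(float_format=lambda v: f"{v:.4g}")


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a logistic regression by IRLS with step-halving.

    Parameters
    ----------
    X : (n, k) full design matrix (include an intercept column yourself).
    y : (n,) binary outcomes; both classes must be present.
    tol : convergence tolerance on the max-norm of the score (gradient).
    max_iter : IRLS iteration cap.

    Raises
    ------
    ValueError
        On a rank-deficient design or a single-class outcome.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank-deficient")
    if names is None:
        names = [f"x{j}" for j in range(k)]

    beta = np.zeros(k)
    # start the intercept-like direction at the empirical log-odds if a
    # constant column exists; harmless otherwise
    const_cols = np.where(np.ptp(X, axis=0) == 0)[0]
    if const_cols.size:
        j = const_cols[0]
        beta[j] = np.log(y.mean() / (1 - y.mean())) / X[0, j]

    def deviance(b):
        eta = X @ b
        # log-likelihood via logaddexp for numerical safety
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -2.0 * ll

    dev = deviance(beta)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        XtWX = X.T @ (X * np.clip(w, 1e-10, None)[:, None])
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the deviance monotone non-increasing
        lam = 1.0
        new_dev = deviance(beta + lam * step)
        while new_dev > dev + 1e-12 and lam > 1e-10:
            lam /= 2.0
            new_dev = deviance(beta + lam * step)
        beta = beta + lam * step
        dev = new_dev
        trace.append(dev)
    else:
        it = max_iter

    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)

    separated = bool(np.max(np.abs(beta)) > 15 or np.min(mu * (1 - mu)) < 1e-10)
    zcrit = stats.norm.ppf(0.975)
    lo = beta - zcrit * se
    hi = beta + zcrit * se
    unbounded = separated & ((np.abs(beta) > 15) | (se > 100))
    if np.any(unbounded):
        lo = np.where(unbounded, -np.inf, lo)
        hi = np.where(unbounded, np.inf, hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    ll = -dev / 2.0
    return LogisticFit(
        names=list(names),
        coefficients=beta,
        standard_errors=se,
        p_values=p,
        ci95=np.exp(np.column_stack([lo, hi])),
        loglik=ll,
        aic=2 * k - 2 * ll,
        converged=converged,
        separated=separated,
        n_iter=it,
        deviance_trace=np.asarray(trace),
        fitted=mu,
    )


# ---------------------------------------------------------------------------
# AUC and the DeLong machinery

def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int).ravel()
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")
    return labels


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-observation placement values (structural components).

    V10[i] for event i is the fraction of non-events it outranks (ties half);
    V01[j] for non-event j the fraction of events outranking it. Midranks
    handle ties, so AUC = P(X>Y) + P(X=Y)/2 exactly.
    """
    scores = np.asarray(scores, dtype=float)
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = x.size, y.size
    r_all = stats.rankdata(np.concatenate([x, y]))
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    a = float(v10.mean())
    return a, v10, v01


@dataclass
class AucResult:
    """Mann-Whitney AUC with a DeLong-variance Wald confidence interval."""

    auc: float
    se: float
    ci95: tuple[float, float]
    n_events: int
    n_nonevents: int

    def __str__(self) -> str:
        return f"AUC {self.auc:.3f} (95% CI {self.ci95[0]:.3f}-{self.ci95[1]:.3f})"


def auc(scores, labels) -> AucResult:
    """AUC by the midrank Mann-Whitney estimator, CI from the DeLong variance."""
    labels = _check_labels(labels)
    a, v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    zcrit = stats.norm.ppf(0.975)
    ci = (max(0.0, a - zcrit * se), min(1.0, a + zcrit * se))
    return AucResult(auc=a, se=se, ci95=ci, n_events=m, n_nonevents=n)


@dataclass
class RocComparison:
    """Paired DeLong comparison of two correlated AUCs on the same cohort."""

    auc1: float
    auc2: float
    var_diff: float
    z: float
    p: float
    degenerate: bool = False

    def __str__(self) -> str:
        return (
            f"DeLong: AUC {self.auc1:.3f} vs {self.auc2:.3f}, "
            f"z = {self.z:.3f}, p = {self.p:.4f}"
        )


def delong_test(scores_a, scores_b, labels) -> RocComparison:
    """Two-sided paired DeLong test of AUC(a) vs AUC(b) on shared labels.

    The covariance of the two AUCs comes from the empirical covariances of
    the per-observation placement values. Identical score vectors give a
    zero-variance difference, reported as z = 0, p = 1 with a degeneracy flag.
    """
    labels = _check_labels(labels)
    a1, v10_1, v01_1 = _placements(scores_a, labels)
    a2, v10_2, v01_2 = _placements(scores_b, labels)
    m, n = v10_1.size, v01_1.size
    d10 = v10_1 - v10_2
    d01 = v01_1 - v01_2
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    if var <= 1e-16:
        return RocComparison(auc1=a1, auc2=a2, var_diff=0.0, z=0.0, p=1.0, degenerate=True)
    z = (a1 - a2) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return RocComparison(auc1=a1, auc2=a2, var_diff=float(var), z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# Net reclassification improvement

@dataclass
class NriResult:
    """Category-free NRI: net up-classification of events plus net
    down-classification of non-events; each component in [-1, 1]."""

    event_component: float
    nonevent_component: float
    nri: float
    z: float
    p: float

    def __str__(self) -> str:
        return (
            f"NRI {self.nri:.4f} (events {self.event_component:+.4f}, "
            f"non-events {self.nonevent_component:+.4f}), p = {self.p:.4f}"
        )


def _nri_from_moves(up_e, down_e, n_e, up_ne, down_ne, n_ne) -> NriResult:
    pe_up, pe_dn = up_e / n_e, down_e / n_e
    pn_up, pn_dn = up_ne / n_ne, down_ne / n_ne
    ev = pe_up - pe_dn
    ne = pn_dn - pn_up
    total = ev + ne
    var = (pe_up + pe_dn - ev**2) / n_e + (pn_up + pn_dn - ne**2) / n_ne
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = total / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    return NriResult(
        event_component=float(ev), nonevent_component=float(ne),
        nri=float(total), z=float(z), p=float(p),
    )


def nri(p_old, p_new, labels) -> NriResult:
    """Category-free (continuous) NRI of new vs old predicted probabilities.

    Any strict change in predicted risk counts as a move; the asymptotic z
    uses the standard multinomial variance of the two net components.
    """
    labels = _check_labels(labels)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    for p in (p_old, p_new):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("predicted probabilities must lie in [0, 1]")
    up = p_new > p_old
    down = p_new < p_old
    e = labels == 1
    return _nri_from_moves(
        up[e].sum(), down[e].sum(), e.sum(),
        up[~e].sum(), down[~e].sum(), (~e).sum(),
    )


def categorical_nri(p_old, p_new, labels, thresholds) -> NriResult:
    """NRI over user-supplied risk categories (provided for completeness)."""
    labels = _check_labels(labels)
    t = np.asarray(thresholds, dtype=float)
    c_old = np.searchsorted(t, np.asarray(p_old, dtype=float), side="right")
    c_new = np.searchsorted(t, np.asarray(p_new, dtype=float), side="right")
    up = c_new > c_old
    down = c_new < c_old
    e = labels == 1
    return _nri_from_moves(
        up[e].sum(), down[e].sum(), e.sum(),
        up[~e].sum(), down[~e].sum(), (~e).sum(),
    )


# ---------------------------------------------------------------------------
# Calibration

@dataclass
class CalibrationResult:
    """Quantile-group calibration table with the Hosmer-Lemeshow statistic."""

    groups: pd.DataFrame   # mean_predicted, observed, n, ci_low, ci_high
    hl_statistic: float
    hl_df: int
    hl_p: float

    def __str__(self) -> str:
        return (
            self.groups.to_string(float_format=lambda v: f"{v:.4f}")
            + f"\nHosmer-Lemeshow chi2 = {self.hl_statistic:.3f}, "
            f"df = {self.hl_df}, p = {self.hl_p:.4f}"
        )


def _wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    z = stats.norm.ppf(1 - alpha / 2)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def hosmer_lemeshow(p_pred, y, n_groups: int = 5) -> CalibrationResult:
    """Hosmer-Lemeshow goodness of fit over predicted-probability quantile groups.

    Groups default to quintiles. Ties at a quantile boundary collapse into the
    lower group; groups emptied by tie collapsing are merged (with a warning).
    chi2 = sum over groups of (O - E)^2 / (E (1 - E/n_g)) for events, on
    ``n_groups - 2`` degrees of freedom.
    """
    p = np.asarray(p_pred, dtype=float)
    y = _check_labels(y)
    n = p.size
    if n < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} observations for {n_groups} groups")
    qs = np.quantile(p, np.linspace(0, 1, n_groups + 1)[1:-1])
    # side='left': a prediction equal to a boundary stays in the lower group
    grp = np.searchsorted(qs, p, side="left")
    counts = np.bincount(grp, minlength=n_groups)
    if np.any(counts == 0):
        warnings.warn("empty calibration group after tie collapsing; merging", stacklevel=2)
        keep = np.flatnonzero(counts > 0)
        remap = {g: i for i, g in enumerate(keep)}
        grp = np.array([remap[g] for g in grp])
        n_groups = keep.size

    rows = []
    chi2 = 0.0
    for g in range(n_groups):
        sel = grp == g
        ng = int(sel.sum())
        obs = int(y[sel].sum())
        exp = float(p[sel].sum())
        mean_p = float(p[sel].mean())
        denom = exp * (1 - exp / ng)
        if denom > 0:
            chi2 += (obs - exp) ** 2 / denom
        lo, hi = _wilson_ci(obs, ng)
        rows.append({
            "mean_predicted": mean_p, "observed": obs / ng, "n": ng,
            "events": obs, "expected": exp, "ci_low": lo, "ci_high": hi,
        })
    df = max(n_groups - 2, 1)
    return CalibrationResult(
        groups=pd.DataFrame(rows),
        hl_statistic=float(chi2),
        hl_df=df,
        hl_p=float(stats.chi2.sf(chi2, df)),
    )


# ---------------------------------------------------------------------------
# Design-stage sample size for a single-ROC test

def _hanley_mcneil_var(a: float, m: int, n: int) -> float:
    """Hanley-McNeil variance of the AUC with m events / n non-events."""
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    return (a * (1 - a) + (m - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (m * n)


def sample_size_auc(
    auc_null: float,
    auc_alt: float,
    alpha: float = 0.05,
    power: float = 0.80,
    allocation: float = 0.5,
    method: str = "analytic",
    seed: int = 0,
    n_reps: int = 400,
    n_max: int = 200_000,
) -> int:
    """Smallest n whose test of AUC = auc_null attains the target power.

    Analytic method: Hanley-McNeil variances under null and alternative with
    the usual two-normal-quantile condition; Monte-Carlo method: binormal
    score simulation with a Wald test using the DeLong variance, binary
    search over n. ``allocation`` is the event fraction.

    Raises
    ------
    ValueError
        If ``auc_alt <= auc_null`` (the required n diverges).
    """
    if not (0.5 <= auc_null < 1 and 0 < auc_alt < 1):
        raise ValueError("AUCs must satisfy 0.5 <= auc_null < auc_alt < 1")
    if auc_alt <= auc_null:
        raise ValueError("auc_alt must exceed auc_null (required n diverges)")
    if not (0 < alpha < 1 and 0 < power < 1 and 0 < allocation < 1):
        raise ValueError("alpha, power and allocation must lie in (0, 1)")

    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)

    def analytic_ok(n_total: int) -> bool:
        m = max(int(round(allocation * n_total)), 1)
        n0 = max(n_total - m, 1)
        v0 = _hanley_mcneil_var(auc_null, m, n0)
        v1 = _hanley_mcneil_var(auc_alt, m, n0)
        return (auc_alt - auc_null) >= z_a * np.sqrt(v0) + z_b * np.sqrt(v1)

    def mc_power(n_total: int, rng: np.random.Generator) -> float:
        m = max(int(round(allocation * n_total)), 2)
        n0 = max(n_total - m, 2)
        sep = np.sqrt(2.0) * stats.norm.ppf(auc_alt)
        se0 = np.sqrt(_hanley_mcneil_var(auc_null, m, n0))  # null-hypothesis SE
        rejections = 0
        for _ in range(n_reps):
            x = rng.normal(sep, 1.0, m)
            yv = rng.normal(0.0, 1.0, n0)
            scores = np.concatenate([x, yv])
            labels = np.concatenate([np.ones(m, int), np.zeros(n0, int)])
            res = auc(scores, labels)
            if (res.auc - auc_null) / se0 > z_a:
                rejections += 1
        return rejections / n_reps

    if method == "analytic":
        ok = analytic_ok
    elif method == "monte-carlo":
        rng = np.random.default_rng(seed)
        ok = lambda n_total: mc_power(n_total, rng) >= power  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")

    lo, hi = 10, 10
    while not ok(hi):
        hi *= 2
        if hi > n_max:
            raise ValueError(f"required n exceeds n_max = {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return int(lo)
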
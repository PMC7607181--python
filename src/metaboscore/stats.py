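"""Cohort statistics implemented from first principles.

Mann-Whitney U (exact enumeration for small tie-free samples, otherwise
tie-corrected normal approximation with continuity correction),
Spearman rank correlation, Kaplan-Meier product-limit estimation with
Greenwood confidence bands, the k-sample logrank test, and Cox
proportional-hazards regression with Breslow tie handling, plus the
cohort filters used around them (early-death exclusion, median split).

Times are months as real numbers throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MWU_MAX_N = 12  # combined-sample size below which the exact null is used


class InsufficientDataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (non-convergence or separation)."""


@dataclass
class TestResult:
    method: str
    statistic: float
    pvalue: float
    effect_name: str = ""
    effect: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    n: tuple = ()
    df: Optional[float] = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isnan(self.pvalue) and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.pvalue}")
        if not (math.isnan(self.ci_low) or math.isnan(self.ci_high)) and self.ci_low > self.ci_high:
            raise ValueError("CI bounds out of order")


# ---------------------------------------------------------------------------
# rank helpers

def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple:
    """Number of rank configurations yielding each U value under the null.

    Recurrence N(n1, n2; u) = N(n1-1, n2; u-n2) + N(n1, n2-1; u).
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_null_counts(n1 - 1, n2)
    b = _u_null_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney(x: Sequence[float], y: Sequence[float], mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode``: "auto" uses the exact null when n1+n2 <= 12 and there are
    no ties, otherwise the normal approximation with tie-corrected
    variance and a continuity correction; "exact"/"asymptotic" force a
    route.  The reported U counts pairs where x exceeds y (ties half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _average_ranks(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if np.all(pooled == pooled[0]):
        return TestResult("mann_whitney", statistic=u, pvalue=1.0,
                          effect_name="U", effect=u, n=(n1, n2),
                          flags={"zero_variance": True, "exact": False})

    if mode == "exact" and has_ties:
        raise ValueError("exact mode is only defined for tie-free samples")
    use_exact = (mode == "exact") or (mode == "auto" and n1 + n2 <= EXACT_MWU_MAX_N and not has_ties)

    mu = n1 * n2 / 2.0
    if use_exact:
        counts = np.asarray(_u_null_counts(n1, n2), dtype=float)
        total = counts.sum()
        dev = abs(u - mu)
        us = np.arange(len(counts))
        p = float(counts[np.abs(us - mu) >= dev - 1e-12].sum() / total)
        return TestResult("mann_whitney", statistic=u, pvalue=min(p, 1.0),
                          effect_name="U", effect=u, n=(n1, n2),
                          flags={"exact": True, "ties": False})

    n = n1 + n2
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult("mann_whitney", statistic=u, pvalue=1.0,
                          effect_name="U", effect=u, n=(n1, n2),
                          flags={"zero_variance": True, "exact": False})
    diff = u - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))
    return TestResult("mann_whitney", statistic=u, pvalue=p,
                      effect_name="U", effect=u, n=(n1, n2),
                      flags={"exact": False, "ties": has_ties, "tie_correction": True})


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman's rho as the Pearson correlation of average ranks.

    p-value from the t approximation with n-2 degrees of freedom.
    Constant input yields an undefined rho (flagged, rho = nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must be paired")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("spearman needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult("spearman", statistic=math.nan, pvalue=math.nan,
                          effect_name="rho", effect=math.nan, n=(n,),
                          flags={"constant_input": True})
    rx, ry = _average_ranks(x), _average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return TestResult("spearman", statistic=rho, pvalue=min(p, 1.0),
                      effect_name="rho", effect=rho, n=(n,), df=n - 2)


# ---------------------------------------------------------------------------
# survival

def filter_survival(records: pd.DataFrame, exclusion_window_months: float = 1.0,
                    time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Drop deaths within the first ``exclusion_window_months`` after surgery.

    Censored records inside the window are retained; only events are
    excluded.  The number of removals is recorded in
    ``result.attrs["n_excluded_early_deaths"]``.
    """
    early = records[event_col].astype(bool) & (records[time_col] <= exclusion_window_months)
    out = records.loc[~early].copy()
    out.attrs["n_excluded_early_deaths"] = int(early.sum())
    return out


def km_estimate(times: Sequence[float], events: Sequence[bool],
                conf_level: float = 0.95) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with Greenwood 95% CI.

    Returns a step-function table (time, n_risk, n_events, n_censored,
    survival, ci_low, ci_high) with a leading row at t = 0, S = 1.
    The CI uses the Greenwood variance on the log scale:
    exp(log S +/- z * sqrt(sum d/(n(n-d)))).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise InsufficientDataError("no records")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    z = float(sps.norm.ppf(0.5 + conf_level / 2.0))

    rows = [dict(time=0.0, n_risk=len(times), n_events=0, n_censored=0,
                 survival=1.0, ci_low=1.0, ci_high=1.0)]
    s = 1.0
    greenwood = 0.0
    n_risk = len(times)
    for t in np.unique(times):
        at_t = times == t
        d = int((at_t & events).sum())
        c = int((at_t & ~events).sum())
        if d > 0:
            s *= 1.0 - d / n_risk
            if n_risk > d:
                greenwood += d / (n_risk * (n_risk - d))
                half = z * math.sqrt(greenwood)
                lo = s * math.exp(-half)
                hi = min(1.0, s * math.exp(half))
            else:
                lo, hi = 0.0, 0.0 if s == 0 else 1.0
            rows.append(dict(time=float(t), n_risk=n_risk, n_events=d, n_censored=c,
                             survival=s, ci_low=lo, ci_high=hi))
        elif c > 0:
            rows.append(dict(time=float(t), n_risk=n_risk, n_events=0, n_censored=c,
                             survival=s,
                             ci_low=rows[-1]["ci_low"], ci_high=rows[-1]["ci_high"]))
        n_risk -= d + c
    return pd.DataFrame(rows)


def logrank(times: Sequence[float], events: Sequence[bool],
            groups: Sequence) -> TestResult:
    """k-sample logrank test (chi-square with k-1 df).

    Observed-minus-expected event counts are summed over event times
    with the hypergeometric variance-covariance; groups never at risk
    are excluded with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups) if (groups == g).any()]
    empty = [g for g in labels if not np.any(groups == g)]
    if empty:  # pragma: no cover - pd.unique only returns present labels
        warnings.warn(f"groups with no subjects excluded: {empty}")
        labels = [g for g in labels if g not in empty]
    k = len(labels)
    if k < 2:
        raise InsufficientDataError("logrank needs at least two groups")
    if not events.any():
        raise InsufficientDataError("logrank needs at least one event")

    gidx = np.array([labels.index(g) for g in groups])
    event_times = np.unique(times[events])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_j = int(at_risk.sum())
        d_j = int((events & (times == t)).sum())
        if n_j == 0:
            continue
        n_gj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(gidx[events & (times == t)], minlength=k).astype(float)
        e_gj = d_j * n_gj / n_j
        o_minus_e += d_gj - e_gj
        if n_j > 1:
            factor = d_j * (n_j - d_j) / (n_j - 1.0)
            p = n_gj / n_j
            cov += factor * (np.diag(p) - np.outer(p, p))

    v = cov[: k - 1, : k - 1]
    z = o_minus_e[: k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(v) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return TestResult("logrank", statistic=chi2, pvalue=p, effect_name="chi2",
                      effect=chi2, n=tuple(int((gidx == i).sum()) for i in range(k)),
                      df=df)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)

def _encode_covariates(records: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list]:
    """Numeric covariates pass through; categoricals become indicator
    contrasts with the first (sorted) level as reference."""
    cols, names = [], []
    for c in covariates:
        s = records[c]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
        else:
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev} vs {levels[0]}]")
    if not cols:
        raise ValueError("no covariates to fit")
    return np.column_stack(cols), names


def _breslow_loglik(beta: np.ndarray, x: np.ndarray, times: np.ndarray,
                    events: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood, score and information.

    Records must be sorted by descending time so risk sets accumulate.
    """
    n, p = x.shape
    eta = x @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[i]
        j = i
        while j < n and times[j] == t:
            s0 += w[j]
            s1 += w[j] * x[j]
            s2 += w[j] * np.outer(x[j], x[j])
            j += 1
        d_idx = [m for m in range(i, j) if events[m]]
        d = len(d_idx)
        if d > 0:
            xsum = x[d_idx].sum(axis=0)
            loglik += float(eta[d_idx].sum()) - d * math.log(s0)
            mean = s1 / s0
            score += xsum - d * mean
            info += d * (s2 / s0 - np.outer(mean, mean))
        i = j
    return loglik, score, info


def cox_ph(records: pd.DataFrame, covariates: Sequence[str],
           time_col: str = "time", event_col: str = "event",
           ties: str = "breslow", tol: float = 1e-8,
           max_iter: int = 50) -> pd.DataFrame:
    """Cox proportional-hazards regression via Newton-Raphson.

    Breslow tie handling (the only implemented method; ``ties`` is
    validated so callers relying on Efron fail loudly).  Returns one row
    per encoded covariate with coef, HR, standard error, Wald 95% CI
    and p.  Raises :class:`ConvergenceError` on non-convergence or
    separation (monotone likelihood).
    """
    if ties != "breslow":
        raise NotImplementedError(f"tie method {ties!r} not implemented (breslow only)")
    df = records.dropna(subset=[time_col, event_col, *covariates])
    times = df[time_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=bool)
    if not events.any():
        raise InsufficientDataError("no events")
    x, names = _encode_covariates(df, covariates)
    x = x - x.mean(axis=0)  # centering for numerical stability
    order = np.argsort(-times, kind="mergesort")
    x, times, events = x[order], times[order], events[order]

    beta = np.zeros(x.shape[1])
    loglik, score, info = _breslow_loglik(beta, x, times, events)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix: {e}") from e
        # step-halving if the likelihood does not improve
        for _ in range(30):
            cand = beta + step
            ll_new, sc_new, in_new = _breslow_loglik(cand, x, times, events)
            if ll_new >= loglik - 1e-12:
                break
            step /= 2.0
        beta, loglik, score, info = cand, ll_new, sc_new, in_new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError("separation suspected (diverging coefficients)")
    else:
        if np.max(np.abs(score)) < tol:
            converged = True
    if not converged:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations")
    if np.max(np.abs(beta)) > 15:
        raise ConvergenceError("separation suspected (monotone partial likelihood)")

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as e:
        raise ConvergenceError(f"information matrix not invertible at optimum: {e}") from e
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    zcrit = float(sps.norm.ppf(0.975))
    return pd.DataFrame({
        "covariate": names,
        "coef": beta,
        "hr": np.exp(beta),
        "se": se,
        "hr_ci_low": np.exp(beta - zcrit * se),
        "hr_ci_high": np.exp(beta + zcrit * se),
        "z": z,
        "pvalue": 2.0 * sps.norm.sf(np.abs(z)),
        "n": len(times),
        "n_events": int(events.sum()),
        "loglik": loglik,
        "ties": "breslow",
    })


def median_split(values: Sequence[float]) -> np.ndarray:
    """Label each value "high" (> median) or "low" (<= median).

    Ties at the median go to "low".  All-equal input is an error since
    it yields a single group.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InsufficientDataError("median split needs n >= 2")
    if np.all(values == values[0]):
        raise ValueError("all values equal: median split yields a single group")
    med = float(np.median(values))
    return np.where(values > med, "high", "low")
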
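"""Survival analysis: Kaplan-Meier, log-rank and Cox proportional hazards.

The Cox model is fitted by Newton iteration on the partial likelihood with
Efron (default) or Breslow handling of tied event times; Wald confidence
intervals and p-values are reported, and the score test at beta = 0 is
exposed (with Breslow ties and no tied events it equals the log-rank
statistic). Censoring convention: at equal times, events precede
censorings (censored subjects at an event time are still at risk).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .intervals import ValidationError


@dataclass
class CoxResult:
    """One covariate's Cox fit summary."""

    covariate: str
    beta: float
    hr: float
    ci95_low: float
    ci95_high: float
    p: float
    flagged: bool = False


@dataclass
class CoxFit:
    results: list[CoxResult]
    converged: bool
    n_iter: int
    score_chi2_at_zero: float
    log_likelihood: float
    covariance: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, covariate: str) -> CoxResult:
        for r in self.results:
            if r.covariate == covariate:
                return r
        raise KeyError(covariate)


def _check_surv(time: np.ndarray, event: np.ndarray) -> None:
    if time.size == 0:
        raise ValidationError("empty survival data")
    if not np.isfinite(time).all() or (time <= 0).any():
        raise ValidationError("times must be finite and positive")
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event flags must be 0/1")


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit survival estimate for one group.

    Returns a DataFrame with one row per distinct event time: columns
    time, at_risk, events, survival (S non-increasing, S before the first
    event time is 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_surv(time, event)
    if event.sum() == 0:
        warnings.warn("no events; survival curve is flat at 1")
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    n = time.size
    rows = []
    s = 1.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        d = 0
        while j < n and time[j] == t:
            d += int(event[j])
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((t, at_risk, d, s))
        i = j
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def kaplan_meier_by_group(time, event, group) -> dict[str, pd.DataFrame]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    return {
        str(g): kaplan_meier(time[group == g], event[group == g])
        for g in np.unique(group)
    }


def logrank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed-minus-expected events in group
    1 are accumulated with the hypergeometric variance; chi2 = (O-E)^2 / V
    with p from chi-square on 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    _check_surv(time, event)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValidationError(f"logrank requires exactly 2 groups, got {labels.size}")
    g1 = group == labels[0]
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(_sps.chi2.sf(chi2, df=1))


def _cox_derivatives(beta, x, time, event, ties):
    """Log partial likelihood, score and information at ``beta``.

    Rows must be pre-sorted by descending time so risk sets are prefix
    sums.
    """
    n, p = x.shape
    eta = x @ beta
    eta -= eta.max()  # stabilise exponentials
    r = np.exp(eta)
    rx = r[:, None] * x
    rxx = rx[:, :, None] * x[:, None, :]
    cum_r = np.cumsum(r)
    cum_rx = np.cumsum(rx, axis=0)
    cum_rxx = np.cumsum(rxx, axis=0)

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        ev = [k for k in range(i, j) if event[k] == 1]
        d = len(ev)
        if d > 0:
            # risk set = rows 0..j-1 (times >= t)
            s0 = cum_r[j - 1]
            s1 = cum_rx[j - 1]
            s2 = cum_rxx[j - 1]
            xe = x[ev]
            ll += eta[ev].sum()  # shifted by the same constant as log(s0); cancels
            if ties == "breslow" or d == 1:
                ll -= d * math.log(s0)
                mean = s1 / s0
                score += xe.sum(axis=0) - d * mean
                info += d * (s2 / s0 - np.outer(mean, mean))
            else:  # efron
                rd = r[ev].sum()
                sd1 = rx[ev].sum(axis=0)
                sd2 = rxx[ev].sum(axis=0)
                for l in range(d):
                    f = l / d
                    s0l = s0 - f * rd
                    s1l = s1 - f * sd1
                    s2l = s2 - f * sd2
                    ll -= math.log(s0l)
                    mean = s1l / s0l
                    score += xe[l] - mean
                    info += s2l / s0l - np.outer(mean, mean)
        i = j
    return ll, score, info


def cox_ph(
    covariates: pd.DataFrame,
    time,
    event,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards regression by Newton iteration.

    ``covariates`` is an n x p numeric DataFrame (one-hot categorical
    covariates with an explicit reference level are the caller's job).
    Convergence when max |score| < ``tol`` or after ``max_iter``
    iterations. Non-convergence or monotone likelihood (perfect
    separation) is flagged with infinite confidence intervals rather than
    reported silently; constant covariates are flagged non-identifiable.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"ties must be efron or breslow, got {ties!r}")
    x_df = covariates.astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_surv(time, event)
    if event.sum() == 0:
        raise ValidationError("at least one event is required")
    if len(x_df) != time.size:
        raise ValidationError("covariates and times disagree in length")

    constant = [c for c in x_df.columns if x_df[c].nunique() <= 1]
    usable = [c for c in x_df.columns if c not in constant]
    names = list(x_df.columns)

    order = np.argsort(-time, kind="mergesort")
    x = x_df[usable].to_numpy()[order]
    t_sorted = time[order]
    e_sorted = event[order]
    # centre covariates for numerical stability; beta is unaffected
    centre = x.mean(axis=0) if x.size else np.zeros(0)
    xc = x - centre
    p = len(usable)

    beta = np.zeros(p)
    ll0, score0, info0 = _cox_derivatives(beta, xc, t_sorted, e_sorted, ties)
    try:
        score_chi2 = float(score0 @ np.linalg.solve(info0, score0)) if p else 0.0
    except np.linalg.LinAlgError:
        score_chi2 = math.nan

    converged = False
    n_iter = 0
    ll = ll0
    if p:
        for n_iter in range(1, max_iter + 1):
            ll, score, info = _cox_derivatives(beta, xc, t_sorted, e_sorted, ties)
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                break
            # step-halving to keep the likelihood increasing
            new_beta = beta + step
            new_ll = _cox_derivatives(new_beta, xc, t_sorted, e_sorted, ties)[0]
            halvings = 0
            while new_ll < ll and halvings < 10:
                step /= 2.0
                new_beta = beta + step
                new_ll = _cox_derivatives(new_beta, xc, t_sorted, e_sorted, ties)[0]
                halvings += 1
            beta = new_beta
        else:
            n_iter = max_iter
        ll, score, info = _cox_derivatives(beta, xc, t_sorted, e_sorted, ties)
        if np.max(np.abs(score)) < tol:
            converged = True
    else:
        converged = True
        info = np.zeros((0, 0))

    separated = np.abs(beta) > 15  # |log HR| > 15: monotone likelihood
    if not converged or separated.any():
        warnings.warn("Cox fit did not converge cleanly (possible separation)")

    cov = np.full((p, p), np.nan)
    se = np.full(p, np.inf)
    if p and converged and not separated.any():
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            pass

    z975 = _sps.norm.ppf(0.975)
    results: list[CoxResult] = []
    usable_idx = {c: k for k, c in enumerate(usable)}
    for name in names:
        if name in constant:
            results.append(
                CoxResult(name, math.nan, math.nan, math.nan, math.nan, math.nan, flagged=True)
            )
            continue
        k = usable_idx[name]
        b = float(beta[k])
        s = float(se[k])
        flagged = not converged or bool(separated[k]) or not math.isfinite(s)
        if math.isfinite(s) and s > 0:
            lo, hi = math.exp(b - z975 * s), math.exp(b + z975 * s)
            pv = min(1.0, 2.0 * float(_sps.norm.sf(abs(b) / s)))
        else:
            lo, hi, pv = 0.0, math.inf, math.nan
        results.append(CoxResult(name, b, math.exp(b), lo, hi, pv, flagged=flagged))
    return CoxFit(
        results=results,
        converged=converged,
        n_iter=n_iter,
        score_chi2_at_zero=score_chi2,
        log_likelihood=float(ll),
        covariance=cov,
    )


def write_cox_table(fit: CoxFit, path) -> None:
    with open(path, "w") as fh:
        fh.write("covariate\tbeta\tHR\tci95_low\tci95_high\tp\tflagged\n")
        for r in fit.results:
            fh.write(
                f"{r.covariate}\t{r.beta:.6g}\t{r.hr:.6g}\t{r.ci95_low:.6g}\t"
                f"{r.ci95_high:.6g}\t{r.p:.6g}\t{r.flagged}\n"
            )


def write_km_table(curves: dict[str, pd.DataFrame], path) -> None:
    with open(path, "w") as fh:
        fh.write("group\ttime\tat_risk\tevents\tsurvival\n")
        for g in sorted(curves):
            for _, row in curves[g].iterrows():
                fh.write(
                    f"{g}\t{row['time']:.6g}\t{int(row['at_risk'])}\t"
                    f"{int(row['events'])}\t{row['survival']:.6g}\n"
                )
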
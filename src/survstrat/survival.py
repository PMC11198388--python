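"""Right-censored survival estimators.

Implements the estimators everything else in the package is built on:
Nelson-Aalen cumulative hazard, per-subject log-rank scores, the
Kaplan-Meier product-limit curve with Greenwood variance, and Cox
proportional-hazards regression by Newton optimisation of the partial
likelihood (Efron or Breslow tie handling) with Wald inference.

Conventions
-----------
* The risk set at time t is ``{i : time_i >= t}``; subjects censored at an
  event time are therefore still at risk at that instant (events precede
  censorings).
* All times are strictly positive and measured in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalData",
    "StepFunction",
    "KMCurve",
    "CoxFit",
    "CoxError",
    "SeparationError",
    "nelson_aalen",
    "logrank_scores",
    "kaplan_meier",
    "survival_at",
    "cox_fit",
    "cox_hr_table",
]


class CoxError(ValueError):
    """Cox model could not be estimated (no events, bad input...)."""


class SeparationError(CoxError):
    """Monotone partial likelihood: a covariate perfectly orders the events."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(
            f"monotone partial likelihood: covariate {covariate!r} appears to "
            "separate the event ordering perfectly; no finite estimate exists"
        )


@dataclass(frozen=True)
class SurvivalData:
    """Follow-up times (years, > 0) and event indicators (1=death, 0=censored)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.ndim != 1 or event.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if time.size == 0:
            raise ValueError("empty survival data")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("times must be finite and strictly positive")
        if not np.all((event == 0) | (event == 1)):
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with jumps at ``x`` reaching ``y``."""

    x: np.ndarray  # strictly increasing jump locations
    y: np.ndarray  # value attained at (and after) each jump

    def __call__(self, t):
        """Evaluate at ``t`` (scalar or array); value before the first jump is 0."""
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.y])
        out = padded[idx]
        return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier curve: survival steps with Greenwood variances."""

    time: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray  # Greenwood variance of S at each event time

    def survival_at(self, t):
        return survival_at(self, t)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time,
                "survival": self.survival,
                "variance": self.variance,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def _event_table(data: SurvivalData):
    """Distinct event times with event counts and at-risk counts."""
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    e = data.event[order]
    uniq, start = np.unique(t, return_index=True)
    n = t.size
    # events per distinct time
    d = np.add.reduceat(e, start)
    # at risk: everyone with time >= uniq (censored at the same instant included)
    at_risk = n - start
    mask = d > 0
    return uniq[mask], d[mask], at_risk[mask]


def nelson_aalen(data: SurvivalData) -> StepFunction:
    """Nelson-Aalen cumulative-hazard estimator Λ̂(t) = Σ_{t_j<=t} d_j/n_j."""
    times, d, n = _event_table(data)
    if times.size == 0:
        return StepFunction(x=np.empty(0), y=np.empty(0))
    return StepFunction(x=times, y=np.cumsum(d / n))


def logrank_scores(data: SurvivalData) -> np.ndarray:
    """Per-subject log-rank scores a_i = δ_i − Λ̂(t_i).

    These are the martingale-type residuals whose group sums form
    log-rank statistics; with the at-risk convention used here they sum
    to zero exactly (up to float round-off).
    """
    cumhaz = nelson_aalen(data)
    return data.event - cumhaz(data.time)


def kaplan_meier(data: SurvivalData) -> KMCurve:
    """Product-limit estimator with Greenwood variance."""
    times, d, n = _event_table(data)
    frac = 1.0 - d / n
    surv = np.cumprod(frac)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_j<=t} d_j / (n_j (n_j - d_j))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    # S hits exactly 0 when the last risk set empties; variance is 0 there
    var = np.where(surv > 0, surv**2 * np.cumsum(terms), 0.0)
    return KMCurve(time=times, survival=surv, at_risk=n, n_events=d, variance=var)


def survival_at(curve: KMCurve, t) -> float:
    """Right-continuous lookup of S(t); S(t)=1 before the first event."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival requested at negative time")
    idx = np.searchsorted(curve.time, t_arr, side="right")
    padded = np.concatenate([[1.0], curve.survival])
    out = padded[idx]
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class CoxFit:
    """Fitted Cox proportional-hazards model with Wald inference."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    ties: str
    n: int = 0
    n_events: int = 0

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )


def _cox_loglik(beta, x, event, start_idx, d_counts, ties):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    ``x`` is sorted by ascending time; ``start_idx`` marks the first row of
    each distinct-time block, ``d_counts`` the number of events per block.
    Blocks with a single event use the (identical) Breslow form and are
    fully vectorised; only blocks with tied events are looped over.
    """
    n, p = x.shape
    eta = x @ beta
    eta = eta - eta.max()  # guard exp overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]

    # risk-set sums at the start of each distinct-time block
    s0_all = np.cumsum(w[::-1])[::-1]
    s1_all = np.cumsum(wx[::-1], axis=0)[::-1]
    s2_all = np.cumsum(wxx[::-1], axis=0)[::-1]
    s0_b = s0_all[start_idx]
    s1_b = s1_all[start_idx]
    s2_b = s2_all[start_idx]

    ex = event[:, None] * x
    xsum_b = np.add.reduceat(ex, start_idx, axis=0)
    etasum_b = np.add.reduceat(event * eta, start_idx)

    has_event = d_counts > 0
    simple = has_event & ((d_counts == 1) | (ties == "breslow"))
    d = d_counts[simple].astype(float)
    s0 = s0_b[simple]
    s1 = s1_b[simple]
    s2 = s2_b[simple]
    loglik = float(etasum_b[simple].sum() - (d * np.log(s0)).sum())
    grad = xsum_b[simple].sum(axis=0) - (d[:, None] * s1 / s0[:, None]).sum(axis=0)
    ratio = s1 / s0[:, None]
    hess = -(
        np.einsum("b,bij->ij", d / s0, s2)
        - np.einsum("b,bi,bj->ij", d, ratio, ratio)
    )

    tied = np.flatnonzero(has_event & ~simple)
    if tied.size:  # Efron correction for tied event times, vectorised
        ew = event * w
        t0_b = np.add.reduceat(ew, start_idx)[tied]
        t1_b = np.add.reduceat(event[:, None] * wx, start_idx, axis=0)[tied]
        t2_b = np.add.reduceat(event[:, None, None] * wxx, start_idx, axis=0)[tied]
        ds = d_counts[tied]
        # expand each tied block into its d within-block steps k = 0..d-1
        rep = np.repeat(np.arange(tied.size), ds)
        starts = np.cumsum(ds) - ds
        k = np.arange(int(ds.sum())) - np.repeat(starts, ds)
        f = k / ds[rep]
        den0 = s0_b[tied][rep] - f * t0_b[rep]
        den1 = s1_b[tied][rep] - f[:, None] * t1_b[rep]
        den2 = s2_b[tied][rep] - f[:, None, None] * t2_b[rep]
        loglik += float(etasum_b[tied].sum() - np.log(den0).sum())
        grad += xsum_b[tied].sum(axis=0) - (den1 / den0[:, None]).sum(axis=0)
        hess -= np.einsum("a,aij->ij", 1.0 / den0, den2) - np.einsum(
            "a,ai,aj->ij", 1.0 / den0**2, den1, den1
        )
    return loglik, grad, hess


def cox_fit(
    covariates,
    data: SurvivalData,
    ties: str = "efron",
    names=None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    covariates : (n, p) array-like
        Covariate matrix; a 1-d array is treated as a single covariate.
    data : SurvivalData
    ties : {"efron", "breslow"}
        Tie correction for the partial likelihood.
    names : optional list of covariate names (used in error messages and
        the summary table).

    Newton-Raphson from β=0 with step-halving whenever a step decreases
    the partial likelihood; convergence requires the max-norm of the
    gradient below ``tol`` scaled by the likelihood magnitude (or a
    Newton step too small to matter). Standard errors come from the inverse observed
    information; CIs and p-values are Wald (normal reference).
    """
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if n != data.n:
        raise ValueError("covariate rows must match survival data length")
    if data.n_events == 0:
        raise CoxError("cannot fit a Cox model with no events")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite (no missing values)")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)

    order = np.argsort(data.time, kind="stable")
    xs = x[order]
    ev = data.event[order]
    ts = data.time[order]
    center = xs.mean(axis=0)
    xs = xs - center  # numerical stabilisation; β is shift-invariant

    _, start_idx = np.unique(ts, return_index=True)
    d_counts = np.add.reduceat(ev, start_idx)

    # a covariate constant across all rows cannot be estimated
    spread = xs.max(axis=0) - xs.min(axis=0)
    for j in np.flatnonzero(spread == 0):
        raise CoxError(f"covariate {names[j]!r} is constant; coefficient not identifiable")

    beta = np.zeros(p)
    loglik, grad, hess = _cox_loglik(beta, xs, ev, start_idx, d_counts, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # gradient tolerance is scaled by the likelihood magnitude so large
        # cohorts are not held to an unreachable absolute float precision
        gtol = tol * max(1.0, abs(loglik))
        if np.abs(grad).max() < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        new_beta = beta + step
        new = _cox_loglik(new_beta, xs, ev, start_idx, d_counts, ties)
        slack = 1e-12 * max(1.0, abs(loglik))
        halvings = 0
        while new[0] < loglik - slack and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new = _cox_loglik(new_beta, xs, ev, start_idx, d_counts, ties)
            halvings += 1
        beta = new_beta
        loglik, grad, hess = new
        if np.abs(step).max() < 1e-10:
            converged = True
            break
        if np.abs(beta).max() > 40:
            raise SeparationError(names[int(np.argmax(np.abs(beta)))])
    else:
        if np.abs(grad).max() < tol * max(1.0, abs(loglik)):
            converged = True
    # a monotone likelihood flattens out at huge |β|, so the gradient test
    # can "converge" on the way to infinity; treat that as separation too
    if not converged or np.abs(beta).max() > 20:
        raise SeparationError(names[int(np.argmax(np.abs(beta)))])

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - zcrit * se),
        ci_high=np.exp(beta + zcrit * se),
        p=pvals,
        log_likelihood=float(loglik),
        converged=converged,
        n_iter=it,
        ties=ties,
        n=n,
        n_events=data.n_events,
    )


def cox_hr_table(leaf_labels, data: SurvivalData, reference, ties: str = "efron"):
    """Per-group hazard ratios versus a reference group.

    Groups are one-hot coded with the reference omitted; the fitted HRs,
    95% CIs and Wald p-values are returned as a DataFrame sorted by HR
    ascending, with the reference row first (HR = 1 by construction).
    Groups without any event get a non-estimable flag rather than a crash.
    """
    import pandas as pd

    labels = np.asarray(leaf_labels)
    if labels.size != data.n:
        raise ValueError("labels must match survival data length")
    uniq = list(pd.unique(labels))
    if reference not in uniq:
        raise ValueError(f"reference group {reference!r} not present")
    if len(uniq) < 2:
        raise ValueError("need at least two groups for a hazard-ratio table")

    others = [u for u in uniq if u != reference]
    events_by = {u: int(data.event[labels == u].sum()) for u in uniq}
    estimable = [u for u in others if events_by[u] > 0]
    rows = []
    ref_mask = labels == reference
    rows.append(
        {
            "group": reference,
            "n": int(ref_mask.sum()),
            "events": events_by[reference],
            "hr": 1.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "reference": True,
            "estimable": True,
        }
    )
    if estimable:
        keep = ref_mask | np.isin(labels, estimable)
        sub = SurvivalData(data.time[keep], data.event[keep])
        x = np.column_stack([(labels[keep] == u).astype(float) for u in estimable])
        fit = cox_fit(x, sub, ties=ties, names=[str(u) for u in estimable])
        for j, u in enumerate(estimable):
            rows.append(
                {
                    "group": u,
                    "n": int((labels == u).sum()),
                    "events": events_by[u],
                    "hr": fit.hr[j],
                    "ci_low": fit.ci_low[j],
                    "ci_high": fit.ci_high[j],
                    "p": fit.p[j],
                    "reference": False,
                    "estimable": True,
                }
            )
    for u in others:
        if u not in estimable:
            rows.append(
                {
                    "group": u,
                    "n": int((labels == u).sum()),
                    "events": 0,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "reference": False,
                    "estimable": False,
                }
            )
    table = pd.DataFrame(rows)
    table = table.sort_values("hr", na_position="last", kind="stable").reset_index(drop=True)
    return table
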
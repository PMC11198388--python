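"""Univariate Cox screening and bootstrap stepwise stability selection.

The variable-selection stage of the analysis: every recorded covariate is
first screened with a univariate Cox model; then, within each variable
domain (clinical / echocardiographic / laboratory), a forward/backward
stepwise Cox procedure is refitted on bootstrap resamples of the cohort
and a covariate is retained when it appears in at least a threshold
fraction (85% by default) of the resampled final models. The union of the
retained sets across the three domains supplies the covariates for the
survival tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .survival import CoxError, SurvivalData, cox_fit

__all__ = [
    "ScreenTable",
    "SelectionReport",
    "univariate_screen",
    "stepwise_cox",
    "bootstrap_selection",
]


def univariate_screen(cohort: pd.DataFrame, variables, data: SurvivalData,
                      ties: str = "efron") -> pd.DataFrame:
    """Single-covariate Cox screen of every variable.

    Returns one row per variable with the per-unit HR (and per-SD HR for
    non-binary variables), 95% CI, Wald p, n and events. Variables whose
    fit fails (constant column, separation) come back flagged rather than
    aborting the screen.
    """
    rows = []
    for name in variables:
        x = np.asarray(cohort[name], dtype=float)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        binary = set(np.unique(x)) <= {0.0, 1.0}
        row = {
            "variable": name,
            "n": data.n,
            "events": data.n_events,
            "failed": False,
            "reason": "",
        }
        try:
            fit = cox_fit(x, data, ties=ties, names=[name])
            row.update(
                hr=float(fit.hr[0]),
                ci_low=float(fit.ci_low[0]),
                ci_high=float(fit.ci_high[0]),
                p=float(fit.p[0]),
                hr_per_sd=float(np.exp(fit.coef[0] * sd)) if not binary else np.nan,
            )
        except (CoxError, ValueError) as exc:
            row.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                       hr_per_sd=np.nan, failed=True, reason=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


#: alias documenting the screen-table shape
ScreenTable = pd.DataFrame


def stepwise_cox(cohort: pd.DataFrame, candidates, data: SurvivalData,
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 ties: str = "efron", max_steps: int = 50) -> list:
    """Forward/backward stepwise Cox selection by Wald p-value.

    Repeatedly adds the not-yet-included candidate with the smallest Wald
    p-value (if below ``p_enter``), then removes included variables whose
    Wald p exceeds ``p_remove``, until the model stops changing or the
    iteration cap is hit. Candidates whose fit fails in a given step are
    skipped for that step. Deterministic given the data; ties are broken
    by candidate order.
    """
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove")
    candidates = list(candidates)
    included: list = []
    for _ in range(max_steps):
        changed = False
        # forward step
        best_name, best_p = None, np.inf
        for name in candidates:
            if name in included:
                continue
            cols = included + [name]
            try:
                fit = cox_fit(cohort[cols].to_numpy(dtype=float), data,
                              ties=ties, names=cols)
            except (CoxError, ValueError, np.linalg.LinAlgError):
                continue
            p = float(fit.p[-1])
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None and best_p < p_enter:
            included.append(best_name)
            changed = True
        # backward step(s)
        while len(included) > 0:
            try:
                fit = cox_fit(cohort[included].to_numpy(dtype=float), data,
                              ties=ties, names=included)
            except (CoxError, ValueError, np.linalg.LinAlgError):
                break
            worst = int(np.argmax(fit.p))
            if float(fit.p[worst]) > p_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return included


@dataclass(frozen=True)
class SelectionReport:
    """Bootstrap inclusion frequencies and retained sets per domain model."""

    frequencies: dict  # domain -> {variable: frequency}
    retained: dict  # domain -> [variables with frequency >= threshold]
    b: int
    threshold: float
    seed: int
    failed_repeats: dict = field(default_factory=dict)  # domain -> count

    @property
    def union(self) -> list:
        out = []
        for domain in self.retained:
            for v in self.retained[domain]:
                if v not in out:
                    out.append(v)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for domain, freqs in self.frequencies.items():
            for v, f in freqs.items():
                rows.append(
                    {
                        "domain": domain,
                        "variable": v,
                        "frequency": f,
                        "retained": v in self.retained[domain],
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_selection(cohort: pd.DataFrame, domain_map: dict,
                        data: SurvivalData, b: int = 500,
                        threshold: float = 0.85, p_enter: float = 0.05,
                        p_remove: float = 0.10, seed: int = 0,
                        ties: str = "efron") -> SelectionReport:
    """Bootstrap stepwise stability selection within variable domains.

    ``domain_map`` maps each candidate variable to its domain (e.g.
    clinical / echo / lab). For each domain, ``b`` bootstrap resamples of
    the cohort (same n, with replacement, seeded) are drawn, the stepwise
    procedure is run on each, and the per-variable inclusion frequency is
    recorded; variables at or above ``threshold`` are retained. A repeat
    whose stepwise fit fails entirely counts as an empty selection.
    """
    if b < 1:
        raise ValueError("need at least one bootstrap repeat")
    domains: dict = {}
    for var, dom in domain_map.items():
        domains.setdefault(dom, []).append(var)
    for dom, vars_ in domains.items():
        if not vars_:
            raise ValueError(f"domain {dom!r} has no variables")

    rng = np.random.default_rng(seed)
    n = data.n
    frequencies: dict = {}
    retained: dict = {}
    failed: dict = {}
    for dom in domains:
        counts = {v: 0 for v in domains[dom]}
        failures = 0
        sub = cohort[domains[dom]].reset_index(drop=True)
        for _ in range(b):
            idx = rng.integers(0, n, size=n)
            boot = sub.iloc[idx].reset_index(drop=True)
            boot_data = SurvivalData(data.time[idx], data.event[idx])
            try:
                chosen = stepwise_cox(boot, domains[dom], boot_data,
                                      p_enter=p_enter, p_remove=p_remove,
                                      ties=ties)
            except Exception:
                chosen = []
                failures += 1
            for v in chosen:
                counts[v] += 1
        frequencies[dom] = {v: counts[v] / b for v in domains[dom]}
        retained[dom] = [v for v in domains[dom] if frequencies[dom][v] >= threshold]
        failed[dom] = failures
    return SelectionReport(
        frequencies=frequencies,
        retained=retained,
        b=b,
        threshold=threshold,
        seed=seed,
        failed_repeats=failed,
    )
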
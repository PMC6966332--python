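"""Backward model selection by AIC over biomarkers + clinical variables.

Starting from the full multivariable Cox model, the single variable whose
removal lowers the AIC the most is dropped, repeatedly, until no removal
improves the model.  Categorical variables are removed as whole blocks
(all their contrast terms together).  The complete-case sample is fixed
once from the full variable set so AICs are comparable across nested
models.  AIC = -2 log(partial likelihood) + 2k with k the number of
estimated coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import CoxFit, efron_newton, fit_cox


def null_partial_loglik(time, event) -> float:
    """Partial log-likelihood of the empty (no-covariate) Cox model."""
    from .survival import _EfronStructure, _partial_loglik

    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    st = _EfronStructure(time, event)
    X = np.zeros((1, time.size, 1))
    return float(_partial_loglik(X, np.zeros((1, 1)), st)[0])


@dataclass
class SelectionTrace:
    """Audit trail of one backward-elimination run."""

    steps: list = field(default_factory=list)  # {removed_variable, aic_before, aic_after}
    final_variables: list = field(default_factory=list)
    final_fit: CoxFit | None = None
    aic_full: float = np.nan
    aic_final: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["removed_variable", "aic_before", "aic_after"])

    def to_json(self, path) -> None:
        payload = {
            "steps": self.steps,
            "final_variables": self.final_variables,
            "aic_full": self.aic_full,
            "aic_final": self.aic_final,
            "final_fit": self.final_fit.to_dict() if self.final_fit else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _aic_of(cohort, time, event, variables) -> tuple[float, CoxFit | None]:
    if not variables:
        ll = null_partial_loglik(cohort[time].to_numpy(), cohort[event].to_numpy())
        return -2 * ll, None
    fit = fit_cox(cohort, time, event, list(variables))
    if not fit.converged:
        return np.inf, fit
    return fit.aic, fit


def backward_aic(
    cohort: pd.DataFrame,
    time: str,
    event: str,
    variables: list[str],
) -> SelectionTrace:
    """Greedy one-at-a-time backward elimination by AIC.

    Deterministic: candidate removals are compared by AIC, ties broken by
    variable name, so a permuted input order returns the identical trace.
    """
    if not variables:
        raise ValueError("empty variable list")
    cols = [time, event] + list(variables)
    sub = cohort[cols].dropna().reset_index(drop=True)

    current = sorted(variables)
    aic_current, fit_current = _aic_of(sub, time, event, current)
    if fit_current is None or not fit_current.converged:
        raise ValueError("full model did not converge; cannot start selection")
    trace = SelectionTrace(aic_full=aic_current)

    while current:
        candidates = []
        for var in current:
            reduced = [v for v in current if v != var]
            try:
                aic, fit = _aic_of(sub, time, event, reduced)
            except (ValueError, KeyError):
                continue
            candidates.append((aic, var, fit))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_aic, best_var, best_fit = candidates[0]
        if best_aic >= aic_current:
            break
        trace.steps.append(
            {"removed_variable": best_var, "aic_before": aic_current, "aic_after": best_aic}
        )
        current = [v for v in current if v != best_var]
        aic_current, fit_current = best_aic, best_fit

    trace.final_variables = current
    trace.final_fit = fit_current
    trace.aic_final = aic_current
    return trace


def exhaustive_aic(
    cohort: pd.DataFrame,
    time: str,
    event: str,
    variables: list[str],
) -> tuple[list[str], float]:
    """All-subsets AIC minimum (reference method; exponential in p)."""
    from itertools import combinations

    if len(variables) > 16:
        raise ValueError("exhaustive search limited to 16 variables")
    cols = [time, event] + list(variables)
    sub = cohort[cols].dropna().reset_index(drop=True)
    best = (np.inf, [])
    for k in range(len(variables) + 1):
        for combo in combinations(sorted(variables), k):
            try:
                aic, fit = _aic_of(sub, time, event, list(combo))
            except (ValueError, KeyError):
                continue
            if fit is not None and not fit.converged:
                continue
            if aic < best[0]:
                best = (aic, list(combo))
    return best[1], best[0]
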
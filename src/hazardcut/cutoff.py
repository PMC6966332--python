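"""Bootstrap-based robust dichotomization cutoff selection.

For one marker and one endpoint: draw B with-replacement resamples of the
cohort; at every admissible cutoff, dichotomize the marker and fit a
multivariable Cox model (marker group + the endpoint's clinical adjustment
set); record the fraction of resamples in which the marker term is
significant (Wald p < 0.05); smooth the fraction curve over nine adjacent
cutoffs; select the cutoff with the highest smoothed fraction.  The final
model is then refit on the original cohort at the selected cutoff with the
"low" group as reference.

Cutoffs that would leave fewer than 10% of patients on either side are
excluded to maintain statistical power.  Note that the final fit at the
*selected* cutoff inherits the optimism of the selection step: under a
null marker its p-value is anti-conservative.  This is a property of the
procedure itself and is asserted (not corrected) in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import ALPHA, CoxFit, EndpointSpec, build_design, efron_newton, fit_cox
from .synth import rng_for


def candidate_cutoffs(values, min_group_frac: float = 0.10) -> np.ndarray:
    """Admissible dichotomization cutoffs for a marker.

    Midpoints between consecutive distinct sorted values whose induced
    low/high split leaves at least ceil(min_group_frac * n) patients on
    each side.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 20:
        raise ValueError("need at least 20 marker values")
    m = math.ceil(min_group_frac * n)
    sv = np.sort(v)
    distinct = np.unique(sv)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_low = np.searchsorted(sv, mids)  # values strictly below each midpoint
    ok = (n_low >= m) & (n - n_low >= m)
    out = mids[ok]
    if out.size == 0:
        raise ValueError("no admissible cutoffs (marker too concentrated)")
    return out


def smooth_fractions(frac, window: int = 9) -> np.ndarray:
    """Centered moving average over ``window`` adjacent cutoffs.

    The window truncates at the edges (shrinking window, no reflection);
    undefined (NaN) entries are excluded from each average.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    f = np.asarray(frac, dtype=float)
    half = window // 2
    valid = np.isfinite(f)
    vals = np.where(valid, f, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(vals, kernel)[half : half + f.size]
    counts = np.convolve(valid.astype(float), kernel)[half : half + f.size]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


@dataclass
class CutoffScan:
    """Result of one marker x endpoint bootstrap cutoff scan."""

    marker: str
    endpoint: EndpointSpec
    candidate_cutoffs: np.ndarray
    frac_significant: np.ndarray
    frac_smoothed: np.ndarray
    selected_cutoff: float
    B: int
    seed: int
    n_significant: np.ndarray
    n_valid: np.ndarray
    n_failed: np.ndarray
    n_low: np.ndarray  # full-cohort group sizes per cutoff
    n_high: np.ndarray
    marker_median: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.candidate_cutoffs,
                "frac_significant": self.frac_significant,
                "frac_smoothed": self.frac_smoothed,
                "n_significant": self.n_significant,
                "n_valid": self.n_valid,
                "n_failed": self.n_failed,
                "n_low": self.n_low,
                "n_high": self.n_high,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_cutoff(scan: CutoffScan) -> float:
    """Argmax of the smoothed significance fraction.

    Exact ties are broken toward the cutoff nearest the marker's median
    (then toward the smaller cutoff), deterministically.
    """
    f = scan.frac_smoothed
    finite = np.isfinite(f)
    if not finite.any():
        raise ValueError("all smoothed fractions undefined")
    best = np.nanmax(f)
    tied = np.flatnonzero(finite & (f == best))
    dist = np.abs(scan.candidate_cutoffs[tied] - scan.marker_median)
    order = np.lexsort((scan.candidate_cutoffs[tied], dist))
    return float(scan.candidate_cutoffs[tied[order[0]]])


def bootstrap_scan(
    cohort: pd.DataFrame,
    marker: str,
    endpoint: EndpointSpec,
    B: int = 10000,
    window: int = 9,
    min_group_frac: float = 0.10,
    seed: int = 0,
) -> CutoffScan:
    """Run the full bootstrap cutoff scan for one marker and endpoint.

    All candidate cutoffs are evaluated against the same B resampled
    cohorts; resample fits that are degenerate (no events, constant design
    column, separation, singular information) are excluded from the
    fraction denominator and counted as failed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cols = [endpoint.time_col, endpoint.event_col, marker] + list(endpoint.covariates)
    sub = cohort[cols].dropna().reset_index(drop=True)
    n = len(sub)
    mvals = sub[marker].to_numpy(dtype=float)
    cutoffs = candidate_cutoffs(mvals, min_group_frac)
    C = cutoffs.size

    t = sub[endpoint.time_col].to_numpy(dtype=float)
    e = sub[endpoint.event_col].to_numpy()
    if endpoint.covariates:
        Z, _, _ = build_design(sub, list(endpoint.covariates))
    else:
        Z = np.empty((n, 0))
    p = 1 + Z.shape[1]

    rng = rng_for(seed, "bootstrap_scan", marker, endpoint.name)
    n_sig = np.zeros(C, dtype=np.int64)
    n_valid = np.zeros(C, dtype=np.int64)
    n_failed = np.zeros(C, dtype=np.int64)

    # Warm start every resample at the full-cohort solution per cutoff:
    # bootstrap estimates scatter around it, cutting Newton iterations.
    X = np.empty((C, n, p))
    X[:, :, 0] = mvals[None, :] > cutoffs[:, None]
    X[:, :, 1:] = Z[None, :, :]
    res_full = efron_newton(t, e, X)
    warm = np.where((res_full.converged & ~res_full.failed)[:, None], res_full.beta, 0.0)

    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        t_b, e_b = t[idx], e[idx]
        Z_b = Z[idx]
        m_b = mvals[idx]
        degenerate = (
            e_b.sum() == 0
            or np.unique(t_b[e_b == 1]).size < 2
            or (Z_b.shape[1] and (np.ptp(Z_b, axis=0) == 0).any())
        )
        if degenerate:
            n_failed += 1
            continue
        X[:, :, 0] = m_b[None, :] > cutoffs[:, None]
        X[:, :, 1:] = Z_b[None, :, :]
        res = efron_newton(t_b, e_b, X, beta0=warm)
        cov = res.covariance()
        ok = res.converged & ~res.failed
        se0 = np.sqrt(cov[:, 0, 0])
        with np.errstate(invalid="ignore", divide="ignore"):
            z0 = np.abs(res.beta[:, 0]) / se0
        pvals = 2 * stats.norm.sf(z0)
        ok &= np.isfinite(pvals)
        n_valid += ok
        n_failed += ~ok
        n_sig += ok & (pvals < ALPHA)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n_sig / n_valid
    frac[n_valid == 0] = np.nan
    smoothed = smooth_fractions(frac, window)

    n_low_full = np.searchsorted(np.sort(mvals), cutoffs)
    scan = CutoffScan(
        marker=marker,
        endpoint=endpoint,
        candidate_cutoffs=cutoffs,
        frac_significant=frac,
        frac_smoothed=smoothed,
        selected_cutoff=np.nan,
        B=B,
        seed=seed,
        n_significant=n_sig,
        n_valid=n_valid,
        n_failed=n_failed,
        n_low=n_low_full,
        n_high=n - n_low_full,
        marker_median=float(np.median(mvals)),
    )
    scan.selected_cutoff = select_cutoff(scan)
    return scan


def dichotomize(values, cutoff: float) -> np.ndarray:
    """High-group indicator (value > cutoff); the low group is reference."""
    return (np.asarray(values, dtype=float) > cutoff).astype(float)


def final_fit(
    cohort: pd.DataFrame,
    marker: str,
    cutoff: float,
    endpoint: EndpointSpec,
    min_group_frac: float = 0.10,
) -> CoxFit:
    """Multivariable Cox fit on the original cohort with the marker
    dichotomized at ``cutoff`` (low group = reference) plus the endpoint's
    clinical covariates."""
    cols = [endpoint.time_col, endpoint.event_col, marker] + list(endpoint.covariates)
    sub = cohort[cols].dropna().reset_index(drop=True)
    v = sub[marker].to_numpy(dtype=float)
    n = len(sub)
    m = math.ceil(min_group_frac * n)
    high = dichotomize(v, cutoff)
    n_high = int(high.sum())
    if min(n_high, n - n_high) < m:
        raise ValueError(
            f"cutoff {cutoff} leaves a group below {min_group_frac:.0%} of patients "
            f"({n - n_high} low / {n_high} high)"
        )
    group_col = f"{marker}_high"
    sub = sub.assign(**{group_col: high})
    fit = fit_cox(sub, endpoint.time_col, endpoint.event_col, [group_col] + list(endpoint.covariates))
    fit.references[group_col] = "low"
    return fit


def marker_term(marker: str) -> str:
    """Name of the dichotomized marker term in a final fit."""
    return f"{marker}_high"
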
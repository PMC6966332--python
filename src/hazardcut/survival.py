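"""Survival-analysis core: endpoint construction, Cox proportional-hazards
fitting, Kaplan-Meier estimation, Spearman correlation, VIF, and marker
clustering.

The Cox fitter maximizes the Efron tie-corrected partial likelihood by
Newton-Raphson.  It is implemented directly (rather than wrapping an
external fitter) because the bootstrap cutoff scan refits the same model
thousands of times per marker; the engine therefore supports a batch axis
so that all candidate cutoffs of one resampled cohort are fit in a single
vectorized pass.  Cross-checks against lifelines live in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger("hazardcut")

#: Wald significance threshold used throughout the analysis.
ALPHA = 0.05

#: |beta| beyond this bound is treated as separation / non-identifiability.
BETA_BOUND = 15.0

ENDPOINTS = ("LRC", "DM", "OS", "PFS")

#: Clinical adjustment sets per endpoint: the clinical variables found to be
#: significantly associated with each outcome, frozen as defaults.
DEFAULT_ENDPOINT_COVARIATES = {
    "LRC": ["sex", "cisplatin"],
    "OS": ["sex", "subsite", "cisplatin"],
    "PFS": ["stage", "subsite", "cisplatin"],
    "DM": ["sex", "alcohol"],
}


@dataclass(frozen=True)
class EndpointSpec:
    """A time-to-event endpoint and its clinical adjustment set."""

    name: str
    covariates: tuple[str, ...]
    event_definition: str = ""

    def __post_init__(self):
        if self.name not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.name!r}; expected one of {ENDPOINTS}")

    @property
    def time_col(self) -> str:
        return f"time_{self.name}"

    @property
    def event_col(self) -> str:
        return f"event_{self.name}"


def default_endpoint_spec(name: str) -> EndpointSpec:
    return EndpointSpec(name=name, covariates=tuple(DEFAULT_ENDPOINT_COVARIATES[name]))


# ---------------------------------------------------------------------------
# Endpoint construction
# ---------------------------------------------------------------------------

_YEAR_DAYS = 365.25


def _to_years(value, start):
    """Difference start->value in years; accepts numeric years or datetimes."""
    delta = value - start
    if isinstance(delta, pd.Series) and pd.api.types.is_timedelta64_dtype(delta):
        return delta.dt.total_seconds() / (_YEAR_DAYS * 86400.0)
    return delta.astype(float)


def build_endpoints(raw: pd.DataFrame) -> pd.DataFrame:
    """Construct the four endpoint time/event column pairs from raw records.

    ``raw`` needs columns ``treatment_start`` and ``last_followup`` plus
    optional ``death_date``, ``lrc_date`` and ``dm_date`` (missing = no such
    event).  Dates may be datetimes or numeric times in years.

    Censoring semantics: for LRC and DM a death occurring before the event
    censors the patient at the death date.  PFS is the time to the earliest
    of locoregional recurrence, distant metastasis or death.  OS is death
    from any cause.
    """
    start = raw["treatment_start"]
    t_fu = _to_years(raw["last_followup"], start)

    def event_time(col):
        if col in raw:
            return _to_years(raw[col], start)
        return pd.Series(np.nan, index=raw.index)

    t_death = event_time("death_date")
    t_lrc = event_time("lrc_date")
    t_dm = event_time("dm_date")

    for name, t in (("death_date", t_death), ("lrc_date", t_lrc), ("dm_date", t_dm)):
        if (t <= 0).any():
            bad = raw.index[t <= 0].tolist()
            raise ValueError(f"{name} on or before treatment_start for rows {bad}")
    if (t_fu <= 0).any():
        bad = raw.index[t_fu <= 0].tolist()
        raise ValueError(f"non-positive follow-up for rows {bad}")

    out = pd.DataFrame(index=raw.index)

    for name, t_ev in (("LRC", t_lrc), ("DM", t_dm)):
        has_ev = t_ev.notna()
        died_first = t_death.notna() & (~has_ev | (t_death < t_ev))
        time = t_fu.copy()
        time[died_first] = t_death[died_first]
        time[has_ev & ~died_first] = t_ev[has_ev & ~died_first]
        out[f"time_{name}"] = time
        out[f"event_{name}"] = (has_ev & ~died_first).astype(int)

    out["time_OS"] = np.where(t_death.notna(), t_death, t_fu)
    out["event_OS"] = t_death.notna().astype(int)

    t_pfs = pd.concat([t_lrc, t_dm, t_death], axis=1).min(axis=1)
    has_pfs = t_pfs.notna()
    out["time_PFS"] = np.where(has_pfs, t_pfs, t_fu)
    out["event_PFS"] = has_pfs.astype(int)
    return out


# ---------------------------------------------------------------------------
# Efron partial-likelihood Newton-Raphson engine (batched)
# ---------------------------------------------------------------------------


class CoxEngineResult:
    """Raw batched fit output; thin container of per-model arrays."""

    __slots__ = ("beta", "loglik", "info", "converged", "failed", "n_iter", "max_score")

    def __init__(self, beta, loglik, info, converged, failed, n_iter, max_score):
        self.beta = beta
        self.loglik = loglik
        self.info = info  # observed information (negative Hessian)
        self.converged = converged
        self.failed = failed
        self.n_iter = n_iter
        self.max_score = max_score

    def covariance(self) -> np.ndarray:
        """Batched inverse information; NaN where the fit failed."""
        K, p, _ = self.info.shape
        cov = np.full_like(self.info, np.nan)
        ok = ~self.failed
        if ok.any():
            try:
                cov[ok] = np.linalg.inv(self.info[ok])
            except np.linalg.LinAlgError:
                for k in np.flatnonzero(ok):
                    try:
                        cov[k] = np.linalg.inv(self.info[k])
                    except np.linalg.LinAlgError:
                        self.failed[k] = True
        return cov


class _EfronStructure:
    """Sorted tie-group layout shared by every model of one batch.

    Rows are sorted by time with events first within each tie group, so the
    d_g event rows of a group are contiguous at its head.  The Efron
    correction is expanded to one term per event carrying its event-group
    index and l/d fraction, which lets every derivative be accumulated with
    segment sums (reduceat) and reversed cumulative sums — no per-group
    Python loop.
    """

    __slots__ = (
        "order", "d", "n", "segments", "pos_start", "pos_stop", "tg", "lfrac",
        "n_terms", "starts", "d_g",
    )

    def __init__(self, time: np.ndarray, event: np.ndarray):
        order = np.lexsort((-event, time))
        t = time[order]
        d = event[order].astype(bool)
        n = t.size
        starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
        d_g = np.add.reduceat(d.astype(np.int64), starts)
        ev_mask = d_g > 0
        reps = d_g[ev_mask]
        ev_groups = np.flatnonzero(ev_mask)
        # risk-set / tie-head sums for event group g are right-cumulative row
        # sums taken at these two row indices:
        ev_start = starts[ev_groups]
        ev_stop = ev_start + reps
        # rows are segmented at every such boundary; right-cumulative segment
        # sums then provide all required risk sums via two gathers
        cuts = np.unique(np.concatenate([ev_start, ev_stop]))
        self.segments = cuts[cuts < n]
        cuts_ext = np.append(self.segments, n)  # index len(segments) -> zero row
        self.pos_start = np.searchsorted(cuts_ext, ev_start)
        self.pos_stop = np.searchsorted(cuts_ext, ev_stop)
        # term expansion: term j belongs to event-group tg[j] with l/d lfrac[j]
        offs = np.concatenate([[0], np.cumsum(reps)[:-1]]).astype(int)
        self.tg = np.repeat(np.arange(ev_groups.size), reps)
        l = np.arange(int(reps.sum())) - np.repeat(offs, reps)
        self.lfrac = l / np.repeat(reps, reps)
        self.order = order
        self.d = d
        self.n = n
        self.n_terms = int(reps.sum())
        self.starts = starts
        self.d_g = d_g

    def group_layout(self):
        """(G+1,) tie-group row boundaries and (G,) events per group."""
        gstart = np.append(self.starts, self.n).astype(np.int64)
        return gstart, self.d_g.astype(np.int64)


def _risk_sums(a: np.ndarray, st: _EfronStructure):
    """Right-cumulative sums of rows at every event-group boundary.

    Returns ``(S, Sd)`` where ``S[:, g]`` sums rows from the start of event
    group g to the end (the risk set) and ``Sd[:, g]`` sums the tied event
    rows at the head of group g.
    """
    seg = np.add.reduceat(a, st.segments, axis=1)
    K = a.shape[0]
    S_all = np.zeros((K, seg.shape[1] + 1) + a.shape[2:], dtype=a.dtype)
    np.cumsum(seg[:, ::-1], axis=1, out=S_all[:, seg.shape[1] - 1 :: -1])
    S = S_all[:, st.pos_start]
    Sd = S - S_all[:, st.pos_stop]
    return S, Sd


def _partial_loglik(Xs, beta, st: _EfronStructure):
    """Efron partial log-likelihood only (used for step-halving)."""
    eta = (Xs @ beta[..., None])[..., 0]
    shift = eta.max(axis=1, keepdims=True)
    w = np.exp(eta - shift)
    S0, s0d = _risk_sums(w, st)
    denom = S0[:, st.tg] - st.lfrac * s0d[:, st.tg]
    logden = np.log(denom)
    return eta[:, st.d].sum(axis=1) - logden.sum(axis=1) - st.n_terms * shift[:, 0]


def _efron_derivs(Xs, XX, beta, st: _EfronStructure):
    """Log-likelihood, score and observed information for a batch.

    ``XX`` is the precomputed (K, n, p*p) outer-product array of ``Xs``.
    w, x*w and xx^T*w are packed into one buffer so all risk-set and tie
    sums come from a single right-cumulative pass plus index gathers
    (event rows sit contiguously at the head of each tie group).
    """
    K, n, p = Xs.shape
    q = 1 + p + p * p
    eta = (Xs @ beta[..., None])[..., 0]
    shift = eta.max(axis=1, keepdims=True)
    w = np.exp(eta - shift)

    buf = np.empty((K, n, q))
    buf[:, :, 0] = w
    np.multiply(Xs, w[..., None], out=buf[:, :, 1 : 1 + p])
    np.multiply(XX, w[..., None], out=buf[:, :, 1 + p :])

    G, gd = _risk_sums(buf, st)  # (K, Ge, q) risk-set / tie-head sums
    # per-term Efron-adjusted risk sums
    A = G[:, st.tg] - st.lfrac[:, None] * gd[:, st.tg]  # (K, T, q)
    denom = A[:, :, 0]
    ll = eta[:, st.d].sum(axis=1) - np.log(denom).sum(axis=1) - st.n_terms * shift[:, 0]
    z = A[:, :, 1 : 1 + p] / denom[..., None]
    grad = Xs[:, st.d].sum(axis=1) - z.sum(axis=1)
    S2term = A[:, :, 1 + p :] / denom[..., None]
    info = S2term.sum(axis=1).reshape(K, p, p) - np.matmul(z.transpose(0, 2, 1), z)
    return ll, grad, info


def efron_newton(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100,
    beta_bound: float = BETA_BOUND,
    ties: str = "efron",
    beta0: np.ndarray | None = None,
    engine: str = "numba",
) -> CoxEngineResult:
    """Fit Cox models by Newton-Raphson on the Efron partial likelihood.

    ``X`` has shape ``(K, n, p)`` — K models sharing the same times/events —
    or ``(n, p)`` for a single model.  Step-halving keeps the likelihood
    non-decreasing; |beta| escaping ``beta_bound`` flags separation.
    ``beta0`` warm-starts the iteration (e.g. at the full-cohort solution
    when fitting resamples).

    Two interchangeable engines implement the same algorithm: a compiled
    per-model kernel (default) and a vectorized numpy path in which models
    that converge or fail drop out of the working set.  Their agreement is
    asserted in the test suite.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    if event.sum() == 0:
        raise ValueError("no events: Cox model undefined")

    st = _EfronStructure(time, event)
    if ties == "breslow":
        st.lfrac = np.zeros_like(st.lfrac)
    Xs = np.ascontiguousarray(X[:, st.order, :])
    K, n, p = Xs.shape

    if engine == "numba":
        from ._kernel import newton_kernel_batch

        d_sorted = st.d.astype(np.uint8)
        gstart, devents = st.group_layout()
        b0 = (
            np.zeros((K, p))
            if beta0 is None
            else np.array(beta0, dtype=float).reshape(K, p).copy()
        )
        efron_flag = ties == "efron"
        beta, loglik, info, conv, fail, niter, mscore = newton_kernel_batch(
            Xs, d_sorted, gstart, devents, b0, tol, max_iter, beta_bound, efron_flag
        )
        const = (np.ptp(Xs, axis=1) == 0).any(axis=1)
        fail = fail.astype(bool) | const
        conv = conv.astype(bool) & ~fail
        return CoxEngineResult(beta, loglik, info, conv, fail, int(niter.max()), mscore)
    if engine != "numpy":
        raise ValueError(f"unknown engine {engine!r}")

    beta = np.zeros((K, p)) if beta0 is None else np.array(beta0, dtype=float).reshape(K, p).copy()
    failed = (np.ptp(Xs, axis=1) == 0).any(axis=1)  # constant column: non-identifiable
    converged = np.zeros(K, dtype=bool)
    loglik = np.full(K, -np.inf)
    info = np.zeros((K, p, p))
    max_score = np.full(K, np.inf)
    n_iter = 0

    XX = (Xs[:, :, :, None] * Xs[:, :, None, :]).reshape(K, n, p * p)
    active = np.flatnonzero(~failed)
    old = np.seterr(divide="ignore", invalid="ignore", over="ignore")
    try:
        for n_iter in range(1, max_iter + 1):
            if active.size == 0:
                break
            whole = active.size == K
            Xa = Xs if whole else Xs[active]
            XXa = XX if whole else XX[active]
            ba = beta[active]
            ll, grad, inf_a = _efron_derivs(Xa, XXa, ba, st)
            loglik[active] = ll
            info[active] = inf_a
            gmax = np.where(np.isfinite(grad).all(axis=1), np.abs(grad).max(axis=1), np.inf)
            max_score[active] = gmax

            bad = ~np.isfinite(ll) | ~np.isfinite(grad).all(axis=1)
            bad |= np.abs(ba).max(axis=1) > beta_bound
            conv = (gmax < tol) & ~bad
            failed[active[bad]] = True
            converged[active[conv]] = True
            keep = ~(bad | conv)
            if not keep.all():
                active = active[keep]
                if active.size == 0:
                    break
                Xa, ba, ll, grad, inf_a = Xa[keep], ba[keep], ll[keep], grad[keep], inf_a[keep]

            try:
                delta = np.linalg.solve(inf_a, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.empty_like(grad)
                sing = np.zeros(active.size, dtype=bool)
                for i in range(active.size):
                    try:
                        delta[i] = np.linalg.solve(inf_a[i], grad[i])
                    except np.linalg.LinAlgError:
                        sing[i] = True
                failed[active[sing]] = True
                ok = ~sing
                active, Xa, ba, ll, delta = active[ok], Xa[ok], ba[ok], ll[ok], delta[ok]
                if active.size == 0:
                    break
            nonfin = ~np.isfinite(delta).all(axis=1)
            if nonfin.any():
                failed[active[nonfin]] = True
                ok = ~nonfin
                active, Xa, ba, ll, delta = active[ok], Xa[ok], ba[ok], ll[ok], delta[ok]
                if active.size == 0:
                    break

            # step-halving on likelihood decrease
            step = np.ones(active.size)
            for _ in range(40):
                ll_try = _partial_loglik(Xa, ba + step[:, None] * delta, st)
                worse = (ll_try < ll - 1e-10) | ~np.isfinite(ll_try)
                if not worse.any():
                    break
                step[worse] *= 0.5
            beta[active] = ba + step[:, None] * delta
    finally:
        np.seterr(**old)

    sep = np.abs(beta).max(axis=1) > beta_bound
    failed |= sep
    converged &= ~failed
    return CoxEngineResult(beta, loglik, info, converged, failed, n_iter, max_score)


# ---------------------------------------------------------------------------
# Design matrices and the public CoxFit interface
# ---------------------------------------------------------------------------


def is_categorical(series: pd.Series) -> bool:
    return (
        isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == object
        or series.dtype == bool
    )


def build_design(
    df: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Expand model terms to a numeric design matrix.

    Categorical variables are dummy-coded with the most frequent observed
    level as the reference; continuous variables enter as-is.  Returns the
    matrix, expanded column names (``var=level`` for contrasts) and the
    reference level per categorical term.
    """
    cols, names, refs = [], [], {}
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"term {term!r} not in cohort columns")
        s = df[term]
        if is_categorical(s):
            counts = s.value_counts()
            # deterministic reference: highest count, then lexicographic
            ref = sorted(counts.index, key=lambda v: (-counts[v], str(v)))[0]
            refs[term] = str(ref)
            levels = sorted((v for v in counts.index if v != ref), key=str)
            if not levels:
                raise ValueError(f"categorical term {term!r} has a single observed level")
            for lev in levels:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{term}={lev}")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names, refs


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model with Wald inference."""

    terms: pd.DataFrame  # index: expanded term name; columns below
    loglik: float
    aic: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    max_score: float
    references: dict[str, str] = field(default_factory=dict)
    n_dropped: int = 0

    COLUMNS = ("coef", "se", "hr", "ci_low", "ci_high", "p")

    def hr(self, term: str) -> float:
        return float(self.terms.loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])

    def to_dict(self) -> dict:
        return {
            "terms": {
                name: {c: float(row[c]) for c in self.COLUMNS}
                for name, row in self.terms.iterrows()
            },
            "references": self.references,
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "max_score": self.max_score,
            "n_dropped": self.n_dropped,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _wald_table(beta, cov, names, ci_level=0.95):
    se = np.sqrt(np.diag(cov))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - zcrit * se),
            "ci_high": np.exp(beta + zcrit * se),
            "p": p,
        },
        index=list(names),
    )


def fit_cox(
    cohort: pd.DataFrame,
    time: str,
    event: str,
    terms: list[str],
    ties: str = "efron",
) -> CoxFit:
    """Fit a multivariable Cox model on a cohort table.

    Rows with missing values in any active column are dropped (complete
    case) and the count logged.  Separation is reported as a non-converged
    fit rather than silent output.
    """
    active = [time, event] + list(terms)
    sub = cohort[active].dropna()
    n_dropped = len(cohort) - len(sub)
    if n_dropped:
        logger.info("fit_cox: dropped %d rows with missing values", n_dropped)
    X, names, refs = build_design(sub, list(terms))
    t = sub[time].to_numpy(dtype=float)
    e = sub[event].to_numpy()
    if e.sum() == 0:
        raise ValueError("zero events in cohort")
    if np.unique(t[e == 1]).size < 2:
        raise ValueError("need >=2 distinct event times")
    if (np.ptp(X, axis=0) == 0).any():
        const = [names[j] for j in np.flatnonzero(np.ptp(X, axis=0) == 0)]
        raise ValueError(f"non-identifiable: constant design columns {const}")

    res = efron_newton(t, e, X, ties=ties)
    beta = res.beta[0]
    cov = res.covariance()[0]
    table = _wald_table(beta, cov, names)
    k = len(names)
    loglik = float(res.loglik[0])
    fit = CoxFit(
        terms=table,
        loglik=loglik,
        aic=-2 * loglik + 2 * k,
        n=len(sub),
        n_events=int(e.sum()),
        n_iter=int(res.n_iter),
        converged=bool(res.converged[0]),
        max_score=float(res.max_score[0]),
        references=refs,
        n_dropped=n_dropped,
    )
    if not fit.converged:
        logger.warning(
            "fit_cox: non-converged fit (max|score|=%.3g, %d iterations)",
            fit.max_score,
            fit.n_iter,
        )
    return fit


def significance(fit: CoxFit, term: str) -> bool:
    """Wald test at the study-wide threshold p < 0.05."""
    if term not in fit.terms.index:
        raise KeyError(f"term {term!r} not in fit")
    if not fit.converged:
        logger.warning("significance: non-converged fit for term %r -> False", term)
        return False
    return fit.p(term) < ALPHA


# ---------------------------------------------------------------------------
# Correlation, collinearity, clustering, Kaplan-Meier
# ---------------------------------------------------------------------------


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def vif(design) -> np.ndarray:
    """Variance inflation factor per column: 1/(1-R^2) regressing each
    column on the others (with intercept).  Exact collinearity -> inf."""
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 columns")
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1 - resid @ resid / ss_tot
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def cluster_markers(
    scores: pd.DataFrame,
    log_columns: tuple[str, ...] = ("tumor_volume", "EGFR"),
    linkage_method: str = "complete",
):
    """Hierarchical clustering of samples x markers.

    Heavily right-skewed columns (tumor volume, single-gene TPM) are
    log-transformed so a few large values do not dominate the distances;
    all columns are then z-scored and clustered on both axes with Euclidean
    distance.  Returns deterministic leaf orderings plus the two linkages.
    """
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 markers")
    mat = scores.astype(float).copy()
    for col in log_columns:
        if col in mat.columns:
            if (mat[col] > -1).all():
                mat[col] = np.log1p(mat[col])
            else:
                # the transform targets positive skewed scales (volume, TPM);
                # already-centred scores are left alone
                logger.warning("cluster_markers: %s not positive; log transform skipped", col)
    sd = mat.std(axis=0, ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        logger.warning("cluster_markers: dropping constant columns %s", const)
        mat = mat.drop(columns=const)
        sd = sd.drop(index=const)
    if mat.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant markers")
    Z = (mat - mat.mean(axis=0)) / sd
    marker_link = hierarchy.linkage(Z.to_numpy().T, method=linkage_method, metric="euclidean")
    sample_link = hierarchy.linkage(Z.to_numpy(), method=linkage_method, metric="euclidean")
    return {
        "marker_order": [Z.columns[i] for i in hierarchy.leaves_list(marker_link)],
        "sample_order": [Z.index[i] for i in hierarchy.leaves_list(sample_link)],
        "marker_linkage": marker_link,
        "sample_linkage": sample_link,
    }


def kaplan_meier(time, event):
    """Product-limit survival estimate.

    Returns ``(times, survival, median)`` where the median is the earliest
    time at which survival drops to <= 0.5 (NaN if never reached).
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("empty input")
    km = KaplanMeierFitter()
    km.fit(time, event_observed=event)
    sf = km.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(km.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return times, surv, median
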
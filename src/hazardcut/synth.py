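"""Synthetic cohort generation with known ground truth.

Emulates the statistical structure of a chemo-radiotherapy HNSCC cohort:
12 correlated biomarker scores (Gaussian copula on target Spearman
correlations), categorical clinical covariates drawn at the published
marginal frequencies, and proportional-hazards event times for four
endpoints with the death-censoring semantics of the real analysis
(death before a locoregional or distant event censors it; PFS is the
earliest of recurrence, metastasis or death).

Event times are exponential given the linear predictor, which keeps the
events-per-person-time oracle closed-form; a Weibull shape is exposed as
an option.  Background death and administrative censoring are independent
of the endpoint processes given covariates.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .survival import ENDPOINTS

MARKERS = (
    "chronic_hypoxia",
    "acute_hypoxia",
    "SLC3A2",
    "CD44",
    "EGFR",
    "proliferation",
    "TIS",
    "CD8",
    "NK_CD56dim",
    "CD8_Treg",
    "EMT",
    "DNA_CL_repair",
)

#: Default pairwise target Spearman correlations between marker scores.
DEFAULT_TARGET_CORR_PAIRS = {
    ("CD44", "SLC3A2"): 0.57,
    ("acute_hypoxia", "proliferation"): 0.58,
    ("acute_hypoxia", "TIS"): 0.51,
    ("acute_hypoxia", "CD8"): 0.54,
    ("acute_hypoxia", "chronic_hypoxia"): 0.26,
}

#: Marginal clinical covariate frequencies of the emulated 197-patient cohort
#: (missing entries excluded, frequencies renormalized).
DEFAULT_CLINICAL_SPEC = {
    "sex": {"Male": 142 / 197, "Female": 55 / 197},
    "alcohol": {"Yes": 146 / 190, "Former": 22 / 190, "No": 22 / 190},
    "subsite": {"Oropharynx": 85 / 197, "Hypopharynx": 78 / 197, "Larynx": 34 / 197},
    "stage": {"IVA": 135 / 197, "III": 40 / 197, "IVB": 20 / 197, "II": 2 / 197},
    "cisplatin": {">=200": 126 / 193, "<200": 67 / 193},
}

#: Tumor volume (cm^3): log-normal with median 23.2.
DEFAULT_VOLUME_MEANLOG = float(np.log(23.2))
DEFAULT_VOLUME_SDLOG = 1.1

#: Ground-truth log-hazard effects per simulated endpoint.  Marker keys act
#: through a step at the marker's true cutoff quantile; ``var=level`` keys
#: act through the level indicator; ``tumor_volume`` acts linearly on the
#: standardized log volume.  Magnitudes mirror the hazard ratios reported
#: for the strongest markers of each endpoint.
DEFAULT_TRUE_EFFECTS = {
    "LRC": {
        "chronic_hypoxia": float(np.log(3.95)),
        "acute_hypoxia": float(np.log(1.9)),
        "cisplatin=<200": float(np.log(2.57)),
        "sex=Female": float(np.log(0.52)),
    },
    "DM": {"EMT": float(np.log(3.14)), "acute_hypoxia": float(np.log(2.44))},
    "OS": {
        "EMT": float(np.log(2.15)),
        "DNA_CL_repair": float(np.log(1.97)),
        "acute_hypoxia": float(np.log(1.62)),
    },
}

#: Baseline hazards (events/year) calibrated so the default cohort shows
#: roughly the published event fractions (~24% locoregional recurrences,
#: ~20% distant metastases, ~5.2 years median follow-up).
DEFAULT_BASELINE_HAZARD = {"LRC": 0.02, "DM": 0.02}
DEFAULT_DEATH_RATE = 0.04
DEFAULT_CENSOR_RATE = 0.19


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible stream for one named operation.

    A single global seed is combined with stable hashes of the key path so
    each operation draws from its own counter-derived stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def pairs_to_matrix(names, pairs) -> np.ndarray:
    """Build a full correlation matrix from {(a, b): r} entries."""
    idx = {n: i for i, n in enumerate(names)}
    C = np.eye(len(names))
    for (a, b), r in pairs.items():
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    return C


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator."""

    n_patients: int = 197
    marker_names: tuple[str, ...] = MARKERS
    target_corr: np.ndarray | None = None  # defaults to the shipped pairs
    clinical_spec: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL_SPEC.items()})
    volume_meanlog: float = DEFAULT_VOLUME_MEANLOG
    volume_sdlog: float = DEFAULT_VOLUME_SDLOG
    true_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_EFFECTS.items()})
    true_cutoffs: dict = field(default_factory=dict)  # marker -> quantile or "linear"; default 0.5
    baseline_hazard: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_HAZARD))
    death_rate: float = DEFAULT_DEATH_RATE
    censor_rate: float = DEFAULT_CENSOR_RATE
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.target_corr is None:
            self.target_corr = pairs_to_matrix(self.marker_names, DEFAULT_TARGET_CORR_PAIRS)
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        C = self.target_corr
        m = len(self.marker_names)
        if C.shape != (m, m):
            raise ValueError("target_corr shape does not match marker_names")
        if not np.allclose(C, C.T):
            raise ValueError("target_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("target_corr must have unit diagonal")
        if np.abs(C).max() > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        for cov, freqs in self.clinical_spec.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"frequencies for {cov!r} sum to {total}, not 1")
        for ep in self.true_effects:
            if ep not in ("LRC", "DM", "OS"):
                raise ValueError(f"true_effects endpoint {ep!r} (simulated endpoints: LRC, DM, OS)")
        for ep in self.baseline_hazard:
            if ep not in ("LRC", "DM"):
                raise ValueError(f"baseline_hazard endpoint {ep!r}")

    def cutoff_quantile(self, marker: str):
        return self.true_cutoffs.get(marker, 0.5)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_names"] = list(self.marker_names)
        d["target_corr"] = np.asarray(self.target_corr).tolist()
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        """Load a config from a YAML (or JSON) file mirroring the field names."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "marker_names" in data:
            data["marker_names"] = tuple(data["marker_names"])
        if data.get("target_corr") is not None:
            data["target_corr"] = np.asarray(data["target_corr"], dtype=float)
        return cls(**data)


# ---------------------------------------------------------------------------
# Correlated marker scores via a Gaussian copula
# ---------------------------------------------------------------------------


def nearest_psd(C: np.ndarray, eps: float = 1e-8, max_repair: float = 0.1) -> np.ndarray:
    """Repair a near-PSD correlation matrix by clipping eigenvalues.

    Raises if the repair moves any entry by more than ``max_repair``.
    """
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= eps:
        return C
    vals = np.clip(vals, eps, None)
    R = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    if np.abs(R - C).max() > max_repair:
        raise ValueError("target correlation matrix is not PSD within repair tolerance")
    return R


def simulate_scores(config: SimulationConfig) -> pd.DataFrame:
    """Draw marker scores with the configured Spearman correlation.

    Spearman targets are converted to the Gaussian-copula Pearson scale by
    ``2*sin(pi*r/6)`` before the Cholesky transform; marginals are standard
    normal (callers may transform them — rank-based downstream statistics
    are unaffected).
    """
    r_s = config.target_corr
    r_p = 2 * np.sin(np.pi * r_s / 6.0)
    np.fill_diagonal(r_p, 1.0)
    R = nearest_psd(r_p)
    vals, vecs = np.linalg.eigh(R)
    L = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
    rng = rng_for(config.seed, "scores")
    Z = rng.standard_normal((config.n_patients, len(config.marker_names)))
    X = Z @ L.T
    return pd.DataFrame(X, columns=list(config.marker_names))


# ---------------------------------------------------------------------------
# Full cohort with proportional-hazards event times
# ---------------------------------------------------------------------------


def _simulate_clinical(config: SimulationConfig) -> pd.DataFrame:
    # one stream per covariate: draws are independent of dict ordering
    n = config.n_patients
    out = {}
    for cov, freqs in config.clinical_spec.items():
        rng = rng_for(config.seed, "clinical", cov)
        levels = sorted(freqs)  # canonical order: draws survive config round trips
        p = np.array([freqs[l] for l in levels], dtype=float)
        p = p / p.sum()
        out[cov] = rng.choice(levels, size=n, p=p)
    rng = rng_for(config.seed, "clinical", "tumor_volume")
    out["tumor_volume"] = np.exp(
        config.volume_meanlog + config.volume_sdlog * rng.standard_normal(n)
    )
    return pd.DataFrame(out)


def _linear_predictor(config, scores: pd.DataFrame, clinical: pd.DataFrame, effects: dict) -> np.ndarray:
    lp = np.zeros(len(scores))
    for var, beta in effects.items():
        if var in scores.columns:
            q = config.cutoff_quantile(var)
            x = scores[var].to_numpy()
            if q == "linear":
                lp += beta * x
            else:
                # ground-truth step at the theoretical N(0,1) quantile
                lp += beta * (x > norm.ppf(float(q)))
        elif var == "tumor_volume":
            z = (np.log(clinical["tumor_volume"].to_numpy()) - config.volume_meanlog) / config.volume_sdlog
            lp += beta * z
        elif "=" in var:
            cov, level = var.split("=", 1)
            if cov not in clinical.columns:
                raise ValueError(f"true_effects references unknown covariate {cov!r}")
            lp += beta * (clinical[cov].to_numpy() == level)
        else:
            raise ValueError(f"true_effects references unknown variable {var!r}")
    return lp


def _event_times(rng, rate: np.ndarray, shape: float) -> np.ndarray:
    """Times with hazard h(t) = rate * shape * t^(shape-1) (Weibull; shape=1
    is exponential)."""
    u = rng.uniform(size=rate.shape)
    return (-np.log(u) / rate) ** (1.0 / shape)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a full cohort table: covariates, marker scores and the four
    endpoint time/event pairs satisfying the death-censoring semantics."""
    n = config.n_patients
    scores = simulate_scores(config)
    clinical = _simulate_clinical(config)
    rng = rng_for(config.seed, "events")

    def latent(endpoint, base_rate):
        lp = _linear_predictor(config, scores, clinical, config.true_effects.get(endpoint, {}))
        if base_rate <= 0:
            return np.full(n, np.inf)
        return _event_times(rng, base_rate * np.exp(lp), config.weibull_shape)

    t_lrc = latent("LRC", config.baseline_hazard.get("LRC", 0.0))
    t_dm = latent("DM", config.baseline_hazard.get("DM", 0.0))
    t_death = latent("OS", config.death_rate)
    if config.censor_rate > 0:
        t_admin = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_admin = np.full(n, np.inf)

    cohort = pd.DataFrame({"patient_id": [f"P{i + 1:04d}" for i in range(n)]})
    cohort = pd.concat([cohort, clinical, scores], axis=1)

    def attach(name, t_ev, competing):
        obs = np.minimum.reduce([t_ev] + competing)
        cohort[f"time_{name}"] = obs
        cohort[f"event_{name}"] = (t_ev <= obs).astype(int)

    attach("LRC", t_lrc, [t_death, t_admin])
    attach("DM", t_dm, [t_death, t_admin])
    attach("OS", t_death, [t_admin])
    t_prog = np.minimum.reduce([t_lrc, t_dm, t_death])
    attach("PFS", t_prog, [t_admin])
    return cohort


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Assert the row-wise endpoint invariants (raises AssertionError)."""
    t = {e: cohort[f"time_{e}"].to_numpy() for e in ENDPOINTS}
    ev = {e: cohort[f"event_{e}"].to_numpy() for e in ENDPOINTS}
    for e in ENDPOINTS:
        assert (t[e] > 0).all(), f"non-positive time_{e}"
        assert np.isin(ev[e], (0, 1)).all(), f"event_{e} not 0/1"
        assert not np.isnan(t[e]).any(), f"missing time_{e}"
    eps = 1e-12
    for e in ("LRC", "DM", "OS"):
        assert (t["PFS"] <= t[e] + eps).all(), f"time_PFS exceeds time_{e}"
    comp_at_pfs = np.zeros(len(cohort), dtype=bool)
    for e in ("LRC", "DM", "OS"):
        comp_at_pfs |= (ev[e] == 1) & (np.abs(t[e] - t["PFS"]) <= eps)
    assert ((ev["PFS"] == 1) == comp_at_pfs).all(), "event_PFS inconsistent with components"


# ---------------------------------------------------------------------------
# Synthetic expression matrices for end-to-end scoring tests
# ---------------------------------------------------------------------------


def simulate_expression(
    signatures,
    scores,
    n_background_genes: int = 500,
    seed: int = 0,
    amplitude: float = 2.0,
    base_meanlog: float = 4.0,
    base_sdlog: float = 1.0,
    noise_sdlog: float = 0.5,
) -> pd.DataFrame:
    """Generate a gene x sample count matrix in which each signature's
    member genes are mean-shifted monotonically in that signature's target
    score, on top of log-normal background counts.

    ``scores``: samples x signatures (column order matches ``signatures``).
    """
    scores = pd.DataFrame(scores)
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("scores must be finite")
    if len(signatures) != scores.shape[1]:
        raise ValueError("one score column per signature required")
    rng = rng_for(seed, "expression")
    n_samples = scores.shape[0]
    sig_genes = []
    for sig in signatures:
        genes = list(getattr(sig, "genes_up", sig))
        if not genes:
            raise ValueError(f"empty gene set {getattr(sig, 'name', sig)!r}")
        sig_genes.append(genes)

    all_sig = [g for genes in sig_genes for g in genes]
    background = [f"BG{i + 1:05d}" for i in range(n_background_genes)]
    if set(all_sig) & set(background):
        raise ValueError("signature genes collide with background gene names")
    gene_names = all_sig + background

    mu = base_meanlog + base_sdlog * rng.standard_normal(len(gene_names))
    logx = mu[:, None] + noise_sdlog * rng.standard_normal((len(gene_names), n_samples))
    row = 0
    for j, genes in enumerate(sig_genes):
        s = scores.iloc[:, j].to_numpy(dtype=float)
        logx[row : row + len(genes), :] += amplitude * s[None, :]
        row += len(genes)
    counts = np.rint(np.exp(logx)).astype(np.int64)
    counts = np.clip(counts, 0, None)
    samples = [str(c) for c in scores.index]
    return pd.DataFrame(counts, index=gene_names, columns=samples)


# ---------------------------------------------------------------------------
# Cohort I/O (tab-separated, empty fields = missing)
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
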
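"""Orchestration: the full analysis from cohort to ranked markers.

Stages: (real mode only) expression scoring -> correlation matrix and
marker clustering -> per-marker, per-endpoint bootstrap cutoff scans and
final dichotomized fits -> backward-AIC combined models -> cutoff-averaged
HR profiles.  Every artifact is written as TSV or JSON together with a
structured run log (seed, versions, parameters, config hash) sufficient to
reproduce the run bit-identically.

No multiple-testing correction is applied anywhere: per-marker p-values
and the correlation matrix are reported unadjusted, as in the analysis
this pipeline reproduces; treat marginal significance accordingly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cutoff import bootstrap_scan, final_fit, marker_term
from .hrprofile import hr_across_cutoffs, spider_table
from .scoring import read_expression, read_gmt, score_matrix, write_scores
from .selection import backward_aic
from .survival import (
    DEFAULT_ENDPOINT_COVARIATES,
    EndpointSpec,
    cluster_markers,
    default_endpoint_spec,
    spearman_corr,
)
from .synth import MARKERS, SimulationConfig, read_cohort, simulate_cohort, write_cohort

logger = logging.getLogger("hazardcut")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # synthetic | real
    out_dir: str = "hazardcut_run"
    expression_path: str | None = None
    gmt_path: str | None = None
    clinical_path: str | None = None
    cohort_path: str | None = None
    markers: tuple[str, ...] = MARKERS
    endpoints: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ENDPOINT_COVARIATES.items()})
    n_patients: int = 197
    B: int = 200
    window: int = 9
    min_group_frac: float = 0.10
    seed: int = 0
    run_selection: bool = True
    run_profiles: bool = True
    profile_endpoints: tuple[str, ...] = ("LRC", "DM")
    keep_going: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be odd and >= 1")
        if self.mode == "real":
            needed = {"clinical_path": self.clinical_path}
            if self.cohort_path is None:
                needed.update({"expression_path": self.expression_path, "gmt_path": self.gmt_path})
            for name, path in needed.items():
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"real mode requires existing {name} (got {path!r})")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["markers"] = list(self.markers)
        d["profile_endpoints"] = list(self.profile_endpoints)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def correlation_report(scores: pd.DataFrame, clinical: pd.DataFrame | None = None):
    """Pairwise Spearman correlation matrix with unadjusted p-values.

    Constant columns are reported as missing rows/columns.  Continuous
    clinical columns, if given, are appended to the score matrix.
    """
    mat = scores.copy()
    if clinical is not None:
        for col in clinical.columns:
            if pd.api.types.is_numeric_dtype(clinical[col]):
                mat[col] = clinical[col].to_numpy()
    if len(mat) < 3:
        raise ValueError("need at least 3 samples")
    cols = list(mat.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                rij, pij = spearman_corr(mat.iloc[:, i], mat.iloc[:, j])
            except ValueError:
                continue
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    for i in range(k):
        if mat.iloc[:, i].nunique() <= 1:
            r[i, :] = r[:, i] = np.nan
            p[i, :] = p[:, i] = np.nan
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and offending unit."""


def _stage(name: str, unit: str | None = None):
    label = f"{name}[{unit}]" if unit else name

    class _ctx:
        def __enter__(self):
            logger.info("stage %s: start", label)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage {label} failed: {exc}") from exc
            return False

    return _ctx()


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under out_dir."""
    config.validate()
    out = Path(config.out_dir)
    for sub in ("scans", "fits", "selection", "profiles"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    bundle: dict = {"config": config.to_dict(), "config_hash": config.config_hash()}

    # --- cohort assembly -------------------------------------------------
    if config.mode == "synthetic":
        with _stage("simulate"):
            sim = SimulationConfig(n_patients=config.n_patients, seed=config.seed)
            cohort = simulate_cohort(sim)
    else:
        with _stage("load"):
            if config.cohort_path:
                cohort = read_cohort(config.cohort_path)
            else:
                expr = read_expression(config.expression_path)
                sigs = read_gmt(config.gmt_path)
                scores = score_matrix(expr, sigs)
                write_scores(scores, out / "scores.tsv")
                clinical = pd.read_csv(config.clinical_path, sep="\t")
                cohort = pd.concat(
                    [clinical.reset_index(drop=True), scores.reset_index(drop=True)], axis=1
                )
    write_cohort(cohort, out / "cohort.tsv")
    bundle["cohort"] = cohort
    markers = [m for m in config.markers if m in cohort.columns]

    # --- correlations & clustering ---------------------------------------
    with _stage("correlation"):
        extras = cohort[["tumor_volume"]] if "tumor_volume" in cohort.columns else None
        corr, pvals = correlation_report(cohort[markers], extras)
        corr.to_csv(out / "correlation.tsv", sep="\t")
        pvals.to_csv(out / "correlation_pvalues.tsv", sep="\t")
        bundle["correlation"] = corr
    with _stage("clustering"):
        clust_input = cohort[markers].copy()
        if "tumor_volume" in cohort.columns:
            clust_input["tumor_volume"] = cohort["tumor_volume"].to_numpy()
        clust = cluster_markers(clust_input)
        with open(out / "clustering.json", "w") as fh:
            json.dump(
                {
                    "marker_order": list(map(str, clust["marker_order"])),
                    "sample_order": list(map(str, clust["sample_order"])),
                },
                fh,
                indent=2,
            )
        bundle["clustering"] = clust

    # --- per-marker, per-endpoint cutoff scans and final fits -------------
    specs = {
        name: EndpointSpec(name=name, covariates=tuple(covs))
        for name, covs in config.endpoints.items()
    }
    scans, fits = {}, {}
    for ep_name, spec in specs.items():
        for marker in markers:
            try:
                with _stage("scan", f"{marker}/{ep_name}"):
                    scan = bootstrap_scan(
                        cohort,
                        marker,
                        spec,
                        B=config.B,
                        window=config.window,
                        min_group_frac=config.min_group_frac,
                        seed=config.seed,
                    )
                    scan.to_tsv(out / "scans" / f"{marker}_{ep_name}.tsv")
                with _stage("final_fit", f"{marker}/{ep_name}"):
                    fit = final_fit(cohort, marker, scan.selected_cutoff, spec,
                                    min_group_frac=config.min_group_frac)
                    fit.to_json(out / "fits" / f"{marker}_{ep_name}.json")
            except StageError:
                if not config.keep_going:
                    raise
                logger.exception("skipping %s/%s under keep_going", marker, ep_name)
                continue
            scans[(marker, ep_name)] = scan
            fits[(marker, ep_name)] = fit
    cut_rows = [
        {
            "marker": m,
            "endpoint": ep,
            "selected_cutoff": s.selected_cutoff,
            "max_frac_smoothed": float(np.nanmax(s.frac_smoothed)),
            "hr": fits[(m, ep)].hr(marker_term(m)),
            "p": fits[(m, ep)].p(marker_term(m)),
        }
        for (m, ep), s in scans.items()
    ]
    pd.DataFrame(cut_rows).to_csv(out / "selected_cutoffs.tsv", sep="\t", index=False)
    bundle["scans"], bundle["fits"] = scans, fits

    # --- backward selection over all markers + clinical -------------------
    if config.run_selection:
        selections = {}
        for ep_name, spec in specs.items():
            try:
                with _stage("backward_aic", ep_name):
                    work = cohort.copy()
                    variables = list(spec.covariates)
                    for m in markers:
                        if (m, ep_name) in scans:
                            col = marker_term(m)
                            work[col] = (work[m] > scans[(m, ep_name)].selected_cutoff).astype(float)
                            variables.append(col)
                    trace = backward_aic(work, spec.time_col, spec.event_col, variables)
                    trace.to_json(out / "selection" / f"{ep_name}.json")
                    trace.to_frame().to_csv(out / "selection" / f"{ep_name}_trace.tsv", sep="\t", index=False)
                    selections[ep_name] = trace
            except StageError:
                if not config.keep_going:
                    raise
                logger.exception("skipping selection for %s under keep_going", ep_name)
        bundle["selection"] = selections

    # --- HR profiles and the spider table ---------------------------------
    if config.run_profiles:
        profiles = []
        per_endpoint: dict[str, set] = {}
        for ep_name in config.profile_endpoints:
            spec = specs[ep_name]
            for m in markers:
                try:
                    with _stage("profile", f"{m}/{ep_name}"):
                        profiles.append(
                            hr_across_cutoffs(cohort, m, spec, min_group_frac=config.min_group_frac)
                        )
                except StageError:
                    if not config.keep_going:
                        raise
                    logger.exception("skipping profile %s/%s under keep_going", m, ep_name)
                    continue
                per_endpoint.setdefault(ep_name, set()).add(m)
        if profiles:
            pd.concat([p.to_frame() for p in profiles]).to_csv(
                out / "profiles" / "hr_profiles.tsv", sep="\t", index=False
            )
            # the spider comparison needs every marker in every endpoint
            common = set.intersection(*per_endpoint.values()) if per_endpoint else set()
            dropped = {p.marker for p in profiles} - common
            if dropped:
                logger.warning("spider table: dropping markers missing in some endpoint: %s", sorted(dropped))
            spider = spider_table([p for p in profiles if p.marker in common])
            spider.to_csv(out / "spider.tsv", sep="\t", index=False)
            bundle["profiles"] = profiles
            bundle["spider"] = spider

    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "config": config.to_dict(),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "versions": {
                    "hazardcut": __version__,
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                },
            },
            fh,
            indent=2,
        )
    return bundle
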
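"""End-to-end pipeline: simulate -> preprocess -> decompose -> impute ->
fit -> effects -> report.

Configuration is one hierarchical YAML mapping (see
:class:`PipelineConfig`); every stage reads and writes delimited-text /
YAML files in the output directory, a global seed deterministically derives
per-stage seeds, and the run manifest records every file written together
with row counts and timings, so a run is reproducible bit-for-bit from its
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .cohort import CohortConfig, TrueParams, apply_missingness, generate_cohort, preprocess
from .decomposition import DecompositionSpec, fit_decomposition_ml, factor_scores, standardize_estimates
from .effects import run_mi_inference
from .mediation import MediationSpec, build_design, fit_growth_mediation, model_fit_indices, predict_trajectories
from .plausible import McmcConfig, chains_psrf, draw_plausible_values, gibbs_decomposition, ppp

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
    "render_report",
    "REQUIRED_COLUMNS",
]

log = logging.getLogger("atnreserve")

REQUIRED_COLUMNS = (
    "age", "sex", "education", "apoe4",
    "hcv", "wbv", "wmh", "tiv",
    "abeta_ratio", "ptau_t0", "ptau_t1", "fdg_t0", "fdg_t2",
    "mem_t0", *cohort_mod.EF_COLUMNS,
)

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_cohort(path, schema=REQUIRED_COLUMNS) -> pd.DataFrame:
    """Read a wide delimited-text cohort table.

    Empty cells and ``NA`` parse as missing; unknown columns are preserved;
    a missing required column or a non-numeric cell raises with the
    offending name / location.
    """
    raw = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=True)
    absent = [c for c in schema if c not in raw.columns]
    if absent:
        raise ValueError(f"cohort file lacks required columns: {absent}")
    for col in schema:
        try:
            raw[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = raw.index[coerced.isna() & raw[col].notna()]
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(
                f"non-numeric cell in column '{col}' at row {row}"
            ) from None
    raw.attrs["preprocessed"] = False
    raw.attrs["missingness_applied"] = True
    log.info("read %d rows from %s (%d missing cells)",
             len(raw), path, int(raw[list(schema)].isna().sum().sum()))
    return raw


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as delimited text (empty cell = missing)."""
    table.to_csv(path, index=False, na_rep="")


@dataclass
class PipelineConfig:
    """Full pipeline configuration (one YAML document)."""

    outdir: str = "atnreserve_run"
    seed: int = 0
    input_path: str | None = None
    simulate: dict | None = None           # CohortConfig/TrueParams overrides
    preprocess: dict = field(default_factory=dict)
    decomposition: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    mediation: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of input_path / simulate must be provided"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    config_hash: str
    global_seed: int
    stage_seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)       # name -> {path, rows}
    timings: dict = field(default_factory=dict)     # stage -> seconds
    n_analyzed: int | None = None

    def record(self, name: str, path: Path, rows: int | None = None):
        self.files[name] = {"path": str(path), "rows": rows}

    def save(self, path: Path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


STAGES = ("simulate", "preprocess", "decompose", "impute", "fit", "effects", "report")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(int(seed) % (2**31))
    children = ss.spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig, stages=None) -> RunManifest:
    """Execute the pipeline (or a prefix-closed subset of its stages)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stages = list(STAGES) if stages is None else list(stages)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config_hash=config.content_hash(),
        global_seed=config.seed,
        stage_seeds=seeds,
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    manifest.record("config", out / "config.yaml")

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", stage)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.timings[stage] = round(time.perf_counter() - self.t0, 3)
                if exc_type is not None:
                    manifest.save(out / "manifest.yaml")
                    log.error("stage %s failed: %s", stage, exc)
                log.info("stage %s: done (%.2fs)", stage, manifest.timings[stage])
        return _T()

    # ---- simulate / read -------------------------------------------------
    if "simulate" in stages:
        with timed("simulate"):
            if config.simulate is not None:
                sim = dict(config.simulate)
                truth_over = sim.pop("truth", {}) or {}
                cc_kwargs = {k: v for k, v in sim.items()
                             if k in {f.name for f in dataclasses.fields(CohortConfig)}}
                cc_kwargs.setdefault("seed", seeds["simulate"])
                cc = CohortConfig(**cc_kwargs)
                truth = TrueParams(**truth_over)
                raw = generate_cohort(cc, truth)
                raw = apply_missingness(raw, cc)
                write_cohort(raw, out / "cohort.csv")
                with open(out / "truth.yaml", "w") as fh:
                    td = dataclasses.asdict(truth)
                    td["psi_eta"] = np.asarray(td["psi_eta"]).tolist()
                    yaml.safe_dump(td, fh, sort_keys=True)
                manifest.record("truth", out / "truth.yaml")
            else:
                raw = read_cohort(config.input_path)
                write_cohort(raw, out / "cohort.csv")
            manifest.record("cohort", out / "cohort.csv", rows=len(raw))
    else:
        raw = read_cohort(out / "cohort.csv")

    # ---- preprocess ------------------------------------------------------
    if "preprocess" in stages:
        with timed("preprocess"):
            table = preprocess(raw, **config.preprocess)
            write_cohort(table, out / "analysis.csv")
            manifest.record("analysis", out / "analysis.csv", rows=len(table))
    else:
        table = pd.read_csv(out / "analysis.csv", na_values=_NA_VALUES)
        table.attrs["preprocessed"] = True

    # ---- decompose -------------------------------------------------------
    dspec = DecompositionSpec(**{
        k: tuple(map(tuple, v)) if k == "zero_cov_constraints" else
        (tuple(v) if isinstance(v, list) else v)
        for k, v in config.decomposition.items()
    })
    if "decompose" in stages:
        with timed("decompose"):
            dfit = fit_decomposition_ml(table, dspec)
            scores = factor_scores(dfit, table)
            scores.to_frame().to_csv(out / "memr_scores.csv", index=False)
            summary = {
                "coefficients": {k: float(v) for k, v in dfit.beta.items()},
                "intercept": dfit.intercept,
                "standardized": {k: float(v) for k, v in
                                 standardize_estimates(dfit).items()},
                "ses": {k: (None if np.isnan(v) else float(v))
                        for k, v in dfit.ses.items()},
                "psi_hat": dfit.psi_hat,
                "theta": dfit.theta,
                "loglik": dfit.loglik,
                "n_used": dfit.n_used,
                "boundary": dfit.boundary,
                "fit": None if dfit.fit is None else dataclasses.asdict(dfit.fit),
            }
            with open(out / "decomposition.yaml", "w") as fh:
                yaml.safe_dump(summary, fh, sort_keys=False)
            manifest.record("decomposition", out / "decomposition.yaml")
            manifest.record("memr_scores", out / "memr_scores.csv", rows=len(scores))
    else:
        dfit = fit_decomposition_ml(table, dspec)

    # ---- impute ----------------------------------------------------------
    eff_opts = dict(config.effects)
    M = int(eff_opts.pop("M", 30))
    if "impute" in stages:
        with timed("impute"):
            mcfg_kwargs = dict(config.mcmc)
            mcfg_kwargs.setdefault("seed", seeds["impute"])
            mcfg = McmcConfig(**mcfg_kwargs)
            chains = gibbs_decomposition(table, dspec, mcfg, ml_fit=dfit)
            pvs = draw_plausible_values(chains, M=M, seed=seeds["impute"])
            pvs.ppp = ppp(chains, seed=seeds["impute"])
            pd.DataFrame(
                pvs.values, columns=[f"im{j+1}" for j in range(M)]
            ).to_csv(out / "plausible_values.csv", index=False)
            diag = {
                "psrf": {k: float(v) for k, v in pvs.psrf.items()},
                "max_psrf": float(max(pvs.psrf.values())),
                "ppp": float(pvs.ppp),
                "icc2k": None if pvs.icc is None else {
                    "value": pvs.icc[0],
                    "ci95": list(pvs.icc[1]),
                },
            }
            with open(out / "imputation_diagnostics.yaml", "w") as fh:
                yaml.safe_dump(diag, fh, sort_keys=False)
            manifest.record("plausible_values", out / "plausible_values.csv",
                            rows=pvs.values.shape[0])
            manifest.record("imputation_diagnostics",
                            out / "imputation_diagnostics.yaml")
            values = pvs.values
    else:
        values = pd.read_csv(out / "plausible_values.csv").to_numpy()

    # ---- fit + effects ---------------------------------------------------
    mspec = MediationSpec(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in config.mediation.items()
    })
    if "fit" in stages or "effects" in stages:
        with timed("effects"):
            w_grid = tuple(eff_opts.pop("w_grid", (-1.0, 0.0, 1.0)))
            B = int(eff_opts.pop("B", 2000))
            alpha = float(eff_opts.pop("alpha", 0.05))
            # express the grid in SDs of the mean plausible value
            w_sd = float(np.std(values.mean(axis=1)))
            grid = tuple(float(g) * w_sd for g in w_grid)
            mi = run_mi_inference(
                values, table, mspec, w_grid=grid, B=B, alpha=alpha,
                seed=seeds["effects"],
            )
            mi.pooled.to_csv(out / "coefficients_pooled.csv", index=False)
            mi.effects.table.to_csv(out / "conditional_effects.csv", index=False)
            mi.boot.to_csv(out / "bootstrap_ci.csv", index=False)
            ds_bar = build_design(
                _with_mean_w(table, mspec, values), mspec
            )
            idx = model_fit_indices(mi.mean_w_fit, ds_bar)
            with open(out / "mediation_fit.yaml", "w") as fh:
                yaml.safe_dump({
                    "n_analyzed": mi.mean_w_fit.n_used,
                    "converged": bool(mi.mean_w_fit.converged),
                    "fit": dataclasses.asdict(idx),
                    "psi_eta": np.asarray(mi.mean_w_fit.psi_eta).tolist(),
                    "theta_ef": np.asarray(mi.mean_w_fit.theta_ef).tolist(),
                }, fh, sort_keys=False)
            traj = predict_trajectories(
                mi.mean_w_fit,
                x_levels=(-1.0, 0.0, 1.0),
                w_levels=tuple(np.asarray(grid)),
            )
            traj.to_csv(out / "trajectories.csv", index=False)
            manifest.record("coefficients_pooled", out / "coefficients_pooled.csv",
                            rows=len(mi.pooled))
            manifest.record("conditional_effects", out / "conditional_effects.csv",
                            rows=len(mi.effects.table))
            manifest.record("bootstrap_ci", out / "bootstrap_ci.csv",
                            rows=len(mi.boot))
            manifest.record("mediation_fit", out / "mediation_fit.yaml")
            manifest.record("trajectories", out / "trajectories.csv", rows=len(traj))
            manifest.n_analyzed = int(mi.mean_w_fit.n_used)
            mi_result = mi
    else:
        mi_result = None

    # ---- report ----------------------------------------------------------
    if "report" in stages and mi_result is not None:
        with timed("report"):
            text = render_report(manifest, out)
            (out / "report.txt").write_text(text)
            manifest.record("report", out / "report.txt")

    manifest.save(out / "manifest.yaml")
    manifest.record("manifest", out / "manifest.yaml")
    manifest.save(out / "manifest.yaml")
    return manifest


def _with_mean_w(table: pd.DataFrame, mspec: MediationSpec, values: np.ndarray):
    work = table.copy()
    work.attrs = dict(table.attrs)
    work[mspec.w_col] = values.mean(axis=1)
    return work


def render_report(manifest: RunManifest, outdir: Path) -> str:
    """Human-readable summary assembled from the stage output files."""
    outdir = Path(outdir)
    lines = ["atnreserve run report", "=" * 60]
    lines.append(f"config hash : {manifest.config_hash}")
    lines.append(f"global seed : {manifest.global_seed}")
    if manifest.n_analyzed is not None:
        lines.append(f"N analyzed  : {manifest.n_analyzed}")
    missing = []

    def section(title):
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))

    dec = outdir / "decomposition.yaml"
    if dec.exists():
        with open(dec) as fh:
            d = yaml.safe_load(fh)
        section("Memory decomposition (residual reserve index)")
        lines.append(f"psi_hat (reserve variance) : {d['psi_hat']:.4f}")
        lines.append(f"theta (fixed error var)    : {d['theta']:.4f}")
        lines.append(f"n used                     : {d['n_used']}")
        lines.append("coefficient        estimate  standardized")
        for k, v in d["coefficients"].items():
            lines.append(f"{k:<18s} {v:9.4f}  {d['standardized'][k]:9.4f}")
    else:
        missing.append("decomposition")

    diag = outdir / "imputation_diagnostics.yaml"
    if diag.exists():
        with open(diag) as fh:
            g = yaml.safe_load(fh)
        section("Plausible-value diagnostics")
        lines.append(f"max PSRF : {g['max_psrf']:.4f}")
        lines.append(f"PPP      : {g['ppp']:.3f}")
        if g.get("icc2k"):
            lo, hi = g["icc2k"]["ci95"]
            lines.append(f"ICC(2,k) : {g['icc2k']['value']:.3f} "
                         f"95% CI ({lo:.3f}, {hi:.3f})")
    else:
        missing.append("imputation diagnostics")

    med = outdir / "mediation_fit.yaml"
    if med.exists():
        with open(med) as fh:
            m = yaml.safe_load(fh)
        section("Moderated sequential mediation model")
        f = m["fit"]
        lines.append(
            f"chi2({f['df']}) = {f['chisq']:.2f}; RMSEA = {f['rmsea']:.3f} "
            f"90% CI ({f['rmsea_ci90'][0]:.3f}, {f['rmsea_ci90'][1]:.3f}); "
            f"CFI = {f['cfi']:.3f}; TLI = {f['tli']:.3f}; SRMR = {f['srmr']:.3f}"
        )
    else:
        missing.append("mediation fit")

    coefs = outdir / "coefficients_pooled.csv"
    if coefs.exists():
        cdf = pd.read_csv(coefs)
        section("Pooled structural coefficients (Rubin's rules)")
        lines.append(f"{'coefficient':<18s}{'est':>9s}{'se':>9s}{'ci_lo':>9s}{'ci_hi':>9s}")
        for _, r in cdf.iterrows():
            if str(r['coefficient']).startswith("phi_"):
                continue
            lines.append(
                f"{r['coefficient']:<18s}{r['estimate']:9.4f}{r['se']:9.4f}"
                f"{r['ci_lo']:9.4f}{r['ci_hi']:9.4f}"
            )
    else:
        missing.append("pooled coefficients")

    eff = outdir / "conditional_effects.csv"
    if eff.exists():
        edf = pd.read_csv(eff)
        section("Conditional effects over the moderator grid")
        lines.append(edf.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))
    boot = outdir / "bootstrap_ci.csv"
    if boot.exists():
        bdf = pd.read_csv(boot)
        section("Bias-corrected bootstrap 95% CIs (mean plausible values)")
        imm = bdf[bdf["quantity"].str.startswith("imm_")]
        lines.append(imm.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))

    if missing:
        section("WARNINGS")
        lines.append("partial report; missing stage outputs: " + ", ".join(missing))
    return "\n".join(lines) + "\n"
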
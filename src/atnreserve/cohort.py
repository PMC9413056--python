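"""Synthetic aging-cohort generator with a known structural ground truth.

The generator draws subject-level tables that mimic the marginal moments of
an aging/AD research cohort (demographics, MRI volumes, CSF amyloid ratio,
plasma p-tau181, FDG SUVR, memory and executive-function composites) while
embedding a fully known structural model:

* a latent residual reserve component (``MEMR``) of baseline memory, on top
  of demographic and brain-integrity predictors;
* a sequential amyloid -> tau -> FDG-metabolism cascade with the reserve
  component moderating every path (interaction coefficients configurable);
* a latent linear growth model for executive function (intercept centred at
  the third annual visit, slope per year) driven by the biomarkers, the
  moderator, their products, and demographic covariates.

Because every arrow carries a named coefficient in :class:`TrueParams`,
every downstream estimator can be validated by parameter recovery.

Conventions follow the field: a *lower* amyloid ratio means more amyloid
pathology, *higher* p-tau181 means more tau pathology, and *lower* FDG SUVR
means more neurodegeneration.  Structural equations operate on z-scored
biomarkers; raw columns are affine maps of those z-scores with configurable
location/scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrueParams",
    "CohortConfig",
    "EF_COLUMNS",
    "DEFAULT_DECOMPOSITION_BETA",
    "generate_cohort",
    "apply_missingness",
    "preprocess",
]

EF_COLUMNS = tuple(f"ef_t{t}" for t in range(8))

#: Default decomposition coefficients, on the analysis (preprocessed) scale:
#: composite-score units per year (age/education), per allele (APOE4), per
#: SD (volumes, log-WMH, biomarkers), per 0/1 code (sex, race, ethnicity).
DEFAULT_DECOMPOSITION_BETA: dict[str, float] = {
    "age_c": -0.020,
    "sex": -0.100,
    "educ_c": 0.030,
    "apoe4": -0.100,
    "race": 0.0,
    "ethnicity": 0.0,
    "hcv_adj": 0.250,
    "wbv_adj": 0.100,
    "logwmh": -0.050,
    "abeta_ratio": 0.100,
    "ptau_t0": -0.100,
    "fdg_t0": 0.200,
}


@dataclass
class TrueParams:
    """Ground-truth parameterization of the full structural model.

    Structural paths are in z-score units of the biomarkers (and in the raw
    units of the moderator ``MEMR`` and of the EF composite).  ``a1``/``a2``
    are the amyloid-ratio effects on tau and FDG, ``d21`` the tau effect on
    FDG; ``b1_*``/``b2_*``/``c_*`` feed the EF growth intercept (``_I``) and
    slope (``_S``); ``g_*`` are moderator main effects; the ``*w`` terms are
    the moderator interactions, one per structural arrow.
    """

    decomposition_beta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DECOMPOSITION_BETA)
    )
    psi_true: float = 0.35          # latent MEMR variance
    theta_true: float = 0.161       # fixed memory error variance
    mem_intercept: float = 0.31

    # amyloid cascade (z units)
    a1: float = -0.33               # amyloid ratio -> tau
    a2: float = 0.33                # amyloid ratio -> FDG
    d21: float = -0.20              # tau -> FDG
    tau_const: float = 0.0
    fdg_const: float = 0.0

    # growth-factor equations
    b1_I: float = -0.10             # tau -> EF intercept
    b1_S: float = -0.01             # tau -> EF slope
    b2_I: float = 0.40              # FDG -> EF intercept
    b2_S: float = 0.04              # FDG -> EF slope
    c_I: float = 0.20               # direct amyloid -> EF intercept
    c_S: float = 0.02               # direct amyloid -> EF slope

    # moderator main effects
    g_tau: float = 0.0
    g_fdg: float = 0.0
    g_I: float = 0.30
    g_S: float = 0.02

    # moderator interactions (all nine paths of the mediation component)
    a1w: float = 0.0
    a2w: float = -0.25
    d21w: float = 0.0
    b1w_I: float = 0.0
    b1w_S: float = 0.0
    b2w_I: float = 0.0
    b2w_S: float = 0.0
    cw_I: float = 0.0
    cw_S: float = 0.0

    # covariate effects on the growth factors
    cov_age_I: float = -0.020
    cov_age_S: float = -0.004
    cov_sex_I: float = -0.050
    cov_sex_S: float = 0.0
    cov_educ_I: float = 0.030
    cov_educ_S: float = 0.002

    intercept_const: float = 0.20
    slope_const: float = -0.05

    psi_eta: np.ndarray = field(
        default_factory=lambda: np.array([[0.30, -0.01], [-0.01, 0.012]])
    )
    theta_ef: float = 0.15
    resid_tau: float = 0.89
    resid_fdg: float = 0.80
    t0_biomarker_corr: float = 0.80

    def __post_init__(self):
        self.psi_eta = np.asarray(self.psi_eta, dtype=float)
        for name in ("psi_true", "theta_true", "resid_tau", "resid_fdg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.theta_ef < 0:
            raise ValueError("theta_ef must be >= 0")
        eig = np.linalg.eigvalsh((self.psi_eta + self.psi_eta.T) / 2.0)
        if eig.min() < -1e-12:
            raise ValueError("psi_eta must be positive semi-definite")

    def structural_truth(self) -> dict[str, float]:
        """Flat name -> value map of every mediation-model coefficient."""
        names = [
            "a1", "a2", "d21", "b1_I", "b1_S", "b2_I", "b2_S", "c_I", "c_S",
            "g_tau", "g_fdg", "g_I", "g_S",
            "a1w", "a2w", "d21w", "b1w_I", "b1w_S", "b2w_I", "b2w_S",
            "cw_I", "cw_S",
            "cov_age_I", "cov_age_S", "cov_sex_I", "cov_sex_S",
            "cov_educ_I", "cov_educ_S",
        ]
        return {k: float(getattr(self, k)) for k in names}


def _default_moments() -> dict:
    # Marginal moments of the emulated cohort (full-sample characteristics).
    return {
        "age": (73.10, 7.27),
        "p_male": 0.529,
        "education": (16.06, 2.75),
        "apoe4_probs": (0.531, 0.371, 0.098),
        "p_african_american": 0.058,
        "p_hispanic": 0.045,
        "tiv": (1514968.61, 164049.96),
        "hcv": (6989.14, 1130.00),
        "hcv_tiv_corr": 0.40,
        "wbv": (910437.0, 98483.23),
        "wbv_tiv_corr": 0.70,
        "wmh": (6.02, 9.43),            # lognormal; log-transformed downstream
        "abeta_ratio": (0.14, 0.06),
        "apoe4_abeta_shift": -0.50,      # z-shift of amyloid ratio per allele
        "ptau_t0": (18.48, 12.32),
        "ptau_t1": (18.59, 11.56),
        "fdg_t0": (1.23, 0.15),
        "fdg_t2": (1.21, 0.17),
    }


@dataclass
class CohortConfig:
    """Size, marginal moments, missingness model and seed for one cohort."""

    n_subjects: int = 2351
    seed: int = 0
    moments: dict = field(default_factory=_default_moments)
    include_truth: bool = True

    # missingness model
    complete_biomarker_fraction: float = 332.0 / 2351.0
    family_missing_prob: float = 0.60     # per biomarker family, incomplete subjects
    dropout_intercept: float = -2.44      # logit of the per-visit hazard
    dropout_slope_prev_ef: float = -0.30
    dropout_slope_age: float = 0.02

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0.0 < self.complete_biomarker_fraction <= 1.0):
            raise ValueError("complete_biomarker_fraction must be in (0, 1]")
        moments = _default_moments()
        moments.update(self.moments)
        self.moments = moments


def generate_cohort(config: CohortConfig, truth: TrueParams | None = None) -> pd.DataFrame:
    """Draw a complete (no missingness) cohort from the structural truth.

    Deterministic given ``config.seed``.  Hidden ground-truth columns
    (``true_memr``, ``true_intercept``, ``true_slope``) are included when
    ``config.include_truth`` and must never be consumed by estimators.
    """
    truth = truth if truth is not None else TrueParams()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    mo = config.moments

    # --- demographics -----------------------------------------------------
    age = rng.normal(mo["age"][0], mo["age"][1], n)
    sex = (rng.random(n) < mo["p_male"]).astype(float)
    education = np.clip(rng.normal(*mo["education"], n), 6.0, 24.0)
    apoe4 = rng.choice(3, size=n, p=np.asarray(mo["apoe4_probs"]) / sum(mo["apoe4_probs"]))
    race = (rng.random(n) < mo["p_african_american"]).astype(float)
    ethnicity = (rng.random(n) < mo["p_hispanic"]).astype(float)
    age_c = age - mo["age"][0]
    educ_c = education - 12.0

    # --- brain volumes (WBV/HCV linear in TIV + noise) --------------------
    tiv = rng.normal(*mo["tiv"], n)
    tiv_sd = mo["tiv"][1]

    def _volume(mean_sd, r):
        m, s = mean_sd
        slope = r * s / tiv_sd
        resid_sd = s * np.sqrt(1.0 - r**2)
        z = rng.standard_normal(n)
        vol = m + slope * (tiv - mo["tiv"][0]) + resid_sd * z
        return vol, z

    hcv, hcv_z = _volume(mo["hcv"], mo["hcv_tiv_corr"])
    wbv, wbv_z = _volume(mo["wbv"], mo["wbv_tiv_corr"])

    # WMH lognormal with the configured raw mean/SD
    m_w, s_w = mo["wmh"]
    sig2 = np.log1p((s_w / m_w) ** 2)
    mu_l = np.log(m_w) - sig2 / 2.0
    logwmh_z = rng.standard_normal(n)
    wmh = np.exp(mu_l + np.sqrt(sig2) * logwmh_z)

    # --- amyloid ratio (APOE4-dependent mean; lower = more pathology) -----
    shift = mo["apoe4_abeta_shift"]
    mu_a = shift * apoe4 - shift * float(np.dot([0, 1, 2], mo["apoe4_probs"]))
    var_mu = float(np.dot(mo["apoe4_probs"], (shift * np.arange(3)) ** 2)
                   - (shift * np.dot([0, 1, 2], mo["apoe4_probs"])) ** 2)
    resid_sd_a = np.sqrt(max(1.0 - var_mu, 0.05))
    abeta_z = mu_a + resid_sd_a * rng.standard_normal(n)
    abeta_ratio = mo["abeta_ratio"][0] + mo["abeta_ratio"][1] * abeta_z

    # --- latent reserve and the amyloid cascade ---------------------------
    memr = rng.normal(0.0, np.sqrt(truth.psi_true), n)
    x = abeta_z
    w = memr
    tau_z = (
        truth.tau_const + truth.a1 * x + truth.g_tau * w + truth.a1w * x * w
        + np.sqrt(truth.resid_tau) * rng.standard_normal(n)
    )
    fdg_z = (
        truth.fdg_const + truth.a2 * x + truth.d21 * tau_z + truth.g_fdg * w
        + truth.a2w * x * w + truth.d21w * tau_z * w
        + np.sqrt(truth.resid_fdg) * rng.standard_normal(n)
    )
    # T0 companions correlate with the *linear* part of the analysis-time
    # biomarkers: the moderator interactions act on the downstream (T1/T2)
    # measurements, so the baseline decomposition stays linear-Gaussian in
    # its predictors (the study found the baseline model well specified)
    rho = truth.t0_biomarker_corr
    tau_lin = tau_z - truth.a1w * x * w
    fdg_lin = fdg_z - truth.a2w * x * w - truth.d21w * tau_z * w
    tau0_z = rho * tau_lin + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    fdg0_z = rho * fdg_lin + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    ptau_t1 = mo["ptau_t1"][0] + mo["ptau_t1"][1] * tau_z
    ptau_t0 = mo["ptau_t0"][0] + mo["ptau_t0"][1] * tau0_z
    fdg_t2 = mo["fdg_t2"][0] + mo["fdg_t2"][1] * fdg_z
    fdg_t0 = mo["fdg_t0"][0] + mo["fdg_t0"][1] * fdg0_z

    # --- baseline memory composite ----------------------------------------
    beta = truth.decomposition_beta
    predictors = {
        "age_c": age_c, "sex": sex, "educ_c": educ_c, "apoe4": apoe4.astype(float),
        "race": race, "ethnicity": ethnicity,
        "hcv_adj": hcv_z, "wbv_adj": wbv_z, "logwmh": logwmh_z,
        "abeta_ratio": abeta_z, "ptau_t0": tau0_z, "fdg_t0": fdg0_z,
    }
    lin = truth.mem_intercept + sum(
        beta.get(name, 0.0) * col for name, col in predictors.items()
    )
    mem_t0 = lin + memr + np.sqrt(truth.theta_true) * rng.standard_normal(n)

    # --- EF growth factors and repeated measures --------------------------
    intercept = (
        truth.intercept_const
        + truth.c_I * x + truth.b1_I * tau_z + truth.b2_I * fdg_z
        + truth.g_I * w
        + truth.cw_I * x * w + truth.b1w_I * tau_z * w + truth.b2w_I * fdg_z * w
        + truth.cov_age_I * age_c + truth.cov_sex_I * sex + truth.cov_educ_I * educ_c
    )
    slope = (
        truth.slope_const
        + truth.c_S * x + truth.b1_S * tau_z + truth.b2_S * fdg_z
        + truth.g_S * w
        + truth.cw_S * x * w + truth.b1w_S * tau_z * w + truth.b2w_S * fdg_z * w
        + truth.cov_age_S * age_c + truth.cov_sex_S * sex + truth.cov_educ_S * educ_c
    )
    if np.any(np.linalg.eigvalsh(truth.psi_eta) > 0):
        eta = rng.multivariate_normal(np.zeros(2), truth.psi_eta, size=n, method="eigh")
        intercept = intercept + eta[:, 0]
        slope = slope + eta[:, 1]

    data = {
        "age": age, "sex": sex, "education": education,
        "apoe4": apoe4.astype(float), "race": race, "ethnicity": ethnicity,
        "hcv": hcv, "wbv": wbv, "wmh": wmh, "tiv": tiv,
        "abeta_ratio": abeta_ratio,
        "ptau_t0": ptau_t0, "ptau_t1": ptau_t1,
        "fdg_t0": fdg_t0, "fdg_t2": fdg_t2,
        "mem_t0": mem_t0,
    }
    ef_sd = np.sqrt(truth.theta_ef)
    for t in range(8):
        noise = ef_sd * rng.standard_normal(n) if truth.theta_ef > 0 else 0.0
        data[f"ef_t{t}"] = intercept + (t - 3) * slope + noise
    if config.include_truth:
        data["true_memr"] = memr
        data["true_intercept"] = intercept
        data["true_slope"] = slope
    table = pd.DataFrame(data)
    table.attrs["preprocessed"] = False
    table.attrs["missingness_applied"] = False
    return table


_BIOMARKER_FAMILIES = (
    ("abeta_ratio",),
    ("ptau_t0", "ptau_t1"),
    ("fdg_t0", "fdg_t2"),
)


def apply_missingness(table: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Impose the study's missingness structure on a complete cohort.

    A random subset of the configured fraction keeps complete biomarkers
    (mirroring the subsample with full amyloid/tau/FDG coverage); the
    remaining subjects lose whole biomarker families at random (at least
    one family each).  Executive function follows monotone dropout with a
    per-visit hazard that is logistic in the previous EF value and age.
    """
    if table.attrs.get("missingness_applied"):
        raise ValueError("missingness already applied to this table")
    if table[[c for fam in _BIOMARKER_FAMILIES for c in fam]].isna().any().any():
        raise ValueError("table already contains missing biomarker cells")
    out = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7019]))
    n = len(out)

    n_complete = int(round(config.complete_biomarker_fraction * n))
    n_complete = max(min(n_complete, n), 1)
    complete_idx = rng.choice(n, size=n_complete, replace=False)
    incomplete = np.ones(n, dtype=bool)
    incomplete[complete_idx] = False

    if incomplete.any():
        m = int(incomplete.sum())
        knock = rng.random((m, len(_BIOMARKER_FAMILIES))) < config.family_missing_prob
        none = ~knock.any(axis=1)
        if none.any():
            forced = rng.integers(0, len(_BIOMARKER_FAMILIES), size=int(none.sum()))
            knock[np.flatnonzero(none), forced] = True
        rows = np.flatnonzero(incomplete)
        for f, fam in enumerate(_BIOMARKER_FAMILIES):
            hit = rows[knock[:, f]]
            for col in fam:
                out.iloc[hit, out.columns.get_loc(col)] = np.nan

    # monotone EF dropout
    age_c = out["age"].to_numpy() - config.moments["age"][0]
    dropped = np.zeros(n, dtype=bool)
    for t in range(1, 8):
        prev = out[f"ef_t{t-1}"].to_numpy()
        prev_filled = np.where(np.isnan(prev), 0.0, prev)
        logit = (
            config.dropout_intercept
            + config.dropout_slope_prev_ef * prev_filled
            + config.dropout_slope_age * age_c
        )
        hazard = 1.0 / (1.0 + np.exp(-logit))
        new_drop = rng.random(n) < hazard
        dropped |= new_drop
        out.loc[dropped, f"ef_t{t}"] = np.nan
    out.attrs = dict(table.attrs)
    out.attrs["missingness_applied"] = True
    return out


def preprocess(
    table: pd.DataFrame,
    age_center: float = 73.10,
    educ_center: float = 12.0,
    zscore_biomarkers: bool = True,
    standardize_ef: bool = True,
) -> pd.DataFrame:
    """Apply the analysis-scale transformations to a raw cohort table.

    * WMH is replaced by its natural log (``logwmh``); WMH must be > 0.
    * Hippocampal and whole-brain volumes are regressed on total
      intracranial volume; the residuals (``hcv_adj``, ``wbv_adj``) carry
      head-size-corrected volume information.
    * Education is centred on ``educ_center`` years, age on ``age_center``.
    * EF columns are standardized by the analysis sample's baseline (T0)
      mean and SD, so EF change reads in baseline SD units.
    * With ``zscore_biomarkers`` (default), the amyloid ratio, p-tau181,
      FDG, adjusted volumes and log-WMH are z-scored in-sample.

    All transformations are recorded in ``table.attrs['provenance']``; a
    second application raises.
    """
    if table.attrs.get("preprocessed"):
        raise ValueError("table is already preprocessed (provenance flag set)")
    out = table.copy()
    prov: dict = {"age_center": age_center, "educ_center": educ_center}

    wmh = out["wmh"].to_numpy()
    if np.any(wmh[~np.isnan(wmh)] <= 0):
        rows = np.flatnonzero((wmh <= 0) & ~np.isnan(wmh)).tolist()
        raise ValueError(f"wmh must be > 0 before log transform; offending rows {rows[:20]}")
    out["logwmh"] = np.log(wmh)
    out = out.drop(columns=["wmh"])

    for vol, name in (("hcv", "hcv_adj"), ("wbv", "wbv_adj")):
        v = out[vol].to_numpy()
        tiv = out["tiv"].to_numpy()
        ok = ~np.isnan(v) & ~np.isnan(tiv)
        X = np.column_stack([np.ones(ok.sum()), tiv[ok]])
        coef, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
        resid = np.full_like(v, np.nan)
        resid[ok] = v[ok] - (coef[0] + coef[1] * tiv[ok])
        out[name] = resid
        prov[f"{name}_tiv_coef"] = [float(coef[0]), float(coef[1])]

    out["age_c"] = out["age"] - age_center
    out["educ_c"] = out["education"] - educ_center

    if zscore_biomarkers:
        zcols = ["abeta_ratio", "ptau_t0", "ptau_t1", "fdg_t0", "fdg_t2",
                 "hcv_adj", "wbv_adj", "logwmh"]
        scales = {}
        for col in zcols:
            v = out[col].to_numpy()
            m, s = np.nanmean(v), np.nanstd(v)
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"cannot z-score degenerate column {col}")
            out[col] = (v - m) / s
            scales[col] = [float(m), float(s)]
        prov["zscore_scales"] = scales

    if standardize_ef:
        ef0 = out["ef_t0"].to_numpy()
        m, s = np.nanmean(ef0), np.nanstd(ef0)
        if not np.isfinite(s) or s <= 0:
            raise ValueError("cannot standardize EF: degenerate T0 column")
        for col in EF_COLUMNS:
            out[col] = (out[col] - m) / s
        prov["ef_t0_scale"] = [float(m), float(s)]

    out.attrs = dict(table.attrs)
    out.attrs["preprocessed"] = True
    out.attrs["provenance"] = prov
    return out
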
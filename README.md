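# atnreserve

Residual cognitive-reserve index and moderated sequential mediation over
AT(N) biomarkers, with a latent-growth executive-function outcome.

## The problem

In aging and Alzheimer's-disease research, *cognitive reserve* is the
capacity to perform better than expected given one's brain pathology. The
residual approach operationalizes it as the part of a memory composite not
explained by demographics and brain integrity: regress baseline memory on
age, sex, education, APOE ε4, MRI volumes and AT(N) biomarkers, fix the
known measurement-error variance, and call the remaining latent variance
the **residual reserve index** (MEMR):

    mem = b0 + beta' x + MEMR + e,   MEMR ~ N(0, psi),  e ~ N(0, 0.161)

The scientific question this package serves: *where* along the amyloid →
tau → neurodegeneration → cognition cascade does reserve act? MEMR enters
a serial mediation model (amyloid ratio X → plasma p-tau181 M1 → FDG
metabolism M2 → executive-function growth factors) as a moderator of every
path, and the conditional indirect effects

    B_AT(w)  = (a1 + a1w·w)(b1 + b1w·w)
    B_ATN(w) = (a1 + a1w·w)(d21 + d21w·w)(b2 + b2w·w)
    B_AN(w)  = (a2 + a2w·w)(b2 + b2w·w)

are traced over the moderator, with the index of moderated mediation
(IMM = dB/dw), bias-corrected bootstrap CIs, and Rubin's-rules pooling
across 30 Bayesian plausible-value imputations of MEMR. The executive
outcome is a latent linear growth model (intercept at the third annual
visit, slope per year) estimated by full-information ML under monotone
dropout.

Because the motivating cohort data are access-restricted, the package
includes a synthetic cohort generator with a fully known structural ground
truth; all estimators are validated by parameter recovery, closed-form and
brute-force oracles, and calibration simulations (see `docs/methods.md`).

## Worked example

```python
import atnreserve as a

# 1. simulate a cohort under the default study conditions
cc = a.CohortConfig(n_subjects=600, seed=11, complete_biomarker_fraction=0.5)
raw = a.apply_missingness(a.generate_cohort(cc, a.TrueParams()), cc)
table = a.preprocess(raw)               # log-WMH, TIV residuals, z-scores, EF T0-standardized

# 2. decomposition -> residual reserve index
fit = a.fit_decomposition_ml(table, a.DecompositionSpec())
print(f"psi_hat = {fit.psi_hat:.3f}  (reserve variance; theta fixed at {fit.theta})")

# 3. Bayesian plausible values
chains = a.gibbs_decomposition(table, a.DecompositionSpec(), a.McmcConfig(seed=1))
pvs = a.draw_plausible_values(chains, M=10)
print(f"max PSRF = {max(pvs.psrf.values()):.3f}   ICC(2,k) = {pvs.icc[0]:.3f}")

# 4. moderated sequential mediation, pooled across imputations
res = a.run_mi_inference(pvs.values, table, a.MediationSpec(w_col="memr"),
                         B=500, seed=2)
row = res.pooled.set_index("coefficient").loc["a2w"]
print(f"a2w (amyloid x reserve -> FDG) = {row['estimate']:.3f} "
      f"[{row['ci_lo']:.3f}, {row['ci_hi']:.3f}]")
imm = res.boot.set_index("quantity").loc["imm_AN_I"]
print(f"IMM_AN (intercept) = {imm['estimate']:.3f} "
      f"BC bootstrap CI [{imm['ci_lo']:.3f}, {imm['ci_hi']:.3f}]")
```

Output from this exact script (seeds as shown):

```
psi_hat = 0.396  (reserve variance; theta fixed at 0.161)
max PSRF = 1.010   ICC(2,k) = 0.953
a2w (amyloid x reserve -> FDG) = -0.188 [-0.386, 0.011]
IMM_AN (intercept) = -0.158 BC bootstrap CI [-0.275, -0.033]
```

Read: the latent reserve variance is recovered near its generating value
(0.35); the chains pass the PSRF < 1.1 gate and the 10 plausible-value
columns agree highly (ICC 0.95); the amyloid-by-reserve interaction on FDG
metabolism is negative (higher reserve predicts relatively higher
metabolism — less neurodegeneration — when amyloid pathology is severe,
and lower metabolism when it is mild), and the bias-corrected bootstrap CI
for the index of moderated mediation on the amyloid → FDG → EF-intercept
pathway excludes zero accordingly.

The same workflow runs from the shell:

```bash
atnreserve all --config run.yaml --seed 11
```

with a YAML config naming either an input cohort CSV or a simulation
block; each stage writes delimited-text/YAML outputs plus a run manifest
and a plain-text report.

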
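# ntcp-rectox

NTCP modeling of acute grade ≥2 rectal toxicity in prostate IMRT,
integrating treatment-planning dosimetry with patient-specific
characteristics. The package is aimed at radiotherapy outcome modelers and
biostatisticians who want a tested, reusable implementation of the full
analysis chain: EQD2-corrected DVH dosimetry, Lyman-Kutcher-Burman and
multivariate logistic NTCP models, ROC-driven selection of the best
dosimetric index, LASSO selection of clinical covariates, and the cohort
statistics behind exposure-stratified toxicity rates.

## The models

**LKB.** The dose distribution is reduced to the generalized equivalent
uniform dose, a power mean over volume fractions vᵢ and voxel doses Dᵢ,

    gEUD = (Σᵢ vᵢ Dᵢ^{1/n})ⁿ,

and mapped through a probit response

    NTCP = Φ((gEUD − TD50) / (m · TD50)),

with TD50 (Gy), slope m and volume exponent n fitted by maximum likelihood
(Nelder-Mead in log coordinates, multi-start; profile-likelihood CIs).
Fixed published parameter sets (e.g. the QUANTEC late rectal model) can be
applied to any cohort for comparison.

**Logistic.** logit(NTCP) = α₀ + Σₖ αₖxₖ + γ·D, where D is a dosimetric
index (D_X%: lowest dose to the hottest X% of volume; V_DGy: volume
fraction at or above D Gy) computed from EQD2-corrected doses
(EQD2 = D·(d + α/β)/(2 + α/β), α/β = 3 Gy), and xₖ are covariates such as
statin use (0/1) or PSA (ng/mL). A univariate sweep over the index grid
picks the most predictive index by ROC AUC; LASSO (dose term unpenalized,
penalty by stratified cross-validation under the one-SE rule) selects the
covariates; inference comes from an unpenalized refit on the selected set.

Because no patient-level data are distributed, a synthetic cohort
generator (`ntcp_rectox.synthetic_cohort`) emulates the study population —
79 prostate IMRT patients with realistic rectal DVHs (D_max ≈ 81.3 Gy,
D_mean ≈ 33.1 Gy), the reported covariate prevalences, and toxicity drawn
from a configurable generating model — so every stage is testable
end-to-end, including parameter recovery against a known truth.

## Worked example

```python
from ntcp_rectox import (CohortSpec, generate_cohort, compute_index_values,
                         fit_logistic, auc, auc_ci, contingency_2x2,
                         prevalence_shift_factor)
from ntcp_rectox.synthetic_cohort import default_logistic_truth

truth = default_logistic_truth()          # reduced-model slopes, 20% event rate
cohort = generate_cohort(CohortSpec(n_patients=79, seed=1, toxicity_model=truth))

vals = compute_index_values(cohort.doses, truth.index)   # EQD2 D25% per patient
model = fit_logistic(cohort.patients, cohort.outcomes, truth.index, vals,
                     ("psa", "statins"))
for name in model.coefs:
    lo, hi = model.ci95[name]
    print(f"{name:10s} {model.coefs[name]:8.3f}  [{lo:7.3f}, {hi:7.3f}]"
          f"  p={model.pvalues[name]:.3f}")

scores = [model.predict(cohort.patients.iloc[i], vals[i]) for i in range(79)]
lo, hi = auc_ci(scores, cohort.outcomes, seed=1)
print(f"AUC {auc(scores, cohort.outcomes):.2f} [{lo:.2f}, {hi:.2f}]")
```

prints

```
intercept    -5.045  [-10.018,  -0.617]  p=0.032
D25%          0.223  [  0.089,   0.388]  p=0.003
psa          -0.628  [ -1.092,  -0.278]  p=0.002
statins      -0.951  [ -2.522,   0.446]  p=0.200
AUC 0.86 [0.75, 0.95]
```

This 79-patient draw produced 16 toxicity events (20.3%). The fitted
coefficients recover the generating slopes (dose 0.19/Gy, PSA −0.53,
statins −1.83) within the wide single-cohort CIs — at 16 events the statin
term is not individually significant in every draw, which is exactly why
the package also reports the unprocessed contingency table:

```python
res = contingency_2x2(cohort.patients, "statins", "tox_acute_ge2")
# statins: 4/32 = 12.5% vs 12/47 = 25.5%, OR 0.42, Fisher p = 0.254

prevalence_shift_factor(1/3, 0.20, 0.50)   # -> 0.769...
```

The last line projects the population consequence of a protective
exposure: if an exposure cuts risk threefold and its prevalence rises from
20% to 50%, expected toxicity incidence falls by the factor 0.77 (−23%).

The full study replica — simulate or load a cohort, fit LKB and the
QUANTEC comparison, sweep indices, select covariates, fit the multivariate
tables, compute cohort statistics and prediction curves — is one call
(`run_full_analysis`) or one shell command:

```sh
ntcp-rectox simulate --n 79 --seed 1 --out cohort/
ntcp-rectox run --config analysis.yaml
```

writing `report.json`, `table1_lkb.csv`, `sweep.csv`, `table2_mv.csv`,
`fig2_curves.csv` and `cohort_stats.json` into the output directory.

## Layout

| module | contents |
| --- | --- |
| `ntcp_rectox.dvh` | dose containers, EQD2 correction, DVH build, D_X%/V_D indices, CSV I/O |
| `ntcp_rectox.lkb` | gEUD, LKB likelihood, MLE with restarts, profile/Wald CIs, partial models, fixed-parameter application |
| `ntcp_rectox.logistic` | logistic MLE with profile CIs, univariate index sweep, LASSO selection |
| `ntcp_rectox.roc` | pairwise AUC, ROC curves, bootstrap/DeLong CIs |
| `ntcp_rectox.stats` | 2×2 contingency, two-sample comparison, prevalence-shift projection |
| `ntcp_rectox.synthetic_cohort` | cohort generator, generating truths, cohort I/O |
| `ntcp_rectox.pipeline` | end-to-end orchestration, report tables, prediction curves |
| `ntcp_rectox.cli` | `ntcp-rectox` command-line interface |

See `docs/methods.md` for model assumptions, calibration of the
generator, numerical choices and known limitations.
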
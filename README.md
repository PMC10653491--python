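# ctiva — censored time-interval variable analysis

Biomedical cohorts often record **two** censored event times per subject —
say, diagnosis of a carcinoma (event 1) and death (event 2) — together with
many categorical and continuous covariates (clinical codes, gene
expression).  The scientific target is frequently neither event on its own
but the **interval between them**, `T2 − T1`: which covariates are
associated with how long a patient survives after diagnosis?  With
right-censoring on either event the interval is unobserved for a large
fraction of subjects, and naive fixes (treating censoring times as events,
or dropping censored subjects) visibly distort the ranking of covariates.

`ctiva` implements a three-stage pipeline for this setting, for
statisticians and bioinformaticians working with doubly-censored
time-to-event tables:

1. **Joint density estimation.** The joint density `f(T1, T2)` is estimated
   from the observed records `(V1, Δ1, V2, Δ2)`, `V = min(T, C)`,
   `Δ = 1{T ≤ C}`, with a bivariate **Optional Polya Tree**: a recursive
   midpoint partition of the plane whose stop/split decisions follow the
   marginal likelihood

   `Φ(A) = ½Φ0(A) + ¼ Σᵢ [B(N(Aᵢ₁)+½, N(Aᵢ₂)+½)/B(½,½)] Φ(Aᵢ₁)Φ(Aᵢ₂)`,

   yielding a piecewise-constant density with leaf values `N(A)/(n|A|)`.
   Censoring is handled by replacing counts with expected counts `N(A|f)`
   and iterating `f ← OPT(N(·|f))` to a fixed point from a Kaplan–Meier
   independence initialisation.
2. **Interval imputation.** Per sample, `y = E[T2 − T1 | V1, Δ1, V2, Δ2]`
   by exact conditional Monte-Carlo sampling from the fitted density
   (four censoring cases; fully observed samples are exact).
3. **Screening.** Each covariate is tested against `y` (ANOVA for
   categorical, regression slope for continuous, permutation and Spearman
   rank tests for both), and detection is summarised by ROC/AUC and
   sensitivity/specificity over the p-value threshold.

The package also contains the full simulation study around the method: the
three data generators (additive exponential, log-normal, Clayton–Oakes),
the covariate block design (interval-/T1-/T2-correlated and null
variables, categorical, continuous, and correlated-group variants), and
the comparator methods (ignore-censoring, complete-case, per-variable
univariate Cox on a single event).

## Worked example

```python
import numpy as np
from ctiva import SimConfig, make_replicate, fit_joint, estimate_all, screen, roc_auc

rep = make_replicate(SimConfig(seed=1))          # 500 samples, 1000 binary covariates
obs = rep.observations                           # columns v1, delta1, v2, delta2

fit = fit_joint(obs, max_depth=8, tol=1e-3)      # bivariate OPT fixed point
est = estimate_all(fit.density, obs, n_mc=1000, rng_seed=1)
y = est["y"].to_numpy()                          # expected interval per sample

print(est["case"].value_counts().to_dict())
print("corr(y, latent T2-T1):", round(np.corrcoef(y, rep.t2 - rep.t1)[0, 1], 3))
naive = (obs.v2 - obs.v1).to_numpy()
print("corr(naive, latent T2-T1):", round(np.corrcoef(naive, rep.t2 - rep.t1)[0, 1], 3))

pv = screen(rep.covariates, rep.variable_types, y, tests=("anova",))
report = roc_auc(pv["p_value"].to_numpy(), (rep.truth == "interval").astype(int))
print("AUC:", round(report.auc, 3), "sens@0.05:", report.sensitivity[0.05])
```

Output:

```
{'both_observed': 231, 't2_censored': 145, 't1_censored': 64, 'both_censored': 60}
corr(y, latent T2-T1): 0.631
corr(naive, latent T2-T1): 0.312
AUC: 0.951 sens@0.05: 0.91
```

Read: about half the samples have at least one censored event; the imputed
interval doubles the correlation with the latent truth relative to naive
`V2 − V1`, and the ANOVA screen ranks the 100 interval-correlated variables
far ahead of the 900 others (AUC 0.95), detecting 91 of them at p < 0.05.

The same flow is available from the shell:

```
ctiva simulate --out data/ --seed 1
ctiva fit --data data/dataset.csv --out density.json
ctiva intervals --data data/dataset.csv --density density.json --out intervals.csv
ctiva screen --data data/dataset.csv --intervals intervals.csv --out results/
ctiva baseline --data data/dataset.csv --method cox1 --out results/
ctiva evaluate --reps 20 --out results/   # full multi-method comparison
```

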
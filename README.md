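# crtmi — multiple imputation for bivariate outcomes in cluster randomised trials

Cluster randomised trials (CRTs) randomise intact groups — care homes,
clinics, schools — rather than individuals, and their outcomes are
correlated within clusters. When two outcomes are analysed jointly (the
canonical case is a cost-effectiveness analysis with costs and QALYs), the
missing-data problem compounds: a record is a complete case only if *both*
outcomes are observed, so at 20% non-response per outcome roughly a third of
records are incomplete. How the missing outcomes are handled determines
whether the treatment-effect confidence intervals can be trusted.

`crtmi` implements, for two-arm CRTs with bivariate continuous outcomes:

- **CCA** — complete-case analysis (records with both outcomes observed);
- **SMI** — single-level multiple imputation, a proper conjugate
  bivariate-normal regression draw that ignores clustering;
- **FMI** — multiple imputation with fixed (dummy-coded) cluster effects,
  reference cluster chosen nearest the arm mean;
- **MMI** — multilevel multiple imputation from a bivariate random-intercept
  joint model, sampled by a Gibbs chain with inverse-Wishart priors;

together with the bivariate linear mixed substantive model (REML with
analytic gradients, fixed effects profiled by GLS), Rubin's-rules pooling
with normal-based intervals, incremental net benefit
INB(λ) = λ·δ_effect − δ_cost, a synthetic-trial generator with calibrated
MAR missingness mechanisms (individual-, cluster-, both- and
differential-by-treatment logistic non-response), and a full-factorial
simulation harness measuring coverage, bias, RMSE and interval width.

The substantive model for individual i in cluster j of arm k is

    Y1_ijk = β1,0 + β1·k + u1_jk + e1_ijk
    Y2_ijk = β2,0 + β2·k + u2_jk + e2_ijk

with (e1, e2) ~ N(0, Σ) at the individual level, (u1, u2) ~ N(0, Φ) at the
cluster level, and ICC_ℓ = τ_ℓ²/(τ_ℓ² + σ_ℓ²). See `docs/methods.md` for the
imputation models, priors, calibration and numerical details.

## Worked example

```python
import numpy as np
from crtmi import (
    ScenarioConfig, fixed_sizes, generate_trial, apply_missingness,
    impute_mmi, fit_bivariate_mixed, rubin_pool, inb, GibbsControl,
)
from crtmi.harness import make_mechanism

# a 2x25-cluster trial, 10 individuals per cluster, ICCs (0.05, 0.05),
# ~20% MAR non-response per outcome, stronger in the intervention arm
mech = make_mechanism("differential", "low", (0.2, 0.2))
scn = ScenarioConfig(J=25, cluster_size_spec=fixed_sizes(10),
                     icc1=0.05, icc2=0.05, mechanism=mech, seed=7)
rng = scn.replicate_rng(0)
full = generate_trial(scn, rng)
observed = apply_missingness(full, mech, rng)

stack = impute_mmi(observed, M=10, control=GibbsControl(200, 200),
                   rng=np.random.default_rng(1))
fits = [fit_bivariate_mixed(d) for d in stack.m_copies]
for est, truth in (("beta1", 120.0), ("beta2", 10.0)):
    p = rubin_pool(fits, est)
    print(f"{est}: {p.q_bar:7.2f}  95% CI ({p.ci_low:7.2f}, {p.ci_high:7.2f})"
          f"   truth {truth}")
```

prints

```
beta1:  117.79  95% CI ( 104.46,  131.12)   truth 120.0
beta2:    8.52  95% CI (   2.09,   14.94)   truth 10.0
```

— both pooled intervals cover the generating effects, with the Y1 interval
about 27 units wide (the pooled total variance combines the
within-imputation variance with 1.1× the between-imputation variance at
M = 10). The same pipeline over many replicates is what the
harness summarises:

```python
from crtmi import run_scenario, MethodSpec
summary = run_scenario(scn, N=200, methods=["cca", "smi", "fmi", "mmi"])
summary.table[("MMI", "beta1")]["coverage_pct"]
```

For user data, `read_trial_csv` ingests a long-format CSV
(`individual_id, cluster_id, arm, x, w, y1, y2`; empty cells = missing;
column names remappable), and the `crtmi` command line wraps the same steps:

```bash
crtmi fixtures -j 25 --sizes fixed:10 --mechanism differential trial.csv
crtmi impute --method mmi --m 10 --seed 1 trial.csv stacked.csv
crtmi analyze --lambda 20000 stacked.csv
crtmi run-grid --scenarios "differential|low" --reps 100 --out grid_out
```

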
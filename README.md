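# prevadjust

Selection-bias-adjusted regional disease prevalence estimation from
health-insurance member records.

## The problem

Health-insurance funds observe far more people per district than any
health survey, which makes their records attractive for regional
(small-area) prevalence estimation.  But fund membership is not a random
sample of the population: historical fund–industry ties, the
statutory/private market split and regional coverage make membership
*informative for morbidity*.  Scaling a fund's diseased member count
`ỹ_rd^c` up by the demographic factor `N_rd^c / Ñ_rd^c` (national over
member cell size) corrects the age/sex/district composition but not the
fact that members are systematically sicker or healthier than
non-members, so

    E[(N_rd^c / Ñ_rd^c) ỹ_rd^c] ≠ y_rd^c

for the true diseased count `y_rd^c` of a cell (a district × age-group ×
sex cross).  `prevadjust` implements a two-step adjustment of this
selection bias:

1. **Conditioning.**  Per region `r`, a linear mixed model is fitted on
   member data over district/cell units:

       y_rd = X_rd β_r + Z_rd b_rd + e_rd,
       b_rd ~ N(0, Ψ),   e_rd ~ N(0, σ²_r I),

   with fixed effects (intercept, cell size, age-group and sex
   indicators, and a set of inpatient diagnosis frequencies chosen by
   region-wise correlation analysis) and a district-level random
   intercept.  Variance components are estimated by REML; fixed effects
   and random-effect predictions use the explicit GLS/BLUP formulas
   `β̂ = (X'V⁻¹X)⁻¹X'V⁻¹y`, `b̂ = Ψ̂Z'V⁻¹(y − Xβ̂)` with
   `V = ZΨZ' + σ²I`.

2. **Benchmarking.**  The member-fitted model is evaluated on the
   *national* auxiliary data (the national hospital diagnosis census and
   population statistics) as benchmarks:

       ŷ_rd^c = x_rd^c' β̂_r + z_rd^c' b̂_rd.

   If the auxiliary data explains the member/national morbidity
   difference — equality of the conditional expectations given cell
   size and diagnosis frequencies — this extrapolation is unbiased even
   though the member prevalence itself is not.

Percentile confidence intervals come from a semiparametric bootstrap
(centered, reflated, resampled random effects and residuals; model
refitted per replicate).  Because real claims data are confidential, the
package ships a fully specified synthetic-population generator with
planted, controllable selectivity, plus the two validation designs that
probe the identifying assumption: a Monte-Carlo simulation against known
truth and a cross-validation that uses a hospital-observed diagnosis,
known in both populations, as a proxy endpoint.

## Worked example

```python
from prevadjust import (default_scenario, default_design, generate_population,
                        estimate_prevalence, semiparametric_bootstrap)

scenario = default_scenario(seed=0)            # planted fund selectivity
pop = generate_population(scenario, seed=1)    # synthetic national population
design = default_design()
table = estimate_prevalence(pop.table, design)
nat = table.aggregates["national"].iloc[0]
print(f"member prevalence:    {100*nat.member_prevalence:.2f}%")
print(f"naive scaled:         {100*nat.naive_prevalence:.2f}%")
print(f"adjusted estimate:    {100*nat.prevalence:.2f}%")
print(f"true prevalence:      {100*pop.national_prevalence:.2f}%")
print(f"relative adjustment:  {nat.relative_adjustment_pct:.2f}%")
ci = semiparametric_bootstrap(pop.table, design, B=200, seed=2).targets["national"].iloc[0]
print(f"95% CI:               [{100*ci.ci_low:.2f}%, {100*ci.ci_high:.2f}%]")
```

prints

```
member prevalence:    13.15%
naive scaled:         12.74%
adjusted estimate:    8.95%
true prevalence:      9.07%
relative adjustment:  -31.94%
95% CI:               [8.77%, 9.14%]
```

The fund's members are markedly sicker than the national population
(13.15% vs a true 9.07%), and demographic rescaling alone barely moves
the needle (12.74%).  The benchmarked model adjusts the member
prevalence down by 32% to 8.95%, within a bootstrap interval that covers
the truth.  Because estimates live on the cell level, any cohort can be
read off the same table — e.g. per age group:

```
age I:   member  9.47%   adjusted  6.25%   (-34.0%)
age II:  member 11.64%   adjusted  7.93%   (-31.9%)
age III: member 14.37%   adjusted 10.18%   (-29.1%)
age IV:  member 18.15%   adjusted 13.14%   (-27.6%)
```

A command-line pipeline covering generation, variable selection,
fitting, estimation, bootstrap and validation is available as
`prevadjust --config config.yaml <generate|select|fit|estimate|bootstrap|validate|run>`.

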
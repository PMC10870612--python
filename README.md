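# earlygsd

Planning and monitoring toolkit for two-arm group-sequential clinical trials
whose interim analyses borrow information from **early longitudinal outcomes**
correlated with the primary outcome.

Pragmatic trials of complex interventions typically measure a continuous
patient-reported outcome at a sequence of follow-up occasions
`d_1 < d_2 < ... < d_s` (e.g. 3, 6 and 12 months), with the last occasion as
the primary endpoint. Before follow-up completes, far more participants have
early data than primary data, and if the within-participant correlations are
appreciable, a generalized-least-squares analysis of all the longitudinal
data delivers substantially more statistical information at an interim than
the primary outcomes alone — often enough to make early stopping feasible at
all. `earlygsd` provides closed-form expressions for this information
accrual under simple recruitment and correlation models, so a group
sequential design can be planned and explored without simulating
individual-participant data — and a seeded participant-level simulator to
verify every formula by Monte Carlo.

## The model

Outcomes for participant *i* in arm *j* are multivariate normal,
`y_i ~ MVN(X_i β, Σ_i)`, with `Σ = S^{1/2} R S^{1/2}` built from occasion
SDs `σ_r` and a correlation matrix `R` from one of two single-parameter
families:

* **uniform** (compound symmetry): `ρ_{rr'} = α` — the natural structure
  under a subject-level random effect;
* **exponential** (AR(1)-type): `ρ_{rr'} = γ^{|d_r − d_r'|}` — correlation
  decays with time separation.

Expected data accrual follows `N_r(t) = k g(t − d_r)` under a fixed,
linearly increasing or linearly decreasing recruitment rate over a period
`T_R`. For both correlation families the variance of the GLS treatment
effect at the primary occasion, `var(β_s)`, is available in closed form in
the per-occasion counts, and the **variance-reduction factor**

```
V_s(t) = var(β_s with early outcomes) / var(β_s from primary data alone)
```

satisfies `n_s1(t) ≤ V_s(t) ≤ 1`, with closed-form extrema over the
placement of the intermediate occasions (a gradient-based constrained
minimization for the exponential model). The information fraction at an
interim is `τ(t) = τ0(t) / V_s(t)`, where `τ0(t) = N_s(t)/N` is the fraction
of participants with primary data; `1/V` is the proportionate information
gain from the early outcomes. Boundary-crossing probabilities, power and
boundary solving use the canonical joint distribution of sequential
z-statistics (`E[Z_k] = δ√I_k`, `cov(Z_j, Z_k) = √(I_j/I_k)`) by recursive
numerical integration.

## Worked example

A 188-participant trial with outcomes at 3/6/12 months (`d = (1, 2, 4)` in
3-month units), 24-month recruitment (`T_R = 8`), SD 12, planning
correlation `α = 0.5`, and a first interim when 25% of participants have
12-month data:

```python
from earlygsd import (CorrelationSpec, DesignPoint, FollowUpSchedule,
                      RecruitmentSpec, information_fraction, time_at_tau0)

sched = FollowUpSchedule([1, 2, 4])
rec = RecruitmentSpec("fixed", 188, 8.0)
t = time_at_tau0(rec, sched, 0.25)          # -> 6.0 (18 months)
point = DesignPoint(t=t, sched=sched, rec=rec,
                    corr=CorrelationSpec("uniform", 0.5), sigma_s=12.0)
print(information_fraction(point))
```

```
InformationSummary(var_beta=9.906..., V=0.8083..., tau0=0.25,
                   tau=0.3093..., info=0.1009...)
```

At 18 months only a quarter of participants have primary data
(`tau0 = 0.25`), but the 3- and 6-month outcomes cut the variance to
`V = 0.808` of the primary-only value, lifting the information fraction to
`tau = 0.309` — about 24% more information for free. Feeding the resulting
information fractions into the group-sequential engine
(`replan_start_reacts("fixed")`) reproduces the full planning table of the
motivating trial and a power of 90.6% for a 6-point treatment difference
(90.7% under decreasing-rate recruitment).

The `examples/` directory walks through each capability: accrual curves,
information accrual, outcome-spacing extrema, the trial replan, and
simulation + GLS monitoring. A thin CLI mirrors the library:

```bash
earlygsd accrual --model fixed --n 188 --tr 8 --d 1,2,4 --t 6
earlygsd replan --model decreasing
earlygsd fig2 --t1 4.5:6.5:0.5 --alpha 0:0.8:0.2
```

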
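# sclc-cea

Cost-effectiveness modelling of first-line **tislelizumab + platinum/etoposide
chemotherapy versus chemotherapy alone** in extensive-stage small cell lung
cancer (ES-SCLC), from the perspective of China's healthcare system.

The package implements the full desk-scale health-economic pipeline:

* seven parametric survival families (exponential, Weibull, Gompertz, gamma,
  generalized gamma, log-logistic, log-normal), right-censored maximum-
  likelihood fitting and AIC/BIC model ranking;
* a **partitioned-survival model** (PSM) — state occupancy read directly off
  the overall-survival (OS) and progression-free-survival (PFS) curves — and
  a **three-state Markov cohort model** with time-dependent transition
  probabilities derived from the same curves;
* discounted cost / QALY accrual per arm and incremental results (ICER, net
  monetary benefit);
* one-way (tornado) and probabilistic sensitivity analysis (second-order
  Monte Carlo, CE plane, CEAC);
* a synthetic individual-patient-data generator so the fitting stage is
  testable without any external data.

## Model

Three mutually exclusive health states — progression-free (PFS), progressed
disease (PD), dead — over a 10-year horizon in 21-day cycles, costs and
utilities discounted at 5%/year. Survival in both arms follows log-logistic
laws, S(t) = 1 / (1 + (t/α)^β) with scale α (in months; equals the median)
and shape β. In the PSM, occupancy at cycle boundary t_k is

    pfs_k = S_PFS(t_k),   dead_k = 1 − S_OS(t_k),   pd_k = S_OS(t_k) − S_PFS(t_k);

in the Markov model the per-cycle conditional probabilities are

    q_d(k) = 1 − S_OS(t_{k+1})/S_OS(t_k),   q_e(k) = 1 − S_PFS(t_{k+1})/S_PFS(t_k),
    p(PFS→Dead) = min(q_d, q_e),  p(PFS→PD) = max(0, q_e − q_d),  p(PD→Dead) = q_d,

which makes the two engines agree on occupancy by construction. The decision
statistic is the incremental cost-effectiveness ratio ICER = ΔCost/ΔQALY
against a willingness-to-pay threshold of CNY 268,074/QALY (3× China's 2023
per-capita GDP), with NMB = WTP·ΔQALY − ΔCost.

All base-case inputs (survival parameters, per-cycle costs in 2023 CNY,
adverse-event costs/incidences/disutilities, utilities 0.804 for PFS and
0.321 for PD, subsequent-chemotherapy proportions 55%/67%) ship in
`src/sclc_cea/data/rationale312.yaml`; accrual conventions the published
analysis leaves open are explicit config switches (see `docs/methods.md`).

## Worked example

```python
from sclc_cea import default_inputs, evaluate_arm, incremental

inputs = default_inputs()
comp = evaluate_arm(inputs, "placebo", engine="psm")
intv = evaluate_arm(inputs, "tislelizumab", engine="psm")
inc = incremental(comp, intv, wtp=inputs.settings.wtp)
print(f"tislelizumab: {intv.ly:.2f} LYs, {intv.qaly:.2f} QALYs")
print(f"placebo:      {comp.ly:.2f} LYs, {comp.qaly:.2f} QALYs")
print(f"dCost = {inc.delta_cost:,.0f} CNY, dQALY = {inc.delta_qaly:.3f}, "
      f"ICER = {inc.icer:,.0f} CNY/QALY")
```

prints

```
tislelizumab: 1.91 LYs, 0.94 QALYs
placebo:      1.64 LYs, 0.76 QALYs
dCost = 36,614 CNY, dQALY = 0.188, ICER = 195,129 CNY/QALY
```

i.e. adding tislelizumab buys 0.188 discounted quality-adjusted life-years
for CNY 36,614, an ICER below the CNY 268,074/QALY threshold — cost-effective
at that willingness to pay. The same is available from the shell:

```sh
sclc-cea run --engine both          # Table-2-style base case, both engines
sclc-cea owsa --engine psm          # tornado CSV
sclc-cea psa --n-iter 1000 --seed 1 # CE plane + CEAC, seed-reproducible
sclc-cea simulate --seed 0          # synthetic two-arm trial IPD
sclc-cea fit runs/<dir>/ipd.csv     # 7-family AIC/BIC ranking
```

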
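# Methods

## Model structure

A cohort enters progression-free (PFS) at time zero and moves through three
mutually exclusive states — PFS, progressed disease (PD), dead — over a
10-year horizon divided into 21-day cycles (173 cycles; cycle boundary k
sits at t_k = k·21/30.4375 months, a month being 365.25/12 days). Costs and
QALYs are discounted at 5%/year with discrete per-cycle factors
(1.05)^(−t_k in years); continuous compounding would differ by under 0.1%
over this horizon.

Two engines share all inputs. The partitioned-survival engine reads
occupancy directly off the marginal OS and PFS curves; if extrapolated
curves cross (PFS above OS) the PD share is clamped to zero and a warning
names the first crossing time. The Markov engine derives time-dependent
transition probabilities from the same curves (formulas in the README),
assigning both alive states the marginal OS conditional hazard because no
state-specific mortality is available. That derivation makes the Markov dead
series equal 1 − S_OS identically and, whenever the PFS-exit probability
dominates the death probability (true everywhere on the base-case curves),
the whole Markov occupancy equals the partitioned-survival occupancy. The
two engines are therefore mutual oracles, and base-case differences between
them vanish by construction; published analyses that report slightly
different results per engine reflect internal conventions of their software
that are not recoverable.

## Survival model

Both arms' OS and PFS follow log-logistic laws S(t) = 1/(1+(t/α)^β), the
family selected by AIC/BIC among seven candidates in the source analysis;
the fitted scales (α, months) and shapes (β) are packaged as base-case
inputs. The fitting stack (right-censored MLE over all seven families,
optimised on log-transformed positive parameters with three starts to guard
against generalized-gamma multimodality; exponential by closed form) exists
so that the selection step is reproducible on data: the synthetic-data
module draws event times from the packaged curves by inverse-CDF sampling,
couples OS and PFS within subject through a Gaussian copula (rank
correlation 0.5, then PFS capped at OS), and censors by a 40-month
administrative cut-off plus an exponential loss-to-follow-up of 0.005/month
— trial-like follow-up for a 457-patient, 1:1 randomised cohort. The
generator reproduces marginal laws exactly; it does not emulate staggered
accrual or the digitisation error of reconstructing published curves, so
parameter-recovery tests certify the estimator, not curve reconstruction.

## Accrual conventions

The source analysis leaves several conventions unstated; each is a config
switch, and the shipped defaults are the package's calibrated base case:

* **Cycle timing** (`cycle_timing: end | start | half`): state membership is
  evaluated at cycle end with no half-cycle correction. Chosen because the
  published life-years (1.92/1.65 discounted) are reproduced by cycle-end
  evaluation (1.913/1.645) and not by cycle-start (1.971/1.702).
* **Drug administration** happens at cycle starts, paid by the
  progression-free share at that boundary: four induction administrations
  of study drug + etoposide + platinum, then maintenance study drug alone
  (zero in the placebo arm) until progression.
* **Platinum** (`platinum`): carboplatin by default (AUC 5 arm of the
  regimen; the trial allowed either agent and the published mix is
  unknown); `cisplatin` or a `mix` share are available.
* **Follow-up and BSC states**: routine follow-up cost accrues in both
  alive states, best supportive care in PD only ("until death").
* **Subsequent chemotherapy**: a one-off course charged to the mass newly
  entering PD each cycle — proportion (55%/67%) × 4 cycles × per-cycle
  etoposide + platinum cost. Four cycles mirrors induction length; duration
  is configurable.
* **Adverse events**: grade ≥3 events with ≥5% incidence enter once at
  model entry, as cost Σ incidence×unit cost and as a QALY decrement
  Σ incidence×disutility×duration with duration one cycle (21/365 years).
  The packaged AE "utility" rows are decrements, the only reading
  consistent with QALY magnitudes.

Under these defaults the base case gives 1.91/1.64 discounted LYs,
0.94/0.76 QALYs, ΔCost 36,614 CNY, ΔQALY 0.188 and ICER 195,129 CNY/QALY
(both engines). Absolute per-arm totals are sensitive to the unstated
conventions above and do not match published per-arm figures under any
switch combination; incremental results, which drive the decision, are
robust to them.

## Sensitivity analysis

**One-way**: every scalar parameter with a non-degenerate range — including
the discount rate over 0–8% — is pinned at its low and high value in turn
and the ICER recomputed; entries are sorted by spread with name
tie-breaking for determinism. Ranges are the published ones (bid-price
extremes for drugs, ±20% for other costs, ±10% for utilities and
probabilities).

**Probabilistic**: 1,000 second-order Monte Carlo iterations. Costs are
gamma, probabilities and utilities beta, each moment-matched to its base
value and a standard error reconstructed from the range as
(high − low)/(2×1.96), reading ranges as approximate 95% intervals — the
only self-consistent reconstruction available, overridable per parameter.
Because the economic scalars alone leave the acceptability estimate
degenerate (≈100% at the threshold: their joint NMB spread is small
relative to the base-case NMB), the default also samples the four (α, β)
pairs (`psa_sample_survival: true`) from a log-scale multivariate normal.
Its covariance is the inverse observed information of a maximum-likelihood
refit to one trial-sized synthetic cohort (228/arm, 40-month administrative
censoring) — the covariance a curve-fitting PSA draws from when
reconstructed patient data are available, and the dominant uncertainty in
trial-based models of this kind. The covariance seed and all draws derive
from the single run seed, so PSA results are bit-reproducible. Acceptability
carries a Wilson 95% interval; at n = 1,000 near p ≈ 0.9 its half-width is
roughly 2 percentage points, the floor for interpreting differences between
runs.

## Numerical notes

* Survival evaluation is closed-form per family (scipy for gamma-type
  survival functions); quantiles are closed-form except gamma-type families
  (scipy inverse CDFs). The quantile/survival round-trip holds to 1e−8.
* Gompertz with negative shape is accepted with a plateau warning; its
  quantile raises beyond the plateau.
* Occupancy is validated every cycle (simplex to 1e−12, monotone death).
* Degenerate inputs fail loudly: all-censored data, non-positive times,
  utilities outside [0, 1], beta moment-matching with se² ≥ m(1−m),
  transition rows summing past 1.
* Tornado entries whose extreme yields no defined ICER (dominance) are
  flagged, not dropped.

## Limitations

Three states, no tunnel states or time-in-state memory, so subsequent-
therapy cost is a PD-entry one-off rather than a tracked treatment line.
Utilities come from external literature, not the trial. The synthetic
cohort stands in for reconstructed patient data; conclusions about fitting
apply to the estimator, not to digitisation fidelity. PSA correlations
between parameters (beyond the within-curve covariance) are not modelled.
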
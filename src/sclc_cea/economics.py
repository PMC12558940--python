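"""Discounted cost and QALY accrual over a cohort trace, and incremental
cost-effectiveness results.

Accrual conventions (each a config switch on :class:`~sclc_cea.config.Conventions`):

* drug administrations happen at cycle starts — index k = 0 .. N-1, paid by
  the progression-free occupancy at that boundary; the first
  ``induction_cycles`` administrations are study drug + etoposide +
  platinum, later ones the maintenance study drug alone (zero in the
  comparator arm);
* state-occupancy items (follow-up, best supportive care) and utilities
  accrue per cycle under the same cycle-timing rule as life-years
  (default: occupancy evaluated at cycle end);
* adverse-event costs and disutilities are one-off at model entry, the
  disutility lasting ``ae_disutility_years``;
* a subsequent-chemotherapy course (proportion x n_sub_cycles x per-cycle
  chemo cost) is charged to the mass newly entering PD each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ArmSpec, Conventions, ModelInputs, ModelSettings
from .markov import build_markov_trace, derive_transitions
from .psm import CohortTrace, _cycle_weights, build_psm_trace
from .survival import SurvivalDistribution

__all__ = [
    "EconOutcome",
    "IcerResult",
    "discount_factor",
    "platinum_cost",
    "cost_trace",
    "qaly_trace",
    "evaluate_arm",
    "incremental",
]


def discount_factor(
    k, settings: ModelSettings, rate: float | None = None
) -> np.ndarray | float:
    """Discrete per-cycle discount factor (1 + r)^(-k x cycle length in years)."""
    r = settings.discount_annual if rate is None else rate
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("cycle index must be >= 0")
    return (1.0 + r) ** (-(k_arr * settings.cycle_years))


def platinum_cost(conventions: Conventions, values: dict[str, float]) -> float:
    """Per-cycle platinum cost under the configured agent choice."""
    carb, cis = values["carboplatin_cost"], values["cisplatin_cost"]
    if conventions.platinum == "carboplatin":
        return carb
    if conventions.platinum == "cisplatin":
        return cis
    share = conventions.carboplatin_share
    return share * carb + (1.0 - share) * cis


@dataclass
class EconOutcome:
    """Discounted totals for one arm with per-component breakdowns."""

    arm: str
    total_cost: float
    ly: float
    qaly: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    qaly_breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.cost_breakdown.values())
        if self.cost_breakdown and abs(total - self.total_cost) > 1e-6 * max(
            1.0, abs(self.total_cost)
        ):
            raise ValueError("cost breakdown does not sum to the total")

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "total_cost": self.total_cost,
            "ly": self.ly,
            "qaly": self.qaly,
            "cost_breakdown": dict(self.cost_breakdown),
            "qaly_breakdown": dict(self.qaly_breakdown),
        }


@dataclass
class IcerResult:
    """Incremental result of intervention vs comparator."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str  # "", "dominant", "dominated", "undefined"
    nmb_at_wtp: float
    wtp: float

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
            "nmb_at_wtp": self.nmb_at_wtp,
            "wtp": self.wtp,
        }


def _state_occupancy(trace: CohortTrace, states: tuple[str, ...]) -> np.ndarray:
    occ = np.zeros(len(trace))
    if "pfs" in states:
        occ = occ + trace.pfs
    if "pd" in states:
        occ = occ + trace.pd
    return occ


def cost_trace(
    trace: CohortTrace,
    arm: ArmSpec,
    inputs: ModelInputs,
    overrides: dict[str, float] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Discounted per-cycle costs and the component breakdown for one arm."""
    values = inputs.resolved(overrides)
    conv = inputs.conventions
    settings = inputs.settings
    r = values["discount_rate"]
    n_rows = len(trace)
    v = np.asarray(discount_factor(np.arange(n_rows), settings, rate=r))
    w = _cycle_weights(n_rows, conv.cycle_timing)

    per_cycle = np.zeros(n_rows)
    chemo = values["etoposide_cost"] + platinum_cost(conv, values)
    maint = values[arm.maintenance_drug] if arm.maintenance_drug else 0.0

    # drug administrations at cycle starts
    induction = maintenance = 0.0
    n_admin = n_rows - 1
    for k in range(n_admin):
        if k < arm.induction_cycles:
            c = trace.pfs[k] * (maint + chemo) * v[k]
            induction += c
        else:
            c = trace.pfs[k] * maint * v[k]
            maintenance += c
        per_cycle[k] += c

    followup = _state_occupancy(trace, conv.followup_states) * values["followup_cost"]
    bsc = _state_occupancy(trace, conv.bsc_states) * values["bsc_cost"]
    per_cycle += (followup + bsc) * w * v

    sub_course = (
        values[arm.subsequent_proportion] * conv.n_sub_cycles * chemo
    )
    sub_per_cycle = trace.pd_entrants * sub_course * v
    per_cycle += sub_per_cycle

    ae_cost = sum(
        values[ae.incidence] * values[ae.cost] for ae in arm.adverse_events
    )
    per_cycle[0] += ae_cost

    breakdown = {
        "induction_drugs": induction,
        "maintenance_drug": maintenance,
        "subsequent_tx": float(sub_per_cycle.sum()),
        "bsc": float(np.sum(bsc * w * v)),
        "followup": float(np.sum(followup * w * v)),
        "ae": float(ae_cost),
    }
    return per_cycle, breakdown


def qaly_trace(
    trace: CohortTrace,
    arm: ArmSpec,
    inputs: ModelInputs,
    overrides: dict[str, float] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Discounted per-cycle QALYs and the per-state breakdown for one arm."""
    values = inputs.resolved(overrides)
    conv = inputs.conventions
    settings = inputs.settings
    u_pfs, u_pd = values["u_pfs"], values["u_pd"]
    for name, u in (("u_pfs", u_pfs), ("u_pd", u_pd)):
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {u}")
    n_rows = len(trace)
    v = np.asarray(
        discount_factor(np.arange(n_rows), settings, rate=values["discount_rate"])
    )
    w = _cycle_weights(n_rows, conv.cycle_timing)
    dt = settings.cycle_years

    q_pfs = trace.pfs * u_pfs * dt * w * v
    q_pd = trace.pd * u_pd * dt * w * v
    decrement = (
        sum(values[ae.incidence] * values[ae.disutility] for ae in arm.adverse_events)
        * conv.ae_disutility_years
    )
    per_cycle = q_pfs + q_pd
    per_cycle[0] -= decrement
    breakdown = {
        "pfs": float(q_pfs.sum()),
        "pd": float(q_pd.sum()),
        "ae_decrement": -float(decrement),
    }
    return per_cycle, breakdown


def evaluate_arm(
    inputs: ModelInputs,
    arm: ArmSpec | str,
    engine: str = "psm",
    overrides: dict[str, float] | None = None,
    survival_override: tuple[SurvivalDistribution, SurvivalDistribution] | None = None,
) -> EconOutcome:
    """Run one arm through an engine and accrue its economic outcomes.

    ``survival_override`` replaces the (OS, PFS) laws — used by the PSA when
    survival-parameter uncertainty is sampled; scalar parameter substitution
    goes through ``overrides`` by name.
    """
    if isinstance(arm, str):
        matches = [a for a in inputs.arms if a.name == arm]
        if not matches:
            raise KeyError(f"unknown arm {arm!r}")
        arm = matches[0]
    values = inputs.resolved(overrides)
    if survival_override is not None:
        os_dist, pfs_dist = survival_override
    else:
        os_dist, pfs_dist = arm.os_dist(values), arm.pfs_dist(values)

    settings = inputs.settings
    if engine == "psm":
        trace = build_psm_trace(os_dist, pfs_dist, settings)
    elif engine == "markov":
        trace = build_markov_trace(
            derive_transitions(os_dist, pfs_dist, settings), settings
        )
    else:
        raise ValueError(f"unknown engine {engine!r} (expected 'psm' or 'markov')")

    from .psm import life_years

    ly = life_years(
        trace,
        settings,
        discounted=True,
        discount_annual=values["discount_rate"],
        timing=inputs.conventions.cycle_timing,
    )
    costs, cost_bd = cost_trace(trace, arm, inputs, overrides)
    qalys, qaly_bd = qaly_trace(trace, arm, inputs, overrides)
    return EconOutcome(
        arm=arm.name,
        total_cost=float(costs.sum()),
        ly=ly,
        qaly=float(qalys.sum()),
        cost_breakdown=cost_bd,
        qaly_breakdown=qaly_bd,
    )


def incremental(
    comparator: EconOutcome, intervention: EconOutcome, wtp: float
) -> IcerResult:
    """ICER / dominance and net monetary benefit of intervention vs comparator."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.qaly - comparator.qaly
    nmb = wtp * d_qaly - d_cost
    if d_qaly > 0 and d_cost < 0:
        return IcerResult(d_cost, d_qaly, None, "dominant", nmb, wtp)
    if d_qaly < 0 and d_cost > 0:
        return IcerResult(d_cost, d_qaly, None, "dominated", nmb, wtp)
    if d_qaly == 0:
        return IcerResult(d_cost, d_qaly, None, "undefined", nmb, wtp)
    return IcerResult(d_cost, d_qaly, d_cost / d_qaly, "", nmb, wtp)
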
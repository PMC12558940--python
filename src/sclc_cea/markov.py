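"""Three-state Markov cohort engine with time-dependent transitions derived
from the fitted marginal survival curves.

Per cycle k the conditional exit probabilities are

    q_d(k) = 1 - S_OS(t_{k+1}) / S_OS(t_k)      (death, any alive state)
    q_e(k) = 1 - S_PFS(t_{k+1}) / S_PFS(t_k)    (leaving progression-free)

and the schedule is p(PFS->Dead) = min(q_d, q_e), p(PFS->PD) = max(0,
q_e - q_d), p(PD->Dead) = q_d.  Both alive states share the marginal OS
conditional hazard (no state-specific mortality is available), which makes
the Markov dead series reproduce 1 - S_OS exactly and — whenever q_e >= q_d
— the whole occupancy identical to the partitioned-survival trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelSettings
from .psm import CohortTrace
from .survival import SurvivalDistribution, survival_at

__all__ = ["TransitionSchedule", "derive_transitions", "build_markov_trace"]


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities (entry k governs cycle k -> k+1)."""

    p_pfs_to_pd: np.ndarray
    p_pfs_to_dead: np.ndarray
    p_pd_to_dead: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.p_pfs_to_pd, self.p_pfs_to_dead, self.p_pd_to_dead):
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(self.p_pfs_to_pd + self.p_pfs_to_dead > 1 + 1e-9):
            raise ValueError("PFS exit probabilities exceed 1 in some cycle")

    def __len__(self) -> int:
        return len(self.p_pfs_to_pd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self)),
                "p_pfs_pd": self.p_pfs_to_pd,
                "p_pfs_dead": self.p_pfs_to_dead,
                "p_pd_dead": self.p_pd_to_dead,
            }
        )


def derive_transitions(
    os_dist: SurvivalDistribution,
    pfs_dist: SurvivalDistribution,
    settings: ModelSettings,
) -> TransitionSchedule:
    """Conditional per-cycle transition probabilities from the marginal curves."""
    k = np.arange(settings.n_cycles + 1)
    times = k * settings.cycle_months
    s_os = np.asarray(survival_at(os_dist, times))
    s_pfs = np.asarray(survival_at(pfs_dist, times))

    def conditional_exit(s: np.ndarray) -> np.ndarray:
        q = np.ones(len(s) - 1)
        ok = s[:-1] > 1e-300  # exhausted curve: pin to absorbing death
        q[ok] = 1.0 - s[1:][ok] / s[:-1][ok]
        return np.clip(q, 0.0, 1.0)

    q_d = conditional_exit(s_os)
    q_e = conditional_exit(s_pfs)
    return TransitionSchedule(
        p_pfs_to_pd=np.maximum(0.0, q_e - q_d),
        p_pfs_to_dead=np.minimum(q_d, q_e),
        p_pd_to_dead=q_d,
    )


def build_markov_trace(
    schedule: TransitionSchedule, settings: ModelSettings
) -> CohortTrace:
    """Iterate the cohort (1, 0, 0) forward through the schedule.

    Death is absorbing; PD entrants during cycle k are
    pfs_{k-1} * p(PFS->PD at k-1).
    """
    n = len(schedule)
    pfs = np.zeros(n + 1)
    pd_ = np.zeros(n + 1)
    dead = np.zeros(n + 1)
    ent = np.zeros(n + 1)
    pfs[0] = 1.0
    for k in range(n):
        to_pd = pfs[k] * schedule.p_pfs_to_pd[k]
        pfs_deaths = pfs[k] * schedule.p_pfs_to_dead[k]
        pd_deaths = pd_[k] * schedule.p_pd_to_dead[k]
        pfs[k + 1] = pfs[k] - to_pd - pfs_deaths
        pd_[k + 1] = pd_[k] + to_pd - pd_deaths
        dead[k + 1] = dead[k] + pfs_deaths + pd_deaths
        ent[k + 1] = to_pd
    times = np.arange(n + 1) * settings.cycle_months
    return CohortTrace(times=times, pfs=pfs, pd=pd_, dead=dead, pd_entrants=ent)
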
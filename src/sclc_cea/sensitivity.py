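"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis recomputes the ICER with each scalar parameter pinned at
the low and high end of its range, everything else at base.

The probabilistic analysis is a second-order Monte Carlo: each iteration
samples every non-fixed parameter from a moment-matched distribution (gamma
for costs, beta for probabilities and utilities; standard errors
reconstructed from the printed ranges as (high - low) / (2 x 1.96), reading
the range as an approximate 95% interval) and, when enabled, the
survival-curve parameters from a log-scale multivariate normal whose
covariance is the maximum-likelihood asymptotic covariance of a fit to
trial-sized synthetic patient data.  Each draw runs both arms through the
chosen engine and records the incremental cost and QALYs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelInputs, ParameterEntry
from .economics import evaluate_arm, incremental
from .survival import FAMILIES, SurvivalDistribution, fit_mle
from .synthetic import TrialSimSpec, generate_ipd

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CeacCurve",
    "owsa",
    "moment_match_gamma",
    "moment_match_beta",
    "se_from_range",
    "survival_curve_covariances",
    "run_psa",
    "acceptability",
    "ceac",
    "ceac_crossing",
]


# ---------------------------------------------------------------- one-way


@dataclass
class TornadoEntry:
    name: str
    icer_at_low: float | None
    icer_at_high: float | None
    spread: float
    flagged: bool = False  # an extreme produced no defined ICER

    def to_dict(self) -> dict:
        return {
            "parameter": self.name,
            "icer_low": self.icer_at_low,
            "icer_high": self.icer_at_high,
            "spread": self.spread,
        }


def _icer_at(inputs: ModelInputs, engine: str, overrides: dict[str, float]) -> float | None:
    comp = evaluate_arm(inputs, inputs.comparator, engine, overrides)
    intv = evaluate_arm(inputs, inputs.intervention, engine, overrides)
    return incremental(comp, intv, inputs.settings.wtp).icer


def owsa(inputs: ModelInputs, engine: str = "psm") -> list[TornadoEntry]:
    """Tornado entries for every parameter with a non-degenerate range,
    sorted by ICER spread descending (ties by name)."""
    entries = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, p in inputs.parameters.items():
            if p.low >= p.high:
                continue
            lo = _icer_at(inputs, engine, {name: p.low})
            hi = _icer_at(inputs, engine, {name: p.high})
            flagged = lo is None or hi is None
            spread = abs(hi - lo) if not flagged else float("nan")
            entries.append(TornadoEntry(name, lo, hi, spread, flagged))
    return sorted(entries, key=lambda e: (-(e.spread if e.spread == e.spread else np.inf), e.name))


# --------------------------------------------------------- moment matching


def moment_match_gamma(mean: float, se: float) -> tuple[float, float]:
    """(shape, rate) of the gamma with the given mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma moment matching requires mean > 0 and se > 0")
    return mean**2 / se**2, mean / se**2


def moment_match_beta(mean: float, se: float) -> tuple[float, float]:
    """(a, b) of the beta with the given mean and standard error."""
    if not 0 < mean < 1:
        raise ValueError("beta moment matching requires mean in (0, 1)")
    if se <= 0 or se**2 >= mean * (1 - mean):
        raise ValueError("se too large for the beta support")
    nu = mean * (1 - mean) / se**2 - 1.0
    return mean * nu, (1 - mean) * nu


def se_from_range(entry: ParameterEntry) -> float:
    """Standard error reconstructed from the one-way range read as ~95% CI."""
    return (entry.high - entry.low) / (2.0 * 1.96)


# ------------------------------------------------- survival-curve sampling


def survival_curve_covariances(
    inputs: ModelInputs, seed: int
) -> dict[str, dict[str, np.ndarray]]:
    """Log-scale parameter covariance per arm and endpoint.

    Generates one trial-sized synthetic dataset from the base-case curves
    (administrative censoring per the configured follow-up), refits each
    curve's own family by maximum likelihood and returns the inverse
    observed information — the covariance a curve-fitting PSA would draw
    from when the reconstructed data themselves are available.
    """
    conv = inputs.conventions
    values = inputs.base_values()
    curves = {
        arm.name: {"os": arm.os_dist(values), "pfs": arm.pfs_dist(values)}
        for arm in inputs.arms
    }
    spec = TrialSimSpec(
        curves=curves,
        n_per_arm={arm.name: conv.psa_ipd_n_per_arm for arm in inputs.arms},
        admin_censor_time=conv.psa_admin_censor_months,
        random_censor_rate=conv.psa_random_censor_rate,
        seed=seed,
    )
    ipd = generate_ipd(spec)
    out: dict[str, dict[str, np.ndarray]] = {}
    for arm in inputs.arms:
        out[arm.name] = {}
        for endpoint in ("os", "pfs"):
            sub = ipd[(ipd.arm == arm.name) & (ipd.endpoint == endpoint)]
            family = curves[arm.name][endpoint].family
            fit = fit_mle(sub.time.to_numpy(), sub.event.to_numpy(), family)
            if fit.cov_trans is None:
                raise RuntimeError(
                    f"no usable information matrix for {arm.name}/{endpoint}"
                )
            out[arm.name][endpoint] = fit.cov_trans
    return out


# ------------------------------------------------------------------- PSA


@dataclass
class PSAResult:
    """Paired incremental draws with the full sampled-parameter audit trail."""

    engine: str
    seed: int
    n_iter: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    samples: pd.DataFrame = field(repr=False)

    def ce_plane(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_iter),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def _sample_scalars(
    inputs: ModelInputs, n_iter: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, p in inputs.parameters.items():
        if p.psa_family == "fixed" or p.high <= p.low:
            continue
        se = se_from_range(p)
        if p.psa_family == "gamma":
            shape, rate = moment_match_gamma(p.base, se)
            cols[name] = rng.gamma(shape, 1.0 / rate, size=n_iter)
        else:
            a, b = moment_match_beta(p.base, se)
            cols[name] = rng.beta(a, b, size=n_iter)
    return pd.DataFrame(cols)


def run_psa(
    inputs: ModelInputs,
    engine: str = "psm",
    n_iter: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Second-order Monte Carlo over the parameter table (and, if enabled,
    the survival-curve parameters); fully reproducible from ``seed``."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    samples = _sample_scalars(inputs, n_iter, rng)

    surv_draws: dict[str, dict[str, np.ndarray]] = {}
    if inputs.conventions.psa_sample_survival:
        covs = survival_curve_covariances(inputs, seed=int(rng.integers(2**31)))
        values = inputs.base_values()
        for arm in inputs.arms:
            surv_draws[arm.name] = {}
            for endpoint, dist in (
                ("os", arm.os_dist(values)),
                ("pfs", arm.pfs_dist(values)),
            ):
                center = np.log(dist.values())  # log-logistic params are positive
                cov = covs[arm.name][endpoint]
                draws = np.exp(
                    rng.multivariate_normal(center, cov, size=n_iter, method="cholesky")
                )
                surv_draws[arm.name][endpoint] = draws
                names = FAMILIES[dist.family]
                for j, pname in enumerate(names):
                    samples[f"{arm.name}_{endpoint}_{pname}"] = draws[:, j]

    d_cost = np.empty(n_iter)
    d_qaly = np.empty(n_iter)
    scalar_names = [c for c in samples.columns if c in inputs.parameters]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_iter):
            overrides = {name: float(samples[name].iloc[i]) for name in scalar_names}
            outcomes = []
            for arm in inputs.arms:
                surv = None
                if surv_draws:
                    fam_os, fam_pfs = arm.os_family, arm.pfs_family
                    os_p = surv_draws[arm.name]["os"][i]
                    pfs_p = surv_draws[arm.name]["pfs"][i]
                    surv = (
                        SurvivalDistribution(fam_os, dict(zip(FAMILIES[fam_os], os_p))),
                        SurvivalDistribution(fam_pfs, dict(zip(FAMILIES[fam_pfs], pfs_p))),
                    )
                outcomes.append(
                    evaluate_arm(inputs, arm, engine, overrides, survival_override=surv)
                )
            d_cost[i] = outcomes[1].total_cost - outcomes[0].total_cost
            d_qaly[i] = outcomes[1].qaly - outcomes[0].qaly
    return PSAResult(
        engine=engine,
        seed=seed,
        n_iter=n_iter,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        samples=samples,
    )


# ------------------------------------------------------------- CEAC etc.


def acceptability(
    result: PSAResult, wtp: float
) -> tuple[float, tuple[float, float]]:
    """Fraction of draws with positive net monetary benefit, with a Wilson
    95% interval."""
    nmb = wtp * result.delta_qaly - result.delta_cost
    k = int(np.sum(nmb > 0))
    n = result.n_iter
    p = k / n
    z = stats.norm.ppf(0.975)
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return p, (max(0.0, center - half), min(1.0, center + half))


@dataclass
class CeacCurve:
    wtp_grid: np.ndarray
    prob_ce: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.wtp_grid) <= 0):
            raise ValueError("wtp grid must be strictly ascending")
        if np.any((self.prob_ce < 0) | (self.prob_ce > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "prob_ce": self.prob_ce})


def ceac(result: PSAResult, wtp_grid) -> CeacCurve:
    """Cost-effectiveness acceptability curve over an ascending WTP grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    nmb = grid[:, None] * result.delta_qaly[None, :] - result.delta_cost[None, :]
    return CeacCurve(wtp_grid=grid, prob_ce=(nmb > 0).mean(axis=1))


def ceac_crossing(curve: CeacCurve, level: float = 0.5) -> float | None:
    """WTP at the first upward crossing of ``level`` (linear interpolation);
    None when the curve never reaches it."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    p = curve.prob_ce
    w = curve.wtp_grid
    if p[0] >= level:
        return float(w[0])
    above = np.nonzero(p >= level)[0]
    if len(above) == 0:
        return None
    j = above[0]
    i = j - 1
    if p[j] == p[i]:
        return float(w[j])
    return float(w[i] + (level - p[i]) * (w[j] - w[i]) / (p[j] - p[i]))
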
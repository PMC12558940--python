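"""Parametric survival laws, right-censored maximum-likelihood fitting and
information-criterion model ranking.

Seven candidate families are supported, each in the standard
survival-analysis parameterisation (time in months throughout):

====================  =====================  ==========================================
family                parameters             survival function S(t)
====================  =====================  ==========================================
exponential           rate λ > 0             exp(−λt)
weibull               shape k, scale λ       exp(−(t/λ)^k)
gompertz              shape b, rate a > 0    exp(−a/b·(e^{bt} − 1))   (b may be < 0)
gamma                 shape k, rate λ        1 − Γ_reg(k, λt)
generalized_gamma     a, c, scale            scipy.stats.gengamma survival
loglogistic           scale α, shape β       1 / (1 + (t/α)^β)
lognormal             mu, sigma              1 − Φ((ln t − mu)/σ)
====================  =====================  ==========================================

The log-logistic scale α equals the median survival time, which is why the
fitted scales of the overall-survival curves sit close to the trial's median
OS.  A Gompertz with negative shape has a survival plateau (S(∞) > 0); it is
accepted but a warning is emitted at construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "SurvivalDistribution",
    "FitResult",
    "survival_at",
    "quantile",
    "fit_mle",
    "rank_models",
    "read_ipd",
    "write_ipd",
]

FAMILIES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "gamma": ("shape", "rate"),
    "generalized_gamma": ("a", "c", "scale"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
}

# parameters that must be strictly positive (others are unconstrained reals)
_POSITIVE: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("rate",),
    "gamma": ("shape", "rate"),
    "generalized_gamma": ("a", "scale"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("sigma",),
}


@dataclass(frozen=True)
class SurvivalDistribution:
    """A parametric survival law: family name plus named parameters."""

    family: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        expected = FAMILIES[self.family]
        if tuple(self.params) != expected:
            missing = set(expected) - set(self.params)
            extra = set(self.params) - set(expected)
            raise ValueError(
                f"{self.family} expects parameters {expected}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        for name in _POSITIVE[self.family]:
            if not self.params[name] > 0:
                raise ValueError(f"{self.family} parameter {name!r} must be > 0")
        if self.family == "gompertz" and self.params["shape"] < 0:
            warnings.warn(
                "Gompertz with negative shape has a survival plateau S(inf) > 0",
                stacklevel=2,
            )

    def values(self) -> np.ndarray:
        return np.array([self.params[p] for p in FAMILIES[self.family]])


def _logsf(family: str, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """log S(t); t > 0 array, p in the family's parameter order."""
    if family == "exponential":
        return -p[0] * t
    if family == "weibull":
        return -((t / p[1]) ** p[0])
    if family == "gompertz":
        b, a = p
        if abs(b) < 1e-12:
            return -a * t
        return -a / b * np.expm1(b * t)
    if family == "gamma":
        return stats.gamma.logsf(t, a=p[0], scale=1.0 / p[1])
    if family == "generalized_gamma":
        return stats.gengamma.logsf(t, a=p[0], c=p[1], scale=p[2])
    if family == "loglogistic":
        return -np.log1p((t / p[0]) ** p[1])
    if family == "lognormal":
        return stats.norm.logsf((np.log(t) - p[0]) / p[1])
    raise ValueError(family)


def _logpdf(family: str, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return np.log(p[0]) - p[0] * t
    if family == "weibull":
        k, lam = p
        z = t / lam
        return np.log(k / lam) + (k - 1) * np.log(z) - z**k
    if family == "gompertz":
        b, a = p
        # hazard a·e^{bt}; density = hazard × survival
        return np.log(a) + b * t + _logsf("gompertz", t, p)
    if family == "gamma":
        return stats.gamma.logpdf(t, a=p[0], scale=1.0 / p[1])
    if family == "generalized_gamma":
        return stats.gengamma.logpdf(t, a=p[0], c=p[1], scale=p[2])
    if family == "loglogistic":
        alpha, beta = p
        z = (t / alpha) ** beta
        return np.log(beta / alpha) + (beta - 1) * np.log(t / alpha) - 2 * np.log1p(z)
    if family == "lognormal":
        return stats.lognorm.logpdf(t, s=p[1], scale=np.exp(p[0]))
    raise ValueError(family)


def survival_at(dist: SurvivalDistribution, t) -> np.ndarray | float:
    """Survival probability S(t) for t >= 0 (months); S(0) = 1."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival_at requires t >= 0")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    out = np.ones_like(t_arr)
    pos = t_arr > 0
    if pos.any():
        out[pos] = np.exp(_logsf(dist.family, t_arr[pos], dist.values()))
    return float(out[0]) if scalar else out


def quantile(dist: SurvivalDistribution, p) -> np.ndarray | float:
    """Inverse CDF: the time t with 1 − S(t) = p, for p in (0, 1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("quantile requires p in (0, 1)")
    scalar = p_arr.ndim == 0
    p_arr = np.atleast_1d(p_arr)
    v = dist.values()
    fam = dist.family
    if fam == "exponential":
        out = -np.log1p(-p_arr) / v[0]
    elif fam == "weibull":
        out = v[1] * (-np.log1p(-p_arr)) ** (1.0 / v[0])
    elif fam == "loglogistic":
        out = v[0] * (p_arr / (1.0 - p_arr)) ** (1.0 / v[1])
    elif fam == "lognormal":
        out = np.exp(v[0] + v[1] * stats.norm.ppf(p_arr))
    elif fam == "gamma":
        out = stats.gamma.ppf(p_arr, a=v[0], scale=1.0 / v[1])
    elif fam == "generalized_gamma":
        out = stats.gengamma.ppf(p_arr, a=v[0], c=v[1], scale=v[2])
    elif fam == "gompertz":
        b, a = v
        arg = 1.0 - b / a * np.log1p(-p_arr)
        if np.any(arg <= 0):
            raise ValueError(
                "quantile beyond the Gompertz plateau (negative shape): S never falls this low"
            )
        out = np.log(arg) / b if abs(b) > 1e-12 else -np.log1p(-p_arr) / a
    else:  # pragma: no cover
        raise ValueError(fam)
    return float(out[0]) if scalar else out


@dataclass
class FitResult:
    """Maximum-likelihood fit of one family to right-censored data."""

    dist: SurvivalDistribution
    loglik: float
    aic: float
    bic: float
    n: int
    k: int
    converged: bool = True
    message: str = ""
    # asymptotic covariance of the unconstrained (log-transformed where
    # positive) parameters, from the inverse observed information
    cov_trans: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "family": self.dist.family,
            "params": dict(self.dist.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "k": self.k,
            "converged": self.converged,
        }


def _transform(family: str, values: np.ndarray) -> np.ndarray:
    """Map native parameters to unconstrained optimizer space (log for positives)."""
    names = FAMILIES[family]
    pos = _POSITIVE[family]
    return np.array(
        [np.log(v) if name in pos else v for name, v in zip(names, values)]
    )


def _untransform(family: str, theta: np.ndarray) -> np.ndarray:
    names = FAMILIES[family]
    pos = _POSITIVE[family]
    return np.array(
        [np.exp(v) if name in pos else v for name, v in zip(names, theta)]
    )


def _starts(family: str, times: np.ndarray, events: np.ndarray) -> list[np.ndarray]:
    """Three native-space starting points per family (moment-style heuristics)."""
    rate0 = max(events.sum(), 1.0) / times.sum()
    med = float(np.median(times))
    mu, sig = float(np.mean(np.log(times))), max(float(np.std(np.log(times))), 0.2)
    base: dict[str, list] = {
        "exponential": [[rate0], [rate0 * 2], [rate0 / 2]],
        "weibull": [[1.0, 1 / rate0], [1.5, med], [0.7, med]],
        "gompertz": [[0.01, rate0], [0.1, rate0 / 2], [-0.01, rate0]],
        "gamma": [[1.0, rate0], [2.0, 2 * rate0], [0.5, rate0 / 2]],
        "generalized_gamma": [[1.0, 1.0, 1 / rate0], [2.0, 0.8, med], [0.5, 1.5, med]],
        "loglogistic": [[med, 1.5], [med, 1.0], [med * 1.5, 2.5]],
        "lognormal": [[mu, sig], [mu, 2 * sig], [np.log(med), 1.0]],
    }
    return [np.array(s, dtype=float) for s in base[family]]


def loglikelihood(
    family: str, params: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Right-censored log-likelihood: events contribute ln f, censored ln S."""
    ll = 0.0
    ev = events.astype(bool)
    if ev.any():
        ll += float(np.sum(_logpdf(family, times[ev], params)))
    if (~ev).any():
        ll += float(np.sum(_logsf(family, times[~ev], params)))
    return ll


def _hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei) - f(x + ej) + f(x)
            ) / h**2
    return H


def fit_mle(
    times: Sequence[float],
    events: Sequence[int],
    family: str,
    n_starts: int = 3,
) -> FitResult:
    """Fit one family to right-censored data by maximum likelihood.

    ``times`` are observation times in months (> 0), ``events`` the usual
    indicator (1 = event observed, 0 = censored).  Optimisation runs on
    log-transformed positive parameters with multiple starts; the
    exponential rate uses its closed form events / total follow-up.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be matching 1-d sequences")
    if np.any(t <= 0):
        raise ValueError("all observation times must be > 0")
    if e.sum() < 2:
        raise ValueError("fitting requires at least 2 observed events")
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    n, k = len(t), len(FAMILIES[family])

    def nll(theta: np.ndarray) -> float:
        params = _untransform(family, theta)
        with np.errstate(all="ignore"):
            ll = loglikelihood(family, params, t, e)
        return -ll if np.isfinite(ll) else 1e12

    if family == "exponential":
        rate = e.sum() / t.sum()
        best = optimize.OptimizeResult(
            x=_transform(family, np.array([rate])), fun=nll(np.log([rate])), success=True
        )
    else:
        best = None
        for s in _starts(family, t, e)[:n_starts]:
            res = optimize.minimize(nll, _transform(family, s), method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
            res = optimize.minimize(nll, res.x, method="BFGS")
            if best is None or res.fun < best.fun:
                best = res

    params = _untransform(family, best.x)
    dist = SurvivalDistribution(family, dict(zip(FAMILIES[family], params)))
    ll = -best.fun
    cov = None
    try:
        H = _hessian(nll, best.x)
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    return FitResult(
        dist=dist,
        loglik=ll,
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
        n=n,
        k=k,
        converged=bool(getattr(best, "success", True)),
        message=str(getattr(best, "message", "")),
        cov_trans=cov,
    )


def rank_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits (same data) ascending by AIC; ties by BIC then family name.

    Returns a DataFrame with family, params, loglik, aic, bic and delta_aic.
    """
    if not fits:
        raise ValueError("rank_models requires at least one fit")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits were made on differing sample sizes: {sorted(ns)}")
    rows = sorted(fits, key=lambda f: (f.aic, f.bic, f.dist.family))
    best_aic = rows[0].aic
    return pd.DataFrame(
        {
            "family": [f.dist.family for f in rows],
            "params": [dict(f.dist.params) for f in rows],
            "loglik": [f.loglik for f in rows],
            "aic": [f.aic for f in rows],
            "bic": [f.bic for f in rows],
            "delta_aic": [f.aic - best_aic for f in rows],
            "converged": [f.converged for f in rows],
        }
    )


def read_ipd(path) -> pd.DataFrame:
    """Read individual patient data CSV with columns time, event."""
    df = pd.read_csv(path)
    if not {"time", "event"}.issubset(df.columns):
        raise ValueError("IPD CSV must have columns 'time' and 'event'")
    return df


def write_ipd(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
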
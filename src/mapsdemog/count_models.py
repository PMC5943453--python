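"""Poisson log-linear abundance model and binomial relative-productivity model.

Adult counts C_{k,s,t} at station s in region k and year t are Poisson with

    log(lambda) = alpha_k + beta_trend_k * t + beta_hf * HF_s
                  + beta_effort * EF_{s,t} + omega_s + eps_{k,s,t}

where omega_s is a station random effect (SD sigma_station) and eps an
observation-level normal deviate (SD sigma_noise) giving lognormal-Poisson
overdispersion.  The juvenile proportion model is binomial,
JUV ~ Bin(N, p) with logit(p) = alpha_k + beta_trend_k * t + beta_hf * HF_s
+ omega_s.  Covariates enter standardized (see
:mod:`mapsdemog.data_io`); t is centered at the study midpoint in years, so
trend coefficients are per-year on the link scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, log_expit, expit

from .data_io import AbundanceData, ProductivityData

_ETA_MAX = 700.0  # exp() overflow guard on the log-mean scale


@dataclass
class AbundanceParams:
    """Concrete parameter values for the count model.

    ``alpha``/``beta_trend`` are length-3 region vectors (west, central,
    east); ``omega`` holds one realized station effect per station and
    ``epsilon`` one realized noise value per observation (zeros when the
    noise layer is switched off).
    """

    alpha: np.ndarray
    beta_trend: np.ndarray
    beta_hf: float = 0.0
    beta_effort: float = 0.0
    omega: np.ndarray | None = None
    sigma_station: float = 0.0
    epsilon: np.ndarray | None = None
    sigma_noise: float = 0.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta_trend = np.asarray(self.beta_trend, dtype=float)
        if self.alpha.shape != (3,) or self.beta_trend.shape != (3,):
            raise ValueError("alpha and beta_trend must be length-3 region vectors")
        if self.sigma_station < 0 or self.sigma_noise < 0:
            raise ValueError("random-effect SDs must be >= 0")

    @classmethod
    def zeros(cls) -> "AbundanceParams":
        return cls(alpha=np.zeros(3), beta_trend=np.zeros(3))


@dataclass
class ProductivityParams:
    """Concrete parameter values for the juvenile-proportion model."""

    alpha: np.ndarray
    beta_trend: np.ndarray
    beta_hf: float = 0.0
    omega: np.ndarray | None = None
    sigma_station: float = 0.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta_trend = np.asarray(self.beta_trend, dtype=float)
        if self.alpha.shape != (3,) or self.beta_trend.shape != (3,):
            raise ValueError("alpha and beta_trend must be length-3 region vectors")
        if self.sigma_station < 0:
            raise ValueError("random-effect SD must be >= 0")

    @classmethod
    def zeros(cls) -> "ProductivityParams":
        return cls(alpha=np.zeros(3), beta_trend=np.zeros(3))


def _omega_term(omega: np.ndarray | None, obs_station: np.ndarray) -> np.ndarray:
    if omega is None:
        return np.zeros(len(obs_station))
    return np.asarray(omega, dtype=float)[obs_station]


def abundance_linpred(params: AbundanceParams, data: AbundanceData) -> np.ndarray:
    """log(lambda) per observation row."""
    k = data.obs_region
    eta = (
        params.alpha[k]
        + params.beta_trend[k] * data.obs_t
        + params.beta_hf * data.hf_std[data.obs_station]
        + params.beta_effort * data.obs_effort_std
        + _omega_term(params.omega, data.obs_station)
    )
    if params.epsilon is not None:
        eta = eta + np.asarray(params.epsilon, dtype=float)
    return eta


def abundance_mean(params: AbundanceParams, data: AbundanceData) -> np.ndarray:
    """Expected count lambda per observation row (strictly positive)."""
    eta = abundance_linpred(params, data)
    if np.any(eta > _ETA_MAX):
        raise OverflowError("log-mean exceeds exp() range")
    return np.exp(eta)


def abundance_loglik(params: AbundanceParams, data: AbundanceData) -> float:
    """Sum of Poisson log-pmf over station-years; 0 for empty data."""
    if len(data.counts) == 0:
        return 0.0
    eta = abundance_linpred(params, data)
    if np.any(eta > _ETA_MAX) or np.any(~np.isfinite(eta)):
        raise OverflowError("non-finite or overflowing log-mean")
    c = data.counts
    ll = c * eta - np.exp(eta) - gammaln(c + 1.0)
    return float(np.sum(ll))


def productivity_linpred(params: ProductivityParams, data: ProductivityData) -> np.ndarray:
    k = data.obs_region
    return (
        params.alpha[k]
        + params.beta_trend[k] * data.obs_t
        + params.beta_hf * data.hf_std[data.obs_station]
        + _omega_term(params.omega, data.obs_station)
    )


def productivity_prob(params: ProductivityParams, data: ProductivityData) -> np.ndarray:
    """Probability that a captured bird is a juvenile, per observation row."""
    return expit(productivity_linpred(params, data))


def productivity_loglik(params: ProductivityParams, data: ProductivityData) -> float:
    """Sum of binomial log-pmf over station-years; 0 for empty data.

    Degenerate edges (p -> 0 or 1 with the matching outcome) evaluate to the
    correct limit because k*log(p) terms enter through log_expit of a finite
    linear predictor.
    """
    if len(data.totals) == 0:
        return 0.0
    juv, tot = data.juveniles, data.totals
    if np.any(juv > tot):
        raise ValueError("juvenile count exceeds total captures")
    eta = productivity_linpred(params, data)
    ll = (
        juv * log_expit(eta)
        + (tot - juv) * log_expit(-eta)
        + gammaln(tot + 1.0)
        - gammaln(juv + 1.0)
        - gammaln(tot - juv + 1.0)
    )
    return float(np.sum(ll))
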
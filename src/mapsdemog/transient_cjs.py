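"""Transient Cormack-Jolly-Seber likelihood with a residency mixture.

Mark-recapture data from constant-effort stations include transients:
birds captured once while passing through that are never available for
recapture.  Ignoring them biases apparent survival low.  The model treats a
newly captured bird as a resident with probability pi and as a transient
otherwise.  Residents survive year to year with probability phi and, when
alive, are recaptured with probability pr; transients are permanently gone
after the first occasion.  Some residents are identified as such by
within-season repeat capture ("pre-determined", probability rho); transients
can never be pre-determined.

All four probabilities are logit-linear:

    logit(phi_{i,t}) = mu_phi + b_region[k] + b_sex*sex_i + b_hf*HF_s
                       + b_trend[k]*t + omega_phi[s]
    logit(pi_i)      = alpha_pi + c_region[k] + c_sex*sex_i + c_hf*HF_s
                       + omega_pi[s]
    logit(pr_i)      = pr_intercept + pr_sex*sex_i + omega_pr[s]
    logit(rho_i)     = rho_intercept + rho_sex*sex_i + omega_rho[s]

with the west region as the reference level (offset fixed at 0) for every
region-structured term, so the common intercept is identified.  The
likelihood conditions on first capture.  Writing P_CJS for the standard
resident CJS probability of the post-first-capture detection record (product
of phi/pr terms to the last detection times the never-seen-again probability
chi), a history with pre-determination flag d has probability

    d = 1:  pi * rho * P_CJS
    d = 0:  pi * (1 - rho) * P_CJS + (1 - pi) * I[no detection after first]

Survival over the interval t -> t+1 uses the trend covariate at the
interval's starting year; pr is indexed to the occasion of potential
recapture (it carries no time structure here, so it is constant within an
individual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from .data_io import CaptureHistory, StationRecord, SurvivalData, REGION_INDEX


@dataclass
class SurvivalParams:
    """Parameters of the transient CJS model.

    Region vectors are length 3 (west, central, east) with the west entry
    fixed at 0.  ``omega_*`` hold realized station effects (``None`` means
    all zero); ``sigma_*`` are their SDs.
    """

    mu_phi: float = 0.0
    beta_phi_region: np.ndarray | None = None
    beta_phi_sex: float = 0.0
    beta_phi_hf: float = 0.0
    beta_phi_trend: np.ndarray | None = None
    omega_phi: np.ndarray | None = None
    sigma_phi: float = 0.0
    alpha_pi: float = 0.0
    beta_pi_region: np.ndarray | None = None
    beta_pi_sex: float = 0.0
    beta_pi_hf: float = 0.0
    omega_pi: np.ndarray | None = None
    sigma_pi: float = 0.0
    pr_intercept: float = 0.0
    pr_sex: float = 0.0
    omega_pr: np.ndarray | None = None
    sigma_pr: float = 0.0
    rho_intercept: float = 0.0
    rho_sex: float = 0.0
    omega_rho: np.ndarray | None = None
    sigma_rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("beta_phi_region", "beta_phi_trend", "beta_pi_region"):
            v = getattr(self, name)
            v = np.zeros(3) if v is None else np.asarray(v, dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a length-3 region vector")
            setattr(self, name, v)
        if self.beta_phi_region[0] != 0.0 or self.beta_pi_region[0] != 0.0:
            raise ValueError("reference-region (west) offsets must be 0")
        for name in ("sigma_phi", "sigma_pi", "sigma_pr", "sigma_rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _omega(vec: np.ndarray | None, idx) -> np.ndarray | float:
    if vec is None:
        return 0.0
    return np.asarray(vec, dtype=float)[idx]


def logit_predictors(
    params: SurvivalParams,
    *,
    region: int | str,
    sex: int,
    hf: float = 0.0,
    station: int | None = None,
    t: float = 0.0,
) -> tuple[float, float, float, float]:
    """Evaluate (phi, pi, pr, rho) for one covariate combination.

    ``hf`` and ``t`` are on the standardized/centered scales used by the
    model; ``station=None`` evaluates at a typical station (random effects
    zero).
    """
    k = REGION_INDEX[region] if isinstance(region, str) else int(region)
    if not 0 <= k <= 2:
        raise ValueError(f"unknown region index {k}")
    om_phi = om_pi = om_pr = om_rho = 0.0
    if station is not None:
        om_phi = float(_omega(params.omega_phi, station))
        om_pi = float(_omega(params.omega_pi, station))
        om_pr = float(_omega(params.omega_pr, station))
        om_rho = float(_omega(params.omega_rho, station))
    phi = expit(
        params.mu_phi + params.beta_phi_region[k] + params.beta_phi_sex * sex
        + params.beta_phi_hf * hf + params.beta_phi_trend[k] * t + om_phi
    )
    pi = expit(
        params.alpha_pi + params.beta_pi_region[k] + params.beta_pi_sex * sex
        + params.beta_pi_hf * hf + om_pi
    )
    pr = expit(params.pr_intercept + params.pr_sex * sex + om_pr)
    rho = expit(params.rho_intercept + params.rho_sex * sex + om_rho)
    return float(phi), float(pi), float(pr), float(rho)


def chi_never_seen(phi_seq, pr_seq) -> np.ndarray:
    """Never-seen-again probabilities over the remaining occasions.

    ``phi_seq[j]`` is survival over interval j -> j+1 and ``pr_seq[j]`` the
    recapture probability at occasion j+1, for j = 0..m-1.  Returns the
    length m+1 vector chi with chi[m] = 1 and

        chi[j] = (1 - phi[j]) + phi[j] * (1 - pr[j]) * chi[j+1].
    """
    phi = np.asarray(phi_seq, dtype=float)
    pr = np.asarray(pr_seq, dtype=float)
    if phi.shape != pr.shape or phi.ndim != 1:
        raise ValueError("phi and pr sequences must be 1-d and the same length")
    m = len(phi)
    chi = np.ones(m + 1)
    for j in range(m - 1, -1, -1):
        chi[j] = (1.0 - phi[j]) + phi[j] * (1.0 - pr[j]) * chi[j + 1]
    return chi


# ---------------------------------------------------------------------------
# Per-history (scalar) evaluation
# ---------------------------------------------------------------------------

def _probs_for_history(
    params: SurvivalParams,
    *,
    region: int,
    sex: int,
    hf: float,
    station: int | None,
    t_std: np.ndarray,
):
    """(phi per interval, pi, pr, rho) for one individual."""
    T = len(t_std)
    _, pi, pr, rho = logit_predictors(
        params, region=region, sex=sex, hf=hf, station=station, t=0.0
    )
    phis = np.empty(T - 1)
    for t in range(T - 1):
        phis[t] = logit_predictors(
            params, region=region, sex=sex, hf=hf, station=station, t=t_std[t]
        )[0]
    return phis, pi, pr, rho


def history_likelihood(
    history: CaptureHistory,
    station: StationRecord | None,
    params: SurvivalParams,
    *,
    t_std: np.ndarray | None = None,
    hf_std: float = 0.0,
    station_index: int | None = None,
    region: int | str | None = None,
) -> float:
    """Probability of one capture history, conditional on first capture.

    A plain scalar evaluation (looped over occasions); the vectorized
    :func:`history_likelihoods` must agree with it to 1e-12.  The covariate
    scale is the model's: ``hf_std`` standardized footprint, ``t_std`` the
    centered year value per occasion (defaults to 0..T-1 centered at the
    midpoint).
    """
    y = history.detections
    T = len(y)
    if region is None:
        if station is None:
            raise ValueError("either a station record or a region is required")
        region = station.region
    k = REGION_INDEX[region] if isinstance(region, str) else int(region)
    if t_std is None:
        t_std = np.arange(T, dtype=float) - (T - 1) / 2.0
    if len(t_std) != T:
        raise ValueError("t_std length must match the number of occasions")

    f, l, d = history.first_year, history.last_detection, history.predetermined
    phis, pi, pr, rho = _probs_for_history(
        params, region=k, sex=history.sex, hf=hf_std, station=station_index,
        t_std=np.asarray(t_std, dtype=float),
    )
    # Resident CJS probability of the post-first record.
    p_res = 1.0
    for t in range(f, l):
        p_res *= phis[t]
        p_res *= pr if y[t + 1] else (1.0 - pr)
    chi = chi_never_seen(phis[l:], np.full(T - 1 - l, pr))
    p_res *= chi[0]

    if d == 1:
        return pi * rho * p_res
    lik = pi * (1.0 - rho) * p_res
    if l == f:  # no detection after first year: transient outcome possible
        lik += 1.0 - pi
    return lik


# ---------------------------------------------------------------------------
# Vectorized evaluation
# ---------------------------------------------------------------------------

def _linpreds(params: SurvivalParams, data: SurvivalData):
    """Linear predictors for all individuals: phi (n, T-1); pi, pr, rho (n,)."""
    k = data.ind_region
    sex = data.ind_sex
    hf = data.ind_hf
    s = data.ind_station
    base_phi = (
        params.mu_phi
        + params.beta_phi_region[k]
        + params.beta_phi_sex * sex
        + params.beta_phi_hf * hf
        + _omega(params.omega_phi, s)
    )
    eta_phi = base_phi[:, None] + params.beta_phi_trend[k][:, None] * data.t_std[None, :-1]
    eta_pi = (
        params.alpha_pi
        + params.beta_pi_region[k]
        + params.beta_pi_sex * sex
        + params.beta_pi_hf * hf
        + _omega(params.omega_pi, s)
    )
    eta_pr = params.pr_intercept + params.pr_sex * sex + _omega(params.omega_pr, s)
    eta_rho = params.rho_intercept + params.rho_sex * sex + _omega(params.omega_rho, s)
    return eta_phi, np.broadcast_to(eta_pi, sex.shape), eta_pr, eta_rho


def history_logliks(params: SurvivalParams, data: SurvivalData) -> np.ndarray:
    """Log-likelihood per individual, vectorized over the whole dataset."""
    n, T = data.n_individuals, data.n_occasions
    eta_phi, eta_pi, eta_pr, eta_rho = _linpreds(params, data)
    phi = expit(eta_phi)                       # (n, T-1)
    pr = expit(np.broadcast_to(eta_pr, (n,)))  # (n,)
    log_phi = log_expit(eta_phi)
    log_pi = log_expit(eta_pi)
    log_1mpi = log_expit(-eta_pi)
    log_rho = log_expit(eta_rho)
    log_1mrho = log_expit(-eta_rho)
    log_pr = log_expit(eta_pr)
    log_1mpr = log_expit(-eta_pr)

    # chi at each individual's last detection, via the backward recursion.
    chi = np.ones(n)
    chi_at_last = np.where(data.last == T - 1, 1.0, 0.0)
    for t in range(T - 2, -1, -1):
        chi = (1.0 - phi[:, t]) + phi[:, t] * (1.0 - pr) * chi
        hit = data.last == t
        if np.any(hit):
            chi_at_last = np.where(hit, chi, chi_at_last)

    s_phi = np.sum(log_phi, axis=1, where=data.int_mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_chi = np.log(chi_at_last)
        # 0 * (-inf) guards for saturated pr under extreme parameters
        redetect_term = np.where(data.n_redetect > 0, data.n_redetect * log_pr, 0.0)
        miss_term = np.where(data.n_miss > 0, data.n_miss * log_1mpr, 0.0)
        log_p_res = s_phi + redetect_term + miss_term + log_chi
        seen_again = data.last > data.first
        ll_resident_d0 = log_pi + log_1mrho + log_p_res
        ll = np.where(
            data.predetermined == 1,
            log_pi + log_rho + log_p_res,
            np.where(
                seen_again,
                ll_resident_d0,
                np.logaddexp(ll_resident_d0, log_1mpi),
            ),
        )
    return ll


def history_likelihoods(params: SurvivalParams, data: SurvivalData) -> np.ndarray:
    """Probability of each capture history (vectorized)."""
    return np.exp(history_logliks(params, data))


def dataset_loglik(params: SurvivalParams, data: SurvivalData) -> float:
    """Total log-likelihood; -inf only if some history has probability 0."""
    if data.n_individuals == 0:
        return 0.0
    ll = history_logliks(params, data)
    bad = np.isnan(ll)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise FloatingPointError(
            f"NaN log-likelihood for individual {data.ind_ids[i]}"
        )
    return float(np.sum(ll))
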
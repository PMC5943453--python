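"""Posterior sampling and MCMC diagnostics.

Models are sampled with adaptive random-walk Metropolis-within-Gibbs:
scalar coefficients and station-random-effect vectors are Metropolis blocks
whose proposal scales tune toward a target acceptance rate during burn-in,
while random-effect variances use exact conjugate Gibbs draws (normal
effects + inverse-gamma(0.001, 0.001) prior).  Coefficients carry diffuse
normal(0, variance 10^3) priors.

The default configuration follows the published protocol: two chains of
100,000 iterations, 80,000 discarded as burn-in, thinned by 2, pooling
20,000 retained draws.  Reduced presets with the same structure are
first-class for tests and desk-scale runs.  Diagnostics are the
Gelman-Rubin potential scale reduction factor, highest-posterior-density
intervals and the posterior mass below zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .data_io import AbundanceData, ModelData, ProductivityData, SurvivalData

COEF_PRIOR_VAR = 1000.0          # normal prior variance for coefficients
IG_SHAPE = IG_SCALE = 0.001      # inverse-gamma prior for variances
_ETA_GUARD = 100.0               # reject proposals with absurd log-means


@dataclass(frozen=True)
class McmcConfig:
    """Chains, lengths, thinning, seed and adaptation settings."""

    n_chains: int = 2
    n_iterations: int = 100_000
    burn_in: int = 80_000
    thin: int = 2
    seed: int = 0
    target_accept: float = 0.35
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained_per_chain(self) -> int:
        return math.ceil((self.n_iterations - self.burn_in) / self.thin)

    @property
    def pooled_draws(self) -> int:
        return self.n_chains * self.retained_per_chain


#: The published protocol: 2 x 100k iterations, 80k burn-in, thin 2.
FULL_PRESET = McmcConfig()
#: Reduced preset for tests and desk-scale runs.
TEST_PRESET = McmcConfig(n_iterations=4_000, burn_in=2_000, thin=1)


@dataclass
class PosteriorChains:
    """Named posterior draws with chain structure.

    ``draws[name]`` has shape (n_chains, n_draws) for scalar parameters or
    (n_chains, n_draws, k) for vector parameters.
    """

    draws: dict[str, np.ndarray]

    @property
    def names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: (n_chains*n_draws,) or (..., k)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def scalar_items(self):
        """Yield (label, (n_chains, n_draws) array), expanding vectors."""
        for name, a in self.draws.items():
            if a.ndim == 2:
                yield name, a
            else:
                for j in range(a.shape[2]):
                    yield f"{name}[{j}]", a[:, :, j]

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        rows = []
        for label, a in self.scalar_items():
            pooled = a.reshape(-1)
            lo, hi = hpd_interval(pooled, mass)
            rows.append(
                {
                    "parameter": label,
                    "mean": float(pooled.mean()),
                    "sd": float(pooled.std(ddof=1)),
                    f"hpd{int(mass * 100)}_low": lo,
                    f"hpd{int(mass * 100)}_high": hi,
                    "prob_below_zero": prob_mass_below_zero(pooled),
                    "rhat": rhat(a) if a.shape[0] >= 2 else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path) -> None:
        c, d = self.n_chains, self.n_draws
        cols: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(c), d),
            "iteration": np.tile(np.arange(d), c),
        }
        for label, a in self.scalar_items():
            cols[label] = a.reshape(-1)
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | Path) -> "PosteriorChains":
        df = pd.read_csv(path)
        c = df["chain"].nunique()
        d = len(df) // c
        vectors: dict[str, dict[int, np.ndarray]] = {}
        draws: dict[str, np.ndarray] = {}
        for col in df.columns:
            if col in ("chain", "iteration"):
                continue
            a = df[col].to_numpy().reshape(c, d)
            if col.endswith("]") and "[" in col:
                name, idx = col[:-1].rsplit("[", 1)
                vectors.setdefault(name, {})[int(idx)] = a
            else:
                draws[col] = a
        for name, parts in vectors.items():
            k = max(parts) + 1
            draws[name] = np.stack([parts[j] for j in range(k)], axis=2)
        return cls(draws)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is (m, n): m >= 2 chains of n >= 10 draws.  With zero
    within-chain variance but identical chains the statistic degenerates:
    two identical chains give B = 0 and the result sqrt((n-1)/n), slightly
    below 1, which is reported as-is (documented degenerate case).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat needs at least two chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("rhat needs at least 10 draws per chain")
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    b = n * float(np.var(np.mean(x, axis=1), ddof=1))
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def hpd_interval(draws: Sequence[float], mass: float = 0.90) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = len(x)
    if n < 100:
        raise ValueError("hpd_interval needs at least 100 draws")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    k = int(math.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def prob_mass_below_zero(draws: Sequence[float]) -> float:
    """Fraction of draws strictly below zero."""
    x = np.asarray(draws, dtype=float).reshape(-1)
    if len(x) == 0:
        raise ValueError("need at least one draw")
    return float(np.mean(x < 0.0))


# ---------------------------------------------------------------------------
# Adaptive Metropolis machinery
# ---------------------------------------------------------------------------

class _Adapt:
    """Proposal scales for one block family, tuned during burn-in only.

    Once per window the log step moves by (acceptance rate - target), so
    the retained chain runs with a fixed kernel.
    """

    def __init__(self, shape, window: int, target: float, init_step: float = 0.1):
        self.log_step = np.full(shape, np.log(init_step))
        self.window = window
        self.target = target
        self.acc = np.zeros(shape)
        self.count = 0

    @property
    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def record(self, accepted, adapting: bool) -> None:
        self.acc = self.acc + accepted
        self.count += 1
        if self.count >= self.window:
            if adapting:
                rate = self.acc / self.count
                self.log_step = np.clip(
                    self.log_step + (rate - self.target), -10.0, 4.0
                )
            self.acc = np.zeros_like(self.acc)
            self.count = 0


def _coef_logprior(x: float) -> float:
    return -0.5 * x * x / COEF_PRIOR_VAR


def _gibbs_variance(rng: np.random.Generator, values: np.ndarray) -> float:
    """Conjugate draw of a random-effect variance; returns the SD."""
    shape = IG_SHAPE + 0.5 * values.size
    scale = IG_SCALE + 0.5 * float(np.sum(values**2))
    return float(np.sqrt(scale / rng.gamma(shape)))


def _chain_rngs(config: McmcConfig) -> list[np.random.Generator]:
    return [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(config.n_chains)
    ]


class _ScalarBlocks:
    """A family of single-parameter Metropolis blocks over a state dict.

    Entries are (name, index) where index=None addresses a scalar state
    entry and an integer addresses one component of a vector entry.
    """

    def __init__(self, entries, config: McmcConfig):
        self.entries = list(entries)
        self.adapt = _Adapt(
            (len(self.entries),), config.adapt_window, config.target_accept
        )

    def sweep(self, state, loglik_total, rng, adapting) -> float:
        """One Metropolis pass over every entry; returns the new total."""
        cur_ll = loglik_total(state)
        accepted = np.zeros(len(self.entries))
        steps = self.adapt.step
        for bi, (name, idx) in enumerate(self.entries):
            cur = state[name] if idx is None else state[name][idx]
            prop = cur + steps[bi] * rng.normal()
            if idx is None:
                state[name] = prop
            else:
                state[name][idx] = prop
            new_ll = loglik_total(state)
            logr = new_ll - cur_ll + _coef_logprior(prop) - _coef_logprior(cur)
            if np.log(rng.random()) < logr:
                cur_ll = new_ll
                accepted[bi] = 1.0
            else:
                if idx is None:
                    state[name] = cur
                else:
                    state[name][idx] = cur
        self.adapt.record(accepted, adapting)
        return cur_ll


def _re_vector_update(
    state: dict,
    om_name: str,
    sig_name: str,
    group_idx: np.ndarray,
    n_groups: int,
    loglik_vec: Callable[[dict], np.ndarray],
    ll_vec: np.ndarray,
    adapt: _Adapt,
    rng: np.random.Generator,
    adapting: bool,
) -> np.ndarray:
    """Elementwise Metropolis update of one random-effect vector.

    The likelihood factorizes over groups (stations / observations), so a
    single vectorized evaluation under the all-changed proposal yields valid
    per-group acceptance decisions.  Ends with a conjugate Gibbs draw of the
    effect SD.
    """
    om = state[om_name]
    prop = om + adapt.step * rng.normal(size=om.shape)
    state[om_name] = prop
    new_vec = loglik_vec(state)
    if group_idx is None:  # groups == likelihood rows
        cur_by_g, new_by_g = ll_vec, new_vec
    else:
        cur_by_g = np.bincount(group_idx, weights=ll_vec, minlength=n_groups)
        new_by_g = np.bincount(group_idx, weights=new_vec, minlength=n_groups)
    sig2 = state[sig_name] ** 2
    logr = (new_by_g - cur_by_g) + (om**2 - prop**2) / (2.0 * sig2)
    acc = np.log(rng.random(size=om.shape)) < logr
    om_new = np.where(acc, prop, om)
    state[om_name] = om_new
    acc_rows = acc if group_idx is None else acc[group_idx]
    ll_vec = np.where(acc_rows, new_vec, ll_vec)
    adapt.record(acc.astype(float), adapting)
    state[sig_name] = _gibbs_variance(rng, om_new)
    return ll_vec


def _storage_for(state: dict, names, config: McmcConfig) -> dict[str, np.ndarray]:
    d = config.retained_per_chain
    out = {}
    for name in names:
        v = state[name]
        if np.ndim(v) == 0:
            out[name] = np.empty(d)
        else:
            out[name] = np.empty((d, len(v)))
    return out


def _store(storage, state, slot) -> None:
    for name, arr in storage.items():
        arr[slot] = state[name]


def _keep_slot(config: McmcConfig, it: int) -> int | None:
    if it < config.burn_in:
        return None
    off = it - config.burn_in
    return off // config.thin if off % config.thin == 0 else None


# ---------------------------------------------------------------------------
# Survival (transient CJS) chain
# ---------------------------------------------------------------------------

_SURV_SCALARS = (
    ("mu_phi", "phi"), ("beta_phi_sex", "phi"), ("beta_phi_hf", "phi"),
    ("alpha_pi", "pi"), ("beta_pi_sex", "pi"), ("beta_pi_hf", "pi"),
    ("pr_intercept", "pr"), ("pr_sex", "pr"),
    ("rho_intercept", "rho"), ("rho_sex", "rho"),
)
_SURV_RE = (
    ("omega_phi", "sigma_phi", "phi"),
    ("omega_pi", "sigma_pi", "pi"),
    ("omega_pr", "sigma_pr", "pr"),
    ("omega_rho", "sigma_rho", "rho"),
)
_SURV_NAMES = tuple(n for n, _ in _SURV_SCALARS) + (
    "beta_phi_region", "beta_pi_region", "beta_phi_trend",
) + tuple(n for n, s, _ in _SURV_RE for n in (n, s))


def _group_histories(data: SurvivalData) -> tuple[SurvivalData, np.ndarray]:
    """Collapse histories with identical sufficient statistics.

    The per-history likelihood depends only on (station, sex, first, last,
    number of re-detections, pre-determination flag), so duplicates can be
    weighted instead of repeated.
    """
    keys = np.stack(
        [data.ind_station, data.ind_sex, data.first, data.last,
         data.n_redetect, data.predetermined], axis=1,
    )
    uniq, counts = np.unique(keys, axis=0, return_counts=True)
    station, sex, first, last, n_redetect, d = uniq.T
    tt = np.arange(data.n_occasions - 1)
    grouped = SurvivalData(
        station_ids=data.station_ids,
        region_idx=data.region_idx,
        hf_std=data.hf_std,
        n_occasions=data.n_occasions,
        t_std=data.t_std,
        ind_ids=[f"group{i}" for i in range(len(uniq))],
        ind_station=station,
        ind_sex=sex,
        first=first,
        last=last,
        predetermined=d,
        n_redetect=n_redetect,
        n_miss=(last - first) - n_redetect,
        int_mask=(tt[None, :] >= first[:, None]) & (tt[None, :] < last[:, None]),
        scaling=data.scaling,
    )
    return grouped, counts.astype(float)


class _SurvEvaluator:
    """Transient-CJS log-likelihood with cached per-family components.

    The likelihood factorizes into phi-, pi-, pr- and rho-dependent pieces;
    a Metropolis update of one family only recomputes that family's caches
    (the chi recursion is redone for phi and pr, which it depends on).
    Partial (per-station) acceptance merges cache rows, which is valid
    because every cached array is per-history and histories belong to a
    single station.
    """

    def __init__(self, data: SurvivalData, weights: np.ndarray):
        self.d = data
        self.w = weights
        self.t_int = data.t_std[:-1]
        self.seen = data.last > data.first
        self.is_d1 = data.predetermined == 1
        self.cache: dict[str, np.ndarray] = {}

    # -- family components ---------------------------------------------------
    def _phi_parts(self, st) -> dict:
        d = self.d
        base = (
            st["mu_phi"]
            + st["beta_phi_region"][d.ind_region]
            + st["beta_phi_sex"] * d.ind_sex
            + st["beta_phi_hf"] * d.ind_hf
            + st["omega_phi"][d.ind_station]
        )
        eta = base[:, None] + st["beta_phi_trend"][d.ind_region][:, None] * self.t_int[None, :]
        return {
            "phi": expit(eta),
            "s_phi": np.sum(log_expit(eta), axis=1, where=d.int_mask),
        }

    def _pr_parts(self, st) -> dict:
        d = self.d
        eta = st["pr_intercept"] + st["pr_sex"] * d.ind_sex + st["omega_pr"][d.ind_station]
        log_pr, log_1mpr = log_expit(eta), log_expit(-eta)
        terms = (
            np.where(d.n_redetect > 0, d.n_redetect * log_pr, 0.0)
            + np.where(d.n_miss > 0, d.n_miss * log_1mpr, 0.0)
        )
        return {"pr": expit(eta), "pr_terms": terms}

    def _pi_parts(self, st) -> dict:
        d = self.d
        eta = (
            st["alpha_pi"]
            + st["beta_pi_region"][d.ind_region]
            + st["beta_pi_sex"] * d.ind_sex
            + st["beta_pi_hf"] * d.ind_hf
            + st["omega_pi"][d.ind_station]
        )
        return {"log_pi": log_expit(eta), "log_1mpi": log_expit(-eta)}

    def _rho_parts(self, st) -> dict:
        d = self.d
        eta = st["rho_intercept"] + st["rho_sex"] * d.ind_sex + st["omega_rho"][d.ind_station]
        return {"log_rho": log_expit(eta), "log_1mrho": log_expit(-eta)}

    def _log_chi(self, phi: np.ndarray, pr: np.ndarray) -> np.ndarray:
        d = self.d
        T = d.n_occasions
        chi = np.ones(len(pr))
        out = np.where(d.last == T - 1, 1.0, 0.0)
        one_m_pr = 1.0 - pr
        for t in range(T - 2, -1, -1):
            chi = (1.0 - phi[:, t]) + phi[:, t] * one_m_pr * chi
            hit = d.last == t
            if hit.any():
                out = np.where(hit, chi, out)
        with np.errstate(divide="ignore"):
            return np.log(out)

    def _assemble(self, c: dict) -> np.ndarray:
        log_pres = c["s_phi"] + c["pr_terms"] + c["log_chi"]
        res_d0 = c["log_pi"] + c["log_1mrho"] + log_pres
        return np.where(
            self.is_d1,
            c["log_pi"] + c["log_rho"] + log_pres,
            np.where(self.seen, res_d0, np.logaddexp(res_d0, c["log_1mpi"])),
        )

    # -- public interface ----------------------------------------------------
    def full(self, st) -> None:
        c = {}
        c.update(self._phi_parts(st))
        c.update(self._pr_parts(st))
        c.update(self._pi_parts(st))
        c.update(self._rho_parts(st))
        c["log_chi"] = self._log_chi(c["phi"], c["pr"])
        c["ll"] = self._assemble(c)
        self.cache = c

    def trial(self, st, family: str) -> dict:
        """Candidate caches for one family's proposal (not committed)."""
        c = dict(self.cache)
        if family == "phi":
            c.update(self._phi_parts(st))
            c["log_chi"] = self._log_chi(c["phi"], c["pr"])
        elif family == "pr":
            c.update(self._pr_parts(st))
            c["log_chi"] = self._log_chi(c["phi"], c["pr"])
        elif family == "pi":
            c.update(self._pi_parts(st))
        elif family == "rho":
            c.update(self._rho_parts(st))
        else:
            raise ValueError(family)
        c["ll"] = self._assemble(c)
        return c

    def commit(self, trial_cache: dict, rows: np.ndarray | None = None) -> None:
        if rows is None:
            self.cache = trial_cache
            return
        merged = dict(self.cache)
        for key, new in trial_cache.items():
            old = self.cache[key]
            if new is old:
                continue
            sel = rows[:, None] if new.ndim == 2 else rows
            merged[key] = np.where(sel, new, old)
        self.cache = merged

    def total(self, ll_vec: np.ndarray | None = None) -> float:
        if ll_vec is None:
            ll_vec = self.cache["ll"]
        return float(self.w @ ll_vec)

    def by_station(self, ll_vec: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.d.ind_station, weights=self.w * ll_vec,
            minlength=self.d.n_stations,
        )


def _survival_scalar_entries(data: SurvivalData):
    entries = [(name, None, fam) for name, fam in _SURV_SCALARS]
    for k in sorted(set(int(v) for v in np.unique(data.ind_region))):
        if k != 0:
            entries.append(("beta_phi_region", k, "phi"))
            entries.append(("beta_pi_region", k, "pi"))
        entries.append(("beta_phi_trend", k, "phi"))
    return entries


class _SurvivalModel:
    names = _SURV_NAMES

    def __init__(self, data: SurvivalData, config: McmcConfig):
        self.data = data
        self.config = config
        grouped, weights = _group_histories(data)
        self.ev = _SurvEvaluator(grouped, weights)
        self.entries = _survival_scalar_entries(data)
        self.scalar_adapt = _Adapt(
            (len(self.entries),), config.adapt_window, config.target_accept
        )
        self.re_adapts = {
            om: _Adapt((data.n_stations,), config.adapt_window, config.target_accept)
            for om, _, _ in _SURV_RE
        }
        self._fresh = True

    def init_state(self, rng):
        S = self.data.n_stations
        state: dict = {
            name: float(rng.normal(0.0, 1.0)) for name, _ in _SURV_SCALARS
        }
        state["beta_phi_region"] = np.zeros(3)
        state["beta_pi_region"] = np.zeros(3)
        state["beta_phi_trend"] = np.zeros(3)
        for om, sig, _ in _SURV_RE:
            state[om] = rng.normal(0.0, 0.5, size=S)
            state[sig] = 1.0
        self._fresh = True
        return state

    def sweep(self, state, rng, adapting):
        ev = self.ev
        if self._fresh:
            ev.full(state)
            self._fresh = False
        cur_total = ev.total()
        accepted = np.zeros(len(self.entries))
        steps = self.scalar_adapt.step
        for bi, (name, idx, family) in enumerate(self.entries):
            cur = state[name] if idx is None else state[name][idx]
            prop = cur + steps[bi] * rng.normal()
            if idx is None:
                state[name] = prop
            else:
                state[name][idx] = prop
            tc = ev.trial(state, family)
            logr = ev.total(tc["ll"]) - cur_total
            logr += _coef_logprior(prop) - _coef_logprior(cur)
            if np.log(rng.random()) < logr:
                ev.commit(tc)
                cur_total = ev.total()
                accepted[bi] = 1.0
            else:
                if idx is None:
                    state[name] = cur
                else:
                    state[name][idx] = cur
        self.scalar_adapt.record(accepted, adapting)

        d = self.ev.d
        for om_name, sig_name, family in _SURV_RE:
            om = state[om_name]
            adapt = self.re_adapts[om_name]
            prop = om + adapt.step * rng.normal(size=om.shape)
            state[om_name] = prop
            tc = ev.trial(state, family)
            cur_by = ev.by_station(ev.cache["ll"])
            new_by = ev.by_station(tc["ll"])
            sig2 = state[sig_name] ** 2
            logr = (new_by - cur_by) + (om**2 - prop**2) / (2.0 * sig2)
            acc = np.log(rng.random(size=om.shape)) < logr
            om_new = np.where(acc, prop, om)
            state[om_name] = om_new
            ev.commit(tc, rows=acc[d.ind_station])
            adapt.record(acc.astype(float), adapting)
            state[sig_name] = _gibbs_variance(rng, om_new)


# ---------------------------------------------------------------------------
# Abundance (Poisson count) chain
# ---------------------------------------------------------------------------

_AB_NAMES = (
    "alpha_lambda", "beta_lambda_trend", "beta_lambda_hf", "beta_lambda_effort",
    "omega_lambda", "sigma_lambda_station", "sigma_lambda_noise",
)


def _ab_loglik_vec(state: dict, data: AbundanceData) -> np.ndarray:
    """Per-observation Poisson log-likelihood, constants dropped."""
    k = data.obs_region
    eta = (
        state["alpha_lambda"][k]
        + state["beta_lambda_trend"][k] * data.obs_t
        + state["beta_lambda_hf"] * data.hf_std[data.obs_station]
        + state["beta_lambda_effort"] * data.obs_effort_std
        + state["omega_lambda"][data.obs_station]
        + state["epsilon_lambda"]
    )
    eta = np.minimum(eta, _ETA_GUARD)  # proposals this extreme are rejected anyway
    return data.counts * eta - np.exp(eta)


class _AbundanceModel:
    names = _AB_NAMES  # epsilon draws are not stored (one value per observation)

    def __init__(self, data: AbundanceData, config: McmcConfig):
        self.data = data
        self.config = config
        entries = [("beta_lambda_hf", None), ("beta_lambda_effort", None)]
        for k in sorted(set(int(v) for v in np.unique(data.obs_region))):
            entries.append(("alpha_lambda", k))
            entries.append(("beta_lambda_trend", k))
        self.scalars = _ScalarBlocks(entries, config)
        self.om_adapt = _Adapt(
            (data.n_stations,), config.adapt_window, config.target_accept
        )
        self.eps_adapt = _Adapt(
            (len(data.counts),), config.adapt_window, config.target_accept,
            init_step=0.3,
        )

    def init_state(self, rng):
        data = self.data
        state = {
            "alpha_lambda": rng.normal(0.0, 1.0, size=3),
            "beta_lambda_trend": rng.normal(0.0, 0.1, size=3),
            "beta_lambda_hf": float(rng.normal(0.0, 1.0)),
            "beta_lambda_effort": float(rng.normal(0.0, 1.0)),
            "omega_lambda": rng.normal(0.0, 0.5, size=data.n_stations),
            "sigma_lambda_station": 1.0,
            "epsilon_lambda": rng.normal(0.0, 0.3, size=len(data.counts)),
            "sigma_lambda_noise": 1.0,
        }
        return state

    def sweep(self, state, rng, adapting):
        data = self.data
        self.scalars.sweep(
            state, lambda s: float(np.sum(_ab_loglik_vec(s, data))), rng, adapting
        )
        ll_vec = _ab_loglik_vec(state, data)
        ll_vec = _re_vector_update(
            state, "omega_lambda", "sigma_lambda_station",
            data.obs_station, data.n_stations,
            lambda s: _ab_loglik_vec(s, data), ll_vec,
            self.om_adapt, rng, adapting,
        )
        # observation-level lognormal noise: groups are the rows themselves
        _re_vector_update(
            state, "epsilon_lambda", "sigma_lambda_noise",
            None, len(data.counts),
            lambda s: _ab_loglik_vec(s, data), ll_vec,
            self.eps_adapt, rng, adapting,
        )


# ---------------------------------------------------------------------------
# Productivity (binomial) chain
# ---------------------------------------------------------------------------

_PROD_NAMES = ("alpha_p", "beta_p_trend", "beta_p_hf", "omega_p", "sigma_p")


def _prod_loglik_vec(state: dict, data: ProductivityData) -> np.ndarray:
    k = data.obs_region
    eta = (
        state["alpha_p"][k]
        + state["beta_p_trend"][k] * data.obs_t
        + state["beta_p_hf"] * data.hf_std[data.obs_station]
        + state["omega_p"][data.obs_station]
    )
    return data.juveniles * log_expit(eta) + (data.totals - data.juveniles) * log_expit(-eta)


class _ProductivityModel:
    names = _PROD_NAMES

    def __init__(self, data: ProductivityData, config: McmcConfig):
        self.data = data
        self.config = config
        entries = [("beta_p_hf", None)]
        for k in sorted(set(int(v) for v in np.unique(data.obs_region))):
            entries.append(("alpha_p", k))
            entries.append(("beta_p_trend", k))
        self.scalars = _ScalarBlocks(entries, config)
        self.om_adapt = _Adapt(
            (data.n_stations,), config.adapt_window, config.target_accept
        )

    def init_state(self, rng):
        return {
            "alpha_p": rng.normal(0.0, 1.0, size=3),
            "beta_p_trend": rng.normal(0.0, 0.1, size=3),
            "beta_p_hf": float(rng.normal(0.0, 1.0)),
            "omega_p": rng.normal(0.0, 0.5, size=self.data.n_stations),
            "sigma_p": 1.0,
        }

    def sweep(self, state, rng, adapting):
        data = self.data
        self.scalars.sweep(
            state, lambda s: float(np.sum(_prod_loglik_vec(s, data))), rng, adapting
        )
        ll_vec = _prod_loglik_vec(state, data)
        _re_vector_update(
            state, "omega_p", "sigma_p", data.obs_station, data.n_stations,
            lambda s: _prod_loglik_vec(s, data), ll_vec,
            self.om_adapt, rng, adapting,
        )


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

class _JointModel:
    """Abundance and survival sampled in one loop, sharing the iteration
    index so derived recruitment uses aligned draws."""

    def __init__(self, abundance: AbundanceData, survival: SurvivalData,
                 config: McmcConfig):
        self.parts = [
            _AbundanceModel(abundance, config),
            _SurvivalModel(survival, config),
        ]
        self.names = tuple(n for p in self.parts for n in p.names)

    def init_state(self, rng):
        state = {}
        for p in self.parts:
            state.update(p.init_state(rng))
        return state

    def sweep(self, state, rng, adapting):
        for p in self.parts:
            p.sweep(state, rng, adapting)


def _run_model_chain(model, config: McmcConfig, rng) -> dict[str, np.ndarray]:
    state = model.init_state(rng)
    storage = _storage_for(state, model.names, config)
    for it in range(config.n_iterations):
        model.sweep(state, rng, adapting=it < config.burn_in)
        slot = _keep_slot(config, it)
        if slot is not None:
            _store(storage, state, slot)
    return storage


def sample_posterior(
    model: str,
    data: ModelData | AbundanceData | ProductivityData | SurvivalData,
    config: McmcConfig,
) -> PosteriorChains:
    """Sample the posterior of one of the three field models.

    ``model`` is "joint" (abundance + survival in a single model, the
    configuration used for recruitment), "abundance", "survival" or
    "productivity".  ``data`` is the matching model-ready container (a
    :class:`~mapsdemog.data_io.ModelData` bundle is unpacked automatically).
    Chains are seeded from ``config.seed`` and runs are exactly
    reproducible.
    """
    def build(config):
        if model == "joint":
            bundle = data if isinstance(data, ModelData) else None
            if bundle is None or bundle.abundance is None or bundle.survival is None:
                raise ValueError("joint model needs abundance and survival data")
            return _JointModel(bundle.abundance, bundle.survival, config)
        if model == "abundance":
            d = data.abundance if isinstance(data, ModelData) else data
            return _AbundanceModel(d, config)
        if model == "survival":
            d = data.survival if isinstance(data, ModelData) else data
            return _SurvivalModel(d, config)
        if model == "productivity":
            d = data.productivity if isinstance(data, ModelData) else data
            return _ProductivityModel(d, config)
        raise ValueError(f"unknown model {model!r}")

    chains: list[dict[str, np.ndarray]] = []
    for rng in _chain_rngs(config):
        m = build(config)
        chains.append(_run_model_chain(m, config, rng))
    names = chains[0].keys()
    return PosteriorChains(
        {name: np.stack([c[name] for c in chains], axis=0) for name in names}
    )


def sample_generic(
    logpost: Callable[[dict[str, float]], float],
    init: dict[str, float],
    config: McmcConfig,
) -> PosteriorChains:
    """Adaptive scalar Metropolis for an arbitrary log-posterior.

    Used for reduced validation models (conjugate toys, simulation-based
    calibration); parameters are unconstrained scalars, priors must be part
    of ``logpost``.
    """
    names = list(init)
    chain_draws = []
    for rng in _chain_rngs(config):
        state = {k: float(v) for k, v in init.items()}
        adapt = _Adapt((len(names),), config.adapt_window, config.target_accept,
                       init_step=1.0)
        cur_lp = logpost(state)
        if not np.isfinite(cur_lp):
            raise ValueError("log-posterior not finite at the initial values")
        storage = {k: np.empty(config.retained_per_chain) for k in names}
        for it in range(config.n_iterations):
            accepted = np.zeros(len(names))
            steps = adapt.step
            for bi, name in enumerate(names):
                cur = state[name]
                state[name] = cur + steps[bi] * rng.normal()
                new_lp = logpost(state)
                if np.log(rng.random()) < new_lp - cur_lp:
                    cur_lp = new_lp
                    accepted[bi] = 1.0
                else:
                    state[name] = cur
            adapt.record(accepted, adapting=it < config.burn_in)
            slot = _keep_slot(config, it)
            if slot is not None:
                for k in names:
                    storage[k][slot] = state[k]
        chain_draws.append(storage)
    return PosteriorChains(
        {k: np.stack([c[k] for c in chain_draws], axis=0) for k in names}
    )
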
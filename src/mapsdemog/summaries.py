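"""Derived quantities and reporting.

From the joint posterior of the count and survival models this module
derives a region-level breeding-density index N_{k,t}, the recruitment
series

    rec_{k,t+1} = N_{k,t+1} - N_{k,t} * phi_{k,t}

(an identity applied draw by draw, so uncertainty propagates exactly),
per-draw log-linear recruitment trends, percent-per-year conversions of
trend coefficients, and the standard report tables: survival/residency by
region and sex, covariate effects with the posterior mass below zero, and
the trend table for density, productivity, survival and recruitment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import REGIONS, AbundanceData, ModelData, SurvivalData
from .inference import PosteriorChains, hpd_interval, prob_mass_below_zero


def centered_years(n_years: int) -> np.ndarray:
    """Year covariate values 0..n_years-1 centered at the study midpoint."""
    return np.arange(n_years, dtype=float) - (n_years - 1) / 2.0


def percent_per_year(coefficient: float) -> float:
    """Annual percent change implied by a per-year log-linear coefficient."""
    return 100.0 * float(np.expm1(coefficient))


@dataclass(frozen=True)
class TrendSummary:
    """Posterior summary of one trend coefficient."""

    parameter: str
    mean: float
    hpd_low: float
    hpd_high: float
    percent_per_year: float
    prob_decline: float


def trend_summary(draws: np.ndarray, name: str, mass: float = 0.90) -> TrendSummary:
    lo, hi = hpd_interval(draws, mass)
    mean = float(np.mean(draws))
    return TrendSummary(
        parameter=name,
        mean=mean,
        hpd_low=lo,
        hpd_high=hi,
        percent_per_year=percent_per_year(mean),
        prob_decline=prob_mass_below_zero(draws),
    )


# ---------------------------------------------------------------------------
# Regional index, survival and recruitment
# ---------------------------------------------------------------------------

def regional_index(
    chains: PosteriorChains,
    data: AbundanceData,
    region: int | str,
    t_values: np.ndarray,
) -> np.ndarray:
    """Per-draw region-level density index N_{k,t}, shape (n_draws, T).

    N is the sum over the region's stations of the expected count at mean
    effort with the observation-level noise set to zero:
    sum_s exp(alpha_k + beta_trend_k * t + beta_hf * HF_s + omega_s).
    Mean effort has a standardized value of 0, so the effort term drops.
    """
    k = REGIONS.index(region) if isinstance(region, str) else int(region)
    members = np.flatnonzero(data.region_idx == k)
    if len(members) == 0:
        raise ValueError(f"region {REGIONS[k]!r} has no stations")
    alpha = chains.pooled("alpha_lambda")[:, k]          # (D,)
    btrend = chains.pooled("beta_lambda_trend")[:, k]
    bhf = chains.pooled("beta_lambda_hf")                # (D,)
    omega = chains.pooled("omega_lambda")[:, members]    # (D, Sk)
    station_sum = np.exp(
        bhf[:, None] * data.hf_std[members][None, :] + omega
    ).sum(axis=1)                                        # (D,)
    t_values = np.asarray(t_values, dtype=float)
    return np.exp(alpha[:, None] + btrend[:, None] * t_values[None, :]) * station_sum[:, None]


def regional_survival(
    chains: PosteriorChains,
    data: SurvivalData,
    region: int | str,
    t_values: np.ndarray,
) -> np.ndarray:
    """Per-draw sex-averaged regional survival phi_{k,t}, shape (n_draws, T-1).

    Evaluated at the region's mean standardized footprint with station
    effects at zero; male and female survival get equal weight.  The value
    at interval t -> t+1 uses the trend covariate at t.
    """
    k = REGIONS.index(region) if isinstance(region, str) else int(region)
    members = np.flatnonzero(data.region_idx == k)
    if len(members) == 0:
        raise ValueError(f"region {REGIONS[k]!r} has no stations")
    hf_bar = float(np.mean(data.hf_std[members]))
    mu = chains.pooled("mu_phi")
    breg = chains.pooled("beta_phi_region")[:, k]
    bsex = chains.pooled("beta_phi_sex")
    bhf = chains.pooled("beta_phi_hf")
    btrend = chains.pooled("beta_phi_trend")[:, k]
    t_int = np.asarray(t_values, dtype=float)[:-1]
    base = mu + breg + bhf * hf_bar
    eta = base[:, None] + btrend[:, None] * t_int[None, :]
    return 0.5 * (expit(eta) + expit(eta + bsex[:, None]))


def recruitment_series(n_draws: np.ndarray, phi_draws: np.ndarray) -> np.ndarray:
    """rec_{k,t+1} = N_{k,t+1} - N_{k,t} * phi_{k,t}, applied per draw.

    ``n_draws`` is (D, T), ``phi_draws`` (D, T-1); returns (D, T-1).
    Values can be negative (losses exceeding replacement); they are kept in
    the series and handled at the trend-fitting stage.
    """
    N = np.asarray(n_draws, dtype=float)
    phi = np.asarray(phi_draws, dtype=float)
    if N.ndim != 2 or phi.shape != (N.shape[0], N.shape[1] - 1):
        raise ValueError("misaligned draw matrices: need N (D, T), phi (D, T-1)")
    return N[:, 1:] - N[:, :-1] * phi


def recruitment_trend(
    rec_draws: np.ndarray, t_values: np.ndarray
) -> tuple[np.ndarray, int]:
    """Per-draw least-squares slope of log(recruitment) on year.

    Only years with positive recruitment enter each draw's fit; draws with
    fewer than 3 positive years are excluded.  Returns (slopes, n_excluded).
    """
    rec = np.asarray(rec_draws, dtype=float)
    x = np.broadcast_to(np.asarray(t_values, dtype=float), rec.shape)
    if rec.shape[1] < 3:
        raise ValueError("need at least 3 years for a recruitment trend")
    w = (rec > 0).astype(float)
    n_pos = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(rec > 0, np.log(np.where(rec > 0, rec, 1.0)), 0.0)
        xb = (w * x).sum(axis=1) / n_pos
        yb = (w * y).sum(axis=1) / n_pos
        dx = x - xb[:, None]
        sxx = (w * dx * dx).sum(axis=1)
        sxy = (w * dx * (y - yb[:, None])).sum(axis=1)
        slope = sxy / sxx
    valid = (n_pos >= 3) & (sxx > 0)
    if not np.any(valid):
        raise ValueError("all draws excluded from the recruitment trend fit")
    return slope[valid], int(np.sum(~valid))


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _prob_table_row(draws, label, mass):
    lo, hi = hpd_interval(draws, mass)
    return {
        "parameter": label,
        "mean": float(np.mean(draws)),
        f"hpd{int(mass*100)}_low": lo,
        f"hpd{int(mass*100)}_high": hi,
        "prob_below_zero": prob_mass_below_zero(draws),
    }


def survival_residency_table(
    chains: PosteriorChains, mass: float = 0.90
) -> pd.DataFrame:
    """Mean apparent survival and residency by region and sex.

    Probabilities are evaluated draw by draw at mean footprint, the study
    mid-year and a typical station (random effects zero), then summarized.
    """
    mu = chains.pooled("mu_phi")
    breg_phi = chains.pooled("beta_phi_region")
    bsex_phi = chains.pooled("beta_phi_sex")
    a_pi = chains.pooled("alpha_pi")
    breg_pi = chains.pooled("beta_pi_region")
    bsex_pi = chains.pooled("beta_pi_sex")
    rows = []
    for k, region in enumerate(REGIONS):
        for sex, sex_name in ((0, "female"), (1, "male")):
            phi = expit(mu + breg_phi[:, k] + bsex_phi * sex)
            pi = expit(a_pi + breg_pi[:, k] + bsex_pi * sex)
            phi_lo, phi_hi = hpd_interval(phi, mass)
            pi_lo, pi_hi = hpd_interval(pi, mass)
            rows.append(
                {
                    "region": region,
                    "sex": sex_name,
                    "phi_mean": float(phi.mean()),
                    "phi_hpd_low": phi_lo,
                    "phi_hpd_high": phi_hi,
                    "pi_mean": float(pi.mean()),
                    "pi_hpd_low": pi_lo,
                    "pi_hpd_high": pi_hi,
                }
            )
    return pd.DataFrame(rows)


def covariate_effect_table(
    joint_chains: PosteriorChains | None,
    productivity_chains: PosteriorChains | None,
    mass: float = 0.90,
) -> pd.DataFrame:
    """Footprint effects on density, productivity, survival and residency."""
    rows = []
    if joint_chains is not None:
        if "beta_lambda_hf" in joint_chains.names:
            rows.append(_prob_table_row(
                joint_chains.pooled("beta_lambda_hf"), "breeding_density_hf", mass))
        rows.append(_prob_table_row(
            joint_chains.pooled("beta_phi_hf"), "apparent_survival_hf", mass))
        rows.append(_prob_table_row(
            joint_chains.pooled("beta_pi_hf"), "residency_hf", mass))
    if productivity_chains is not None:
        rows.append(_prob_table_row(
            productivity_chains.pooled("beta_p_hf"), "productivity_hf", mass))
    return pd.DataFrame(rows)


def trend_table(
    joint_chains: PosteriorChains | None,
    productivity_chains: PosteriorChains | None,
    model_data: ModelData | None = None,
    t_values: np.ndarray | None = None,
    mass: float = 0.90,
) -> pd.DataFrame:
    """Per-region trend summaries for density, productivity, survival and
    (when the joint model and data are available) derived recruitment."""
    rows: list[dict] = []

    def add(draws, rate, region):
        s = trend_summary(draws, f"{rate}_{region}", mass)
        row = asdict(s)
        row["rate"], row["region"] = rate, region
        rows.append(row)

    for k, region in enumerate(REGIONS):
        if joint_chains is not None:
            if "beta_lambda_trend" in joint_chains.names:
                add(joint_chains.pooled("beta_lambda_trend")[:, k],
                    "breeding_density", region)
            add(joint_chains.pooled("beta_phi_trend")[:, k],
                "apparent_survival", region)
        if productivity_chains is not None:
            add(productivity_chains.pooled("beta_p_trend")[:, k],
                "productivity", region)
        if (
            joint_chains is not None
            and model_data is not None
            and model_data.abundance is not None
            and model_data.survival is not None
            and t_values is not None
            and k in set(model_data.abundance.region_idx.tolist())
        ):
            N = regional_index(joint_chains, model_data.abundance, k, t_values)
            phi = regional_survival(joint_chains, model_data.survival, k, t_values)
            rec = recruitment_series(N, phi)
            slopes, n_excl = recruitment_trend(rec, t_values[1:])
            s = trend_summary(slopes, f"recruitment_{region}", mass)
            row = asdict(s)
            row["rate"], row["region"] = "recruitment", region
            row["n_draws_excluded"] = n_excl
            rows.append(row)
    return pd.DataFrame(rows)


def make_report(
    joint_chains: PosteriorChains | None,
    productivity_chains: PosteriorChains | None,
    model_data: ModelData | None = None,
    t_values: np.ndarray | None = None,
    mass: float = 0.90,
) -> dict:
    """Assemble the report tables; missing inputs leave explicit gaps."""
    report: dict = {"gaps": []}
    if joint_chains is not None:
        report["survival_residency"] = survival_residency_table(joint_chains, mass)
    else:
        report["gaps"].append("survival_residency: no joint chains")
    effects = covariate_effect_table(joint_chains, productivity_chains, mass)
    if len(effects):
        report["covariate_effects"] = effects
    else:
        report["gaps"].append("covariate_effects: no chains provided")
    trends = trend_table(joint_chains, productivity_chains, model_data, t_values, mass)
    if len(trends):
        report["trends"] = trends
        if joint_chains is not None and not (trends["rate"] == "recruitment").any():
            report["gaps"].append("recruitment: joint chains or model data absent")
    else:
        report["gaps"].append("trends: no chains provided")
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    """Write each table as CSV plus a combined JSON; byte-stable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = {"gaps": report.get("gaps", [])}
    for key, value in report.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(outdir / f"{key}.csv", index=False, float_format="%.10g")
            combined[key] = json.loads(value.to_json(orient="records"))
    with open(outdir / "report.json", "w") as fh:
        json.dump(combined, fh, indent=2, sort_keys=True)


def plot_trend_coefficients(trends: pd.DataFrame, path: str | Path) -> None:
    """Dot-and-interval figure of annual trend coefficients by rate and region."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rates = list(dict.fromkeys(trends["rate"]))
    fig, axes = plt.subplots(1, len(rates), figsize=(3.2 * len(rates), 3.4),
                             sharey=False)
    if len(rates) == 1:
        axes = [axes]
    for ax, rate in zip(axes, rates):
        sub = trends[trends["rate"] == rate]
        xs = np.arange(len(sub))
        ax.errorbar(
            xs, sub["mean"],
            yerr=[sub["mean"] - sub["hpd_low"], sub["hpd_high"] - sub["mean"]],
            fmt="o", capsize=3,
        )
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks(xs, sub["region"], rotation=45)
        ax.set_title(rate.replace("_", " "))
        ax.set_ylabel("trend coefficient (per year)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
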
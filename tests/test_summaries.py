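"""Derived recruitment, trend conversion and report assembly."""

import numpy as np
import pytest
from scipy.special import logit

from mapsdemog import data_io, synthetic_data as sd
from mapsdemog.inference import PosteriorChains
from mapsdemog.summaries import (
    centered_years,
    make_report,
    percent_per_year,
    recruitment_series,
    recruitment_trend,
    regional_index,
    regional_survival,
    trend_summary,
    write_report,
)


class TestPercentPerYear:
    def test_reference_points(self):
        assert percent_per_year(0.0) == 0.0
        assert percent_per_year(np.log(0.9)) == pytest.approx(-10.0)
        assert percent_per_year(-0.0475) == pytest.approx(-4.64, abs=5e-3)

    def test_strictly_increasing(self, rng):
        betas = np.sort(rng.normal(scale=0.1, size=20))
        vals = [percent_per_year(b) for b in betas]
        assert all(b > a for a, b in zip(vals, vals[1:]))


def _fake_chains(rng, n_stations, n_chains=2, n_draws=600, **overrides):
    S = n_stations
    c, d = n_chains, n_draws
    draws = {
        "alpha_lambda": np.zeros((c, d, 3)),
        "beta_lambda_trend": np.zeros((c, d, 3)),
        "beta_lambda_hf": np.zeros((c, d)),
        "beta_lambda_effort": np.zeros((c, d)),
        "omega_lambda": np.zeros((c, d, S)),
        "sigma_lambda_station": np.full((c, d), 0.1),
        "sigma_lambda_noise": np.full((c, d), 0.1),
        "mu_phi": np.zeros((c, d)),
        "beta_phi_region": np.zeros((c, d, 3)),
        "beta_phi_sex": np.zeros((c, d)),
        "beta_phi_hf": np.zeros((c, d)),
        "beta_phi_trend": np.zeros((c, d, 3)),
        "omega_phi": np.zeros((c, d, S)),
        "sigma_phi": np.full((c, d), 0.1),
        "alpha_pi": np.zeros((c, d)),
        "beta_pi_region": np.zeros((c, d, 3)),
        "beta_pi_sex": np.zeros((c, d)),
        "beta_pi_hf": np.zeros((c, d)),
        "omega_pi": np.zeros((c, d, S)),
        "sigma_pi": np.full((c, d), 0.1),
        "pr_intercept": np.zeros((c, d)),
        "pr_sex": np.zeros((c, d)),
        "omega_pr": np.zeros((c, d, S)),
        "sigma_pr": np.full((c, d), 0.1),
        "rho_intercept": np.zeros((c, d)),
        "rho_sex": np.zeros((c, d)),
        "omega_rho": np.zeros((c, d, S)),
        "sigma_rho": np.full((c, d), 0.1),
    }
    for k, v in overrides.items():
        draws[k] = v
    # tiny jitter so interval widths are positive without changing means much
    for k, a in draws.items():
        if k not in overrides:
            draws[k] = a + rng.normal(scale=1e-9, size=a.shape)
    return PosteriorChains(draws)


@pytest.fixture(scope="module")
def small_data():
    sc = sd.SimulationScenario(
        n_stations_per_region=(2, 2, 2), n_years=8, full_activity=True,
        new_individuals_rate=2.0, seed=8,
    )
    ds = sd.simulate_dataset(sc)
    return data_io.standardize_covariates(
        ds.stations, ds.counts, ds.productivity, ds.histories, n_years=8
    )


class TestRegionalIndex:
    def test_all_zero_params_counts_stations(self, small_data, rng):
        a = small_data.abundance
        ch = _fake_chains(rng, a.n_stations)
        t = centered_years(8)
        # with all parameters 0 except the (nonzero) footprint z-scores,
        # setting beta_hf = 0 gives exp(0) per station: N = number of stations
        N = regional_index(ch, a, "west", t)
        np.testing.assert_allclose(N, 2.0, atol=1e-6)

    def test_doubling_stations_doubles_index(self, rng):
        sc2 = sd.SimulationScenario(
            n_stations_per_region=(4, 0, 0), n_years=4, full_activity=True,
            new_individuals_rate=1.0, seed=9,
        )
        ds = sd.simulate_dataset(sc2)
        md = data_io.standardize_covariates(ds.stations, ds.counts, n_years=4)
        a = md.abundance
        a.hf_std[:] = 0.0  # identical covariates
        ch = _fake_chains(rng, 4)
        t = centered_years(4)
        full = regional_index(ch, a, 0, t)
        a2 = data_io.AbundanceData(
            station_ids=a.station_ids[:2], region_idx=a.region_idx[:2],
            hf_std=a.hf_std[:2], obs_station=a.obs_station,
            obs_t=a.obs_t, obs_effort_std=a.obs_effort_std, counts=a.counts,
            scaling=a.scaling,
        )
        ch2 = _fake_chains(np.random.default_rng(1), 2)
        half = regional_index(ch2, a2, 0, t)
        np.testing.assert_allclose(full, 2 * half, atol=1e-6)

    def test_trend_ratio_over_ten_years(self, small_data, rng):
        a = small_data.abundance
        c, d = 2, 600
        bt = np.full((c, d, 3), np.log(0.9))
        ch = _fake_chains(rng, a.n_stations, beta_lambda_trend=bt)
        t = np.array([0.0, 10.0])
        N = regional_index(ch, a, "east", t)
        np.testing.assert_allclose(N[:, 1] / N[:, 0], 0.9**10, rtol=1e-10)

    def test_empty_region_rejected(self, rng):
        sc2 = sd.SimulationScenario(
            n_stations_per_region=(2, 0, 2), n_years=4, full_activity=True,
            new_individuals_rate=1.0, seed=9,
        )
        ds = sd.simulate_dataset(sc2)
        md = data_io.standardize_covariates(ds.stations, ds.counts, n_years=4)
        ch = _fake_chains(rng, 4)
        with pytest.raises(ValueError, match="no stations"):
            regional_index(ch, md.abundance, "central", centered_years(4))


class TestRecruitment:
    def test_identity_cases(self):
        N = np.full((3, 5), 100.0)
        phi = np.ones((3, 4))
        np.testing.assert_allclose(recruitment_series(N, phi), 0.0)
        N2 = np.array([[100.0, 90.0]])
        phi2 = np.array([[0.5]])
        assert recruitment_series(N2, phi2)[0, 0] == pytest.approx(40.0)

    def test_negative_when_decline_outpaces_survival(self):
        N = np.array([[100.0, 50.0]])
        phi = np.array([[0.9]])
        assert recruitment_series(N, phi)[0, 0] < 0

    def test_identity_holds_per_draw_exactly(self, rng):
        N = np.exp(rng.normal(size=(200, 10)))
        phi = 1 / (1 + np.exp(-rng.normal(size=(200, 9))))
        rec = recruitment_series(N, phi)
        np.testing.assert_allclose(rec, N[:, 1:] - N[:, :-1] * phi, atol=1e-12)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            recruitment_series(np.ones((2, 5)), np.ones((2, 5)))

    def test_geometric_series_recovers_log_ratio_exactly(self):
        t = np.arange(1.0, 11.0)
        rec = 100.0 * 0.9 ** np.arange(10.0)
        slopes, n_excl = recruitment_trend(np.tile(rec, (4, 1)), t)
        np.testing.assert_allclose(slopes, np.log(0.9), atol=1e-12)
        assert n_excl == 0

    def test_constant_series_zero_slope(self):
        slopes, _ = recruitment_trend(np.full((3, 6), 5.0), np.arange(6.0))
        np.testing.assert_allclose(slopes, 0.0, atol=1e-14)

    def test_matches_normal_equations_oracle(self, rng):
        rec = np.exp(rng.normal(size=(50, 12)))
        rec[rec < 0.5] = -1.0  # sprinkle non-positive years
        t = np.arange(12.0)
        slopes, n_excl = recruitment_trend(rec, t)
        expected = []
        for row in rec:
            m = row > 0
            if m.sum() < 3:
                continue
            x, y = t[m], np.log(row[m])
            b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
            expected.append(b)
        np.testing.assert_allclose(slopes, expected, atol=1e-10)
        assert n_excl == 50 - len(expected)

    def test_all_draws_excluded_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            recruitment_trend(-np.ones((5, 6)), np.arange(6.0))


class TestTrendSummary:
    def test_percent_consistent_with_mean(self, rng):
        draws = rng.normal(-0.05, 0.01, size=2000)
        s = trend_summary(draws, "x")
        assert s.percent_per_year == pytest.approx(
            100 * (np.exp(s.mean) - 1), abs=1e-12
        )
        assert s.hpd_low < s.mean < s.hpd_high
        assert s.prob_decline == pytest.approx(1.0)


class TestReport:
    def test_report_sections_and_gaps(self, small_data, rng):
        S = small_data.abundance.n_stations
        joint = _fake_chains(rng, S)
        report = make_report(joint, None, small_data, centered_years(8))
        assert set(report) >= {"survival_residency", "covariate_effects", "trends"}
        assert len(report["survival_residency"]) == 6
        assert (report["trends"]["rate"] == "recruitment").sum() == 3
        missing = make_report(None, None)
        assert any("survival_residency" in g for g in missing["gaps"])

    def test_report_regeneration_byte_identical(self, small_data, rng, tmp_path):
        joint = _fake_chains(rng, small_data.abundance.n_stations)
        report = make_report(joint, None, small_data, centered_years(8))
        write_report(report, tmp_path / "a")
        report2 = make_report(joint, None, small_data, centered_years(8))
        write_report(report2, tmp_path / "b")
        for name in ("report.json", "trends.csv", "survival_residency.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_survival_table_transforms_probabilities(self, rng, small_data):
        c, d = 2, 600
        mu = np.full((c, d), float(logit(0.31)))
        bsex = np.full((c, d), 0.58)
        joint = _fake_chains(rng, small_data.abundance.n_stations,
                             mu_phi=mu, beta_phi_sex=bsex)
        tab = make_report(joint, None)["survival_residency"]
        wf = tab[(tab.region == "west") & (tab.sex == "female")].iloc[0]
        wm = tab[(tab.region == "west") & (tab.sex == "male")].iloc[0]
        assert wf.phi_mean == pytest.approx(0.31, abs=1e-6)
        assert wm.phi_mean == pytest.approx(0.446, abs=1e-3)
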
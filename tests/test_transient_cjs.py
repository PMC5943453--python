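"""Transient CJS likelihood: closed-form cases, brute-force enumeration over
latent states, normalization, the standard-CJS limit and monotonicity."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from mapsdemog.data_io import (
    CaptureHistory,
    build_survival_data,
    CovariateScaling,
)
from mapsdemog.transient_cjs import (
    SurvivalParams,
    chi_never_seen,
    dataset_loglik,
    history_likelihood,
    history_likelihoods,
    history_logliks,
    logit_predictors,
)

from conftest import make_history


def flat_params(phi=0.5, pi=0.5, pr=0.5, rho=0.5, **kw):
    """Parameters with no covariate structure and given probabilities."""
    return SurvivalParams(
        mu_phi=float(logit(phi)),
        alpha_pi=float(logit(pi)),
        pr_intercept=float(logit(pr)),
        rho_intercept=float(logit(rho)),
        **kw,
    )


def random_params(rng, n_stations=2):
    g = rng.normal
    return SurvivalParams(
        mu_phi=g(), beta_phi_region=np.array([0.0, g(), g()]),
        beta_phi_sex=g(), beta_phi_hf=g() * 0.5,
        beta_phi_trend=g(size=3) * 0.1,
        omega_phi=g(size=n_stations) * 0.5, sigma_phi=0.5,
        alpha_pi=g(), beta_pi_region=np.array([0.0, g(), g()]),
        beta_pi_sex=g(), beta_pi_hf=g() * 0.5,
        omega_pi=g(size=n_stations) * 0.5, sigma_pi=0.5,
        pr_intercept=g(), pr_sex=g(),
        omega_pr=g(size=n_stations) * 0.5, sigma_pr=0.5,
        rho_intercept=g(), rho_sex=g(),
        omega_rho=g(size=n_stations) * 0.5, sigma_rho=0.5,
    )


def brute_force_history_prob(history, phi_seq, pi, pr, rho):
    """Sum over latent residency and survival trajectories.

    ``phi_seq[t]`` is survival over interval t -> t+1.  A transient
    contributes only to the all-zero post-first history and can never be
    pre-determined.  Residents are enumerated over the last occasion at
    which they are alive.
    """
    y = history.detections
    T = len(y)
    f, d = history.first_year, history.predetermined
    total = 0.0
    if d == 0 and not any(y[f + 1:]):
        total += 1.0 - pi  # transient branch
    for last_alive in range(f, T):
        p_path = pi * (rho if d == 1 else 1.0 - rho)
        for t in range(f, last_alive):          # survived these intervals
            p_path *= phi_seq[t]
        if last_alive < T - 1:                  # died in the next interval
            p_path *= 1.0 - phi_seq[last_alive]
        ok = True
        for t in range(f + 1, T):               # detection outcomes
            if t <= last_alive:
                p_path *= pr if y[t] else 1.0 - pr
            elif y[t]:
                ok = False                      # detected while dead
                break
        if ok:
            total += p_path
    return total


class TestLogitPredictors:
    def test_all_zero_gives_half(self):
        p = SurvivalParams()
        assert logit_predictors(p, region=0, sex=0) == (0.5, 0.5, 0.5, 0.5)

    def test_reference_region_male_survival(self):
        p = flat_params(phi=0.45)
        phi, _, _, _ = logit_predictors(p, region="west", sex=0)
        assert phi == pytest.approx(0.45, abs=1e-12)

    def test_sex_effect_on_logit_scale(self):
        p = SurvivalParams(mu_phi=float(logit(0.31)), beta_phi_sex=0.58)
        phi, _, _, _ = logit_predictors(p, region=0, sex=1)
        assert phi == pytest.approx(float(expit(logit(0.31) + 0.58)), abs=1e-12)
        assert phi == pytest.approx(0.446, abs=5e-3)

    def test_unknown_region_rejected(self):
        with pytest.raises((ValueError, KeyError)):
            logit_predictors(SurvivalParams(), region=7, sex=0)


class TestChiRecursion:
    def test_dead_individuals_never_seen(self):
        chi = chi_never_seen([0.0, 0.0, 0.0], [0.5, 0.5, 0.5])
        np.testing.assert_allclose(chi, 1.0)

    def test_certain_detection(self):
        chi = chi_never_seen([1.0, 1.0], [1.0, 1.0])
        np.testing.assert_allclose(chi[:-1], 0.0)
        assert chi[-1] == 1.0

    def test_two_remaining_occasions(self):
        chi = chi_never_seen([0.5, 0.5], [0.5, 0.5])
        assert chi[0] == pytest.approx(0.5 + 0.25 * 0.75, abs=1e-15)  # 0.6875

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi_never_seen([0.5, 0.5], [0.5])

    def test_monotone_in_phi_and_pr(self):
        base = chi_never_seen([0.5] * 4, [0.5] * 4)
        higher_phi = chi_never_seen([0.7] * 4, [0.5] * 4)
        higher_pr = chi_never_seen([0.5] * 4, [0.7] * 4)
        assert np.all(higher_phi <= base + 1e-15)
        assert np.all(higher_pr <= base + 1e-15)


class TestHistoryLikelihood:
    def test_single_occasion_study_carries_only_the_flag(self):
        # With one occasion the detection record is uninformative; the only
        # data term left is the pre-determination flag: P(d=0) = 1 - pi*rho.
        h = CaptureHistory("i", "s", 0, 0, (1,), 0)
        p = flat_params()
        assert history_likelihood(h, None, p, region=0) == pytest.approx(0.75)
        h1 = CaptureHistory("i", "s", 0, 0, (1,), 1)
        assert history_likelihood(h1, None, p, region=0) == pytest.approx(0.25)

    def test_seen_both_years_predetermined(self):
        # pi = rho = 1: likelihood is phi * pr = 0.25
        h = make_history([1, 1], predetermined=1)
        p = flat_params(pi=1 - 1e-14, rho=1 - 1e-14)
        assert history_likelihood(h, None, p, region=0) == pytest.approx(0.25, abs=1e-9)

    def test_never_seen_again_mixture_value(self):
        # (1,0,0), d=0, phi=pr=0.5, pi=0.6, rho=0.5:
        # (1-pi) + pi(1-rho)*chi = 0.4 + 0.3*0.6875 = 0.60625
        h = make_history([1, 0, 0])
        p = flat_params(pi=0.6)
        assert history_likelihood(h, None, p, region=0) == pytest.approx(
            0.60625, abs=1e-12
        )

    def test_impossible_event_returns_zero(self):
        # detection after first year with pi = 0 is impossible, not an error
        h = make_history([1, 1])
        p = flat_params(pi=1e-300)
        assert history_likelihood(h, None, p, region=0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("pattern, d", [
        ((1, 0, 1, 0), 0), ((1, 1, 0, 0), 1), ((1, 0, 0, 0), 0),
        ((0, 1, 0, 1), 0), ((1, 1, 1, 1), 1),
    ])
    def test_matches_brute_force_enumeration(self, pattern, d, rng):
        h = make_history(pattern, predetermined=d)
        phi, pi, pr, rho = 0.62, 0.71, 0.44, 0.3
        p = flat_params(phi=phi, pi=pi, pr=pr, rho=rho)
        expected = brute_force_history_prob(h, [phi] * 3, pi, pr, rho)
        got = history_likelihood(h, None, p, region=0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_pr_for_all_ones_history(self):
        h = make_history([1, 1, 1], predetermined=1)
        liks = [
            history_likelihood(h, None, flat_params(pr=pr), region=0)
            for pr in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(b >= a for a, b in zip(liks, liks[1:]))


def _survival_data(histories, params_stations=2, t_std=None, hf=(0.0, 0.0)):
    T = len(histories[0].detections)
    scaling = CovariateScaling(0, 1, 0, 1, (T - 1) / 2)
    return build_survival_data(
        histories, ["W01", "W02"], np.array([0, 0]), np.array(hf), T, 0, scaling
    )


class TestNormalization:
    @pytest.mark.parametrize("T", [2, 3, 4, 5])
    def test_outcome_probabilities_sum_to_one(self, T, rng):
        for _ in range(25):
            p = random_params(rng)
            f = int(rng.integers(0, T))
            sex = int(rng.integers(2))
            region = int(rng.integers(3))
            hf = float(rng.normal())
            si = int(rng.integers(2))
            total = 0.0
            for tail in itertools.product([0, 1], repeat=T - 1 - f):
                y = [0] * T
                y[f] = 1
                for j, v in enumerate(tail):
                    y[f + 1 + j] = v
                for d in (0, 1):
                    h = CaptureHistory("i", "s", sex, f, tuple(y), d)
                    total += history_likelihood(
                        h, None, p, hf_std=hf, station_index=si, region=region
                    )
            assert total == pytest.approx(1.0, abs=1e-10)


class TestStandardCjsLimit:
    def test_reduces_to_textbook_cjs(self, rng):
        """With pi = 1, rho = 0 the mixture is the plain CJS likelihood."""

        def textbook_cjs(y, phi, p_cap):
            f = y.index(1)
            last = max(t for t, v in enumerate(y) if v)
            T = len(y)
            lik = 1.0
            for t in range(f, last):
                lik *= phi
                lik *= p_cap if y[t + 1] else 1.0 - p_cap
            chi = 1.0
            for _ in range(T - 1 - last):
                chi = (1.0 - phi) + phi * (1.0 - p_cap) * chi
            return lik * chi

        T = 6
        phi, p_cap = 0.55, 0.4
        params = flat_params(phi=phi, pi=1 - 1e-14, pr=p_cap, rho=1e-300)
        n_checked = 0
        for _ in range(1000):
            f = int(rng.integers(0, T))
            y = [0] * T
            y[f] = 1
            alive_tail = rng.random(T - 1 - f) < 0.5
            for j, v in enumerate(alive_tail):
                y[f + 1 + j] = int(v)
            h = CaptureHistory("i", "s", 0, f, tuple(y), 0)
            got = history_likelihood(h, None, params, region=0)
            assert got == pytest.approx(textbook_cjs(y, phi, p_cap), abs=1e-12)
            n_checked += 1
        assert n_checked == 1000


class TestDatasetLoglik:
    def test_empty_dataset_is_zero(self):
        data = _survival_data([make_history([1, 0, 0])])
        data.ind_station = data.ind_station[:0]
        data.ind_sex = data.ind_sex[:0]
        data.first = data.first[:0]
        data.last = data.last[:0]
        data.predetermined = data.predetermined[:0]
        data.n_redetect = data.n_redetect[:0]
        data.n_miss = data.n_miss[:0]
        data.int_mask = data.int_mask[:0]
        data.ind_ids = []
        assert dataset_loglik(SurvivalParams(), data) == 0.0

    def test_duplicate_dataset_doubles_loglik(self, rng):
        hists = [
            make_history([1, 0, 1, 0], individual_id="a"),
            make_history([1, 1, 0, 0], individual_id="b", predetermined=1),
        ]
        p = random_params(rng)
        single = dataset_loglik(p, _survival_data(hists))
        double = dataset_loglik(p, _survival_data(hists + [
            make_history([1, 0, 1, 0], individual_id="c"),
            make_history([1, 1, 0, 0], individual_id="d", predetermined=1),
        ]))
        assert double == pytest.approx(2 * single, abs=1e-10)

    def test_vectorized_equals_scalar_loop(self, rng):
        hists = []
        T = 5
        for i in range(50):
            f = int(rng.integers(0, T))
            y = [0] * T
            y[f] = 1
            for t in range(f + 1, T):
                y[t] = int(rng.random() < 0.4)
            d = int(rng.random() < 0.3) if True else 0
            hists.append(
                CaptureHistory(f"i{i}", "W01" if i % 2 else "W02",
                               int(rng.integers(2)), f, tuple(y), d)
            )
        data = _survival_data(hists, hf=(0.3, -0.3))
        p = random_params(rng)
        vec = history_logliks(p, data)
        for i, h in enumerate(hists):
            si = int(data.ind_station[i])
            scalar = history_likelihood(
                h, None, p, t_std=data.t_std, hf_std=float(data.hf_std[si]),
                station_index=si, region=int(data.region_idx[si]),
            )
            assert np.exp(vec[i]) == pytest.approx(scalar, abs=1e-12)

    def test_sum_of_logs_consistency(self, rng):
        hists = [
            make_history([1, 0, 1], individual_id="a"),
            make_history([1, 1, 1], individual_id="b", predetermined=1),
        ]
        data = _survival_data(hists)
        p = random_params(rng)
        liks = history_likelihoods(p, data)
        assert dataset_loglik(p, data) == pytest.approx(
            float(np.sum(np.log(liks))), abs=1e-10
        )


from hypothesis import given, settings, strategies as st

probs = st.floats(min_value=0.01, max_value=0.99)


class TestPropertyBased:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(phi=probs, pr=probs, m=st.integers(min_value=1, max_value=8))
    def test_chi_is_a_probability_and_decreasing_toward_the_present(
        self, phi, pr, m
    ):
        chi = chi_never_seen([phi] * m, [pr] * m)
        assert np.all((chi >= 0.0) & (chi <= 1.0 + 1e-12))
        # more remaining occasions -> more chances to be seen -> smaller chi
        assert np.all(np.diff(chi) >= -1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(phi=probs, pi=probs, pr=probs, rho=probs,
           data=st.data(), T=st.integers(min_value=2, max_value=5))
    def test_history_likelihood_is_a_probability(self, phi, pi, pr, rho, data, T):
        f = data.draw(st.integers(min_value=0, max_value=T - 1))
        y = [0] * T
        y[f] = 1
        for t in range(f + 1, T):
            y[t] = data.draw(st.integers(min_value=0, max_value=1))
        d = data.draw(st.integers(min_value=0, max_value=1))
        h = CaptureHistory("i", "s", 0, f, tuple(y), d)
        p = flat_params(phi=phi, pi=pi, pr=pr, rho=rho)
        lik = history_likelihood(h, None, p, region=0)
        assert 0.0 <= lik <= 1.0 + 1e-12


class TestScoreIdentity:
    def test_mean_gradient_zero_at_simulation_truth(self):
        """E[d logL / d theta] = 0 at the generating parameters (score
        identity), checked by central finite differences averaged over
        replicate simulated datasets."""
        from mapsdemog import data_io, synthetic_data as sd

        truth = flat_params(phi=0.5, pi=0.65, pr=0.45, rho=0.4)
        eps = 1e-4
        checks = {"mu_phi": [], "alpha_pi": [], "pr_intercept": []}
        for rep in range(40):
            sc = sd.SimulationScenario(
                n_stations_per_region=(2, 0, 0), n_years=6, full_activity=True,
                new_individuals_rate=10.0, seed=3000 + rep,
            )
            stations = sd.simulate_stations(sc)
            hists = sd.simulate_capture_histories(stations, truth, sc, 4000 + rep)
            data = data_io.standardize_covariates(
                stations, histories=hists, n_years=6
            ).survival
            for name in checks:
                import dataclasses
                up = dataclasses.replace(truth, **{name: getattr(truth, name) + eps})
                dn = dataclasses.replace(truth, **{name: getattr(truth, name) - eps})
                grad = (dataset_loglik(up, data) - dataset_loglik(dn, data)) / (2 * eps)
                checks[name].append(grad)
        for name, grads in checks.items():
            grads = np.asarray(grads)
            se = grads.std(ddof=1) / np.sqrt(len(grads))
            assert abs(grads.mean()) <= 3 * se, (name, grads.mean(), se)
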
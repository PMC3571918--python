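"""Attractor, correlation term (direct and series), Lyapunov machinery,
and the assembled averaged field."""

import numpy as np
import pytest

from slowfast_plasticity import (make_params, make_sinusoid_input,
                                 make_pattern_input, PeriodicInput,
                                 periodic_attractor, correlation_term_direct,
                                 correlation_family, correlation_term_series,
                                 solve_lyapunov, solve_lyapunov_series,
                                 noise_term, averaged_rhs, AveragedField,
                                 integrate_averaged, solve_equilibrium)
from slowfast_plasticity.averaged import spectral_radius

from conftest import random_admissible_W


def scalar_params(mu=1.0, sigma=0.0, rule="hebbian", **kw):
    return make_params({"rule": rule, "n": 1, "l": 1.0, "kappa": 1.0,
                        "sigma": sigma, "mu": mu, **kw})


class TestPeriodicAttractor:
    @pytest.mark.parametrize("mu", [0.3, 1.0, 2.5])
    def test_scalar_sinusoid_closed_form(self, mu, unit_sinusoid):
        # vbar(t) = (sin(mu t) - mu cos(mu t)) / (1 + mu^2) for l=1, W=0
        p = scalar_params(mu=mu)
        vbar = periodic_attractor(np.zeros((1, 1)), p, unit_sinusoid)
        t = vbar.grid
        exact = (np.sin(mu * t) - mu * np.cos(mu * t)) / (1 + mu ** 2)
        assert np.abs(vbar.samples[0] - exact).max() < 1e-12
        assert vbar.tau == pytest.approx(2 * np.pi / mu)

    def test_zero_input_zero_attractor(self, hebbian_params):
        u0 = PeriodicInput(tau=1.0, samples=np.zeros((4, 64)))
        vbar = periodic_attractor(np.zeros((4, 4)), hebbian_params, u0)
        assert np.all(vbar.samples == 0)

    def test_matches_neumann_series_solution(self, hebbian_params,
                                             pattern_input, rng):
        # vbar = sum_k W^k / l^(k+1) u * g^(k+1): partial sum to k=30
        p = hebbian_params
        W = random_admissible_W(p.n, 0.3 * p.l, rng)
        vbar = periodic_attractor(W, p, pattern_input)
        omega = p.mu * pattern_input.freqs
        g = p.l / (p.l + 2j * np.pi * omega)
        acc = np.zeros_like(pattern_input.fourier)
        Wk = np.eye(p.n)
        for k in range(31):
            acc += (Wk / p.l ** (k + 1)) @ (pattern_input.fourier
                                            * g ** (k + 1))
            Wk = Wk @ W
        series = np.fft.irfft(acc * pattern_input.M, n=pattern_input.M, axis=1)
        assert np.abs(series - vbar.samples).max() < 1e-8 * pattern_input.u_m

    def test_unstable_connectivity_rejected(self, hebbian_params):
        W = 2 * hebbian_params.l * np.eye(4)
        u = make_sinusoid_input(4, 1.0)
        with pytest.raises(ValueError):
            periodic_attractor(W, hebbian_params, u)


class TestCorrelationDirect:
    @pytest.mark.parametrize("mu", [0.5, 1.0, 4.0])
    def test_scalar_sinusoid_value(self, mu, unit_sinusoid):
        p = scalar_params(mu=mu)
        C = correlation_term_direct(np.zeros((1, 1)), p, unit_sinusoid)
        assert C[0, 0] == pytest.approx(1.0 / (2 * (1 + mu ** 2)), abs=1e-12)

    def test_zero_input_gives_zero(self, hebbian_params):
        u0 = PeriodicInput(tau=1.0, samples=np.zeros((4, 64)))
        C = correlation_term_direct(np.zeros((4, 4)), hebbian_params, u0)
        assert np.all(C == 0)

    def test_hebbian_output_symmetric_psd(self, hebbian_params,
                                          pattern_input, rng):
        W = random_admissible_W(4, 0.4 * hebbian_params.l, rng)
        C = correlation_term_direct(W, hebbian_params, pattern_input)
        assert np.abs(C - C.T).max() < 1e-12
        assert np.linalg.eigvalsh(C).min() > -1e-12


class TestCorrelationFamily:
    def test_slow_input_limit_collapses_orders(self, pattern_input):
        # band-limited input: all C_{k,q} coincide with C_{0,0} to 1e-4
        # already at mu = 1e-3
        rng = np.random.default_rng(0)
        a = rng.standard_normal(4)
        a /= np.linalg.norm(a)
        u = make_sinusoid_input(4, 2 * np.pi, amplitudes=a)
        p = make_params({"rule": "hebbian", "n": 4, "l": 12.0, "kappa": 5.0,
                         "sigma": 0.1, "mu": 1e-3})
        fam = correlation_family(p, u, K=3)
        dev = max(np.abs(fam[k, q] - fam[0, 0]).max()
                  for k in range(4) for q in range(4))
        assert dev < 1e-4
        # broadband (square-wave) input: the collapse is O(mu)
        devs = []
        for mu in (1e-2, 1e-3, 1e-4):
            fam = correlation_family(p.replace(mu=mu), pattern_input, K=3)
            devs.append(max(np.abs(fam[k, q] - fam[0, 0]).max()
                            for k in range(4) for q in range(4)))
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.15 * devs[1] < 0.15 ** 2 * devs[0]

    def test_norm_bound_and_transpose_symmetry(self, hebbian_params,
                                               pattern_input):
        fam = correlation_family(hebbian_params, pattern_input, K=5)
        assert fam.max_norm <= 1.0 + 1e-8
        for k in range(6):
            for q in range(6):
                assert np.abs(fam[q, k] - fam[k, q].T).max() < 1e-12

    def test_zero_input_rejected(self, hebbian_params):
        u0 = PeriodicInput(tau=1.0, samples=np.zeros((4, 64)))
        with pytest.raises(ValueError):
            correlation_family(hebbian_params, u0, K=1)


class TestCorrelationSeries:
    def test_w_zero_keeps_only_leading_term(self, hebbian_params,
                                            pattern_input):
        p = hebbian_params
        fam = correlation_family(p, pattern_input, K=4)
        W0 = np.zeros((4, 4))
        series = correlation_term_series(W0, fam, p)
        lead = pattern_input.u_m ** 2 / p.l ** 2 * fam[0, 0]
        assert np.abs(series - lead).max() < 1e-15
        direct = correlation_term_direct(W0, p, pattern_input)
        assert np.abs(series - direct).max() < 1e-12

    @pytest.mark.parametrize("rule", ["hebbian", "trace", "stdp"])
    def test_matches_direct_evaluation(self, rule, pattern_input, rng,
                                       request):
        p = request.getfixturevalue(f"{rule}_params")
        fam = correlation_family(p, pattern_input, K=12)
        scale = p.l / fam.v_l1 if rule == "trace" else p.l
        W = random_admissible_W(4, 0.25 * scale, rng,
                                symmetric=(rule != "stdp"))
        series = correlation_term_series(W, fam, p)
        direct = correlation_term_direct(W, p, pattern_input)
        rel = np.linalg.norm(series - direct) / np.linalg.norm(direct)
        assert rel < 1e-6

    def test_slow_input_limit_closed_form(self, pattern_input, rng):
        # mu -> 0: correlation -> (L-W)^-1 <u u'> (L-W')^-1
        p = make_params({"rule": "hebbian", "n": 4, "l": 2.0, "kappa": 5.0,
                         "sigma": 0.1, "mu": 1e-4})
        W = random_admissible_W(4, 0.3 * p.l, rng)
        direct = correlation_term_direct(W, p, pattern_input)
        uu = pattern_input.samples @ pattern_input.samples.T / pattern_input.M
        R = np.linalg.inv(p.L - W)
        assert np.abs(direct - R @ uu @ R.T).max() < 1e-4

    def test_tail_bound_covers_truncation_error(self, hebbian_params,
                                                pattern_input, rng):
        p = hebbian_params
        W = random_admissible_W(4, 0.4 * p.l, rng)
        direct = correlation_term_direct(W, p, pattern_input)
        fam = correlation_family(p, pattern_input, K=3)
        series, tail = correlation_term_series(W, fam, p, return_tail=True)
        assert np.linalg.norm(series - direct, 2) <= tail

    def test_inadmissible_w_rejected(self, hebbian_params, pattern_input):
        fam = correlation_family(hebbian_params, pattern_input, K=2)
        W = 1.5 * hebbian_params.l * np.eye(4)
        with pytest.raises(ValueError):
            correlation_term_series(W, fam, hebbian_params)


class TestLyapunov:
    def test_scalar_balance(self):
        Q = solve_lyapunov(2.0 * np.eye(1), 0.5 * np.eye(1))
        assert Q[0, 0] == pytest.approx(0.5 / 4.0)

    def test_residual_on_random_stable_matrix(self, rng):
        A = rng.standard_normal((5, 5))
        A = A @ A.T / 10 + 2 * np.eye(5)       # positive definite part
        D = rng.standard_normal((5, 5))
        D = D @ D.T
        Q = solve_lyapunov(A, D)
        resid = np.linalg.norm(A @ Q + Q @ A.T - D)
        assert resid < 1e-10 * np.linalg.norm(D)

    def test_series_backend_matches_direct(self, rng):
        l = 3.0
        W = random_admissible_W(4, l / 3, rng)
        D = rng.standard_normal((4, 4))
        D = D @ D.T
        Q1 = solve_lyapunov(l * np.eye(4) - W, D)
        Q2 = solve_lyapunov_series(W, l, D)
        assert np.linalg.norm(Q1 - Q2) < 1e-8 * np.linalg.norm(Q1)

    def test_degenerate_spectrum_rejected(self):
        A = np.diag([1.0, -1.0])     # eigenvalue sum 0
        with pytest.raises(ValueError):
            solve_lyapunov(A, np.eye(2))


class TestNoiseTerm:
    def test_hebbian_at_zero_connectivity(self):
        p = make_params({"rule": "hebbian", "n": 3, "l": 2.0, "kappa": 1.0,
                         "sigma": 0.4})
        Q = noise_term(np.zeros((3, 3)), p)
        assert np.allclose(Q, 0.4 ** 2 / (2 * 2.0) * np.eye(3))

    def test_stdp_balanced_amplitudes_cancel_on_symmetric_w(self, rng):
        p = make_params({"rule": "stdp", "n": 4, "l": 2.0, "kappa": 1.0,
                         "sigma": 0.3, "gamma": 1.5, "a_plus": 0.7,
                         "a_minus": 0.7})
        W = random_admissible_W(4, 0.5 * p.l, rng)
        Q = noise_term(W, p)
        assert np.abs(Q).max() < 1e-12

    def test_stdp_q11_series_equals_direct(self, stdp_params, rng):
        p = stdp_params
        W = random_admissible_W(4, p.l / 3, rng, symmetric=False)
        SS = p.noise_matrix @ p.noise_matrix.T
        Q11_direct = solve_lyapunov(p.L - W, SS)
        Q11_series = solve_lyapunov_series(W, p.l, SS)
        assert np.allclose(Q11_direct, Q11_series, atol=1e-12)

    def test_asymmetric_w_rejected_for_hebbian(self, hebbian_params, rng):
        W = rng.standard_normal((4, 4)) * 0.01
        with pytest.raises(ValueError):
            noise_term(W, hebbian_params)


class TestAveragedField:
    def test_scalar_closed_form_field(self, unit_sinusoid):
        # for l = kappa = 1, u = sin: decay -w, correlation (at frozen
        # connectivity 0) 1/(2(1+mu^2)), noise sigma^2/2
        sigma, mu = 0.3, 2.0
        p = scalar_params(mu=mu, sigma=sigma)
        fld = AveragedField(p, unit_sinusoid, mode="direct")
        for w in (0.0, 0.2, -0.1):
            total, comp = averaged_rhs(np.array([[w]]), fld)
            assert comp["decay"][0, 0] == pytest.approx(-w)
        _, comp0 = averaged_rhs(np.zeros((1, 1)), fld)
        assert comp0["correlation"][0, 0] == pytest.approx(
            1 / (2 * (1 + mu ** 2)), abs=1e-12)
        assert comp0["noise"][0, 0] == pytest.approx(sigma ** 2 / 2, abs=1e-15)

    def test_pure_decay_without_input_and_noise(self):
        p = make_params({"rule": "hebbian", "n": 2, "l": 1.0, "kappa": 3.0,
                         "sigma": 0.0})
        u0 = PeriodicInput(tau=1.0, samples=np.zeros((2, 64)))
        fld = AveragedField(p, u0, mode="direct")
        W = np.array([[0.1, 0.02], [0.02, 0.05]])
        total, comp = averaged_rhs(W, fld)
        assert np.allclose(total, -3.0 * W)

    def test_direct_and_series_modes_agree(self, hebbian_params,
                                           pattern_input, rng):
        p = hebbian_params
        W = random_admissible_W(4, 0.2 * p.l, rng)
        direct = AveragedField(p, pattern_input, mode="direct")
        series = AveragedField(p, pattern_input, mode="series", K=12)
        assert np.abs(direct(W) - series(W)).max() < 1e-8

    def test_additivity_against_monte_carlo_average(self, rng):
        # for quadratic G the averaged field is the attractor correlation
        # plus the stationary covariance, with no cross term: check against
        # brute-force sampling of the frozen Gaussian law
        p = make_params({"rule": "hebbian", "n": 2, "l": 1.5, "kappa": 2.0,
                         "sigma": 0.3, "mu": 1.0})
        u = make_sinusoid_input(2, 2 * np.pi, amplitudes=(1.0, 0.5),
                                phases=(0.0, 1.0))
        W = random_admissible_W(2, 0.3 * p.l, rng)
        vbar = periodic_attractor(W, p, u).samples       # (2, M)
        Qcov = p.sigma ** 2 / 2 * np.linalg.inv(p.L - W)
        chol = np.linalg.cholesky(Qcov)
        draws = chol @ rng.standard_normal((2, 200_000))
        # Monte-Carlo E[(vbar(t)+x)(vbar(t)+x)'] averaged over the period
        mc = vbar @ vbar.T / vbar.shape[1] + draws @ draws.T / draws.shape[1]
        fld = AveragedField(p, u, mode="direct")
        _, comp = averaged_rhs(W, fld)
        assembled = comp["correlation"] + comp["noise"]
        assert np.abs(mc - assembled).max() < 5e-3


class TestIntegrateAveraged:
    def test_equilibrium_start_stays_constant(self, unit_sinusoid):
        p = scalar_params(sigma=0.1)
        fld = AveragedField(p, unit_sinusoid, mode="direct")
        W_star = solve_equilibrium(fld)
        traj = integrate_averaged(fld, W0=W_star, T=2.0)
        assert np.abs(traj.W_stack - W_star).max() < 1e-6

    def test_scalar_relaxation_closed_form(self, unit_sinusoid):
        # with the fast equation frozen at w = 0 (weak-coupling regime) the
        # solution is w(t) ~ wbar (1 - e^{-t}); full coupling only perturbs
        # it at O(wbar^2), which the tolerance covers
        sigma = 0.1
        p = scalar_params(sigma=sigma)
        fld = AveragedField(p, unit_sinusoid, mode="direct")
        traj = integrate_averaged(fld, T=4.0)
        wbar = sigma ** 2 / 2 + 0.25
        closed = wbar * (1 - np.exp(-traj.times))
        assert np.abs(traj.W_stack[:, 0, 0] - closed).max() < 10 * wbar ** 2

    def test_invariant_set_preserved_on_reference_config(self):
        # Hebbian reference parameters: symmetric, PSD, spectral norm < l/3
        p = make_params({"rule": "hebbian", "n": 3, "l": 12.0, "kappa": 100.0,
                         "sigma": 0.05, "mu": 1.0})
        rng = np.random.default_rng(0)
        a = rng.standard_normal(3)
        a /= np.linalg.norm(a)
        u = make_sinusoid_input(3, 2 * np.pi, amplitudes=a)
        fld = AveragedField(p, u, mode="direct")
        traj = integrate_averaged(fld, T=0.05)
        for W in traj.W_stack:
            assert np.abs(W - W.T).max() < 1e-9
            assert np.linalg.eigvalsh(0.5 * (W + W.T)).min() > -1e-9
            assert spectral_radius(W) < p.l / 3
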
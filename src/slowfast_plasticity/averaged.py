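"""The averaged deterministic connectivity dynamics.

In the limit of perfect time-scale separation, the connectivity of each
learning rule follows a deterministic ODE ``dW/dt = -kappa W + correlation(W)
+ noise(W)``:

* the *correlation* term is the period-average of the appropriate outer
  product of the frozen fast system's periodic attractor (activity traces for
  the trace rule, a lagged asymmetric product for STDP);
* the *noise* term is the stationary covariance of the frozen
  Ornstein-Uhlenbeck fluctuations, a Lyapunov-equation solution.

Both terms admit two evaluation routes, kept deliberately independent so
each can serve as the other's oracle:

* **direct** -- solve the attractor harmonic-by-harmonic in the Fourier
  domain and average by Parseval (exact periodic averaging, no transient
  contamination);
* **series** -- a weakly connected expansion in powers of ``W / l`` whose
  coefficients are the filtered input-correlation matrices ``C_{k,q}``
  (Hebbian), ``C~_{k,q}`` (trace, damped/Bessel kernels) or ``D_{k,q}``
  (STDP), all with spectral norm at most 1.

All harmonics are evaluated at the fast-frame frequencies
``omega_j = mu * j / tau`` with the unscaled rates ``l``, ``beta``, ``gamma``
(equivalently: input-frame filtering with rates divided by ``mu``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as _integrate
from scipy import linalg as _linalg

from .core_model import ModelParams, PeriodicInput
from .filters import _v_hat, _v_l1_closed, _damped_meta
from .sde import Trajectory

__all__ = [
    "CorrelationFamily", "AveragedField", "periodic_attractor",
    "correlation_term_direct", "correlation_family",
    "correlation_term_series", "solve_lyapunov", "solve_lyapunov_series",
    "noise_term", "averaged_rhs", "integrate_averaged", "spectral_radius",
]


def spectral_radius(W: np.ndarray) -> float:
    """Largest eigenvalue magnitude (the matrix norm used by the stability
    conditions; equals the spectral norm for symmetric W)."""
    return float(np.abs(np.linalg.eigvals(W)).max())


def _g_hat(rate: float, omega: np.ndarray) -> np.ndarray:
    return rate / (rate + 2j * np.pi * omega)


def _check_stable(W: np.ndarray, l: float):
    abscissa = float(np.real(np.linalg.eigvals(W)).max()) - l
    if abscissa >= 0:
        raise ValueError(
            f"spectral abscissa of W - L is {abscissa:.3g} >= 0: the frozen "
            "fast system has no attractor (see the well-posedness module)")


def periodic_attractor(W: np.ndarray, params: ModelParams,
                       inp: PeriodicInput) -> PeriodicInput:
    """Periodic attractor of the frozen fast system at fixed connectivity W.

    Solves ``dv/dt = (W - L) v + u(mu t)`` (Hebbian/STDP) or its filtered
    variant ``dv/dt = (W - L) (v * g_beta) + u(mu t)`` (trace) harmonic by
    harmonic: ``v_j = (2 i pi omega_j I - (W - L) g_beta(omega_j))^{-1} u_j``
    with ``omega_j = mu j / tau``.  Returns the ``tau/mu``-periodic attractor.
    """
    W = np.asarray(W, dtype=float)
    n = params.n
    omega = params.mu * inp.freqs
    nh = len(omega)
    A = W - params.L
    if params.rule == "trace":
        gains = _g_hat(params.beta, omega)
    else:
        _check_stable(W, params.l)
        gains = np.ones(nh)
    mats = (2j * np.pi * omega)[:, None, None] * np.eye(n)[None] \
        - gains[:, None, None] * A[None]
    rhs = inp.fourier.T[:, :, None]              # (nh, n, 1)
    try:
        vhat = np.linalg.solve(mats, rhs)[:, :, 0].T   # (n, nh)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular resolvent at some harmonic: frozen fast system "
            "unstable for this W") from exc
    tau_out = inp.tau / params.mu
    samples = np.fft.irfft(vhat * inp.M, n=inp.M, axis=1)
    return PeriodicInput(tau=tau_out, samples=samples, fourier=vhat)


def _parseval_outer(coeffs_left: np.ndarray, coeffs_right: np.ndarray,
                    weights: np.ndarray,
                    scalar: np.ndarray | None = None) -> np.ndarray:
    """Real part of sum_j w_j s_j x_j conj(y_j)^T over stored harmonics."""
    w = weights if scalar is None else weights * scalar
    return np.real(np.einsum("j,ij,kj->ik", w, coeffs_left,
                             np.conj(coeffs_right)))


def correlation_term_direct(W: np.ndarray, params: ModelParams,
                            inp: PeriodicInput) -> np.ndarray:
    """Period-averaged activity correlation from the attractor's Fourier
    coefficients (Parseval): ``(mu/tau) int vbar vbar' dt`` for Hebbian,
    with the trace-filtered or STDP-lagged variants for the other rules.
    """
    vbar = periodic_attractor(W, params, inp)
    vhat = vbar.fourier
    wts = inp.harmonic_weights
    omega = params.mu * inp.freqs
    if params.rule == "hebbian":
        return _parseval_outer(vhat, vhat, wts)
    if params.rule == "trace":
        zhat = _g_hat(params.beta, omega)[None, :] * vhat
        return _parseval_outer(zhat, zhat, wts)
    # stdp: (mu/tau) * (a+ vbar.(vbar*g)' - a- (vbar*g).vbar')
    g = _g_hat(params.gamma, omega)
    scalar = params.a_plus * np.conj(g) - params.a_minus * g
    return _parseval_outer(vhat, vhat, wts, scalar=scalar)


# ---------------------------------------------------------------------------
# Correlation families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationFamily:
    """Filtered input-correlation matrices of one learning rule.

    ``mats[k, q]`` is the ``n x n`` matrix coupling the ``W^k ... W'^q`` term
    of the weakly connected expansion; every stored matrix has spectral norm
    at most 1.  ``v_l1`` is ``||v||_1`` (trace rule only; 1.0 otherwise).
    """

    rule: str
    K: int
    mats: np.ndarray           # (K+1, K+1, n, n)
    u_m: float
    tau: float
    v_l1: float = 1.0
    a_abs_sum: float = 0.0

    def __getitem__(self, kq) -> np.ndarray:
        k, q = kq
        return self.mats[k, q]

    @property
    def max_norm(self) -> float:
        """Largest spectral norm across the stored matrices."""
        return float(max(
            np.linalg.norm(self.mats[k, q], 2)
            for k in range(self.K + 1) for q in range(self.K + 1)))


def correlation_family(params: ModelParams, inp: PeriodicInput,
                       K: int) -> CorrelationFamily:
    """Build the correlation matrices C_{k,q} / C~_{k,q} / D_{k,q} for
    ``k, q <= K`` by Fourier-domain filtering and Parseval averaging.

    * Hebbian: ``C_{k,q} = (u * g^(k+1)).(u * g^(q+1))' / (u_m^2 tau)`` with
      the exponential window at rate ``l`` on the fast frame.
    * Trace: same with the damped kernel ``v`` and a ``||v||_1^(k+q+2)``
      normalization.
    * STDP:   left factor additionally filtered through the learning window
      ``a+ g_gamma(-t) - a- g_gamma(t)``, normalized by ``|a+| + |a-|``.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    u_m = inp.u_m
    if u_m == 0:
        raise ValueError("u_m = 0: correlation normalization undefined")
    n = params.n
    omega = params.mu * inp.freqs
    wts = inp.harmonic_weights
    uhat = inp.fourier
    v_l1 = 1.0
    if params.rule == "trace":
        delta, osc = _damped_meta(params.l, params.beta, 1.0)
        v_l1 = _v_l1_closed(delta, osc)
        base = _v_hat(omega, params.l, params.beta, 1.0) / v_l1
    else:
        base = _g_hat(params.l, omega)
    # filtered input coefficients, one per expansion order
    filt = np.empty((K + 1, n, len(omega)), dtype=complex)
    gain = base.copy()
    for k in range(K + 1):
        filt[k] = gain[None, :] * uhat
        gain = gain * base
    if params.rule == "stdp":
        g = _g_hat(params.gamma, omega)
        window = (params.a_plus * np.conj(g) - params.a_minus * g) \
            / params.a_abs_sum
        left = filt * window[None, None, :]
    else:
        left = filt
    mats = np.empty((K + 1, K + 1, n, n))
    for k in range(K + 1):
        for q in range(K + 1):
            mats[k, q] = _parseval_outer(left[k], filt[q], wts) / u_m ** 2
    fam = CorrelationFamily(rule=params.rule, K=K, mats=mats, u_m=u_m,
                            tau=inp.tau, v_l1=v_l1,
                            a_abs_sum=params.a_abs_sum)
    if fam.max_norm > 1.0 + 1e-8:
        raise AssertionError(
            f"correlation-matrix norm bound violated: {fam.max_norm}")
    return fam


def correlation_term_series(W: np.ndarray, family: CorrelationFamily,
                            params: ModelParams,
                            return_tail: bool = False):
    """Truncated weakly connected series for the correlation term.

    Requires the spectral radius of W below ``l`` (Hebbian/STDP) or
    ``l / ||v||_1`` (trace).  With ``return_tail`` the geometric tail bound
    ``prefactor * rho^(K+1) (2 - rho^(K+1)) / (1 - rho)^2`` (``rho`` the
    contraction ratio) is returned alongside the matrix.
    """
    W = np.asarray(W, dtype=float)
    l = params.l
    scale = l / family.v_l1 if family.rule == "trace" else l
    rho = spectral_radius(W) / scale
    if rho >= 1.0:
        raise ValueError(
            f"series precondition violated: spectral radius ratio {rho:.3g} >= 1")
    K = family.K
    powers = [np.eye(params.n)]
    for _ in range(K):
        powers.append(powers[-1] @ (W / scale))
    if family.rule == "hebbian":
        pref = family.u_m ** 2 / l ** 2
    elif family.rule == "trace":
        pref = family.u_m ** 2 * family.v_l1 ** 2 / l ** 2
    else:
        pref = family.u_m ** 2 * family.a_abs_sum / l ** 2
    total = np.zeros((params.n, params.n))
    for k in range(K + 1):
        for q in range(K + 1):
            total += powers[k] @ family.mats[k, q] @ powers[q].T
    total *= pref
    if return_tail:
        r = rho ** (K + 1)
        tail = pref * r * (2.0 - r) / (1.0 - rho) ** 2
        return total, tail
    return total


# ---------------------------------------------------------------------------
# Noise term (Lyapunov machinery)
# ---------------------------------------------------------------------------

def solve_lyapunov(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Dense solve of ``A Q + Q A' = D`` where ``A`` is the stable part
    (eigenvalues with positive real parts), e.g. ``A = L - W``.

    This is the stationary-covariance equation of the Ornstein-Uhlenbeck
    fluctuations around the attractor, written with the sign convention
    ``A = l Id, D = sigma^2 Id  ->  Q = sigma^2 / (2 l) Id``.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    eigs = np.linalg.eigvals(A)
    pair_sums = eigs[:, None] + np.conj(eigs)[None, :]
    if np.min(np.abs(pair_sums)) < 1e-12 * max(np.abs(eigs).max(), 1.0):
        raise ValueError("eigenvalue-sum degeneracy: Lyapunov equation singular")
    # A Q + Q A' = D  <=>  (-A) Q + Q (-A)' = -D
    return _linalg.solve_continuous_lyapunov(-A, -D)


def solve_lyapunov_series(W: np.ndarray, l: float, D: np.ndarray,
                          tol: float = 1e-14, max_terms: int = 512) -> np.ndarray:
    """Geometric-series solution of ``(L - W) Q + Q (L - W)' = D``:

    ``Q = sum_k W^k . D . (2L - W')^{-(k+1)}``,

    valid when ``|||W||| * |||(2L - W)^{-1}||| < 1``.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    L2inv = np.linalg.inv(2 * l * np.eye(n) - W.T)
    ratio = spectral_radius(W) * spectral_radius(L2inv)
    if ratio >= 1.0:
        raise ValueError(
            f"series convergence condition violated (ratio {ratio:.3g} >= 1)")
    term = np.asarray(D, dtype=float) @ L2inv
    total = term.copy()
    for _ in range(max_terms):
        term = W @ term @ L2inv
        total += term
        if np.abs(term).max() < tol * max(np.abs(total).max(), 1e-300):
            break
    return total


def noise_term(W: np.ndarray, params: ModelParams) -> np.ndarray:
    """Contribution of the stationary noise covariance to the averaged field.

    Hebbian/trace (symmetric W, scalar noise): ``sigma^2/2 (L - W)^{-1}``.
    STDP: solve ``(W - L) Q11 + Q11 (W' - L) + Sigma Sigma' = 0``, set
    ``Q12 = gamma Q11 (L + gamma - W')^{-1}`` and return
    ``a+ Q12' - a- Q12``.
    """
    W = np.asarray(W, dtype=float)
    n = params.n
    L = params.L
    if spectral_radius(W) >= params.l:
        raise ValueError("W inadmissible: spectral radius >= l")
    if params.rule in ("hebbian", "trace"):
        if not np.allclose(W, W.T, atol=1e-10 * max(1.0, np.abs(W).max())):
            raise ValueError(f"{params.rule} rule requires symmetric W")
        if params.Sigma is None:
            return params.sigma ** 2 / 2.0 * np.linalg.inv(L - W)
        return solve_lyapunov(L - W, params.Sigma @ params.Sigma.T)
    SS = params.noise_matrix @ params.noise_matrix.T
    Q11 = solve_lyapunov(L - W, SS)
    Q12 = params.gamma * Q11 @ np.linalg.inv(
        L + params.gamma * np.eye(n) - W.T)
    return params.a_plus * Q12.T - params.a_minus * Q12


# ---------------------------------------------------------------------------
# Assembled field
# ---------------------------------------------------------------------------

@dataclass
class AveragedField:
    """The averaged drift ``G(W) = -kappa W + correlation(W) + noise(W)``.

    ``mode`` selects the correlation evaluation route: ``direct`` (attractor
    plus Parseval, the default for integration) or ``series`` (truncated
    expansion, requires ``family``).
    """

    params: ModelParams
    input: PeriodicInput
    mode: str = "direct"
    family: CorrelationFamily | None = None
    K: int = 4

    def __post_init__(self):
        if self.mode not in ("direct", "series"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "series" and self.family is None:
            self.family = correlation_family(self.params, self.input, self.K)

    def components(self, W: np.ndarray) -> dict[str, np.ndarray]:
        W = np.asarray(W, dtype=float)
        if self.mode == "direct":
            corr = correlation_term_direct(W, self.params, self.input)
        else:
            corr = correlation_term_series(W, self.family, self.params)
        return {
            "decay": -self.params.kappa * W,
            "correlation": corr,
            "noise": noise_term(W, self.params),
        }

    def __call__(self, W: np.ndarray) -> np.ndarray:
        c = self.components(W)
        return c["decay"] + c["correlation"] + c["noise"]

    def fixed_point_map(self, W: np.ndarray) -> np.ndarray:
        """F(W)/kappa where G(W) = -kappa (W - F(W)/kappa)."""
        c = self.components(W)
        return (c["correlation"] + c["noise"]) / self.params.kappa


def averaged_rhs(W: np.ndarray, field: AveragedField):
    """Evaluate the averaged drift; returns (total, components)."""
    c = field.components(W)
    return c["decay"] + c["correlation"] + c["noise"], c


def integrate_averaged(field: AveragedField, W0: np.ndarray | None = None,
                       T: float = 1.0, dt: float | None = None,
                       rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the averaged ODE with adaptive Runge-Kutta (RK45).

    ``W0`` defaults to the zero matrix (the conventional initial
    connectivity).  The trajectory is sampled every ``dt`` slow-time units
    (default ``T/200``).
    """
    n = field.params.n
    W0 = np.zeros((n, n)) if W0 is None else np.asarray(W0, dtype=float)
    if dt is None:
        dt = T / 200.0
    t_eval = np.arange(0.0, T + 0.5 * dt, dt)

    def rhs(t, y):
        W = y.reshape(n, n)
        if spectral_radius(W) >= field.params.l:
            raise RuntimeError(
                "trajectory left the invariant set (spectral radius >= l); "
                "check the well-posedness report for these parameters")
        return field(W).ravel()

    sol = _integrate.solve_ivp(rhs, (0.0, T), W0.ravel(), t_eval=t_eval,
                               method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"averaged integration failed: {sol.message}")
    W_stack = sol.y.T.reshape(len(sol.t), n, n)
    meta = {"rule": field.params.rule, "mode": field.mode, "averaged": True}
    return Trajectory(times=sol.t, W_stack=W_stack, meta=meta)
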
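"""Equilibrium connectivity: fixed point, weak-connectivity index, expansions.

Under the weak-connectivity condition the averaged dynamics contracts to a
unique equilibrium ``W*``.  Because ``W*/l`` is of the order of the
*weak connectivity index*

``p~ = u_m^2/(kappa l^3) + sigma^2/(2 kappa l^2)``   (Hebbian / trace)

``p~ = (|a+|+|a-|)/(kappa l^3) (s^2/2 (1/l + 1/gamma) + u_m^2)``   (STDP),

the equilibrium admits an expansion in powers of ``p~`` whose coefficients
combine the noise/input ratio ``lambda`` and the filtered input-correlation
matrices.  Orders 1 and 2 are implemented for the three rules; the STDP
equilibrium additionally splits into a symmetric (Hebbian-like, input
auto-correlation) and an antisymmetric (input/derivative cross-correlation)
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ModelParams, PeriodicInput
from .averaged import (AveragedField, CorrelationFamily, correlation_family,
                       spectral_radius, _g_hat, _parseval_outer)

__all__ = ["ExpansionResult", "weak_connectivity_index", "solve_equilibrium",
           "expansion", "stdp_sym_antisym"]


def weak_connectivity_index(params: ModelParams,
                            inp: PeriodicInput) -> tuple[float, float]:
    """The weak connectivity index ``p~`` and noise/input ratio ``lambda``.

    ``p~`` controls the size of the equilibrium (``W* = O(p~ l)``) and is the
    small parameter of the expansions; ``lambda`` is the ratio of its noise
    part to its input part.
    """
    u_m = inp.u_m
    if u_m == 0:
        raise ValueError("u_m = 0: weak connectivity index undefined")
    l, kappa = params.l, params.kappa
    if params.rule == "stdp":
        s2 = params.s2
        g = params.gamma
        lam = s2 / (2 * u_m ** 2) * (1 / l + 1 / g)
        p_tilde = params.a_abs_sum / (kappa * l ** 3) * (
            s2 / 2 * (1 / l + 1 / g) + u_m ** 2)
        return p_tilde, lam
    s2 = params.s2
    p_tilde = u_m ** 2 / (kappa * l ** 3) + s2 / (2 * kappa * l ** 2)
    lam = s2 * l / (2 * u_m ** 2)
    return p_tilde, lam


def solve_equilibrium(field: AveragedField, tol: float = 1e-12,
                      max_iter: int = 500, damping: float = 0.8,
                      W0: np.ndarray | None = None) -> np.ndarray:
    """Damped Picard iteration for the equilibrium of the averaged field.

    The equilibrium satisfies ``W = F(W)/kappa`` where ``F`` gathers the
    correlation and noise terms; under the contraction condition the plain
    iteration converges from any admissible start, and the damping
    ``W <- (1 - w) W + w F(W)/kappa`` widens the practical basin.
    Convergence: ``||F(W)/kappa - W||_F < tol * max(||W||_F, tol)``.
    """
    n = field.params.n
    W = np.zeros((n, n)) if W0 is None else np.asarray(W0, dtype=float).copy()
    for it in range(max_iter):
        FW = field.fixed_point_map(W)
        resid = float(np.linalg.norm(FW - W))
        if resid < tol * max(float(np.linalg.norm(W)), tol):
            return FW
        W = (1.0 - damping) * W + damping * FW
    raise RuntimeError(
        f"equilibrium iteration did not converge in {max_iter} steps "
        f"(last residual {resid:.3g})")


@dataclass(frozen=True)
class ExpansionResult:
    """Orders 1-2 of the weakly connected equilibrium expansion."""

    rule: str
    p_tilde: float
    lam: float
    order1: np.ndarray
    order2: np.ndarray
    S: np.ndarray | None = None       # STDP symmetric component (Eq.-level)
    A: np.ndarray | None = None       # STDP antisymmetric component
    alpha_plus: float | None = None
    alpha_minus: float | None = None

    @property
    def W_expansion(self) -> np.ndarray:
        return self.order1 + self.order2


def expansion(params: ModelParams, inp: PeriodicInput, order: int = 2,
              family: CorrelationFamily | None = None) -> ExpansionResult:
    """Weakly connected expansion of the equilibrium, orders 1 and 2.

    The recursion solves the averaged fixed-point equation order by order in
    ``p~``; the order-``a`` coefficient mixes a noise part (geometric in the
    rescaled connectivity) and a correlation part (the ``C``/``C~``/``D``
    matrices with ``k + q <= a``).  A warning-level error is raised above
    order 2.
    """
    if order > 2 or order < 1:
        raise ValueError(f"only expansion orders 1-2 are supported, got {order}")
    if family is None:
        family = correlation_family(params, inp, K=2)
    if family.K < 1 and order >= 2:
        raise ValueError("order-2 expansion needs family with K >= 1")
    p_tilde, lam = weak_connectivity_index(params, inp)
    if p_tilde >= 0.2:
        raise ValueError(
            f"p~ = {p_tilde:.3g} >= 0.2: expansion outside its validity range")
    l = params.l
    n = params.n
    I = np.eye(n)
    if params.rule == "hebbian":
        C00, C10, C01 = family[0, 0], family[1, 0], family[0, 1]
        om0 = (lam * I + C00) / (1 + lam)
        om1 = (lam * om0 + om0 @ C10 + C01 @ om0) / (1 + lam)
    elif params.rule == "trace":
        V = family.v_l1
        C00, C10, C01 = family[0, 0], family[1, 0], family[0, 1]
        om0 = (lam * I + V ** 2 * C00) / (1 + lam)
        om1 = (lam * om0 + V ** 3 * (om0 @ C10 + C01 @ om0)) / (1 + lam)
    else:
        D00, D10, D01 = family[0, 0], family[1, 0], family[0, 1]
        a_abs = params.a_abs_sum
        ap, am = params.a_plus / a_abs, params.a_minus / a_abs
        N = params.noise_matrix @ params.noise_matrix.T / params.s2
        gl = 1.0 / (1.0 + params.gamma / l)
        q0 = (ap - am) * N
        om0 = (D00 + lam * q0) / (1 + lam)
        q1 = 0.5 * (ap - am) * (om0 @ N + N @ om0.T) \
            + gl * (ap * om0 @ N - am * N @ om0.T)
        f1 = om0 @ D10 + D01 @ om0.T
        om1 = (f1 + lam * q1) / (1 + lam)
    order1 = p_tilde * l * om0
    order2 = p_tilde ** 2 * l * om1 if order >= 2 else np.zeros((n, n))
    S = A = None
    alpha = (None, None)
    if params.rule == "stdp":
        S, A = stdp_sym_antisym(params, inp)
        alpha = (params.a_plus / params.a_abs_sum,
                 params.a_minus / params.a_abs_sum)
    return ExpansionResult(rule=params.rule, p_tilde=p_tilde, lam=lam,
                           order1=order1, order2=order2, S=S, A=A,
                           alpha_plus=alpha[0], alpha_minus=alpha[1])


def stdp_sym_antisym(params: ModelParams,
                     inp: PeriodicInput) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric / antisymmetric decomposition of the first-order STDP
    input-correlation structure.

    ``S = (a+ - a-) (u*g_l*g_gamma).(u*g_l*g_gamma)'`` is the trace-like
    auto-correlation of the doubly filtered input;
    ``A = (a+ + a-)/gamma (du/dt*g_l*g_gamma).(u*g_l*g_gamma)'`` is the
    cross-correlation of the filtered input with its derivative.  Both are
    built in the Fourier domain; they reconstruct
    ``u_m^2 tau (|a+|+|a-|) D_{0,0} = S + A``.
    """
    if params.rule != "stdp":
        raise ValueError("sym/antisym decomposition is specific to the stdp rule")
    omega = params.mu * inp.freqs
    wts = inp.harmonic_weights
    x = (_g_hat(params.l, omega) * _g_hat(params.gamma, omega))[None, :] \
        * inp.fourier
    tau = inp.tau
    S = (params.a_plus - params.a_minus) * tau * _parseval_outer(x, x, wts)
    dx = (2j * np.pi * omega)[None, :] * x
    A = (params.a_plus + params.a_minus) / params.gamma * tau \
        * _parseval_outer(dx, x, wts)
    # enforce exact (anti)symmetry against round-off
    S = 0.5 * (S + S.T)
    A = 0.5 * (A - A.T)
    return S, A
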
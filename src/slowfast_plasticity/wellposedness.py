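"""Admissibility and stability certificates for the averaged dynamics.

The averaged flow preserves the set

``E_p = { W symmetric, W >= 0, |||W||| < p l }``   (0 < p < 1)

provided the excitation (input strength ``u_m``, noise ``sigma``) is small
against the decay mechanism (``kappa``, ``l``).  The rule-specific
inequalities certifying this are scanned over ``p`` here, together with the
stronger thresholds under which the equilibrium is unique and globally
stable, the explicit contraction bound, and the scalar truncation example
(one neuron, white-noise input) whose equilibria are available in closed
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import ModelParams, PeriodicInput
from .filters import _v_l1_closed, _damped_meta

__all__ = ["WellPosednessReport", "check_assumption", "invariant_set_check",
           "contraction_condition", "scalar_truncation_equilibria"]


@dataclass(frozen=True)
class WellPosednessReport:
    """Outcome of the admissibility scan for one parameter set."""

    rule: str
    admissible_p: list[tuple[float, float]]   # open intervals in ]0,1[
    assumption_ok: bool
    stability_threshold: float
    stability_ok: bool
    P_coeffs: tuple[float, float, float, float] | None = None
    details: dict = field(default_factory=dict)

    def best_p(self) -> float | None:
        """A representative admissible p (midpoint of the widest interval)."""
        if not self.admissible_p:
            return None
        lo, hi = max(self.admissible_p, key=lambda ab: ab[1] - ab[0])
        return 0.5 * (lo + hi)


def _lhs(params: ModelParams, u_m: float, p: np.ndarray) -> np.ndarray:
    """Left-hand side of the rule's admissibility inequality (< kappa l^3)."""
    l = params.l
    if params.rule == "stdp":
        s2, g = params.s2, params.gamma
        return params.a_abs_sum / (p * (1 - p)) * (
            s2 * g / (2 * (1 + g / l - p)) + u_m ** 2 / (1 - p))
    s2 = params.s2
    return s2 * l / (2 * p * (1 - p)) + u_m ** 2 / (p * (1 - p) ** 2)


def check_assumption(params: ModelParams, inp: PeriodicInput,
                     n_scan: int = 10000) -> WellPosednessReport:
    """Scan ``p in ]0,1[`` for the rule's admissibility inequality.

    A dense scan locates the sign changes of ``lhs(p) - kappa l^3`` and
    bisection refines the interval endpoints.  ``stability_ok`` records
    whether the inequality holds somewhere at or below the rule's
    uniqueness/global-stability threshold (``1/3`` for Hebbian and STDP,
    ``1/(2 ||v||_1^3 + 1)`` for the trace rule).
    """
    u_m = inp.u_m
    l, kappa = params.l, params.kappa
    rhs = kappa * l ** 3
    ps = np.linspace(0.0, 1.0, n_scan + 2)[1:-1]
    ok = _lhs(params, u_m, ps) < rhs
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < len(ps):
        if ok[i]:
            j = i
            while j + 1 < len(ps) and ok[j + 1]:
                j += 1
            lo = _bisect_edge(params, u_m, rhs, ps[i - 1] if i > 0 else 0.0,
                              ps[i], want_ok_at_hi=True)
            hi = _bisect_edge(params, u_m, rhs, ps[j],
                              ps[j + 1] if j + 1 < len(ps) else 1.0,
                              want_ok_at_hi=False)
            intervals.append((lo, hi))
            i = j + 1
        else:
            i += 1
    if params.rule == "trace":
        delta, osc = _damped_meta(l, params.beta, 1.0)
        v1 = _v_l1_closed(delta, osc)
        thr = 1.0 / (2 * v1 ** 3 + 1)
    else:
        thr = 1.0 / 3.0
    stability_ok = any(lo < thr for lo, hi in intervals)
    P_coeffs = None
    if params.rule != "stdp":
        s2 = params.s2
        P_coeffs = (-kappa, 2 * kappa * l, -(kappa * l ** 2 + s2 / 2),
                    u_m ** 2 + l * s2 / 2)
    return WellPosednessReport(
        rule=params.rule, admissible_p=intervals,
        assumption_ok=bool(intervals), stability_threshold=thr,
        stability_ok=stability_ok, P_coeffs=P_coeffs,
        details={"u_m": u_m, "kappa_l3": rhs})


def _bisect_edge(params, u_m, rhs, a, b, want_ok_at_hi, iters=60):
    """Refine an endpoint of an admissible interval inside (a, b)."""
    for _ in range(iters):
        m = 0.5 * (a + b)
        if m <= 0.0 or m >= 1.0:
            break
        mid_ok = bool(_lhs(params, u_m, np.array([m]))[0] < rhs)
        if mid_ok == want_ok_at_hi:
            b = m
        else:
            a = m
    return b if want_ok_at_hi else a


def invariant_set_check(W: np.ndarray, p: float,
                        params: ModelParams) -> tuple[bool, dict]:
    """Is W inside ``E_p``?  Returns the verdict and per-criterion margins.

    Symmetry is required for the Hebbian and trace rules only; positive
    semi-definiteness and the strict spectral bound ``|||W||| < p l`` apply
    to all rules.  Margins are positive when the criterion is satisfied
    (strictness tolerance ``1e-9 l`` on the spectral bound).
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in ]0,1[, got {p}")
    W = np.asarray(W, dtype=float)
    tol_sym = 1e-9 * max(1.0, float(np.abs(W).max()))
    diagnostics: dict[str, float] = {}
    ok = True
    if params.rule in ("hebbian", "trace"):
        asym = float(np.abs(W - W.T).max())
        diagnostics["symmetry_defect"] = asym
        if asym > tol_sym:
            ok = False
        eigs = np.linalg.eigvalsh(0.5 * (W + W.T))
    else:
        # for STDP positivity refers to the symmetric part
        eigs = np.linalg.eigvalsh(0.5 * (W + W.T))
    diagnostics["min_eigenvalue"] = float(eigs.min())
    if eigs.min() < -1e-9 * params.l:
        ok = False
    radius = float(np.abs(np.linalg.eigvals(W)).max())
    margin = p * params.l - radius
    diagnostics["spectral_margin"] = margin
    if margin <= 1e-9 * params.l:
        ok = False
    return ok, diagnostics


def contraction_condition(params: ModelParams, p: float,
                          inp: PeriodicInput) -> bool:
    """Explicit Lipschitz/contraction bound certifying a unique globally
    stable equilibrium:  ``2 u_m^2/(1-p)^3 + l sigma^2/(2 (1-p)^2) < kappa l^3``
    (strict)."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in ]0,1[, got {p}")
    u_m = inp.u_m
    lhs = 2 * u_m ** 2 / (1 - p) ** 3 \
        + params.l * params.s2 / (2 * (1 - p) ** 2)
    return bool(lhs < params.kappa * params.l ** 3)


def scalar_truncation_equilibria(l: float, kappa: float, sigma: float):
    """Equilibria of the one-neuron white-noise model
    ``dw/dt = -kappa w + sigma^2 / (2 (l - w))``.

    Returns ``(eta, w_minus, w_plus)`` with ``eta = 2 sigma^2/(kappa l^2)``.
    For ``eta <= 1`` the two roots ``l/2 (1 -+ sqrt(1 - eta))`` exist in
    ``(0, l)`` (coinciding at ``l/2`` when ``eta = 1``); ``w_minus`` is the
    stable one, ``w_plus`` unstable.  For ``eta > 1`` there is no equilibrium
    and ``(eta, None, None)`` is returned.
    """
    if l <= 0 or kappa <= 0:
        raise ValueError("l and kappa must be strictly positive")
    eta = 2 * sigma ** 2 / (kappa * l ** 2)
    if eta > 1 + 1e-12:
        return eta, None, None
    root = np.sqrt(max(1 - eta, 0.0))
    return eta, l / 2 * (1 - root), l / 2 * (1 + root)
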
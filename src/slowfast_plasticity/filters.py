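"""Causal convolution kernels and Fourier-domain filtering of periodic signals.

Three kernel families appear in the averaged learning dynamics:

* the exponential window ``g_rate(t) = rate * exp(-rate*t) * H(t)`` and its
  ``(k+1)``-fold self-convolutions (gamma densities, unit L1 norm) -- the
  temporal filters of the linear-activity (Hebbian and STDP) models;
* the damped kernels ``v`` and ``w`` of the trace model, solutions of a
  second-order filter with discriminant ``Delta = sqrt(1 - 4 l / beta)``:
  hyperbolic decay for real Delta (``4 l <= beta``), damped oscillations for
  imaginary Delta (``4 l > beta``).  Iterated versions ``v*...*v`` have a
  closed form in terms of Bessel functions;
* two-sided temporal profiles ``g^(k+1) * g'^(q+1)`` describing the lagged
  input correlations picked up by the plasticity rules.

All transfer functions use the ordinary-frequency convention
``ghat(xi) = int g(t) exp(-2 i pi xi t) dt``; the damped kernels carry the
time-scale ratio ``mu`` internally (their rates scale as ``1/mu``).

Filtering of a :class:`~slowfast_plasticity.core_model.PeriodicInput` is
performed exactly in the Fourier domain: the kernel's infinite tail is fully
accounted for and the periodic steady state has no truncation bias.  The
sampled time-domain values exist for L1 norms, plotting and oracle
cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal as _signal
from scipy import special as _special

from .core_model import PeriodicInput

__all__ = [
    "Kernel", "exp_kernel", "iterated_exp_kernel", "temporal_profile",
    "damped_kernels", "iterated_damped_kernel", "kernel_l1_norm",
    "apply_filter_periodic",
]

# |Delta| below this is routed to the confluent (Delta = 0) branch
_DELTA_TOL = 1e-8
_MAX_ITER_ORDER = 64


@dataclass(frozen=True)
class Kernel:
    """A sampled convolution kernel with closed-form metadata.

    ``values`` sample the kernel on ``t`` (causal kernels on ``[0, T]``,
    profile kernels on ``[-T, T]``); ``freq_response`` is the closed-form
    transfer function.
    """

    kind: str
    params: dict
    t: np.ndarray
    values: np.ndarray
    freq_response: Callable[[np.ndarray], np.ndarray]
    closed_form_l1: float | None = None
    closed_form_integral: float | None = None
    two_sided: bool = False

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def signed_integral(self) -> float:
        """Trapezoid-rule integral of the sampled kernel."""
        return float(np.trapezoid(self.values, self.t))

    @property
    def l1(self) -> float:
        """Trapezoid-rule L1 norm of the sampled kernel."""
        return float(np.trapezoid(np.abs(self.values), self.t))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"t": self.t, "value": self.values})


def _grid(dt: float, horizon: float) -> np.ndarray:
    return np.arange(0.0, horizon + 0.5 * dt, dt)


def exp_kernel(rate: float, dt: float | None = None,
               horizon: float | None = None) -> Kernel:
    """Causal exponential window ``g_rate(t) = rate * exp(-rate t) * H(t)``.

    Unit signed integral; transfer ``rate / (rate + 2 i pi xi)``.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if horizon is None:
        horizon = 40.0 / rate
    if horizon < 5.0 / rate:
        raise ValueError(
            f"horizon {horizon} truncates the tail too aggressively (< 5/rate)")
    if dt is None:
        dt = horizon / 4096
    t = _grid(dt, horizon)
    values = rate * np.exp(-rate * t)

    def freq_response(xi, rate=rate):
        return rate / (rate + 2j * np.pi * np.asarray(xi))

    return Kernel("exp", {"rate": rate}, t, values, freq_response,
                  closed_form_l1=1.0, closed_form_integral=1.0)


def iterated_exp_kernel(rate: float, k: int, dt: float | None = None,
                        horizon: float | None = None) -> Kernel:
    """(k+1)-fold self-convolution of the exponential window.

    Closed form is the gamma density
    ``rate^(k+1) t^k exp(-rate t) / k!`` with unit L1 norm and mode ``k/rate``.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 0):
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    if k > _MAX_ITER_ORDER:
        raise ValueError(f"k = {k} too large (cap {_MAX_ITER_ORDER})")
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if horizon is None:
        horizon = (40.0 + 10.0 * k) / rate
    if dt is None:
        dt = horizon / 4096
    t = _grid(dt, horizon)
    # log-space evaluation avoids overflow for large k
    with np.errstate(divide="ignore"):
        logv = ((k + 1) * math.log(rate) + k * np.log(np.where(t > 0, t, 1.0))
                - rate * t - _special.gammaln(k + 1))
    values = np.exp(logv)
    values[t == 0] = rate if k == 0 else 0.0

    def freq_response(xi, rate=rate, k=k):
        return (rate / (rate + 2j * np.pi * np.asarray(xi))) ** (k + 1)

    return Kernel("exp_iter", {"rate": rate, "k": k}, t, values, freq_response,
                  closed_form_l1=1.0, closed_form_integral=1.0)


def temporal_profile(rate: float, k: int, q: int, dt: float | None = None,
                     horizon: float | None = None) -> Kernel:
    """Two-sided (k,q)-temporal profile ``g^(k+1) * g'^(q+1)``.

    ``g'`` is the time-reversed window, so the profile describes the lag
    sensitivity of the filtered input correlation: even about 0 when
    ``k == q``, peaked at positive lags when ``k > q``.  Computed by FFT
    convolution of the sampled one-sided kernels; transfer
    ``ghat^(k+1) conj(ghat)^(q+1)``.
    """
    if k < 0 or q < 0:
        raise ValueError("k and q must be non-negative")
    gk = iterated_exp_kernel(rate, k, dt=dt, horizon=horizon)
    gq = iterated_exp_kernel(rate, q, dt=gk.dt, horizon=gk.t[-1])
    vals = _signal.fftconvolve(gk.values, gq.values[::-1]) * gk.dt
    m = len(gk.t) - 1
    t = np.concatenate([-gk.t[::-1][:-1], gk.t]) if m else gk.t
    assert len(vals) == 2 * m + 1
    # trapezoid end-correction at the moving integration boundary (the
    # windows jump at 0 when k or q is 0)
    vals[m:] -= 0.5 * gk.dt * gk.values * gq.values[0]
    vals[:m + 1] -= 0.5 * gk.dt * gk.values[0] * gq.values[::-1]
    vals[m] += 0.5 * gk.dt * gk.values[0] * gq.values[0]  # counted twice above

    def freq_response(xi, rate=rate, k=k, q=q):
        g = rate / (rate + 2j * np.pi * np.asarray(xi))
        return g ** (k + 1) * np.conj(g) ** (q + 1)

    return Kernel("profile", {"rate": rate, "k": k, "q": q}, t, vals,
                  freq_response, closed_form_integral=1.0, two_sided=True)


# ---------------------------------------------------------------------------
# Damped (second-order) kernels of the trace model
# ---------------------------------------------------------------------------

def _damped_meta(l: float, beta: float, mu: float):
    if l <= 0 or beta <= 0 or mu <= 0:
        raise ValueError("l, beta, mu must be strictly positive")
    d2 = 1.0 - 4.0 * l / beta
    delta = math.sqrt(abs(d2))
    oscillatory = d2 < 0
    if delta < _DELTA_TOL:
        delta, oscillatory = 0.0, False
    return delta, oscillatory


def _v_values(t: np.ndarray, l: float, beta: float, mu: float,
              delta: float, oscillatory: bool) -> np.ndarray:
    decay = np.exp(-beta * t / (2 * mu))
    if delta == 0.0:
        return (l * beta / mu ** 2) * t * decay
    arg = beta * delta * t / (2 * mu)
    if oscillatory:
        return (2 * l / (mu * delta)) * decay * np.sin(arg)
    # hyperbolic branch, evaluated overflow-safely:
    # e^{-bt/2mu} sinh(arg) = (e^{-b(1-d)t/2mu} - e^{-b(1+d)t/2mu})/2
    return (l / (mu * delta)) * (np.exp(-beta * (1 - delta) * t / (2 * mu))
                                 - np.exp(-beta * (1 + delta) * t / (2 * mu)))


def _w_values(t: np.ndarray, l: float, beta: float, mu: float,
              delta: float, oscillatory: bool) -> np.ndarray:
    decay = np.exp(-beta * t / (2 * mu))
    if delta == 0.0:
        return (l / mu) * decay * (beta * t / (2 * mu) + 1.0)
    arg = beta * delta * t / (2 * mu)
    if oscillatory:
        return (l / (mu * delta)) * decay * (np.sin(arg) + delta * np.cos(arg))
    return (l / (2 * mu * delta)) * (
        (1 + delta) * np.exp(-beta * (1 - delta) * t / (2 * mu))
        - (1 - delta) * np.exp(-beta * (1 + delta) * t / (2 * mu)))


def _v_hat(xi, l, beta, mu):
    s = 2j * np.pi * mu * np.asarray(xi)
    return l * beta / (l * beta + beta * s + s ** 2)


def _w_hat(xi, l, beta, mu):
    s = 2j * np.pi * mu * np.asarray(xi)
    return l * (beta + s) / (l * beta + beta * s + s ** 2)


def _v_l1_closed(delta: float, oscillatory: bool) -> float | None:
    if oscillatory:
        if delta == 0:
            return 1.0
        return 1.0 / math.tanh(math.pi / (2 * delta))
    return 1.0


def damped_kernels(l: float, beta: float, mu: float, dt: float | None = None,
                   horizon: float | None = None) -> tuple[Kernel, Kernel]:
    """The damped kernels ``(v, w)`` of the trace model.

    Both have unit signed integral.  ``v`` is non-negative with ``||v||_1 = 1``
    on the hyperbolic branch (``4 l <= beta``) and changes sign with
    ``||v||_1 = coth(pi / (2 |Delta|)) > 1`` on the oscillatory branch.
    ``Delta = 0`` (``beta = 4 l``) uses the confluent limit kernel
    ``(l beta / mu^2) t exp(-beta t / (2 mu))``.
    """
    delta, oscillatory = _damped_meta(l, beta, mu)
    # slowest decay rate governs the tail
    slow_rate = beta * (1 - (delta if not oscillatory else 0.0)) / (2 * mu)
    slow_rate = max(slow_rate, 1e-12)
    if horizon is None:
        horizon = 40.0 / slow_rate
    if dt is None:
        dt = horizon / 8192
    t = _grid(dt, horizon)
    params = {"l": l, "beta": beta, "mu": mu, "delta": delta,
              "oscillatory": oscillatory}
    v = Kernel("damped_v", params, t,
               _v_values(t, l, beta, mu, delta, oscillatory),
               lambda xi, l=l, beta=beta, mu=mu: _v_hat(xi, l, beta, mu),
               closed_form_l1=_v_l1_closed(delta, oscillatory),
               closed_form_integral=1.0)
    w = Kernel("damped_w", params, t,
               _w_values(t, l, beta, mu, delta, oscillatory),
               lambda xi, l=l, beta=beta, mu=mu: _w_hat(xi, l, beta, mu),
               closed_form_l1=(1.0 if not oscillatory else None),
               closed_form_integral=1.0)
    return v, w


def iterated_damped_kernel(l: float, beta: float, mu: float, k: int,
                           dt: float | None = None,
                           horizon: float | None = None) -> Kernel:
    """k-fold self-convolution ``v_k = v * ... * v`` (``k >= 1``, ``v_1 = v``).

    Closed form via Bessel functions:
    ``v_k(t) = (l beta / mu^2)^k e^{-beta t/(2 mu)} (sqrt(pi)/Gamma(k))
    (t mu / (beta Delta))^{k-1/2} I_{k-1/2}(beta Delta t / (2 mu))``
    on the hyperbolic branch, with ``I -> J`` and ``Delta -> |Delta|`` on the
    oscillatory branch.  Transfer ``vhat^k``.  Falls back to FFT
    self-convolution if the Bessel evaluation fails.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be an integer >= 1, got {k!r}")
    if k > _MAX_ITER_ORDER:
        raise ValueError(f"k = {k} too large (cap {_MAX_ITER_ORDER})")
    delta, oscillatory = _damped_meta(l, beta, mu)
    slow_rate = beta * (1 - (delta if not oscillatory else 0.0)) / (2 * mu)
    slow_rate = max(slow_rate, 1e-12)
    if horizon is None:
        horizon = (40.0 + 10.0 * k) / slow_rate
    if dt is None:
        dt = horizon / 8192
    t = _grid(dt, horizon)
    try:
        values = _vk_closed_form(t, l, beta, mu, k, delta, oscillatory)
        if not np.all(np.isfinite(values)):
            raise FloatingPointError("non-finite Bessel values")
    except (FloatingPointError, ValueError):
        v1 = _v_values(t, l, beta, mu, delta, oscillatory)
        values = v1.copy()
        for _ in range(k - 1):
            values = _signal.fftconvolve(values, v1)[: len(t)] * dt

    def freq_response(xi, l=l, beta=beta, mu=mu, k=k):
        return _v_hat(xi, l, beta, mu) ** k

    return Kernel("damped_v_iter",
                  {"l": l, "beta": beta, "mu": mu, "k": k, "delta": delta,
                   "oscillatory": oscillatory},
                  t, values, freq_response)


def _vk_closed_form(t, l, beta, mu, k, delta, oscillatory):
    if delta == 0.0:
        # confluent limit: (l beta/mu^2)^k t^(2k-1) e^{-beta t/(2 mu)}/(2k-1)!
        logv = (k * math.log(l * beta / mu ** 2)
                + (2 * k - 1) * np.log(np.where(t > 0, t, 1.0))
                - beta * t / (2 * mu) - _special.gammaln(2 * k))
        vals = np.exp(logv)
        vals[t <= 0] = 0.0
        return vals
    arg = beta * delta * t / (2 * mu)
    pref = ((l * beta / mu ** 2) ** k * math.sqrt(math.pi) / math.gamma(k))
    order = k - 0.5
    scale = (t * mu / (beta * delta)) ** order
    if oscillatory:
        bess = _special.jv(order, arg)
        vals = pref * scale * np.exp(-beta * t / (2 * mu)) * bess
    else:
        # exponentially scaled ive avoids overflow: I(nu,x) = ive(nu,x) e^x
        bess = _special.ive(order, arg)
        vals = pref * scale * np.exp(-beta * (1 - delta) * t / (2 * mu)) * bess
    vals = np.where(t > 0, vals, 0.0)
    return vals


def causal_convolve(a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid-accurate convolution of two causal kernels sampled on the
    same grid, truncated to that grid.  The half-weight end corrections
    matter because the exponential windows jump at t = 0."""
    n = len(a)
    c = _signal.fftconvolve(a, b)[:n]
    c = c - 0.5 * (a[0] * b + b[0] * a)
    return c * dt


def kernel_l1_norm(kernel: Kernel) -> float:
    """Trapezoid-rule L1 norm of a sampled kernel.

    Closed forms, when they exist, live in ``kernel.closed_form_l1``
    (exponential family: 1; damped ``v``, hyperbolic branch: 1; damped ``v``,
    oscillatory branch: ``coth(pi/(2|Delta|))``).  No closed form is known for
    ``||w||_1`` on the oscillatory branch, hence the numeric route.
    """
    return kernel.l1


def apply_filter_periodic(signal: PeriodicInput, kernel: Kernel,
                          mu_rescale: float = 1.0) -> PeriodicInput:
    """Filter a periodic signal through a kernel, exactly, in Fourier domain.

    Harmonic ``j`` (frequency ``j / tau``) is multiplied by the kernel's
    transfer evaluated at ``mu_rescale * j / tau``; ``mu_rescale = mu``
    filters a signal expressed on the input time-scale through a kernel whose
    rates live on the fast time-scale.  The period is preserved and the
    kernel's infinite tail is fully accounted for.
    """
    gains = kernel.freq_response(mu_rescale * signal.freqs)
    return signal.with_fourier(signal.fourier * gains[None, :])
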
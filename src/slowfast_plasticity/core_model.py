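"""Parameter container and synthetic periodic-input generators.

Every other module consumes the two data types defined here:

* :class:`ModelParams` gathers the scalar network/learning parameters of the
  three plasticity rules (Hebbian, trace, STDP) together with the derived
  quantities (the damping discriminant ``Delta``, the largest noise
  eigenvalue ``s2``, the leak matrix ``L``).
* :class:`PeriodicInput` is a tau-periodic vector signal stored both as
  uniform samples and as Fourier coefficients; all periodic filtering in the
  package happens on the Fourier side, so the two representations are kept
  consistent to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

RULES = ("hebbian", "trace", "stdp")


class ParameterError(ValueError):
    """Raised when a model parameter is missing or out of range."""


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of a slow-fast learning network.

    Attributes
    ----------
    n : int
        Number of neurons.
    rule : str
        One of ``hebbian``, ``trace``, ``stdp``.
    l : float
        Activity leak rate (per fast-time unit), ``L = l * Id``.
    kappa : float
        Connectivity decay rate (per slow-time unit).
    sigma : float or None
        Scalar noise amplitude; mutually exclusive with ``Sigma``.
    Sigma : ndarray or None
        Full ``n x n`` noise matrix (STDP allows spatial correlations).
    mu : float
        Asymptotic time-scale ratio eps1/eps2 between internal activity
        dynamics and the external input.
    eps1, eps2 : float
        Time-scale separation parameters, used only by the stochastic
        simulator.
    beta : float
        Activity-trace integration rate (trace rule); ``inf`` for Hebbian.
    gamma : float
        STDP learning-window rate.
    a_plus, a_minus : float
        STDP potentiation/depression amplitudes.
    """

    n: int
    rule: str
    l: float
    kappa: float
    mu: float = 1.0
    sigma: float | None = None
    Sigma: np.ndarray | None = None
    eps1: float = 1e-3
    eps2: float = 1e-3
    beta: float = math.inf
    gamma: float = 1.0
    a_plus: float = 1.0
    a_minus: float = 1.0

    def __post_init__(self):
        if self.rule not in RULES:
            raise ParameterError(f"rule must be one of {RULES}, got {self.rule!r}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ParameterError(f"n must be a positive integer, got {self.n!r}")
        for name in ("l", "kappa", "mu", "eps1", "eps2", "gamma"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ParameterError(f"{name} must be strictly positive, got {val!r}")
        if self.beta <= 0:
            raise ParameterError(f"beta must be > 0 (or +inf), got {self.beta!r}")
        if self.sigma is not None and self.Sigma is not None:
            raise ParameterError("give either scalar sigma or matrix Sigma, not both")
        if self.sigma is not None and self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma!r}")
        if self.Sigma is not None:
            S = np.asarray(self.Sigma, dtype=float)
            if S.shape != (self.n, self.n):
                raise ParameterError(
                    f"Sigma must be {self.n}x{self.n}, got shape {S.shape}")
            object.__setattr__(self, "Sigma", S)
        if self.sigma is None and self.Sigma is None:
            object.__setattr__(self, "sigma", 0.0)
        if self.rule == "hebbian" and np.isfinite(self.beta):
            raise ParameterError("hebbian rule has no activity trace: beta must be +inf")
        if self.rule == "trace" and not np.isfinite(self.beta):
            raise ParameterError("trace rule requires a finite beta")

    # -- derived quantities -------------------------------------------------

    @property
    def noise_matrix(self) -> np.ndarray:
        """The n x n diffusion matrix (sigma*Id when a scalar was given)."""
        if self.Sigma is not None:
            return self.Sigma
        return self.sigma * np.eye(self.n)

    @property
    def s2(self) -> float:
        """Largest eigenvalue of Sigma.Sigma' (= sigma^2 for scalar noise)."""
        if self.Sigma is None:
            return self.sigma ** 2
        return float(np.linalg.eigvalsh(self.Sigma @ self.Sigma.T).max())

    @property
    def L(self) -> np.ndarray:
        """Leak matrix l * Id."""
        return self.l * np.eye(self.n)

    @property
    def delta_magnitude(self) -> float:
        """|Delta| where Delta = sqrt(1 - 4 l / beta) (0 for Hebbian: beta=inf
        gives Delta=1; returns |Delta| on either branch)."""
        d2 = 1.0 - 4.0 * self.l / self.beta
        return math.sqrt(abs(d2))

    @property
    def oscillatory(self) -> bool:
        """True iff Delta is pure imaginary (4 l > beta): damped oscillations."""
        return 4.0 * self.l > self.beta

    @property
    def a_abs_sum(self) -> float:
        return abs(self.a_plus) + abs(self.a_minus)

    def replace(self, **kw) -> "ModelParams":
        data = {f: getattr(self, f) for f in (
            "n", "rule", "l", "kappa", "mu", "sigma", "Sigma",
            "eps1", "eps2", "beta", "gamma", "a_plus", "a_minus")}
        if "sigma" in kw and kw["sigma"] is not None:
            data["Sigma"] = None
        if "Sigma" in kw and kw["Sigma"] is not None:
            data["sigma"] = None
        data.update(kw)
        return ModelParams(**data)


_REQUIRED = {
    "hebbian": ("n", "l", "kappa"),
    "trace": ("n", "l", "kappa", "beta"),
    "stdp": ("n", "l", "kappa", "gamma"),
}


def make_params(raw: Mapping) -> ModelParams:
    """Validate a name->value mapping and build a :class:`ModelParams`.

    The mapping must contain ``rule`` plus the keys that rule requires
    (``beta`` for trace, ``gamma`` for STDP).  Missing or ill-signed entries
    raise :class:`ParameterError` naming the offending field.
    """
    raw = dict(raw)
    rule = raw.get("rule")
    if rule not in RULES:
        raise ParameterError(f"rule must be one of {RULES}, got {rule!r}")
    for key in _REQUIRED[rule]:
        if key not in raw:
            raise ParameterError(f"missing required parameter {key!r} for rule {rule!r}")
    if rule == "hebbian":
        raw.setdefault("beta", math.inf)
    known = {"n", "rule", "l", "kappa", "mu", "sigma", "Sigma", "eps1",
             "eps2", "beta", "gamma", "a_plus", "a_minus"}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
    return ModelParams(**raw)


# ---------------------------------------------------------------------------
# Periodic inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodicInput:
    """A tau-periodic vector signal with its Fourier representation.

    ``samples`` holds ``u`` on ``M`` uniform times of ``[0, tau)``;
    ``fourier`` holds the one-sided Fourier coefficients
    ``c_k = (1/M) sum_m u(t_m) exp(-2 i pi k m / M)`` for ``0 <= k <= M/2``,
    so that harmonic ``k`` lives at ordinary frequency ``k / tau``.
    """

    tau: float
    samples: np.ndarray          # (n, M)
    fourier: np.ndarray = field(default=None)  # (n, M//2+1) complex

    def __post_init__(self):
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", s)
        if self.fourier is None:
            object.__setattr__(self, "fourier", np.fft.rfft(s, axis=1) / s.shape[1])

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def M(self) -> int:
        return self.samples.shape[1]

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.M) * (self.tau / self.M)

    @property
    def freqs(self) -> np.ndarray:
        """Ordinary frequencies k/tau of the stored harmonics (k=0..M/2)."""
        return np.arange(self.fourier.shape[1]) / self.tau

    @property
    def harmonic_weights(self) -> np.ndarray:
        """Multiplicities for two-sided sums over harmonics: 1 for k=0 (and
        the Nyquist bin when M is even), 2 otherwise."""
        nh = self.fourier.shape[1]
        w = np.full(nh, 2.0)
        w[0] = 1.0
        if self.M % 2 == 0:
            w[-1] = 1.0
        return w

    @property
    def u_m(self) -> float:
        """sup_t ||u(t)||_2 over the sampling grid."""
        return float(np.linalg.norm(self.samples, axis=0).max())

    def reconstruct(self) -> np.ndarray:
        """Inverse-transform the Fourier coefficients back to samples."""
        return np.fft.irfft(self.fourier * self.M, n=self.M, axis=1)

    def with_fourier(self, coeffs: np.ndarray, tau: float | None = None) -> "PeriodicInput":
        """Build a new signal (same grid) from modified Fourier coefficients."""
        tau = self.tau if tau is None else tau
        samples = np.fft.irfft(coeffs * self.M, n=self.M, axis=1)
        return PeriodicInput(tau=tau, samples=samples, fourier=coeffs)

    def __call__(self, t) -> np.ndarray:
        """Evaluate u at arbitrary times by trigonometric interpolation-free
        nearest-grid lookup (the generators sample densely enough that the
        simulator uses grid lookup)."""
        idx = np.asarray(np.floor((np.asarray(t) / self.tau) % 1.0 * self.M),
                         dtype=int) % self.M
        return self.samples[:, idx]

    def to_frame(self):
        """Time column + one column per component, as a pandas DataFrame."""
        import pandas as pd
        data = {"t": self.grid}
        for i in range(self.n):
            data[f"u{i}"] = self.samples[i]
        return pd.DataFrame(data)


DEFAULT_M = 4096


def make_sinusoid_input(n: int, tau: float,
                        amplitudes: Sequence[float] | float = 1.0,
                        phases: Sequence[float] | float = 0.0,
                        M: int = DEFAULT_M) -> PeriodicInput:
    """Sinusoidal input: component i is amplitudes[i]*sin(2*pi*t/tau + phases[i]).

    This is the forcing used throughout the scalar worked examples
    (``n=1, tau=2*pi`` gives ``u(t) = sin t``).
    """
    if M < 8:
        raise ParameterError(f"M must be >= 8 to resolve a sinusoid, got {M}")
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    amp = np.broadcast_to(np.asarray(amplitudes, dtype=float), (n,))
    pha = np.broadcast_to(np.asarray(phases, dtype=float), (n,))
    t = np.arange(M) * (tau / M)
    samples = amp[:, None] * np.sin(2 * np.pi * t[None, :] / tau + pha[:, None])
    return PeriodicInput(tau=tau, samples=samples)


def _orthonormalize(patterns: np.ndarray) -> np.ndarray:
    """Gram-Schmidt via QR; rows are patterns."""
    q, r = np.linalg.qr(patterns.T)
    # fix signs so each orthonormalized pattern correlates positively with
    # the original one
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return (q * signs).T


def make_pattern_input(n: int,
                       patterns: Sequence[Sequence[float]] | np.ndarray | None = None,
                       durations: Sequence[float] | None = None,
                       M: int = DEFAULT_M,
                       smooth_frac: float = 0.0,
                       seed: int | None = None,
                       orthogonalize: bool = False,
                       n_patterns: int | None = None) -> PeriodicInput:
    """Piecewise-constant input cycling through spatial patterns.

    The signal presents ``patterns[j]`` for ``durations[j]`` time units, over
    one period ``tau = sum(durations)``.  When ``patterns`` is None,
    ``n_patterns`` random unit-norm patterns are drawn from ``seed`` (frozen
    spatial structure).  With ``orthogonalize`` the patterns are replaced by
    an orthonormal set (pairwise dot products 0, unit norms).  Transitions are
    hard switches by default; ``smooth_frac`` in (0, 1) applies a raised-cosine
    ramp over that fraction of each segment.
    """
    if patterns is None:
        if n_patterns is None:
            raise ParameterError("give patterns or n_patterns")
        rng = np.random.default_rng(seed)
        patterns = rng.standard_normal((n_patterns, n))
        patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    P = patterns.shape[0]
    if patterns.shape[1] != n:
        raise ParameterError(f"patterns must have {n} components, got {patterns.shape[1]}")
    if orthogonalize:
        if P > n:
            raise ParameterError(f"cannot orthogonalize {P} patterns in dimension {n}")
        patterns = _orthonormalize(patterns)
    if durations is None:
        durations = np.ones(P)
    durations = np.asarray(durations, dtype=float)
    if durations.shape != (P,) or np.any(durations <= 0):
        raise ParameterError("durations must be positive, one per pattern")
    tau = float(durations.sum())
    t = np.arange(M) * (tau / M)
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    seg = np.searchsorted(edges, t, side="right") - 1
    seg = np.clip(seg, 0, P - 1)
    samples = patterns[seg].T.copy()
    if smooth_frac > 0:
        if not smooth_frac < 1:
            raise ParameterError("smooth_frac must be in [0, 1)")
        # raised-cosine crossfade centred on each switch time
        for j in range(P):
            t_switch = edges[j]  # start of segment j (crossfade from j-1 to j)
            half = 0.5 * smooth_frac * durations[j]
            prev = patterns[(j - 1) % P]
            cur = patterns[j]
            d = (t - t_switch + tau / 2) % tau - tau / 2  # signed distance
            mask = np.abs(d) < half
            lam = 0.5 * (1 + np.sin(np.pi * d[mask] / (2 * half)))
            samples[:, mask] = (np.outer(prev, 1 - lam) + np.outer(cur, lam))
    return PeriodicInput(tau=tau, samples=samples)


def make_one_hot_cycle_input(n: int, tau: float, M: int = DEFAULT_M,
                             amplitude: float = 1.0) -> PeriodicInput:
    """Circular one-hot pattern sequence: neuron i is excited (value
    ``amplitude``) during the i-th of ``n`` equal sub-intervals of the
    period, all other components 0."""
    durations = np.full(n, tau / n)
    patterns = amplitude * np.eye(n)
    return make_pattern_input(n, patterns=patterns, durations=durations, M=M)
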
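"""Euler-Maruyama simulation of the coupled activity/connectivity systems.

The simulator integrates in *fast* time ``s`` (activity time units): the
activity drift is O(1) there, the additive noise enters with ``sqrt(dt)``,
and the slow connectivity update is scaled by ``eps1``.  The periodic input
is driven at phase ``mu * s``, so the averaged machinery (which works with
the frozen fast system forced by ``u(mu t)``) describes the same limit.
With additive noise in ``v`` the Euler-Maruyama scheme has strong order 1.0.

The trace and STDP rules are history-dependent through an exponential window;
they are simulated in their augmented memoryless form with an auxiliary
variable ``z`` integrating ``v`` at rate ``beta`` (resp. ``gamma``), with no
noise of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import ModelParams, PeriodicInput

__all__ = ["Trajectory", "simulate", "sup_deviation"]


@dataclass
class Trajectory:
    """Time-stamped stack of connectivity matrices (slow-time units)."""

    times: np.ndarray               # (S,)
    W_stack: np.ndarray             # (S, n, n)
    v_stack: np.ndarray | None = None
    z_stack: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.W_stack.shape[1]

    def final(self) -> np.ndarray:
        return self.W_stack[-1]

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linearly interpolate W at times ``t`` (within the sampled range)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        S, n, _ = self.W_stack.shape
        flat = self.W_stack.reshape(S, n * n)
        out = np.empty((len(t), n * n))
        for j in range(n * n):
            out[:, j] = np.interp(t, self.times, flat[:, j])
        return out.reshape(len(t), n, n)

    def to_frame(self):
        """Time column then the n^2 W entries in row-major order (Wij)."""
        import pandas as pd
        S, n, _ = self.W_stack.shape
        data = {"t": self.times}
        for i in range(n):
            for j in range(n):
                data[f"W{i}{j}"] = self.W_stack[:, i, j]
        return pd.DataFrame(data)


def simulate(params: ModelParams, inp: PeriodicInput, T_fast: float,
             dt: float = 0.01, seed: int | None = None,
             thinning: int = 10) -> Trajectory:
    """Euler-Maruyama integration of the stochastic learning system.

    Parameters
    ----------
    params : ModelParams
        Network parameters; ``eps1`` scales the connectivity update.
    inp : PeriodicInput
        Periodic drive, evaluated at phase ``mu * s`` on the fast time grid.
    T_fast : float
        Fast-time horizon; the covered slow horizon is ``eps1 * T_fast``.
    dt : float
        Fast-time step.
    seed : int, optional
        Seed for the Brownian increments; same seed and dt give bit-identical
        runs.
    thinning : int
        Store every ``thinning``-th step.

    Returns
    -------
    Trajectory
        Connectivity (and activity) samples; times are slow-time stamps
        ``eps1 * s``.  ``W(0) = 0``.
    """
    n = params.n
    if inp.n != n:
        raise ValueError(f"input has {inp.n} components, params.n = {n}")
    if dt <= 0 or T_fast <= 0:
        raise ValueError("dt and T_fast must be positive")
    if dt * params.l >= 0.5:
        raise ValueError(f"dt = {dt} too large for leak rate l = {params.l}")
    rng = np.random.default_rng(seed)
    n_steps = int(round(T_fast / dt))
    Sig = params.noise_matrix
    scalar_noise = params.Sigma is None
    sigma = params.sigma if scalar_noise else None
    sqdt = np.sqrt(dt)
    eps1 = params.eps1
    kappa, l_rate = params.kappa, params.l
    rule = params.rule
    aux_rate = params.beta if rule == "trace" else params.gamma
    a_p, a_m = params.a_plus, params.a_minus

    # precompute input lookup indices on the fast grid
    s_times = np.arange(n_steps) * dt
    phase = (params.mu * s_times) % inp.tau
    idx = np.minimum((phase / inp.tau * inp.M).astype(int), inp.M - 1)
    u_seq = inp.samples[:, idx]        # (n, n_steps)

    v = np.zeros(n)
    z = np.zeros(n)
    W = np.zeros((n, n))
    n_keep = n_steps // thinning + 1
    times = np.empty(n_keep)
    W_stack = np.empty((n_keep, n, n))
    v_stack = np.empty((n_keep, n))
    z_stack = np.empty((n_keep, n)) if rule != "hebbian" else None
    kept = 0

    def store(step):
        nonlocal kept
        times[kept] = eps1 * step * dt
        W_stack[kept] = W
        v_stack[kept] = v
        if z_stack is not None:
            z_stack[kept] = z
        kept += 1

    store(0)
    with np.errstate(over="ignore", invalid="ignore"):
        # overflow is diagnosed by the explicit blow-up check below
        for m in range(n_steps):
            u = u_seq[:, m]
            if scalar_noise:
                noise = sigma * sqdt * rng.standard_normal(n)
            else:
                noise = sqdt * (Sig @ rng.standard_normal(n))
            if rule == "hebbian":
                dv = (W @ v - l_rate * v + u) * dt
                dW = (-kappa * W + np.outer(v, v)) * (eps1 * dt)
            elif rule == "trace":
                dv = (W @ z - l_rate * z + u) * dt
                dz = aux_rate * (v - z) * dt
                dW = (-kappa * W + np.outer(z, z)) * (eps1 * dt)
            else:  # stdp
                dv = (W @ v - l_rate * v + u) * dt
                dz = aux_rate * (v - z) * dt
                dW = (-kappa * W + a_p * np.outer(v, z)
                      - a_m * np.outer(z, v)) * (eps1 * dt)
            v = v + dv + noise
            if rule != "hebbian":
                z = z + dz
            W = W + dW
            if (m + 1) % thinning == 0:
                if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8 \
                        or np.abs(v).max() > 1e8:
                    raise RuntimeError(
                        f"numerical blow-up at fast step {m + 1} (check the "
                        "well-posedness assumption for these parameters)")
                if kept < n_keep:
                    store(m + 1)

    meta = {"rule": rule, "seed": seed, "dt": dt, "thinning": thinning,
            "eps1": eps1, "mu": params.mu, "T_fast": T_fast}
    return Trajectory(times=times[:kept], W_stack=W_stack[:kept],
                      v_stack=v_stack[:kept],
                      z_stack=None if z_stack is None else z_stack[:kept],
                      meta=meta)


def sup_deviation(traj_a: Trajectory, traj_b: Trajectory) -> float:
    """Sup over shared times of the squared Frobenius distance between the
    two connectivity trajectories (the coarser one is linearly interpolated).
    """
    lo = max(traj_a.times[0], traj_b.times[0])
    hi = min(traj_a.times[-1], traj_b.times[-1])
    if hi < lo:
        raise ValueError("trajectories have disjoint time ranges")
    ta = traj_a.times[(traj_a.times >= lo) & (traj_a.times <= hi)]
    tb = traj_b.times[(traj_b.times >= lo) & (traj_b.times <= hi)]
    t = ta if len(ta) >= len(tb) else tb
    if len(t) == 0:
        t = np.array([lo])
    Wa = traj_a.interp(t)
    Wb = traj_b.interp(t)
    d2 = ((Wa - Wb) ** 2).sum(axis=(1, 2))
    return float(d2.max())
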
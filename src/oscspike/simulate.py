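"""Stochastic simulation of the perfect integrate-and-fire neuron.

The voltage obeys ``v' = 1 + y + eta`` with threshold 1 and reset 0; the
noise is *not* reset at spikes.  Because the velocity does not depend on
``v``, the time of the n-th spike equals the first-passage time of the
free (non-resetting) process ``p(t) = t + X(t)`` through the level n,
where ``X(t)`` is the integrated noise.  The simulator exploits this: it
advances the linear noise system *augmented by its own integral*,

    (y, s, eta, X),   X' = y + eta,

with the exact one-step Gaussian transition of the joint linear SDE
(conditional mean ``M z`` and covariance ``S`` computed by the Van Loan
matrix-exponential construction).  The noise statistics therefore carry no
time-step bias at all; the only discretisation effect is the linear
interpolation of the threshold-crossing time inside a step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.linalg import expm

from .params import CanonicalParams

__all__ = ["SpikeTrain", "simulate", "transition_matrices"]

_BLOCK = 1 << 16


@dataclass
class SpikeTrain:
    """Ordered spike times, in seconds if ``rate_hz`` is set, else canonical."""

    times: np.ndarray
    params_used: Optional[CanonicalParams] = None
    seed: Optional[int] = None
    canonical: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            i = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise ValueError(f"spike times not strictly increasing at index {i}")

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def rate(self) -> float:
        """Empirical mean firing rate (1/mean ISI)."""
        return 1.0 / float(np.mean(self.isis))


def transition_matrices(params: CanonicalParams, dt: float):
    """Exact one-step transition (M, S) of the linear system (y, s, eta, X).

    ``z_{k+1} = M z_k + w_k`` with ``w_k ~ N(0, S)``.  Uses the Van Loan
    block-exponential; S is the exact conditional covariance over a step.
    """
    g, w0, _, d_h = params.gamma, params.omega0, params.omega1, params.d_h
    tau, d_ou = params.tau_ou, params.d_ou
    A = np.array([
        [0.0, 1.0, 0.0, 0.0],
        [-w0 ** 2, -g, 0.0, 0.0],
        [0.0, 0.0, -1.0 / tau, 0.0],
        [1.0, 0.0, 1.0, 0.0],
    ])
    GGt = np.zeros((4, 4))
    GGt[1, 1] = 2.0 * d_h
    GGt[2, 2] = 2.0 * d_ou / tau ** 2
    Z = np.zeros((8, 8))
    Z[:4, :4] = A
    Z[:4, 4:] = GGt
    Z[4:, 4:] = -A.T
    E = expm(Z * dt)
    M = E[:4, :4]
    S = E[:4, 4:] @ M.T
    return M, 0.5 * (S + S.T)


def _sqrtm_psd(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals))


@njit(cache=False)
def _advance(E, M, z, k, m, p_old, dt, spikes, found):  # pragma: no cover - jit
    n = E.shape[0]
    ntot = spikes.shape[0]
    for i in range(n):
        z0 = M[0, 0] * z[0] + M[0, 1] * z[1] + M[0, 2] * z[2] + E[i, 0]
        z1 = M[1, 0] * z[0] + M[1, 1] * z[1] + M[1, 2] * z[2] + E[i, 1]
        z2 = M[2, 2] * z[2] + E[i, 2]
        z3 = M[3, 0] * z[0] + M[3, 1] * z[1] + M[3, 2] * z[2] + z[3] + E[i, 3]
        z[0] = z0
        z[1] = z1
        z[2] = z2
        z[3] = z3
        k += 1
        p_new = k * dt + z3
        while p_new >= m and found < ntot:
            frac = (m - p_old) / (p_new - p_old)
            spikes[found] = (k - 1 + frac) * dt
            found += 1
            m += 1.0
        p_old = p_new
        if found >= ntot:
            break
    return k, m, p_old, found


def simulate(
    params: CanonicalParams,
    n_spikes: int,
    dt: float = 1.0 / 500.0,
    seed: Optional[int] = None,
    discard: int = 100,
) -> SpikeTrain:
    """Simulate ``n_spikes`` spike times (after discarding ``discard`` warm-up spikes).

    The initial noise state is drawn from its stationary law; the warm-up
    discard erases the (non-stationary) phase condition v(0)=0.  A single
    seeded generator drives the whole call, so results are bit-reproducible.
    Times are returned in seconds when ``params.rate_hz`` is set.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if dt > 1.0 / (10.0 * params.omega0):
        raise ValueError(
            f"dt={dt:g} too coarse: must not exceed 1/(10*omega0)={1/(10*params.omega0):g}"
        )
    rng = np.random.default_rng(seed)
    M, S = transition_matrices(params, dt)
    L = _sqrtm_psd(S)

    z = np.zeros(4)
    z[0] = rng.normal(0.0, params.sigma_h)
    z[1] = rng.normal(0.0, params.sigma_h * params.omega0)
    z[2] = rng.normal(0.0, params.sigma_ou)

    ntot = int(n_spikes) + int(discard)
    spikes = np.empty(ntot)
    found = 0
    k = 0
    m = 1.0
    p_old = 0.0
    while found < ntot:
        E = rng.standard_normal((_BLOCK, 4)) @ L.T
        k, m, p_old, found = _advance(E, M, z, k, m, p_old, dt, spikes, found)
        if not np.isfinite(z).all():
            raise FloatingPointError(
                "non-finite noise state encountered; check parameters and dt"
            )
    times = spikes[discard:]
    if params.rate_hz is not None:
        times = times / params.rate_hz
    return SpikeTrain(times=times, params_used=params, seed=seed,
                      canonical=params.rate_hz is None)
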
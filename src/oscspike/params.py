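"""Model parameters for the stochastically forced perfect integrate-and-fire neuron.

The neuron integrates a constant base current plus two zero-mean Gaussian
noise sources and fires when the voltage reaches threshold:

    v' = 1 + y(t) + eta(t)          (canonical units: threshold 1, reset 0)

* ``y`` is *harmonic noise* -- the position of a noise-driven damped harmonic
  oscillator -- a stochastic oscillation with a spectral peak at the damped
  frequency ``omega1 = 2 pi w`` and coherence set by the quality factor
  ``Q = omega1 / gamma``.
* ``eta`` is an Ornstein-Uhlenbeck (OU) process with correlation time
  ``tau_ou``; for short ``tau_ou`` it acts like broadband (white) noise.

All quantities are non-dimensionalised: time is measured in units of the
mean interspike interval (the mean firing rate is exactly 1 regardless of
the noise), and noise amplitudes ``sigma_h``, ``sigma_ou`` are stationary
standard deviations relative to the base current.  Setting ``rate_hz``
attaches a physical firing rate used purely for unit conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CanonicalParams",
    "NoiseState",
    "harmonic_coefficients",
    "epsilon",
    "sample_stationary_noise_state",
    "CV_VALIDITY_LIMIT",
]

#: Predicted CV above which the weak-noise expressions are outside the
#: regime in which they were validated against simulation.
CV_VALIDITY_LIMIT = 0.3


def harmonic_coefficients(w: float, Q: float, sigma_h: float):
    """Langevin coefficients of the harmonic-noise oscillator.

    The oscillator pair ``y' = s``, ``s' = -gamma*s - omega0^2*y + sqrt(2 D_h) xi``
    has a spectral peak at the damped frequency ``omega1`` with full width at
    half maximum ``gamma``.  The conventions adopted here are

        omega1 = 2 pi w,   gamma = omega1 / Q,   omega0^2 = omega1^2 + gamma^2/4,

    and the noise intensity ``D_h`` is fixed by requiring the stationary
    variance of ``y`` to equal ``sigma_h**2``:

        D_h = sigma_h^2 * gamma * omega0^2.

    Returns
    -------
    (gamma, omega0, omega1, D_h)
    """
    if w <= 0:
        raise ValueError(f"frequency ratio w must be positive, got {w}")
    if Q <= 0:
        raise ValueError(f"quality factor Q must be positive, got {Q}")
    if sigma_h < 0:
        raise ValueError(f"sigma_h must be non-negative, got {sigma_h}")
    omega1 = 2.0 * math.pi * w
    gamma = omega1 / Q
    omega0 = math.sqrt(omega1 ** 2 + gamma ** 2 / 4.0)
    d_h = sigma_h ** 2 * gamma * omega0 ** 2
    return gamma, omega0, omega1, d_h


@dataclass(frozen=True)
class CanonicalParams:
    """Non-dimensional parameter set of the model.

    Parameters
    ----------
    w : frequency ratio of the stochastic oscillation to the firing rate (>0).
    Q : quality factor of the harmonic noise (>0).
    sigma_h : stationary SD of the harmonic-noise variable y (>=0).
    sigma_ou : stationary SD of the OU variable eta (>=0).
    tau_ou : OU correlation time in units of the mean ISI (>0).
    rate_hz : optional physical mean firing rate used for unit conversion.
    """

    w: float
    Q: float
    sigma_h: float
    sigma_ou: float = 0.0
    tau_ou: float = 0.1
    rate_hz: Optional[float] = None

    def __post_init__(self):
        harmonic_coefficients(self.w, self.Q, self.sigma_h)  # validates w, Q, sigma_h
        if self.sigma_ou < 0:
            raise ValueError("sigma_ou must be non-negative")
        if self.tau_ou <= 0:
            raise ValueError("tau_ou must be positive")
        if self.rate_hz is not None and self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    # ---- derived Langevin coefficients -------------------------------
    @property
    def omega1(self) -> float:
        return 2.0 * math.pi * self.w

    @property
    def gamma(self) -> float:
        return self.omega1 / self.Q

    @property
    def omega0(self) -> float:
        return math.sqrt(self.omega1 ** 2 + self.gamma ** 2 / 4.0)

    @property
    def d_h(self) -> float:
        """Harmonic-noise intensity giving Var(y) = sigma_h**2."""
        return self.sigma_h ** 2 * self.gamma * self.omega0 ** 2

    @property
    def d_ou(self) -> float:
        """OU noise intensity D = sigma_ou**2 * tau_ou."""
        return self.sigma_ou ** 2 * self.tau_ou

    @property
    def epsilon(self) -> float:
        """Small parameter of the weak-noise expansion."""
        return self.sigma_h ** 2 + self.sigma_ou ** 2

    def replace(self, **kw) -> "CanonicalParams":
        d = dict(w=self.w, Q=self.Q, sigma_h=self.sigma_h,
                 sigma_ou=self.sigma_ou, tau_ou=self.tau_ou, rate_hz=self.rate_hz)
        d.update(kw)
        return CanonicalParams(**d)

    def to_dict(self) -> dict:
        return dict(w=self.w, Q=self.Q, sigma_h=self.sigma_h,
                    sigma_ou=self.sigma_ou, tau_ou=self.tau_ou, rate_hz=self.rate_hz)

    @classmethod
    def from_dict(cls, d: dict) -> "CanonicalParams":
        keys = ("w", "Q", "sigma_h", "sigma_ou", "tau_ou", "rate_hz")
        return cls(**{k: d[k] for k in keys if k in d})


@dataclass
class NoiseState:
    """Instantaneous state of the driving noise (y, s, eta)."""

    y: float
    s: float
    eta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.y, self.s, self.eta], dtype=float)


def epsilon(params: CanonicalParams):
    """Small parameter eps = sigma_h^2 + sigma_ou^2 and a validity flag.

    The flag is False ("outside validated regime") when the predicted CV
    exceeds ``CV_VALIDITY_LIMIT``; the perturbative results degrade there,
    most visibly in the serial correlations.
    """
    from .theory import cv_theory  # local import to avoid a cycle

    eps = params.epsilon
    valid = cv_theory(params, mode="general") <= CV_VALIDITY_LIMIT
    return eps, valid


def sample_stationary_noise_state(params: CanonicalParams, seed=None) -> NoiseState:
    """Draw (y, s, eta) from the stationary law of the noise.

    The harmonic pair is bivariate Gaussian with Var(y) = sigma_h^2,
    Var(s) = sigma_h^2 * omega0^2 and Cov(y, s) = 0; eta is Gaussian with
    SD sigma_ou.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, params.sigma_h)
    s = rng.normal(0.0, params.sigma_h * params.omega0)
    eta = rng.normal(0.0, params.sigma_ou)
    return NoiseState(y=y, s=s, eta=eta)
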
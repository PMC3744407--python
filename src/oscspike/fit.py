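"""Oscillator-parameter extraction from a measured spike train.

The inverse problem: given only an ISI sequence, recover the parameters of
the stochastic oscillation driving the neuron -- quality factor Q,
frequency ratio w, harmonic-noise SD sigma_h -- and the intensity D_ou of
the residual broadband noise.  The pipeline mirrors the standard analysis
of long stationary sensory-afferent records:

1. normalise the ISI sequence to unit mean;
2. measure CV and serial correlation coefficients (with segment error bars);
3. fit the damped-oscillation SCC closed form by nonlinear least squares,
   with the CV prefactor pinned to the measured CV and the frequency ratio
   initialised from the ratio of the two spectral peaks of the spike-train
   PSD;
4. invert the closed-form CV expression for the OU intensity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .params import CanonicalParams
from .stats import (SCCSeries, ISISummary, isis, psd_estimate, scc_errorbars,
                    stationarity_filter, summary_stats, PSDEstimate)
from .theory import SCCCoefficients, harmonic_cv2

__all__ = [
    "FitConfig",
    "FitResult",
    "normalize_isis",
    "initial_w_from_psd",
    "fit_scc",
    "d_ou_from_cv",
    "extract_parameters",
]

W_FALLBACK = 0.5  # mid-range of frequency ratios seen across afferent samples


def normalize_isis(intervals):
    """Rescale an ISI sequence to unit mean; returns (normalised, scale)."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two intervals")
    scale = float(x.mean())
    return x / scale, scale


def initial_w_from_psd(psd: PSDEstimate):
    """Initial frequency ratio from the two spectral peaks of the train PSD.

    The afferent peak is searched near the mean rate (0.8-1.2 r0) and the
    driving-oscillation peak below it (0.25-0.8 r0); w_init is their ratio.
    Falls back to 0.5 with a warning when either peak is missing.
    """
    r0 = psd.rate
    f_osc = psd.peak_frequency(0.25 * r0, 0.8 * r0)
    f_aff = psd.peak_frequency(0.8 * r0, 1.2 * r0)
    if f_osc is None or f_aff is None or f_aff <= 0:
        warnings.warn("no usable spectral peaks; falling back to w_init=0.5",
                      stacklevel=2)
        return W_FALLBACK
    return float(f_osc / f_aff)


@dataclass
class FitResult:
    Q: float
    w: float
    sigma_h: float
    d_ou: float
    sigma_ou: float
    tau_ou: float
    cv_measured: float
    w_init: float
    residual_norm: float
    converged: bool
    identifiable: bool = True
    d_ou_feasible: bool = True
    se: Optional[np.ndarray] = None
    summary: Optional[ISISummary] = None
    scc: Optional[SCCSeries] = None
    scc_fit: Optional[np.ndarray] = None
    rate_hz: Optional[float] = None
    stage_info: dict = field(default_factory=dict)

    @property
    def params(self) -> CanonicalParams:
        return CanonicalParams(w=self.w, Q=self.Q, sigma_h=self.sigma_h,
                               sigma_ou=self.sigma_ou, tau_ou=self.tau_ou,
                               rate_hz=self.rate_hz)

    def to_dict(self) -> dict:
        return dict(Q=self.Q, w=self.w, sigma_h=self.sigma_h, d_ou=self.d_ou,
                    sigma_ou=self.sigma_ou, tau_ou=self.tau_ou,
                    cv_measured=self.cv_measured, w_init=self.w_init,
                    residual_norm=self.residual_norm, converged=self.converged,
                    identifiable=self.identifiable,
                    d_ou_feasible=self.d_ou_feasible, rate_hz=self.rate_hz)


_BOUNDS = ((1.0, 0.1, 0.0), (200.0, 3.0, 1.0))  # (Q, w, sigma_h)


def _scc_fit_model(theta, k, cv2, decoherence: bool = True):
    """Damped-oscillation SCC model evaluated at lags k.

    With ``decoherence=True`` the leading-order envelope exp(-pi w k / Q)
    is multiplied by exp(-w1^2 (V(k) - V(1)) / 2), where V is the n-th-order
    interval variance implied by the candidate parameters and the measured
    CV.  This accounts for the sampling jitter of the spike clock: the
    oscillation is probed at spike times whose separation diffuses with the
    lag, decorrelating the sampled phase faster than the oscillator's own
    bandwidth.  The factor is normalised to 1 at lag 1 (adjacent-interval
    correlations are captured by the leading order) and tends to 1 as the
    noise vanishes, leaving the weak-noise closed form intact.
    """
    Q, w, sh = theta
    w1 = 2.0 * math.pi * w
    a = math.pi * w / Q
    co = SCCCoefficients.from_values(w, Q, sh, cv2)
    rho = co.evaluate(k)
    if not decoherence:
        return rho
    d = max(0.0, (cv2 - harmonic_cv2(w, Q, sh)) / 2.0)
    g = 2.0 * a
    env = np.exp(-a * k)
    vk = (2.0 * sh ** 2 / w1 ** 2) * (
        1.0 + g * k - env * (np.cos(w1 * k) + (3.0 * a / w1) * np.sin(w1 * k))
    ) + 2.0 * d * k
    v1 = (2.0 * sh ** 2 / w1 ** 2) * (
        1.0 + g - math.exp(-a) * (math.cos(w1) + (3.0 * a / w1) * math.sin(w1))
    ) + 2.0 * d
    return rho * np.exp(-w1 ** 2 * np.clip(vk - v1, 0.0, None) / 2.0)


def fit_scc(scc: SCCSeries, cv_measured: float, w_init: float,
            lag_range: Optional[tuple] = None, weighted: bool = False,
            decoherence: bool = True):
    """Fit the damped-oscillation SCC form for (Q, w, sigma_h).

    The squared-CV prefactor is fixed to the measured value, leaving three
    free parameters.  The objective is oscillatory in w, so a multi-start
    grid around ``w_init`` (+-0.05) is mandatory; the lowest-residual
    solution is returned.  A flat SCC (no detectable oscillation) is
    flagged unidentifiable with sigma_h -> 0.  ``decoherence`` enables the
    second-order envelope correction (see ``_scc_fit_model``), which
    removes the systematic underestimation of Q at realistic noise levels.
    """
    if cv_measured <= 0:
        raise ValueError("cv_measured must be positive")
    if scc.lags.size < 10:
        raise ValueError("need at least 10 SCC lags to fit")
    lo, hi = lag_range if lag_range is not None else (1, int(scc.lags.max()))
    sel = (scc.lags >= lo) & (scc.lags <= hi)
    k = scc.lags[sel].astype(float)
    rho = scc.rho[sel]
    sig = None
    if weighted and scc.se is not None:
        sig = np.clip(scc.se[sel], 1e-4, None)
    cv2 = cv_measured ** 2

    noise_floor = 3.0 / math.sqrt(max(scc.n_segments, 1) * 2000.0) \
        if scc.se is None else float(2.0 * np.median(scc.se[sel]))
    if np.max(np.abs(rho)) < max(noise_floor, 0.02):
        return dict(Q=1.0, w=w_init, sigma_h=0.0, residual_norm=float(np.linalg.norm(rho)),
                    converged=True, identifiable=False, se=None,
                    model=np.zeros_like(rho))

    def resid(theta):
        r = _scc_fit_model(theta, k, cv2, decoherence=decoherence) - rho
        return r / sig if sig is not None else r

    best = None
    w_starts = np.concatenate([[w_init], w_init + np.linspace(-0.05, 0.05, 10)])
    w_starts = np.clip(w_starts, _BOUNDS[0][1] + 1e-6, _BOUNDS[1][1] - 1e-6)
    for w0 in w_starts:
        for Q0 in (8.0, 20.0):
            x0 = np.array([Q0, w0, max(0.05, cv_measured)])
            try:
                sol = least_squares(resid, x0, bounds=_BOUNDS, method="trf",
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return dict(Q=float("nan"), w=float("nan"), sigma_h=float("nan"),
                    residual_norm=float("inf"), converged=False,
                    identifiable=False, se=None, model=None)
    Qf, wf, shf = best.x
    se = None
    try:
        jtj = best.jac.T @ best.jac
        dof = max(k.size - 3, 1)
        cov = np.linalg.inv(jtj) * 2.0 * best.cost / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        pass
    model = _scc_fit_model(best.x, k, cv2, decoherence=decoherence)
    return dict(Q=float(Qf), w=float(wf), sigma_h=float(shf),
                residual_norm=float(math.sqrt(2.0 * best.cost)),
                converged=bool(best.success), identifiable=True, se=se,
                model=model)


def d_ou_from_cv(cv_measured: float, Q: float, w: float, sigma_h: float):
    """OU intensity from the measured CV by inverting the closed-form CV.

    D_ou = [CV^2 - CV_harm^2(w, Q, sigma_h)] / 2.  If the harmonic
    contribution alone exceeds the measured CV^2 the result is clipped to 0
    and flagged infeasible.
    """
    gap = cv_measured ** 2 - harmonic_cv2(w, Q, sigma_h)
    if gap < 0:
        return 0.0, False
    return gap / 2.0, True


@dataclass
class FitConfig:
    """Configuration of the extraction pipeline (all times in the spike-file unit)."""

    kmax: int = 100
    n_segments: int = 20
    segment_len: int = 2000
    delta: float = 1e-3
    nperseg: int = 2 ** 14
    tau_ou: float = 0.1
    apply_stationarity: bool = True
    stationarity_window: float = 10.0
    stationarity_tol: float = 0.02
    weighted: bool = False
    lag_range: Optional[tuple] = None
    decoherence: bool = True


def extract_parameters(spike_times, config: Optional[FitConfig] = None) -> FitResult:
    """Full pipeline: spike times -> fitted (Q, w, sigma_h, D_ou).

    Stages: stationarity filter -> ISIs -> unit-mean normalisation ->
    summary statistics -> PSD -> spectral w_init -> SCC with error bars ->
    SCC fit -> CV inversion for D_ou.  Deterministic: the same input always
    produces the same FitResult.
    """
    cfg = config or FitConfig()
    t = np.asarray(spike_times, dtype=float)
    info = {}
    if cfg.apply_stationarity:
        seg = stationarity_filter(t, window=cfg.stationarity_window,
                                  tol=cfg.stationarity_tol)
        if not seg.admissible:
            raise ValueError("stationarity_filter: no admissible segment found")
        info["stationarity_rejected_fraction"] = seg.rejected_fraction
        t = seg.times

    raw = isis(t)
    if raw.size < 4000:
        warnings.warn(f"only {raw.size} ISIs; parameter estimates will be noisy",
                      stacklevel=2)
    norm, scale = normalize_isis(raw)
    summ = summary_stats(norm)
    info["mean_isi"] = scale

    psd = psd_estimate(t, delta=cfg.delta, nperseg=cfg.nperseg)
    w_init = initial_w_from_psd(psd)
    info["psd_rate"] = psd.rate

    scc = scc_errorbars(norm, kmax=cfg.kmax, n_segments=cfg.n_segments,
                        segment_len=cfg.segment_len)
    fit = fit_scc(scc, cv_measured=summ.cv, w_init=w_init,
                  lag_range=cfg.lag_range, weighted=cfg.weighted,
                  decoherence=cfg.decoherence)
    d_ou, feasible = d_ou_from_cv(summ.cv, fit["Q"], fit["w"], fit["sigma_h"]) \
        if fit["identifiable"] else d_ou_from_cv(summ.cv, 10.0, fit["w"], 0.0)
    sigma_ou = math.sqrt(d_ou / cfg.tau_ou)
    return FitResult(
        Q=fit["Q"], w=fit["w"], sigma_h=fit["sigma_h"], d_ou=d_ou,
        sigma_ou=sigma_ou, tau_ou=cfg.tau_ou, cv_measured=summ.cv,
        w_init=w_init, residual_norm=fit["residual_norm"],
        converged=fit["converged"], identifiable=fit["identifiable"],
        d_ou_feasible=feasible, se=fit["se"], summary=summ, scc=scc,
        scc_fit=fit["model"], rate_hz=1.0 / scale if scale > 0 else None,
        stage_info=info)
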
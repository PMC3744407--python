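"""Non-parametric estimators for spike trains.

These operate on any ordered sequence of spike times -- simulated or
recorded -- and mirror the standard analysis chain for long stationary
records: ISI summary statistics, serial correlation coefficients with
segment-based error bars, the correlation lag, the spike-train power
spectral density, and a rate-stationarity filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "ISISummary",
    "SCCSeries",
    "PSDEstimate",
    "CorrelationLagEstimate",
    "StationarySegment",
    "isis",
    "summary_stats",
    "scc_estimate",
    "scc_errorbars",
    "correlation_lag_estimate",
    "psd_estimate",
    "stationarity_filter",
]


def isis(spike_times) -> np.ndarray:
    """Interspike intervals of a strictly increasing spike-time sequence."""
    t = np.asarray(spike_times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two spike times")
    d = np.diff(t)
    if np.any(d <= 0):
        i = int(np.argmax(d <= 0)) + 1
        raise ValueError(f"spike times not strictly increasing at index {i}")
    return d


@dataclass
class ISISummary:
    n: int
    mean: float
    cv: float
    skewness: float


def summary_stats(intervals) -> ISISummary:
    """Mean, CV and skewness of an ISI sequence."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 intervals for skewness")
    m = float(x.mean())
    c = x - m
    m2 = float(np.mean(c ** 2))
    m3 = float(np.mean(c ** 3))
    cv = math.sqrt(m2) / m
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    return ISISummary(n=int(x.size), mean=m, cv=cv, skewness=skew)


@dataclass
class SCCSeries:
    """Serial correlation coefficients rho_k for lags k >= 1."""

    lags: np.ndarray
    rho: np.ndarray
    se: Optional[np.ndarray] = None
    n_segments: int = 0

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=int)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)


def _scc_pooled(x: np.ndarray, kmax: int) -> np.ndarray:
    """Stationary SCC estimator with pooled mean and variance."""
    c = x - x.mean()
    var = float(np.mean(c ** 2))
    if var == 0.0:
        raise ValueError("ISI variance is zero; SCC undefined for constant ISIs")
    out = np.empty(kmax)
    for k in range(1, kmax + 1):
        out[k - 1] = float(np.mean(c[:-k] * c[k:])) / var
    return out


def scc_estimate(intervals, kmax: int) -> SCCSeries:
    """Estimate rho_k for k = 1..kmax using full-sequence mean and variance."""
    x = np.asarray(intervals, dtype=float)
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if x.size <= kmax:
        raise ValueError("need more intervals than the maximum lag")
    if x.size < 10 * kmax:
        warnings.warn(
            f"only {x.size} intervals for kmax={kmax}; SCC estimates will be noisy",
            stacklevel=2)
    return SCCSeries(lags=np.arange(1, kmax + 1), rho=_scc_pooled(x, kmax))


def scc_errorbars(intervals, kmax: int, n_segments: int = 20,
                  segment_len: int = 2000) -> SCCSeries:
    """Pooled SCC with per-lag error bars from consecutive segments.

    The record is split into ``n_segments`` stretches of ``segment_len``
    ISIs; the per-lag SD across segment-wise estimates is reported as the
    error bar.  If the record is too short the number of segments is
    reduced (with a warning); with fewer than 2 usable segments no error
    bars are attached.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < n_segments * segment_len:
        n_segments = int(x.size // segment_len)
        warnings.warn(
            f"record shorter than requested segmentation; using {n_segments} "
            f"segments of {segment_len}", stacklevel=2)
    pooled = scc_estimate(x, kmax)
    if n_segments < 2:
        return SCCSeries(lags=pooled.lags, rho=pooled.rho, se=None, n_segments=n_segments)
    seg_rho = np.empty((n_segments, kmax))
    for i in range(n_segments):
        seg = x[i * segment_len:(i + 1) * segment_len]
        seg_rho[i] = _scc_pooled(seg, kmax)
    se = seg_rho.std(axis=0, ddof=1)
    return SCCSeries(lags=pooled.lags, rho=pooled.rho, se=se, n_segments=n_segments)


@dataclass
class CorrelationLagEstimate:
    value: float
    k_stop: int
    rule: str


def correlation_lag_estimate(scc: SCCSeries, noise_floor_runs: int = 3,
                             kcap: int = 200) -> CorrelationLagEstimate:
    """Correlation lag: sum of |rho_k| up to a noise-floor truncation.

    The unrestricted sum diverges under estimator noise, so summation stops
    at the first run of ``noise_floor_runs`` consecutive lags with
    |rho_k| < 2 SE_k (when error bars are present), capped at ``kcap``.
    """
    absr = np.abs(scc.rho)
    kmax = min(len(absr), kcap)
    stop = kmax
    if scc.se is not None:
        below = absr[:kmax] < 2.0 * scc.se[:kmax]
        run = 0
        for i in range(kmax):
            run = run + 1 if below[i] else 0
            if run >= noise_floor_runs:
                stop = i + 1 - noise_floor_runs
                break
        rule = f"first run of {noise_floor_runs} lags with |rho|<2SE, cap {kcap}"
    else:
        rule = f"cap {kcap} (no error bars)"
    return CorrelationLagEstimate(value=float(absr[:stop].sum()),
                                  k_stop=int(stop), rule=rule)


@dataclass
class PSDEstimate:
    """Welch power spectral density of the mean-subtracted spike train.

    The spike train is binned at sampling interval ``delta`` (each spike a
    rectangular pulse of width delta and height 1/delta) with the mean rate
    subtracted.  ``power`` is the two-sided spectral density shown on
    f >= 0, so a Poisson train has a flat level equal to its rate.
    """

    freqs: np.ndarray
    power: np.ndarray
    delta: float
    rate: float
    duration: float
    welch: dict = field(default_factory=dict)

    def peak_frequency(self, f_lo: float, f_hi: float) -> Optional[float]:
        """Frequency of the highest local maximum in (f_lo, f_hi), if any."""
        sel = (self.freqs > f_lo) & (self.freqs < f_hi)
        if not np.any(sel):
            return None
        f, p = self.freqs[sel], self.power[sel]
        pk, _ = sps.find_peaks(p)
        if pk.size == 0:
            return None
        return float(f[pk[np.argmax(p[pk])]])


def psd_estimate(spike_times, delta: float = 1e-3, nperseg: int = 2 ** 14,
                 window: str = "hann", overlap: float = 0.5) -> PSDEstimate:
    """Welch PSD of a spike train (times in seconds by default).

    For a train with two underlying oscillators the spectrum shows peaks at
    both fundamental frequencies plus sidebands at combination frequencies.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two spikes")
    t = t - t[0]
    duration = float(t[-1])
    nbins = int(math.ceil(duration / delta)) + 1
    if nbins < 2 * nperseg * (1 - overlap) + nperseg:
        raise ValueError(
            f"record too short for Welch estimate: {nbins} bins at delta={delta} "
            f"but nperseg={nperseg}")
    counts = np.bincount(np.minimum((t / delta).astype(int), nbins - 1),
                         minlength=nbins).astype(float)
    x = counts / delta
    rate = x.mean()
    x -= rate
    freqs, pxx = sps.welch(x, fs=1.0 / delta, window=window, nperseg=nperseg,
                           noverlap=int(nperseg * overlap), detrend=False)
    return PSDEstimate(freqs=freqs, power=pxx / 2.0, delta=delta, rate=float(rate),
                       duration=duration,
                       welch=dict(nperseg=nperseg, window=window, overlap=overlap))


@dataclass
class StationarySegment:
    times: np.ndarray
    start: float
    stop: float
    rejected_fraction: float
    admissible: bool


def stationarity_filter(spike_times, window: float = 10.0,
                        tol: float = 0.02) -> StationarySegment:
    """Longest contiguous stretch with a stationary windowed firing rate.

    The firing rate is averaged over a moving window; a stretch is
    admissible when every windowed rate inside it stays within ``+-tol``
    (relative) of the stretch's own mean windowed rate.  Returns the
    longest admissible stretch and the fraction of spikes rejected.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two spikes")
    duration = t[-1] - t[0]
    if duration <= window:
        raise ValueError("recording shorter than the stationarity window")
    step = window / 10.0
    centers = np.arange(t[0] + window / 2.0, t[-1] - window / 2.0 + 1e-12, step)
    lo = np.searchsorted(t, centers - window / 2.0)
    hi = np.searchsorted(t, centers + window / 2.0)
    rates = (hi - lo) / window
    n = rates.size
    cum = np.concatenate([[0.0], np.cumsum(rates)])
    best = (0, -1)  # (length, start index)
    i = 0
    while i < n:
        rmin = rmax = rates[i]
        for j in range(i, n):
            rmin = min(rmin, rates[j])
            rmax = max(rmax, rates[j])
            mean = (cum[j + 1] - cum[i]) / (j - i + 1)
            if max(rmax - mean, mean - rmin) <= tol * mean:
                if j - i + 1 > best[0]:
                    best = (j - i + 1, i)
            else:
                break
        i += 1
    if best[1] < 0:
        return StationarySegment(times=t[:0], start=float("nan"),
                                 stop=float("nan"), rejected_fraction=1.0,
                                 admissible=False)
    i0 = best[1]
    j0 = i0 + best[0] - 1
    start = centers[i0] - window / 2.0
    stop = centers[j0] + window / 2.0
    keep = t[(t >= start) & (t <= stop)]
    return StationarySegment(times=keep, start=float(start), stop=float(stop),
                             rejected_fraction=1.0 - keep.size / t.size,
                             admissible=True)
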
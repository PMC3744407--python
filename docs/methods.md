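# Methods

## Model

The package studies a perfect integrate-and-fire (PIF) neuron whose voltage
integrates a constant base current plus two independent zero-mean Gaussian
noise sources,

    v' = mu + y(t) + eta(t),        spike when v = v_T, reset to v_R,

with the noise *not* reset at spikes.  All computations use canonical
units: time in units of the mean interspike interval (ISI) and voltage in
units of the threshold, i.e. mu = 1, v_T = 1, v_R = 0.  Because the
velocity does not depend on v, the mean ISI equals 1 exactly for any
zero-mean noise, and an optional physical firing rate `rate_hz` only
rescales times on input/output.

`y` is *harmonic noise*, the position of a noise-driven damped harmonic
oscillator

    y' = s,    s' = -gamma s - omega0^2 y + sqrt(2 D_h) xi(t),

a Gaussian stochastic oscillation with spectral peak at the damped
frequency omega1 = sqrt(omega0^2 - gamma^2/4) and bandwidth gamma.  `eta`
is an Ornstein-Uhlenbeck (OU) process with correlation time tau_ou and
stationary SD sigma_ou, broadband ("white-like") when tau_ou << 1.

### Parameters

| name      | meaning                                            | default / range used |
|-----------|----------------------------------------------------|----------------------|
| `w`       | oscillation frequency over firing rate, omega1/2pi | afferent range 0.40-0.61 |
| `Q`       | quality factor omega1/gamma (peak over FWHM)       | afferent range 8.6-29.5 |
| `sigma_h` | stationary SD of y relative to the base current    | afferent range 0.129-0.443 |
| `sigma_ou`| stationary SD of eta relative to the base current  | afferent range 0.084-0.303 |
| `tau_ou`  | OU correlation time, mean-ISI units                | 0.1 (fixed for all fits) |
| `rate_hz` | physical mean rate for unit conversion             | optional |

Derived: gamma = omega1/Q, omega0^2 = omega1^2 + gamma^2/4,
D_h = sigma_h^2 gamma omega0^2 (so Var y = sigma_h^2),
D_ou = sigma_ou^2 tau_ou.  The perturbation parameter is
eps = sigma_h^2 + sigma_ou^2; the closed forms are validated for
predicted CV up to about 0.3, and `epsilon()` flags parameter sets beyond
that.

The Q convention (omega1/gamma rather than omega0/gamma) is pinned by a
spectral-calibration test: the simulated y-spectrum's peak frequency and
FWHM-based quality factor reproduce `w` and `Q` directly.

## Simulation

Spike times are first-passage times of the free process p(t) = t + X(t)
through the integer levels 1, 2, 3, ... , where X is the integrated noise
(reset-equivalence of the PIF).  The simulator advances the linear system
(y, s, eta) *augmented by its exact integral X* with the exact one-step
Gaussian transition of the joint 4-D linear SDE (conditional mean and
covariance from the Van Loan block-exponential).  Noise statistics and
spike positions therefore carry no time-step bias; the only
discretisation effect is linear interpolation of the crossing time inside
a step.  Defaults: dt = 1/500 canonical (refused above 1/(10 omega0)),
100 warm-up spikes discarded to erase the v(0) = 0 phase condition, one
seeded generator per call.  A test verifies the sampled CV moves by less
than 0.5% under dt halving at eps = 0.1.

## Weak-noise theory

Let C(t) be the stationary autocorrelation of the total noise z = y + eta,
F(t) its integral and V(t) = 2 int_0^t (t-s) C(s) ds the variance of X(t).
All closed forms follow from the Gaussian law of (X(t), z(t)) under the
firing ensemble (stationary law tilted by the threshold flux 1 + z):

* **n-th-order interval variance**: Delta V_n = V(n) in leading order;
  the squared CV is V(1).
* **SCC**: rho_k = [V(k+1) - 2V(k) + V(k-1)] / (2 V(1)), evaluated in
  closed form ("general" mode).  For high Q and short tau_ou this
  simplifies to a damped oscillation
  rho_k = (decay^k / CV^2)(b1 cos omega1 k + b2 sin omega1 k) with
  decay = exp(-pi w / Q) per lag ("simplified" mode, the fitting form).
  At w = 1 the sine term vanishes and b1 ~ (1 - cosh(gamma/2)) is tiny:
  the train is nearly renewal when the drive matches the firing rate.
* **CV closed form (simplified)**:
  CV^2 = (2 sigma_h^2/omega1^2) [1 + gamma - e^{-gamma/2}(cos omega1 +
  (3 gamma / 2 omega1) sin omega1)] + 2 D_ou,
  the consistent O(1/Q) truncation of V(1) with white OU noise.  Its
  algebraic inversion for D_ou given a measured CV is exact by
  construction.
* **ISI density**: the threshold flux gives
  p_n(T) = [1 + C(T) + F(T)(n - T - F(T))/V(T)] *
  Normal(n - T; F(T), V(T)).  "Full" mode uses the exact C, F, V
  (any Q, tau_ou); "simplified" mode applies the narrow-band / white-OU
  approximations and requires Q >= 5, tau_ou <= 0.2.  The characteristic
  function of this linear problem is Gaussian-times-linear, so its Fourier
  inversion is analytic and no numerical inversion is needed.  Tiny
  negative perturbative values are clipped and the curve renormalised
  (clipped mass recorded).  Skewness is computed by quadrature on a grid
  spanning at least 8 predicted SDs (tail mass < 1e-6).
* **Correlation lag**: tau_c = sum_{k>=1} |rho_k| of the simplified SCC,
  evaluated analytically by expanding |cos| in its Fourier series and
  summing each harmonic as a geometric series (truncation error ~1e-9
  relative); it matches direct summation to 1e-8 and diverges only in the
  Q -> infinity limit.  Estimated (data-side) correlation lags truncate
  the sum at the first run of 3 lags below twice the per-lag standard
  error, capped at lag 200; the rule is recorded with every estimate.

Validation is oracle-based: at eps = 2.5e-3 the simulated CV, skewness and
rho_1..rho_20 (4e5 ISIs) match the closed forms within Monte-Carlo error
over a grid of w in [0.4, 3] and Q in [5, 50]; the density achieves
Kolmogorov distance < 0.01 against 1e5-ISI samples.

Known limitation: the leading-order SCC envelope decays with the
oscillator bandwidth only.  At experimental noise levels (eps ~ 0.09) the
true envelope decays visibly faster because spike-time jitter accumulates
diffusively and decorrelates the oscillation *as sampled at spike times*.
The discrepancy grows with eps and is strongest in rho_k at mid lags --
expected, documented behaviour of the perturbative result, not a defect.

## Multimodal ISI densities

With a fast (w >= 2), strong (sigma_h ~ 0.5) and highly coherent
(Q >= 100) oscillation at half-integer w, the ISI density splits into two
peaks (intervals shortened or lengthened by the oscillation phase).  Both
the closed-form density and simulated histograms show the same peak
positions.  At sigma_h ~ 0.2 the density is unimodal in both routes:
multimodality genuinely requires eps of order 0.25 or more, outside the
weak-noise regime proper, yet the closed form still locates the peaks.

## Inverse pipeline

`extract_parameters` maps a spike-time sequence to (Q, w, sigma_h, D_ou):

1. stationarity filter: longest contiguous stretch whose 10 s moving-window
   rate stays within +-2% of the stretch mean;
2. ISIs, normalised to unit mean; CV and skewness;
3. Welch PSD of the binned, mean-subtracted train (delta = 1 ms,
   2^14-sample Hann segments, 50% overlap; two-sided density scale so a
   Poisson train sits at its rate); w_init = ratio of the spectral peak in
   (0.25, 0.8) r0 to the peak in (0.8, 1.2) r0, falling back to 0.5;
4. SCC to lag 100 with error bars from 20 segments of 2000 ISIs (per-lag
   SD across segments);
5. nonlinear least squares of the damped-oscillation SCC form with the
   CV prefactor pinned to the measured CV; free parameters (Q, w, sigma_h)
   with bounds Q in [1, 200], w in [0.1, 3], sigma_h in [0, 1]; the
   objective is oscillatory in w, so a mandatory multi-start grid spans
   w_init +- 0.05 (and two Q starts); residuals unweighted by default
   (1/SE weighting switchable);
6. D_ou from the algebraic CV inversion; sigma_ou = sqrt(D_ou/tau_ou) with
   tau_ou fixed at 0.1.

A flat SCC (below the segment noise floor) is flagged unidentifiable:
sigma_h is reported as 0 and D_ou follows from the CV alone -- the w = 1
degeneracy, where the model is observationally close to renewal.

**Decoherence correction.**  Fitting the leading-order SCC form to data
generated at experimental noise levels underestimates Q by 30-50%,
because the measured envelope includes the sampling-jitter decoherence
described above.  The fit model therefore multiplies the envelope by
exp(-omega1^2 (V(k) - V(1))/2), with V the n-th-order variance implied by
the candidate parameters and the measured CV; the factor is normalised to
1 at lag 1 and tends to 1 as eps -> 0, leaving the weak-noise form
intact.  With the correction, median recovery errors over 20 surrogates
of 4e4 ISIs at each reference parameter set are: |w| <= 0.003,
Q <= 8.2%, sigma_h <= 8.1%, D_ou <= 11%.  The correction is on by default
and switchable (`FitConfig.decoherence`).

## Surrogate data

The generator emulates long stationary extracellular records from
electroreceptor afferents: spike counts 15000-50000, rates 37.9-77.7 Hz,
w 0.40-0.61, CV 0.11-0.31, with Q, sigma_h, sigma_ou drawn uniformly and
independently within the printed sample ranges.  It does not emulate
spike-sorting errors, missed spikes, adaptation, or slow drift (beyond a
constructed rate-step test case), so passing recovery tests demonstrate
estimator correctness under the model, not robustness to recording
artifacts.  Every dataset ships a JSON manifest (true parameters, seeds)
and is bit-reproducible from it.

Because the sampled unit parameters are independent, population-level
statistics that depend on their joint distribution (e.g. the strength of
the Q vs correlation-lag correlation across units) need not match a real
sample, where parameters co-vary; the package asserts the qualitative
trends (positive coherence trend, resonance at w = 1/2) only.

## Numerical choices and problem sizes

Theory-vs-simulation checks use 4e5 ISIs per parameter set (Monte-Carlo
SE via 20-segment replication); recovery studies use 20 replicates of
4e4 ISIs per reference set; the dt-halving check uses 3e5 ISIs.  These
sizes put Monte-Carlo error well below the tolerances being asserted
while keeping the full suite to a few minutes.  Simultaneous 3-SE
comparisons across ~400 statistics are judged family-wise (no excursion
beyond 5 SE, at most 2% beyond 3 SE), since isolated 3-sigma excursions
are expected by chance at that multiplicity.
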
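# oscspike

Spike-train statistics of neurons driven by **stochastic oscillations** —
narrow-band noise such as epithelial oscillations forcing electroreceptor
afferents, network rhythms, or subthreshold periodicities with limited
phase coherence.

The package implements, for a perfect integrate-and-fire (PIF) neuron
driven by harmonic noise (a noise-driven damped oscillator `y`) plus
broadband Ornstein–Uhlenbeck noise `eta`,

    v' = mu + y(t) + eta(t),   spike at v_T, reset to v_R, noise not reset,

* an exact-transition stochastic **simulator** (no time-step bias in the
  noise statistics),
* closed-form weak-noise **ISI statistics**: the n-th-order interval
  density and variance, CV, skewness, serial correlation coefficients
  (SCC), and the correlation lag `tau_c = sum_k |rho_k|`,
* non-parametric **spike-train estimators** (ISI summary, SCC with
  segment error bars, Welch power spectra, a rate-stationarity filter),
* the **inverse pipeline**: from a measured spike train alone, recover the
  driving oscillator's quality factor `Q`, frequency ratio `w`
  (oscillation frequency / firing rate), amplitude `sigma_h`, and the
  broadband intensity `D_ou`, by fitting the damped-oscillation SCC form
  and inverting the CV formula,
* seeded **surrogate data** emulating a sample of paddlefish
  electroreceptor afferents (rates 37.9–77.7 Hz, w 0.40–0.61,
  15000–50000 spikes), with golden parameter rows for three reference
  afferents.

The central closed form: for a coherent oscillation (`Q >> 1`, short
`tau_ou`) the ISI serial correlations are a damped oscillation in the lag,

    rho_k = (e^{-pi w k / Q} / CV^2) (b1 cos 2 pi w k + b2 sin 2 pi w k),

and the squared CV is

    CV^2 = (2 sigma_h^2 / omega1^2) [1 + gamma - e^{-gamma/2}(cos omega1
           + (3 gamma / 2 omega1) sin omega1)] + 2 D_ou,

with `omega1 = 2 pi w`, `gamma = omega1 / Q`.  These two expressions make
the inverse problem tractable: the SCC fit carries (Q, w, sigma_h) and
the measured CV pins `D_ou`.

## Worked example

```python
import oscspike as osc

# reference afferent 1: 53 Hz, oscillation at 0.408 x firing rate
params, cv_measured, rate = osc.table1_params(1)
train = osc.simulate(params, n_spikes=40_001, seed=42)
result = osc.extract_parameters(train.times)
print(f"{result.w:.4f} {result.Q:.2f} {result.sigma_h:.3f} {result.d_ou:.2e}")
```

prints (seed 42)

```
0.4060 17.90 0.184 5.56e-03
```

against ground truth `w=0.408, Q=16.40, sigma_h=0.197, D_ou=5.10e-03`:
the oscillation frequency is recovered to three decimals, its coherence
and amplitude to ~10%, from nothing but a list of spike times.  The
closed-form CV at the fitted afferent parameters reproduces the measured
CV (0.1802 vs 0.181) because the broadband intensity is defined by the
algebraic inversion of the same formula.

The `examples/` directory holds one short script per capability
(simulation + summary statistics, theory curves across the frequency
ratio, parameter extraction, population trends); each prints the numbers
it computes and what they mean.  A thin CLI mirrors the library:

```
oscspike simulate --w 0.45 --q 18 --sigma-h 0.2 --sigma-ou 0.15 \
    --rate-hz 50 --n 20000 --seed 1 --out spikes.txt
oscspike stats spikes.txt --scc-kmax 100
oscspike fit spikes.txt --out fit.json
```

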
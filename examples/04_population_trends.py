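"""Population-level trends across a sample of surrogate afferents.

Draws a 56-unit parameter sample from the observed afferent ranges and
evaluates the sample-averaged tendency of the correlation lag while
sweeping the oscillation coherence Q, then while sweeping the frequency
ratio w.
"""

import numpy as np
from scipy.stats import spearmanr

import oscspike as osc

sets = osc.sample_population(56, seed=7)

grid_q = np.linspace(5, 30, 6)
mean_q, sd_q = osc.population_trend(sets, "Q", grid_q, stat="corrlag")
print("correlation lag vs oscillation coherence (mean +- SD over 56 units):")
for g, m, s in zip(grid_q, mean_q, sd_q):
    print(f"  Q={g:5.1f}:  tau_c = {m:6.2f} +- {s:5.2f}")
print("-> more coherent driving oscillations sustain ISI correlations longer.")

grid_w = np.array([0.44, 0.47, 0.50, 0.53, 0.56])
mean_w, sd_w = osc.population_trend(sets, "w", grid_w, stat="corrlag")
print("\ncorrelation lag vs frequency ratio:")
for g, m, s in zip(grid_w, mean_w, sd_w):
    print(f"  w={g:4.2f}:  tau_c = {m:6.2f} +- {s:5.2f}")
print("-> a resonant local maximum at w = 1/2: exactly two spikes per")
print("   oscillation cycle lock the interval alternation to the drive.")

tc = [osc.correlation_lag_theory(p) for p in sets]
rho = spearmanr([p.Q for p in sets], tc).statistic
print(f"\nSpearman correlation of per-unit Q with per-unit tau_c: {rho:.2f}")
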
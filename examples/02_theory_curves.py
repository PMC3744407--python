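"""Closed-form ISI statistics as the oscillation frequency is varied.

Sweeps the frequency ratio w (oscillation frequency over firing rate) and
prints the CV, skewness and correlation lag.  The CV dips at integer w
(driving at a multiple of the firing rate regularises spiking), the
skewness alternates sign between the half-integer bands, and the
correlation lag peaks sharply at w = 1/2 and nearly vanishes at integer w.
"""

import oscspike as osc

base = osc.CanonicalParams(w=0.5, Q=20.0, sigma_h=0.2, sigma_ou=0.05,
                           tau_ou=0.1)
print(" w      CV      skewness   corr-lag tau_c")
for w in (0.3, 0.4, 0.5, 0.6, 0.75, 1.0, 1.25, 1.5, 2.0):
    p = base.replace(w=w)
    print(f"{w:4.2f}  {osc.cv_theory(p):7.4f}  {osc.skewness_theory(p):+8.3f}"
          f"  {osc.correlation_lag_theory(p):10.3f}")

p = base
curve = osc.isi_density(None, p, mode="full")
mode_t = curve.grid[curve.values.argmax()]
print(f"\nISI density at w=0.5: peaks at T={mode_t:.3f} mean-ISI units; "
      "the drive at half the firing rate makes adjacent intervals")
print("anticorrelated (short-long alternation), giving the long correlation "
      "lag above.")
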
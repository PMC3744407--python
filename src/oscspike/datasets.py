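"""Reference parameter sets and seeded surrogate spike-train data.

Three fitted parameter sets for representative electroreceptor afferents
(frequency ratios below, near and above one half) are bundled as golden
rows, together with the printed population ranges of the full 56-unit
afferent sample.  Surrogate spike trains generated from these parameters
by the model simulator stand in for the recordings, so the whole analysis
pipeline is testable without any data download; each dataset ships a JSON
manifest with the ground-truth parameters and seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import math
import numpy as np

from .io import write_spike_times
from .params import CanonicalParams
from .simulate import simulate

__all__ = ["Table1Row", "TABLE1", "table1_params", "PopulationRanges",
           "sample_population", "surrogate_dataset"]

DEFAULT_TAU_OU = 0.1  # OU correlation time, in mean-ISI units, used throughout


@dataclass(frozen=True)
class Table1Row:
    afferent: int
    rate_hz: float
    cv: float
    w: float
    Q: float
    sigma_h: float
    d_ou: float

    def params(self, tau_ou: float = DEFAULT_TAU_OU) -> CanonicalParams:
        return CanonicalParams(w=self.w, Q=self.Q, sigma_h=self.sigma_h,
                               sigma_ou=math.sqrt(self.d_ou / tau_ou),
                               tau_ou=tau_ou, rate_hz=self.rate_hz)


TABLE1 = {
    1: Table1Row(1, 53.00, 0.181, 0.408, 16.40, 0.197, 5.10e-3),
    2: Table1Row(2, 49.42, 0.153, 0.495, 22.38, 0.198, 3.20e-3),
    3: Table1Row(3, 38.29, 0.164, 0.591, 19.38, 0.224, 6.10e-3),
}


def table1_params(afferent_id: int, tau_ou: float = DEFAULT_TAU_OU):
    """Golden fitted parameters of one reference afferent.

    Returns (CanonicalParams, measured CV, mean rate in Hz).
    """
    try:
        row = TABLE1[int(afferent_id)]
    except (KeyError, ValueError):
        raise KeyError(f"unknown afferent id {afferent_id!r}; have {sorted(TABLE1)}")
    return row.params(tau_ou), row.cv, row.rate_hz


@dataclass(frozen=True)
class PopulationRanges:
    """Printed parameter ranges of the 56-unit afferent sample."""

    rate_hz: tuple = (37.9, 77.7)
    w: tuple = (0.40, 0.61)
    cv: tuple = (0.11, 0.31)
    Q: tuple = (8.570, 29.46)
    sigma_h: tuple = (0.129, 0.443)
    sigma_ou: tuple = (0.084, 0.303)
    n_units: int = 56
    n_isis: tuple = (15000, 50000)


def sample_population(n: int, seed=None,
                      ranges: PopulationRanges = PopulationRanges()
                      ) -> List[CanonicalParams]:
    """Draw n parameter sets uniformly within the population ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(CanonicalParams(
            w=rng.uniform(*ranges.w),
            Q=rng.uniform(*ranges.Q),
            sigma_h=rng.uniform(*ranges.sigma_h),
            sigma_ou=rng.uniform(*ranges.sigma_ou),
            tau_ou=DEFAULT_TAU_OU,
            rate_hz=rng.uniform(*ranges.rate_hz),
        ))
    return out


def surrogate_dataset(param_sets: Sequence[CanonicalParams], n_isis: int,
                      seed: int, out_dir: Union[str, Path],
                      dt: float = 1.0 / 500.0) -> dict:
    """Simulate one spike-time file per parameter set, plus a JSON manifest.

    The manifest records the true parameters and the per-unit seed, making
    every file reproducible and enabling parameter-recovery scoring.
    """
    if n_isis < 1000:
        raise ValueError("n_isis must be >= 1000 for meaningful statistics")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    units = []
    for i, p in enumerate(param_sets):
        unit_seed = int(seed) + i
        train = simulate(p, n_spikes=n_isis + 1, dt=dt, seed=unit_seed)
        fname = f"unit{i:03d}.txt"
        write_spike_times(out_dir / fname, train.times, rate_hz=p.rate_hz,
                          seed=unit_seed)
        units.append(dict(file=fname, seed=unit_seed, n_isis=n_isis,
                          params=p.to_dict()))
    manifest = dict(seed=int(seed), dt=dt, units=units)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
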
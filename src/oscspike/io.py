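"""Plain-text spike-time files and run configuration.

Spike files hold one timestamp per line (seconds, or canonical units when
no physical rate applies); lines starting with '#' are comments.  The
writer records provenance (rate, seed) in the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .params import CanonicalParams

__all__ = ["read_spike_times", "write_spike_times", "load_config", "save_config"]


def read_spike_times(path: Union[str, Path]) -> np.ndarray:
    """Read a spike-time file, skipping '#' comment lines."""
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            times.append(float(line))
    return np.asarray(times, dtype=float)


def write_spike_times(path: Union[str, Path], times, rate_hz: Optional[float] = None,
                      seed: Optional[int] = None, **extra) -> None:
    """Write spike times, one per line, with provenance comments."""
    meta = {}
    if rate_hz is not None:
        meta["rate_hz"] = rate_hz
    if seed is not None:
        meta["seed"] = seed
    meta.update(extra)
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + ", ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        for t in np.asarray(times, dtype=float):
            fh.write(f"{t:.9f}\n")


def load_config(path: Union[str, Path]) -> CanonicalParams:
    """Load a CanonicalParams config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return CanonicalParams.from_dict(data)


def save_config(path: Union[str, Path], params: CanonicalParams) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
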
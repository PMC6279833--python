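"""Paired voltage/calcium time series for one (averaged) paced beat."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np


@dataclass
class Trace:
    """One paced beat of membrane potential and cytosolic calcium.

    ``t`` is in ms on a uniform grid with t=0 at the stimulus onset (or at the
    re-zeroed upstroke for averaged optical recordings).  Simulated traces
    carry ``v`` in mV and ``ca`` in mM; measured (optical) traces are in
    arbitrary units with ``provenance='measured'``.
    """

    t: np.ndarray
    v: np.ndarray
    ca: np.ndarray
    pacing_period: float = 1000.0
    currents: Optional[Dict[str, np.ndarray]] = None
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if not (len(self.t) == len(self.v) == len(self.ca)):
            raise ValueError("t, v, ca must have equal length")
        if len(self.t) < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
            raise ValueError("time grid must be uniform")
        if self.provenance not in ("simulated", "measured"):
            raise ValueError(f"provenance must be 'simulated' or 'measured', got {self.provenance!r}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def copy(self) -> "Trace":
        cur = None if self.currents is None else {k: v.copy() for k, v in self.currents.items()}
        return Trace(self.t.copy(), self.v.copy(), self.ca.copy(),
                     self.pacing_period, cur, self.provenance)
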
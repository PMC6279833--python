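"""Scalar waveform characteristics of one AP / calcium-transient beat.

Eight features drive the inversion cost: the voltage integral over the 30%
transient, the voltage transient durations APD30/50/80, the maximal calcium
upstroke velocity (dc/dt)max, and the calcium transient durations at the same
three levels.  Durations are measured between level crossings relative to the
baseline-to-peak amplitude, which makes every duration feature invariant
under positive affine rescaling of the signal — the property that lets
arbitrary-unit optical traces be compared with simulated traces in mV/mM.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np

from cardioinverse.trace import Trace


class FeatureError(ValueError):
    """A feature is undefined on the given trace (e.g. no repolarization)."""


@dataclass
class FeatureSet:
    int_v: float       # integral of v over [t0, t1] (mV*ms or a.u.*ms)
    apd_v30: float     # ms
    apd_v50: float
    apd_v80: float
    dcdt_max: float    # mM/ms or a.u./ms
    apd_ca30: float
    apd_ca50: float
    apd_ca80: float
    t0: float          # 30%-level upstroke crossing of v, ms
    t1: float          # 30%-level repolarization crossing of v, ms

    def as_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.as_dict().items():
                fh.write(f"{k}\t{v!r}\n")


def _baseline_and_peak(t: np.ndarray, x: np.ndarray) -> Tuple[float, float]:
    """Baseline = minimum over the pre-upstroke window, peak = global max."""
    dx = np.diff(x)
    i_up = int(np.argmax(dx))
    if i_up > 0:
        base = float(np.min(x[: i_up + 1]))
    else:
        base = float(np.min(x))
    return base, float(np.max(x))


def _count_excursions(x: np.ndarray, thr: float, reset: float) -> int:
    """Number of suprathreshold excursions with hysteresis at ``reset``."""
    n = 0
    armed = True
    for xi in x:
        if armed and xi >= thr:
            n += 1
            armed = False
        elif not armed and xi < reset:
            armed = True
    return n


def transient_duration(t: np.ndarray, x: np.ndarray, percent: float) -> Tuple[float, float, float]:
    """Duration of the transient at a repolarization level.

    ``percent=30`` gives the time from the upstroke crossing of the level 30%
    below the peak (relative to the baseline-to-peak amplitude) until the
    signal repolarizes back through the same level.  Crossings are located by
    linear interpolation; flat segments at the threshold resolve to the
    earliest sample.  Returns ``(duration, t_start, t_end)`` in the units of
    ``t``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if not 0.0 < percent < 100.0:
        raise ValueError(f"percent must be in (0, 100), got {percent}")
    if len(t) != len(x) or len(t) < 3:
        raise ValueError("need equally long t, x with >= 3 samples")
    base, peak = _baseline_and_peak(t, x)
    amp = peak - base
    if amp <= 0:
        raise FeatureError("no transient: peak does not exceed baseline")
    thr = peak - (percent / 100.0) * amp
    n_beats = _count_excursions(x, thr, thr - 0.05 * amp)
    if n_beats > 1:
        raise FeatureError(f"multiple beats detected ({n_beats} excursions above the {percent}% level)")

    above = x >= thr
    if not above.any():
        raise FeatureError(f"duration undefined: trace never reaches the {percent}% level")
    i_first = int(np.argmax(above))
    if i_first == 0:
        t_start = float(t[0])
    else:
        x0, x1_ = x[i_first - 1], x[i_first]
        t_start = float(t[i_first - 1] + (thr - x0) / (x1_ - x0) * (t[i_first] - t[i_first - 1]))
    below_after = np.where(~above[i_first:])[0]
    if len(below_after) == 0:
        raise FeatureError(f"duration undefined: trace does not repolarize through the {percent}% level")
    i_down = i_first + int(below_after[0])      # first sample back below threshold
    x0, x1_ = x[i_down - 1], x[i_down]
    t_end = float(t[i_down - 1] + (thr - x0) / (x1_ - x0) * (t[i_down] - t[i_down - 1]))
    return t_end - t_start, t_start, t_end


def max_upstroke(t: np.ndarray, ca: np.ndarray) -> Tuple[float, float]:
    """Maximal upstroke velocity and its time (central differences inside)."""
    t = np.asarray(t, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    d = np.gradient(ca, t)
    i = int(np.argmax(d))
    return float(d[i]), float(t[i])


def voltage_integral(t: np.ndarray, v: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoidal integral of v over [t0, t1] with interpolated endpoints."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if not t0 < t1:
        raise ValueError(f"require t0 < t1, got ({t0}, {t1})")
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(f"[{t0}, {t1}] outside trace span [{t[0]}, {t[-1]}]")
    inside = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inside], [t1]))
    vv = np.concatenate(([np.interp(t0, t, v)], v[inside], [np.interp(t1, t, v)]))
    return float(np.trapezoid(vv, tt))


def extract_features(trace: Trace, normalize: bool | None = None) -> FeatureSet:
    """All eight features of a single-beat trace.

    ``normalize=True`` min-max rescales both channels to [0, 1] before the
    scale-dependent features (voltage integral, calcium upstroke velocity) are
    computed; default is to normalize measured (arbitrary-unit) traces and to
    leave simulated traces in physical units.  Duration features are affine
    invariant either way.
    """
    if normalize is None:
        normalize = trace.provenance == "measured"
    v = trace.v
    ca = trace.ca
    if normalize:
        v = (v - v.min()) / (v.max() - v.min())
        ca = (ca - ca.min()) / (ca.max() - ca.min())

    apd_v30, t0, t1 = transient_duration(trace.t, v, 30)
    apd_v50, _, _ = transient_duration(trace.t, v, 50)
    apd_v80, _, _ = transient_duration(trace.t, v, 80)
    apd_ca30, _, _ = transient_duration(trace.t, ca, 30)
    apd_ca50, _, _ = transient_duration(trace.t, ca, 50)
    apd_ca80, _, _ = transient_duration(trace.t, ca, 80)
    dcdt, _ = max_upstroke(trace.t, ca)
    if dcdt <= 0:
        raise FeatureError("calcium upstroke velocity is not positive")
    iv = voltage_integral(trace.t, v, t0, t1)
    return FeatureSet(int_v=iv, apd_v30=apd_v30, apd_v50=apd_v50, apd_v80=apd_v80,
                      dcdt_max=dcdt, apd_ca30=apd_ca30, apd_ca50=apd_ca50,
                      apd_ca80=apd_ca80, t0=t0, t1=t1)
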
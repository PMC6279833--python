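"""Trace file I/O and 1-D optical-recording preprocessing.

Optical MPS recordings arrive as fluorescence intensity series (~100 frames/s,
6-8 s, paced at 1 Hz).  Preprocessing follows the standard recipe: 3-point
median filtering, beat segmentation, alignment of beats at their maximum
discrete dF/dt, outlier-beat exclusion, and pointwise averaging into a single
representative transient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from cardioinverse.trace import Trace

log = logging.getLogger(__name__)

#: pre-upstroke margin retained ahead of the aligned upstroke sample, ms
PRE_UPSTROKE_MARGIN_MS = 100.0


@dataclass
class RawRecording:
    """A raw single-channel fluorescence recording."""

    t: np.ndarray          # ms
    signal: np.ndarray     # a.u.
    channel: str           # 'voltage' | 'calcium'
    frame_rate: float      # Hz

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(self.t) != len(self.signal):
            raise ValueError("t and signal must have equal length")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise ValueError("recording must be uniformly sampled")
        if self.channel not in ("voltage", "calcium"):
            raise ValueError("channel must be 'voltage' or 'calcium'")


def median_filter3(signal: np.ndarray) -> np.ndarray:
    """3-point running median; endpoints pass through unchanged."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 3:
        return x.copy()
    out = x.copy()
    stacked = np.vstack([x[:-2], x[1:-1], x[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def _upstroke_indices(signal: np.ndarray, dt_ms: float, pacing_period: float) -> List[int]:
    """Per-beat maximum discrete dF/dt sample indices.

    Candidate upstrokes are local maxima of the forward difference exceeding
    half the global maximum, separated by at least half a pacing period.
    """
    d = np.diff(signal)
    thr = 0.5 * d.max()
    min_sep = int(0.5 * pacing_period / dt_ms)
    idx = []
    order = np.argsort(d)[::-1]
    for i in order:
        if d[i] < thr:
            break
        if all(abs(i - k) >= min_sep for k in idx):
            idx.append(int(i))
    return sorted(idx)


def segment_and_average(rec: RawRecording, pacing_period: float = 1000.0,
                        n_beats: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Align beats at maximum dF/dt and average into one transient.

    Returns ``(t, signal)`` for one averaged beat of length one pacing period,
    re-zeroed at the aligned upstroke minus a fixed pre-upstroke margin.
    Beats whose inter-upstroke interval deviates more than 20% from the pacing
    period, or whose RMS deviation from the provisional mean exceeds 3x the
    median RMS deviation, are excluded (logged).
    """
    dt = 1000.0 / rec.frame_rate
    sig = median_filter3(rec.signal)
    ups = _upstroke_indices(sig, dt, pacing_period)
    if n_beats is not None and len(ups) < n_beats:
        raise ValueError(f"found {len(ups)} beats, fewer than the requested {n_beats}")
    if len(ups) < 2:
        raise ValueError("need at least two detected beats to segment")

    # drop beats with irregular inter-upstroke intervals
    keep = []
    for k, u in enumerate(ups):
        neigh = []
        if k > 0:
            neigh.append((ups[k] - ups[k - 1]) * dt)
        if k + 1 < len(ups):
            neigh.append((ups[k + 1] - ups[k]) * dt)
        if any(abs(iv - pacing_period) / pacing_period <= 0.2 for iv in neigh):
            keep.append(u)
        else:
            log.info("excluding beat at %.0f ms: inter-upstroke interval off by >20%%", u * dt)
    ups = keep

    pre = int(round(PRE_UPSTROKE_MARGIN_MS / dt))
    n_win = int(round(pacing_period / dt))
    windows = []
    for u in ups:
        a, b = u - pre, u - pre + n_win
        if a >= 0 and b <= len(sig):
            windows.append(sig[a:b])
    if n_beats is not None:
        windows = windows[:n_beats]
    if not windows:
        raise ValueError("no complete beat window inside the recording")
    W = np.vstack(windows)

    # outlier exclusion: RMS deviation from provisional mean > 3x median RMS
    mean0 = W.mean(axis=0)
    rms = np.sqrt(((W - mean0) ** 2).mean(axis=1))
    med = np.median(rms)
    if med > 0:
        good = rms <= 3.0 * med
        for k in np.where(~good)[0]:
            log.info("excluding beat %d: RMS deviation %.3g > 3x median %.3g", k, rms[k], med)
        W = W[good]
    avg = W.mean(axis=0)
    t = np.arange(n_win) * dt
    return t, avg


def preprocess_pair(v_rec: RawRecording, ca_rec: RawRecording,
                    pacing_period: float = 1000.0, n_beats: Optional[int] = None) -> Trace:
    """Average both channels and assemble a measured single-beat Trace."""
    tv, v = segment_and_average(v_rec, pacing_period, n_beats)
    tc, ca = segment_and_average(ca_rec, pacing_period, n_beats)
    n = min(len(tv), len(tc))
    return Trace(tv[:n], v[:n], ca[:n], pacing_period=pacing_period, provenance="measured")


def write_trace_csv(trace: Trace, path, meta_path=None) -> None:
    """CSV with columns time_ms, v, ca (plus per-current columns if present)."""
    data = {"time_ms": trace.t, "v": trace.v, "ca": trace.ca}
    if trace.currents:
        for k, series in trace.currents.items():
            data[f"current_{k}"] = series
    # default float repr is shortest-round-trip; paired with the
    # round_trip parser below the CSV is lossless
    pd.DataFrame(data).to_csv(path, index=False)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            fh.write(f"pacing_period\t{trace.pacing_period!r}\n")
            fh.write(f"provenance\t{trace.provenance}\n")


def read_trace_csv(path, meta_path=None) -> Trace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_ms", "v", "ca"} - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} is missing column(s) {sorted(missing)}")
    currents = None
    cur_cols = [c for c in df.columns if c.startswith("current_")]
    if cur_cols:
        currents = {c[len("current_"):]: df[c].to_numpy() for c in cur_cols}
    pacing_period = 1000.0
    provenance = "simulated"
    if meta_path is not None:
        with open(meta_path) as fh:
            for line in fh:
                parts = line.strip().split("\t")
                if len(parts) != 2:
                    continue
                if parts[0] == "pacing_period":
                    pacing_period = float(parts[1])
                elif parts[0] == "provenance":
                    provenance = parts[1]
    return Trace(df["time_ms"].to_numpy(), df["v"].to_numpy(), df["ca"].to_numpy(),
                 pacing_period=pacing_period, currents=currents, provenance=provenance)
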
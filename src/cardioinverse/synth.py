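"""Synthetic pseudo-measured datasets with known ground-truth blocks.

Generates paired control/drug beats by simulating the base model with a
specified block vector, optionally dressed up as optical MPS data: per-channel
positive affine rescaling into arbitrary units, additive Gaussian noise, and
100 frames/s sampling.  The ground truth is always returned alongside the
data so downstream recovery can be scored.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from cardioinverse.models import CellModel, PacingProtocol, simulate, EVAL_PROTOCOL
from cardioinverse.parameters import ParameterVector, BlockVector, apply_block
from cardioinverse.trace import Trace

#: optical acquisition rate of the emulated MPS recordings, Hz
OPTICAL_FRAME_RATE = 100.0


def drug_presets() -> Dict[str, BlockVector]:
    """Simulated reference-compound block vectors.

    ``verapamil_sim`` blocks I_CaL by 50% and I_Kr by 25% (multichannel
    blocker); ``cisapride_sim`` blocks I_Kr by 50% (selective hERG blocker).
    """
    return {
        "verapamil_sim": BlockVector({"I_CaL": -0.5, "I_Kr": -0.25}, mode="drug"),
        "cisapride_sim": BlockVector({"I_Kr": -0.5}, mode="drug"),
    }


def get_preset(name: str) -> BlockVector:
    presets = drug_presets()
    if name not in presets:
        raise KeyError(f"unknown drug preset {name!r}; available: {sorted(presets)}")
    return presets[name]


def _resample(trace: Trace, frame_rate_hz: float) -> Trace:
    dt = 1000.0 / frame_rate_hz
    t_new = np.arange(0.0, trace.t[-1] + 1e-9, dt)
    return Trace(t_new, np.interp(t_new, trace.t, trace.v),
                 np.interp(t_new, trace.t, trace.ca),
                 pacing_period=trace.pacing_period, provenance=trace.provenance)


def _opticalize(trace: Trace, rng: np.random.Generator, noise_sd: float,
                arbitrary_units: bool, frame_rate_hz: Optional[float]) -> Trace:
    tr = trace
    if frame_rate_hz is not None:
        tr = _resample(tr, frame_rate_hz)
    v, ca = tr.v.copy(), tr.ca.copy()
    if arbitrary_units:
        # positive gain, arbitrary offset per channel, as for raw fluorescence
        v = rng.uniform(0.5, 5.0) * v + rng.uniform(-50.0, 50.0)
        ca = rng.uniform(50.0, 5000.0) * ca + rng.uniform(0.0, 10.0)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd * (v.max() - v.min()), size=v.shape)
        ca = ca + rng.normal(0.0, noise_sd * (ca.max() - ca.min()), size=ca.shape)
    prov = "measured" if (arbitrary_units or noise_sd > 0) else tr.provenance
    return Trace(tr.t, v, ca, pacing_period=tr.pacing_period, provenance=prov)


def simulate_drug_dataset(model: CellModel, base_p: ParameterVector, truth: BlockVector,
                          noise_sd: float = 0.0, arbitrary_units: bool = False,
                          seed: int = 0, protocol: Optional[PacingProtocol] = None,
                          frame_rate_hz: Optional[float] = None
                          ) -> Tuple[Trace, Trace, BlockVector]:
    """Simulate a (control, drugged) beat pair with known ground truth.

    With ``noise_sd=0`` and ``arbitrary_units=False`` the drugged trace is the
    direct simulation of ``apply_block(base_p, truth)``.  ``noise_sd`` is
    relative to each channel's amplitude.  ``frame_rate_hz`` resamples to an
    optical-style grid (e.g. 100 Hz).
    """
    if truth.mode != "drug":
        raise ValueError("ground-truth block vector must be in drug mode")
    proto = protocol or EVAL_PROTOCOL
    rng = np.random.default_rng(seed)
    control = simulate(model, base_p, proto)
    drugged = simulate(model, apply_block(base_p, truth), proto)
    if noise_sd > 0 or arbitrary_units or frame_rate_hz is not None:
        control = _opticalize(control, rng, noise_sd, arbitrary_units, frame_rate_hz)
        drugged = _opticalize(drugged, rng, noise_sd, arbitrary_units, frame_rate_hz)
    return control, drugged, truth


def make_optical_recording(trace: Trace, n_beats: int = 6, noise_sd: float = 0.01,
                           jitter_ms: float = 5.0, seed: int = 0,
                           frame_rate_hz: float = OPTICAL_FRAME_RATE,
                           channel: str = "voltage"):
    """Tile one beat into a multi-beat raw fluorescence recording.

    Emulates a 1 Hz-paced acquisition of ``n_beats`` beats at the optical
    frame rate with per-beat onset jitter and additive Gaussian noise, for
    exercising the preprocessing chain (median filter, alignment, averaging).
    """
    from cardioinverse.traceio import RawRecording

    rng = np.random.default_rng(seed)
    dt = 1000.0 / frame_rate_hz
    period = trace.pacing_period
    sig_src = trace.v if channel == "voltage" else trace.ca
    n_total = int(round((n_beats + 0.5) * period / dt))
    t = np.arange(n_total) * dt
    # half-period lead-in of baseline before the first beat
    sig = np.full(n_total, sig_src[0], dtype=float)
    for b in range(n_beats):
        onset = (b + 0.5) * period + rng.uniform(-jitter_ms, jitter_ms)
        local = t - onset
        m = (local >= 0) & (local <= trace.t[-1])
        sig[m] = np.interp(local[m], trace.t, sig_src)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd * (sig.max() - sig.min()), size=sig.shape)
    return RawRecording(t=t, signal=sig, channel=channel, frame_rate=frame_rate_hz)


def save_truth(truth: BlockVector, path) -> None:
    with open(path, "w") as fh:
        for k, v in truth.values.items():
            fh.write(f"{k}\t{v!r}\n")
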
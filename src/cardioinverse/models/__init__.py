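"""Conductance-scalable cell models and the pacing/simulation engine.

The two concrete models are the Paci 2013 ventricular hiPSC-CM model (the
immature base model) and the ten Tusscher 2006 epicardial model (the adult
reference).  Both expose the same contract: a right-hand side in which every
scalable current/flux appears exactly once behind a named multiplicative
factor, so that a :class:`~cardioinverse.parameters.ParameterVector` of ones
reproduces the published model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from scipy.integrate import odeint

from cardioinverse.parameters import ParameterVector, GEOMETRY_KEY
from cardioinverse.trace import Trace
from cardioinverse.models import paci2013, tentusscher2006


class SimulationError(RuntimeError):
    """Stiff-solver failure or non-finite state during integration."""


@dataclass(frozen=True)
class PacingProtocol:
    """Square-pulse field pacing at a fixed period.

    Amplitude is in A/F (depolarizing); when amplitude or duration is left as
    None, the model's published pacing pulse is used (the immature and adult
    models need very different stimulus strengths for 1:1 capture).  ``n_prepace`` beats are run to (quasi-)steady state
    before ``n_record`` beats are kept on a uniform ``dt_ms`` output grid.
    ``start_from='paced'`` begins from the cached 1 Hz paced state of the
    unscaled model rather than the published initial state.
    """

    period_ms: float = 1000.0
    stim_duration_ms: Optional[float] = None    # None -> model default
    stim_amplitude: Optional[float] = None      # A/F; None -> model default
    n_prepace: int = 50
    n_record: int = 1
    dt_ms: float = 1.0
    start_from: str = "y0"          # 'y0' | 'paced'
    rtol: float = 1e-6
    atol: float = 1e-8


#: canonical evaluation protocol used for cost evaluations and synthetic
#: targets alike: one conditioning beat under the candidate parameters,
#: starting from the cached 1 Hz paced state of the unscaled model, with
#: features taken from the following beat.  Using the identical protocol on
#: both sides of the cost keeps the inversion consistent at desk scale.
EVAL_PROTOCOL = PacingProtocol(n_prepace=1, n_record=1, start_from="paced")


@dataclass
class CellModel:
    """A conductance-scalable AP model with per-current bookkeeping."""

    name: str
    state_names: Tuple[str, ...]
    parameter_names: Tuple[str, ...]
    base_conductances: Dict[str, Tuple[float, str]]
    geometry: Dict[str, float]
    y0: np.ndarray
    default_stim_amplitude: float = 5.5     # A/F
    default_stim_duration_ms: float = 5.0
    _rhs: Callable = field(repr=False, default=None)
    _currents: Callable = field(repr=False, default=None)
    t_native_per_ms: float = 1.0
    v_to_mv: float = 1.0
    v_index: int = 0
    cai_index: int = 0
    #: machine-readable record of deviations from the published equations
    changelog: Dict[str, str] = field(default_factory=dict)
    #: conductance patch applied on top of the published values
    patch: Dict[str, float] = field(default_factory=dict)

    def scale_array(self, p: Optional[ParameterVector]) -> Tuple[np.ndarray, float]:
        """Aligned (scales, geometry) pair for the jitted right-hand side.

        The patch folds into the scale array so that patched conductances act
        exactly like the published ones times a fixed factor.
        """
        if p is None:
            s = np.ones(len(self.parameter_names))
            geom = 1.0
        else:
            s = p.to_array(self.parameter_names)
            geom = p.geometry
        if self.patch:
            for i, n in enumerate(self.parameter_names):
                if n in self.patch:
                    base = self.base_conductances[n][0]
                    if base != 0.0:
                        s[i] *= self.patch[n] / base
        return s, geom

    def rhs(self, t_ms: float, state: np.ndarray, p: Optional[ParameterVector] = None) -> np.ndarray:
        """Time derivative at ``t_ms`` (ms), per ms, in the model's native state units."""
        s, geom = self.scale_array(p)
        tn = t_ms * self.t_native_per_ms
        dy = self._rhs(tn, np.asarray(state, dtype=float), s, geom, 0.0)
        # native derivative is per native time unit; convert to per ms
        return dy * self.t_native_per_ms

    def currents_at(self, t_ms: float, state: np.ndarray, p: Optional[ParameterVector] = None) -> Dict[str, float]:
        s, geom = self.scale_array(p)
        cur = self._currents(t_ms * self.t_native_per_ms, np.asarray(state, dtype=float), s, geom)
        return dict(zip(self.parameter_names, cur))

    def export_manifest(self, path) -> None:
        """Flat key-value manifest of scalable parameters (id, value, units)."""
        lines = [f"model\t{self.name}"]
        for n in self.parameter_names:
            v, u = self.base_conductances[n]
            if n in self.patch:
                v = self.patch[n]
            lines.append(f"{n}\t{v!r}\t{u}")
        for k, v in self.geometry.items():
            lines.append(f"geometry.{k}\t{v!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _load_patch(patch) -> Dict[str, float]:
    """Patch = mapping id -> absolute conductance, or path to a key-value file."""
    if patch is None:
        return {}
    if isinstance(patch, dict):
        return {k: float(v) for k, v in patch.items()}
    out = {}
    with open(patch) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, v = line.replace("=", "\t").split("\t")[:2]
            out[k.strip()] = float(v)
    return out


def build_base_model(patch=None) -> CellModel:
    """The immature base model (Paci 2013 ventricular hiPSC-CM).

    ``patch`` optionally overrides published maximal conductances (mapping or
    key-value text file); overrides are recorded in the model changelog.
    """
    patch_d = _load_patch(patch)
    unknown = set(patch_d) - set(paci2013.PARAM_NAMES)
    if unknown:
        raise KeyError(f"patch names unknown parameters: {sorted(unknown)}")
    changelog = {k: f"base conductance overridden: {paci2013.BASE_CONDUCTANCES[k][0]} -> {v}"
                 for k, v in patch_d.items()}
    return CellModel(
        name=paci2013.NAME,
        state_names=paci2013.STATE_NAMES,
        parameter_names=paci2013.PARAM_NAMES,
        base_conductances=dict(paci2013.BASE_CONDUCTANCES),
        geometry=dict(paci2013.GEOMETRY),
        y0=paci2013.Y0.copy(),
        _rhs=paci2013.rhs,
        _currents=paci2013.currents,
        t_native_per_ms=paci2013.T_NATIVE_PER_MS,
        v_to_mv=paci2013.V_TO_MV,
        v_index=paci2013.V_INDEX,
        cai_index=paci2013.CAI_INDEX,
        changelog=changelog,
        patch=patch_d,
    )


def build_mature_model(patch=None) -> CellModel:
    """The adult reference model (ten Tusscher 2006, epicardial variant)."""
    patch_d = _load_patch(patch)
    unknown = set(patch_d) - set(tentusscher2006.PARAM_NAMES)
    if unknown:
        raise KeyError(f"patch names unknown parameters: {sorted(unknown)}")
    changelog = {"I_f": "exposed as zero-conductance placeholder (model has no funny current)"}
    changelog.update({k: f"base conductance overridden: {tentusscher2006.BASE_CONDUCTANCES[k][0]} -> {v}"
                      for k, v in patch_d.items()})
    return CellModel(
        name=tentusscher2006.NAME,
        state_names=tentusscher2006.STATE_NAMES,
        parameter_names=tentusscher2006.PARAM_NAMES,
        base_conductances=dict(tentusscher2006.BASE_CONDUCTANCES),
        geometry=dict(tentusscher2006.GEOMETRY),
        y0=tentusscher2006.Y0.copy(),
        default_stim_amplitude=52.0,
        default_stim_duration_ms=1.0,
        _rhs=tentusscher2006.rhs,
        _currents=tentusscher2006.currents,
        t_native_per_ms=tentusscher2006.T_NATIVE_PER_MS,
        v_to_mv=tentusscher2006.V_TO_MV,
        v_index=tentusscher2006.V_INDEX,
        cai_index=tentusscher2006.CAI_INDEX,
        changelog=changelog,
        patch=patch_d,
    )


def _integrate(model: CellModel, y: np.ndarray, s: np.ndarray, geom: float,
               t0_ms: float, t1_ms: float, istim: float,
               t_eval_ms: Optional[np.ndarray], rtol: float, atol: float):
    """Integrate one constant-stimulus segment; returns (states, y_end)."""
    f = model._rhs
    scale = model.t_native_per_ms

    def fun(yy, tt):
        return f(tt, yy, s, geom, istim)

    if t_eval_ms is None:
        ts = np.array([t0_ms, t1_ms]) * scale
    else:
        ts = np.concatenate(([t0_ms], t_eval_ms, [t1_ms])) * scale
        ts = np.unique(ts)
    sol, info = odeint(fun, y, ts, rtol=rtol, atol=atol, mxstep=100000,
                       full_output=True, tfirst=False)
    if info["message"] != "Integration successful.":
        raise SimulationError(f"{model.name}: solver failed on [{t0_ms}, {t1_ms}] ms: {info['message']}")
    if not np.all(np.isfinite(sol)):
        raise SimulationError(f"{model.name}: non-finite state on [{t0_ms}, {t1_ms}] ms")
    if t_eval_ms is None:
        return None, sol[-1]
    # map requested times back to rows of the (unique-sorted) grid
    idx = np.searchsorted(ts, np.asarray(t_eval_ms) * scale)
    return sol[idx], sol[-1]


_PACED_STATE_CACHE: Dict[tuple, np.ndarray] = {}


def _resolve_stim(model: CellModel, proto: PacingProtocol) -> Tuple[float, float]:
    dur = proto.stim_duration_ms if proto.stim_duration_ms is not None else model.default_stim_duration_ms
    amp = proto.stim_amplitude if proto.stim_amplitude is not None else model.default_stim_amplitude
    return dur, amp


def paced_initial_state(model: CellModel, protocol: Optional[PacingProtocol] = None,
                        n_beats: int = 50) -> np.ndarray:
    """Quasi-steady state of the unscaled model after ``n_beats`` paced beats.

    Cached per (model, patch, protocol) so that inversion runs share one
    pre-pacing computation.
    """
    proto = protocol or PacingProtocol()
    stim_dur, stim_amp = _resolve_stim(model, proto)
    key = (model.name, tuple(sorted(model.patch.items())), proto.period_ms,
           stim_dur, stim_amp, n_beats, proto.rtol, proto.atol)
    if key in _PACED_STATE_CACHE:
        return _PACED_STATE_CACHE[key].copy()
    s, geom = model.scale_array(None)
    y = model.y0.copy()
    for _ in range(n_beats):
        _, y = _integrate(model, y, s, geom, 0.0, stim_dur,
                          stim_amp, None, proto.rtol, proto.atol)
        _, y = _integrate(model, y, s, geom, stim_dur, proto.period_ms,
                          0.0, None, proto.rtol, proto.atol)
    _PACED_STATE_CACHE[key] = y.copy()
    return y


def simulate(model: CellModel, p: Optional[ParameterVector] = None,
             protocol: Optional[PacingProtocol] = None,
             record_currents: bool = False,
             y0: Optional[np.ndarray] = None) -> Trace:
    """Pace the model and return the recorded beat(s) as a :class:`Trace`.

    The returned time grid starts at the stimulus onset of the first recorded
    beat.  Integration is deterministic: identical inputs produce identical
    traces.
    """
    proto = protocol or PacingProtocol()
    stim_dur, stim_amp = _resolve_stim(model, proto)
    s, geom = model.scale_array(p)
    if y0 is not None:
        y = np.asarray(y0, dtype=float).copy()
    elif proto.start_from == "paced":
        y = paced_initial_state(model, PacingProtocol(
            period_ms=proto.period_ms, stim_duration_ms=stim_dur,
            stim_amplitude=stim_amp, rtol=proto.rtol, atol=proto.atol))
    else:
        y = model.y0.copy()

    for _ in range(proto.n_prepace):
        _, y = _integrate(model, y, s, geom, 0.0, stim_dur,
                          stim_amp, None, proto.rtol, proto.atol)
        _, y = _integrate(model, y, s, geom, stim_dur, proto.period_ms,
                          0.0, None, proto.rtol, proto.atol)

    n_t = int(round(proto.n_record * proto.period_ms / proto.dt_ms)) + 1
    t_out = np.arange(n_t) * proto.dt_ms
    states = np.empty((n_t, len(model.state_names)))
    for b in range(proto.n_record):
        off = b * proto.period_ms
        in_beat = (t_out >= off) & (t_out <= off + proto.period_ms) if b == proto.n_record - 1 \
            else (t_out >= off) & (t_out < off + proto.period_ms)
        tb = t_out[in_beat] - off
        seg1 = tb[tb <= stim_dur]
        seg2 = tb[tb > stim_dur]
        rows = np.where(in_beat)[0]
        y_start = y
        got = []
        if len(seg1):
            sol1, y_mid = _integrate(model, y_start, s, geom, 0.0, stim_dur,
                                     stim_amp, seg1, proto.rtol, proto.atol)
            got.append(sol1)
        else:
            _, y_mid = _integrate(model, y_start, s, geom, 0.0, stim_dur,
                                  stim_amp, None, proto.rtol, proto.atol)
        sol2, y = _integrate(model, y_mid, s, geom, stim_dur, proto.period_ms,
                             0.0, seg2 if len(seg2) else None, proto.rtol, proto.atol)
        if len(seg2):
            got.append(sol2)
        block = np.vstack(got)
        states[rows] = block

    v = states[:, model.v_index] * model.v_to_mv
    ca = states[:, model.cai_index]
    currents = None
    if record_currents:
        vals = np.empty((n_t, len(model.parameter_names)))
        for i in range(n_t):
            vals[i] = model._currents(t_out[i] * model.t_native_per_ms, states[i], s, geom)
        currents = {n: vals[:, k] for k, n in enumerate(model.parameter_names)}
    return Trace(t_out, v, ca, pacing_period=proto.period_ms,
                 currents=currents, provenance="simulated")


def current_integrals(model: CellModel, p: Optional[ParameterVector] = None,
                      protocol: Optional[PacingProtocol] = None) -> Dict[str, float]:
    """Per-current integral of |I| over one paced beat, in nC/uF.

    Transmembrane currents in A/F integrated over ms give nC/uF numerically;
    SR fluxes integrate to mM (reported in the same table for completeness).
    """
    proto = protocol or PacingProtocol()
    tr = simulate(model, p, proto, record_currents=True)
    out = {}
    flux_time_scale = 1e-3 if model.t_native_per_ms == 1e-3 else 1.0
    for n, series in tr.currents.items():
        val = float(np.trapezoid(np.abs(series), tr.t))
        if n.startswith("J_"):
            val *= flux_time_scale  # mM/s * ms -> mM (immature model)
        out[n] = val
    return out
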
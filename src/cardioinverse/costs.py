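"""Regularized waveform-mismatch cost functions.

The cost of a candidate block vector ``lambda`` is

    H(lambda) = ( sum_j H_j(lambda) + eps * sum_i lambda_i^2 )^(1/2)

where the H_j are absolute relative mismatches of the eight waveform features
between the model (simulated with the blocked conductances) and the target:
H1 the voltage integral over the 30% transient, H2-H4 the voltage durations
APD30/50/80, H5 the maximal calcium upstroke velocity, H6-H8 the calcium
durations.  The voltage-only variant sums H1-H4, the calcium-only variant
H5-H8, the combined variant all eight.  Default regularization weight is
eps = 0.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from cardioinverse.features import FeatureSet, extract_features, FeatureError
from cardioinverse.models import CellModel, PacingProtocol, simulate, SimulationError
from cardioinverse.parameters import ParameterVector, BlockVector, apply_block
from cardioinverse.trace import Trace

#: the six currents whose block is searched by default
DEFAULT_ADJUSTABLE = ("I_Na", "I_CaL", "I_to", "I_Ks", "I_Kr", "I_K1")

#: cost assigned to failed / non-physiological simulations so that the
#: derivative-free search can continue past them
SENTINEL_COST = 1.0e6

_H_FEATURES = {
    "H1": "int_v", "H2": "apd_v30", "H3": "apd_v50", "H4": "apd_v80",
    "H5": "dcdt_max", "H6": "apd_ca30", "H7": "apd_ca50", "H8": "apd_ca80",
}
_VARIANT_TERMS = {
    "V": ("H1", "H2", "H3", "H4"),
    "Ca": ("H5", "H6", "H7", "H8"),
    "V+Ca": ("H1", "H2", "H3", "H4", "H5", "H6", "H7", "H8"),
}


@dataclass(frozen=True)
class CostSpec:
    """Which feature mismatches enter the cost, and the penalty weight."""

    variant: str = "V+Ca"
    epsilon: float = 0.2
    adjustable: Sequence[str] = DEFAULT_ADJUSTABLE

    def __post_init__(self):
        if self.variant not in _VARIANT_TERMS:
            raise ValueError(f"variant must be one of {sorted(_VARIANT_TERMS)}, got {self.variant!r}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not self.adjustable:
            raise ValueError("adjustable set must be non-empty")


@dataclass
class CostValue:
    total: float
    terms: Dict[str, float]
    penalty: float

    @property
    def squared(self) -> float:
        return self.total ** 2


def h_terms(model_features: FeatureSet, target_features: FeatureSet) -> Dict[str, float]:
    """The eight absolute relative feature mismatches H1..H8.

    Denominators come from the target; a zero target denominator raises with
    the offending feature named.
    """
    out = {}
    mf = model_features.as_dict()
    tf = target_features.as_dict()
    for h, name in _H_FEATURES.items():
        denom = tf[name]
        if denom == 0:
            raise ZeroDivisionError(f"target feature {name!r} is zero; {h} undefined")
        out[h] = abs(mf[name] - denom) / abs(denom)
    return out


def _assemble(terms: Dict[str, float], lam_values: Sequence[float], spec: CostSpec) -> CostValue:
    penalty = spec.epsilon * float(sum(v * v for v in lam_values))
    total = math.sqrt(sum(terms[h] for h in _VARIANT_TERMS[spec.variant]) + penalty)
    return CostValue(total=total, terms=terms, penalty=penalty)


def cost_from_features(model_features: FeatureSet, target_features: FeatureSet,
                       lam: BlockVector, spec: CostSpec) -> CostValue:
    return _assemble(h_terms(model_features, target_features), list(lam.values.values()), spec)


def evaluate_cost(lam: BlockVector, base_p: ParameterVector, model: CellModel,
                  target: FeatureSet, spec: CostSpec,
                  protocol: Optional[PacingProtocol] = None,
                  normalize: bool = False) -> CostValue:
    """Simulate the blocked model, extract features, assemble the cost.

    Simulation failures and undefined features map to a large finite sentinel
    cost rather than an exception so random search can proceed.
    """
    p = apply_block(base_p, lam)
    try:
        tr = simulate(model, p, protocol)
        feats = extract_features(tr, normalize=normalize)
        return cost_from_features(feats, target, lam, spec)
    except (SimulationError, FeatureError):
        return CostValue(total=SENTINEL_COST, terms={h: float("nan") for h in _H_FEATURES},
                         penalty=float("nan"))


class CostEvaluator:
    """Callable cost with per-run caching keyed by rounded lambda.

    Wraps a fixed (model, base parameter vector, target features, spec,
    protocol) tuple; calling it with an array of lambdas ordered like
    ``spec.adjustable`` returns the scalar cost.
    """

    def __init__(self, model: CellModel, base_p: ParameterVector, target: FeatureSet,
                 spec: CostSpec, protocol: Optional[PacingProtocol] = None,
                 mode: str = "free", normalize: bool = False):
        self.model = model
        self.base_p = base_p
        self.target = target
        self.spec = spec
        self.protocol = protocol
        self.mode = mode
        self.normalize = normalize
        self.n_evals = 0
        self._cache: Dict[tuple, float] = {}

    @classmethod
    def for_trace(cls, model: CellModel, base_p: ParameterVector, target: Trace,
                  spec: CostSpec, protocol: Optional[PacingProtocol] = None,
                  mode: str = "free") -> "CostEvaluator":
        """Evaluator against a recorded target trace.

        Measured (arbitrary-unit) targets are min-max normalized, and the
        simulated candidate traces are produced on the target's sampling grid
        so that grid-dependent features (the discrete upstroke velocity in
        particular) are compared like for like.
        """
        from dataclasses import replace

        normalize = target.provenance == "measured"
        feats = extract_features(target, normalize=normalize)
        proto = protocol
        if normalize and proto is not None and abs(proto.dt_ms - target.dt) > 1e-9:
            proto = replace(proto, dt_ms=target.dt)
        return cls(model, base_p, feats, spec, proto, mode=mode, normalize=normalize)

    def block_vector(self, lam_array) -> BlockVector:
        return BlockVector(dict(zip(self.spec.adjustable, map(float, lam_array))), mode=self.mode)

    def __call__(self, lam_array) -> float:
        key = tuple(round(float(x), 6) for x in lam_array)
        if key in self._cache:
            return self._cache[key]
        cv = evaluate_cost(self.block_vector(lam_array), self.base_p, self.model,
                           self.target, self.spec, self.protocol, normalize=self.normalize)
        self.n_evals += 1
        self._cache[key] = cv.total
        return cv.total

    def detailed(self, lam_array) -> CostValue:
        return evaluate_cost(self.block_vector(lam_array), self.base_p, self.model,
                             self.target, self.spec, self.protocol, normalize=self.normalize)
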
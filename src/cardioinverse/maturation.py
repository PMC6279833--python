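"""Diagonal maturation map between immature and mature parameter vectors.

Maturation is modeled as multiplication: each membrane protein is functionally
invariant while its expression level, the membrane area and the cell volume
change, so the mature parameter vector is ``p_M = Q p_IM`` for a positive
diagonal ``Q``.  The leading factor is the area-to-volume (geometry) ratio;
the rest scale the individual currents and SR fluxes.  Because ``Q`` is
diagonal, a fractional block commutes with the map — a drug identified on
immature cells transfers verbatim to the mature parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from cardioinverse.parameters import ParameterVector, GEOMETRY_KEY

_PACI_KEYS = (
    GEOMETRY_KEY, "I_Na", "I_CaL", "I_to", "I_Ks", "I_Kr", "I_K1",
    "I_NaCa", "I_NaK", "I_pCa", "I_f", "I_bNa", "I_bCa",
    "J_leak", "J_up", "J_rel",
)
_PACI_FACTORS = (1.7, 0.4, 3, 5, 20, 0.7, 1.3, 0.05, 0.3, 0.6, 0.1, 0.5, 0.4, 200, 1, 36)

_TT_KEYS = (
    GEOMETRY_KEY, "I_Na", "I_CaL", "I_to", "I_Ks", "I_Kr", "I_K1",
    "I_NaCa", "I_NaK", "I_pCa", "I_f", "I_pK", "I_bNa", "I_bCa",
    "J_leak", "J_up", "J_rel",
)
_TT_FACTORS = (1.7, 4, 4.2, 17, 40, 1, 2.2, 0.4, 0.7, 1.7, 0.05, 19, 0.1, 0.6, 500, 1.3, 34)


@dataclass
class MaturationMap:
    """Ordered positive diagonal factors, geometry first."""

    factors: Dict[str, float]

    def __post_init__(self):
        for k, v in self.factors.items():
            if not v > 0:
                raise ValueError(f"maturation factor {k!r} must be positive, got {v}")

    def __getitem__(self, key: str) -> float:
        return self.factors[key]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.factors.items():
                fh.write(f"{k}\t{v!r}\n")

    @classmethod
    def load(cls, path) -> "MaturationMap":
        factors = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, v = line.split("\t")[:2]
                factors[k] = float(v)
        return cls(factors)


def paci_map() -> MaturationMap:
    """The printed immature-model maturation diagonal (16 factors)."""
    return MaturationMap(dict(zip(_PACI_KEYS, map(float, _PACI_FACTORS))))


def tt_map() -> MaturationMap:
    """The printed adult-model maturation diagonal (17 factors, incl. I_pK)."""
    return MaturationMap(dict(zip(_TT_KEYS, map(float, _TT_FACTORS))))


def invert_map(Q: MaturationMap) -> MaturationMap:
    """Elementwise reciprocal (maps mature back to immature)."""
    return MaturationMap({k: 1.0 / v for k, v in Q.factors.items()})


def apply_map(Q: MaturationMap, p: ParameterVector) -> ParameterVector:
    """Elementwise product ``p_M = Q p_IM``.

    ``p`` may omit the geometry entry (implicitly 1); any other key mismatch
    is an error.  The result always carries the geometry entry.
    """
    pk = set(p.values) - {GEOMETRY_KEY}
    qk = set(Q.factors) - {GEOMETRY_KEY}
    if pk != qk:
        raise KeyError(f"key mismatch between map and parameter vector: "
                       f"only in map {sorted(qk - pk)}, only in vector {sorted(pk - qk)}")
    out = {GEOMETRY_KEY: Q.factors.get(GEOMETRY_KEY, 1.0) * p.geometry}
    for k in Q.factors:
        if k == GEOMETRY_KEY:
            continue
        out[k] = Q.factors[k] * p.values[k]
    return ParameterVector(out)


def update_map(p_im_control: ParameterVector, p_m_reference: ParameterVector) -> MaturationMap:
    """The map sending the inverted control cell onto the mature reference.

    Defined entrywise as ``Q_i = p_M_i / p_IM_i`` so that
    ``apply_map(update_map(a, b), a) == b``.
    """
    keys = [GEOMETRY_KEY] + sorted(set(p_m_reference.values) - {GEOMETRY_KEY})
    factors = {}
    for k in keys:
        num = p_m_reference.values.get(k, 1.0) if k == GEOMETRY_KEY else p_m_reference.values[k]
        den = p_im_control.values.get(k, 1.0) if k == GEOMETRY_KEY else p_im_control.values[k]
        if not (num > 0 and den > 0):
            raise ValueError(f"non-positive entry for {k!r}: {num}/{den}")
        factors[k] = num / den
    return MaturationMap(factors)


def drug_effect_on_mature(p_m: ParameterVector, p_m_drug: ParameterVector) -> Dict[str, float]:
    """Per-current fractional change ``p_m_drug / p_m - 1``.

    Equals the identified block vector by construction: the diagonal map
    cancels, so the mature fractional change is the immature one.
    """
    keys = set(p_m.values) | set(p_m_drug.values)
    out = {}
    for k in sorted(keys):
        a = p_m.values.get(k, 1.0)
        b = p_m_drug.values.get(k, 1.0)
        out[k] = b / a - 1.0
    return out
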
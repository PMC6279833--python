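"""Named conductance scale factors and fractional channel blocks.

A :class:`ParameterVector` holds one positive multiplier per scalable current
or flux of a cell model (relative to the published maximal conductances), plus
an optional geometry factor scaling the surface-to-volume relation.  A
:class:`BlockVector` holds fractional perturbations ``lambda``; a drug that
blocks a channel by 50% is ``lambda = -0.5``, applied multiplicatively as
``(1 + lambda) * q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

GEOMETRY_KEY = "geometry"


class UnknownParameterError(KeyError):
    """A named identifier is not among the model's scalable parameters."""


@dataclass
class ParameterVector:
    """Positive multiplicative factors on a model's maximal conductances."""

    values: Dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not v > 0:
                raise ValueError(f"parameter {k!r} must be positive, got {v}")

    @classmethod
    def ones(cls, names: Iterable[str], geometry: bool = False) -> "ParameterVector":
        vals = {n: 1.0 for n in names}
        if geometry:
            vals = {GEOMETRY_KEY: 1.0, **vals}
        return cls(vals)

    @property
    def geometry(self) -> float:
        return self.values.get(GEOMETRY_KEY, 1.0)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def get(self, key: str, default: float = 1.0) -> float:
        return self.values.get(key, default)

    def current_keys(self) -> list[str]:
        return [k for k in self.values if k != GEOMETRY_KEY]

    def copy(self) -> "ParameterVector":
        return ParameterVector(dict(self.values))

    def to_array(self, names: Iterable[str]):
        import numpy as np

        return np.array([self.values.get(n, 1.0) for n in names], dtype=float)


@dataclass
class BlockVector:
    """Fractional conductance perturbations, one per named current/flux.

    ``mode='drug'`` restricts every entry to (-1, 0] (pure channel block);
    ``mode='free'`` only enforces the physical floor ``lambda > -1``.
    """

    values: Dict[str, float]
    mode: str = "free"

    def __post_init__(self) -> None:
        if self.mode not in ("free", "drug"):
            raise ValueError(f"mode must be 'free' or 'drug', got {self.mode!r}")
        for k, v in self.values.items():
            if not v > -1.0:
                raise ValueError(
                    f"block {k!r} = {v} is not > -1 (full or negative conductance is non-physical)"
                )
            if self.mode == "drug" and v > 0.0:
                raise ValueError(f"drug-mode block {k!r} = {v} must lie in (-1, 0]")

    @classmethod
    def zeros(cls, names: Iterable[str], mode: str = "free") -> "BlockVector":
        return cls({n: 0.0 for n in names}, mode=mode)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def get(self, key: str, default: float = 0.0) -> float:
        return self.values.get(key, default)

    def percent_block(self) -> Dict[str, float]:
        """Blocks as positive percentages (lambda = -0.5 -> 50.0)."""
        return {k: -100.0 * v for k, v in self.values.items()}


def apply_block(p: ParameterVector, lam: BlockVector) -> ParameterVector:
    """Scale a parameter vector by ``(1 + lambda_i)`` entrywise.

    Entries of ``p`` not named in ``lam`` pass through unchanged.  Raises
    :class:`UnknownParameterError` if ``lam`` names an identifier absent from
    ``p``.
    """
    unknown = [k for k in lam.values if k not in p.values]
    if unknown:
        raise UnknownParameterError(
            f"block names unknown parameter(s) {unknown!r}; model has {sorted(p.values)}"
        )
    out = dict(p.values)
    for k, lv in lam.values.items():
        out[k] = p.values[k] * (1.0 + lv)
    return ParameterVector(out)
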
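"""Shrinking-bounding-box random search and the drug-identification wrapper.

The minimizer is derivative-free: draw N block vectors uniformly from a
bounding box, keep the five cheapest, center five new boxes on them with every
interval shrunk to 90% of its previous length, draw N/5 from each, and repeat.
Refined boxes may drift outside the initial box; the only hard clips are the
physical floor (lambda > -1) and, in drug mode, the ceiling lambda <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from cardioinverse.costs import CostEvaluator, CostSpec, CostValue
from cardioinverse.models import CellModel, PacingProtocol
from cardioinverse.parameters import ParameterVector, BlockVector, apply_block
from cardioinverse.trace import Trace

_LAMBDA_FLOOR = -1.0 + 1e-6   # open bound lambda > -1
_N_KEEP = 5
_SHRINK = 0.9


@dataclass
class BoundingBox:
    """Per-dimension lambda intervals for the random search."""

    intervals: Dict[str, Tuple[float, float]]
    mode: str = "free"

    def __post_init__(self):
        for k, (lo, hi) in self.intervals.items():
            if not lo < hi:
                raise ValueError(f"interval for {k!r} is empty: ({lo}, {hi})")
            if lo <= -1.0:
                raise ValueError(f"interval for {k!r} reaches the lambda <= -1 floor: ({lo}, {hi})")
            if self.mode == "drug" and hi > 0.0:
                raise ValueError(f"drug-mode interval for {k!r} must satisfy hi <= 0: ({lo}, {hi})")

    @classmethod
    def uniform(cls, names: Sequence[str], lo: float, hi: float, mode: str = "free") -> "BoundingBox":
        return cls({n: (lo, hi) for n in names}, mode=mode)

    def arrays(self, names: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.intervals[n][0] for n in names])
        hi = np.array([self.intervals[n][1] for n in names])
        return lo, hi


@dataclass
class InversionResult:
    best_lambda: BlockVector
    best_cost: float
    history: List[List[Tuple[np.ndarray, float]]]   # per-iteration 5 retained (lambda, cost)
    n_evals: int
    seed: int
    updated_p: Optional[ParameterVector] = None
    best_cost_value: Optional[CostValue] = None

    def percent_block(self) -> Dict[str, float]:
        return self.best_lambda.percent_block()


def _clipped_box(center: np.ndarray, length: np.ndarray, mode: str) -> Tuple[np.ndarray, np.ndarray]:
    lo = center - length / 2.0
    hi = center + length / 2.0
    lo = np.maximum(lo, _LAMBDA_FLOOR)
    if mode == "drug":
        hi = np.minimum(hi, 0.0)
    bad = ~(lo < hi)
    if bad.any():
        # fully clipped dimension: collapse to a sliver at the boundary
        hi[bad] = lo[bad] + 1e-9
    return lo, hi


def random_search(cost: Callable[[np.ndarray], float], box0: BoundingBox,
                  names: Sequence[str], N: int = 5000, iterations: int = 10,
                  seed: int = 0) -> InversionResult:
    """Minimize ``cost`` over lambda by shrinking-box random search.

    ``cost`` maps an array ordered like ``names`` to a scalar.  Draws are
    reproducible given ``seed``; each iteration uses its own child stream so
    changing N does not reorder other iterations' draws.
    """
    if N < _N_KEEP or N % _N_KEEP:
        raise ValueError(f"N must be a positive multiple of {_N_KEEP}, got {N}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(iterations + 1)
    mode = box0.mode
    lo0, hi0 = box0.arrays(names)
    length = hi0 - lo0

    history: List[List[Tuple[np.ndarray, float]]] = []
    pool_lams: List[np.ndarray] = []
    pool_costs: List[float] = []
    n_evals = 0

    rng = np.random.default_rng(streams[0])
    draws = rng.uniform(lo0, hi0, size=(N, len(names)))
    for lam in draws:
        pool_costs.append(cost(lam))
        pool_lams.append(lam)
        n_evals += 1

    def top5() -> List[int]:
        order = sorted(range(len(pool_costs)), key=lambda i: (pool_costs[i], i))
        return order[:_N_KEEP]

    best_idx = top5()
    history.append([(pool_lams[i].copy(), pool_costs[i]) for i in best_idx])

    for it in range(1, iterations + 1):
        length = length * _SHRINK
        rng = np.random.default_rng(streams[it])
        n_per = N // _N_KEEP
        for i in best_idx:
            lo, hi = _clipped_box(pool_lams[i], length, mode)
            draws = rng.uniform(lo, hi, size=(n_per, len(names)))
            for lam in draws:
                pool_costs.append(cost(lam))
                pool_lams.append(lam)
                n_evals += 1
        best_idx = top5()
        history.append([(pool_lams[i].copy(), pool_costs[i]) for i in best_idx])

    b = best_idx[0]
    best_lam = BlockVector(dict(zip(names, map(float, pool_lams[b]))), mode=mode)
    return InversionResult(best_lambda=best_lam, best_cost=pool_costs[b],
                           history=history, n_evals=n_evals, seed=seed)


@dataclass(frozen=True)
class SearchSettings:
    N: int = 5000
    iterations: int = 10
    seed: int = 0
    box_halfwidth_free: float = 0.5    # free-mode initial box [-0.5, 0.5]
    drug_floor: float = -0.99          # drug-mode initial box [-0.99, 0]


#: reduced desk-scale settings used throughout the test/acceptance runs
REDUCED_SETTINGS = SearchSettings(N=500, iterations=10)


def invert_traces(target: Trace, model: CellModel, base_p: ParameterVector,
                  spec: Optional[CostSpec] = None, mode: str = "free",
                  settings: Optional[SearchSettings] = None,
                  protocol: Optional[PacingProtocol] = None) -> InversionResult:
    """Identify the conductance blocks that best reproduce ``target``.

    Free mode (control inversion) searches [-0.5, 0.5] per adjustable
    current; drug mode assumes a pure channel blocker and searches
    [-0.99, 0].  Returns the best block vector together with the updated
    parameter vector ``apply_block(base_p, best_lambda)``.
    """
    spec = spec or CostSpec()
    settings = settings or SearchSettings()
    evaluator = CostEvaluator.for_trace(model, base_p, target, spec, protocol, mode=mode)
    names = list(spec.adjustable)
    if mode == "drug":
        box0 = BoundingBox.uniform(names, settings.drug_floor, 0.0, mode="drug")
    else:
        box0 = BoundingBox.uniform(names, -settings.box_halfwidth_free,
                                   settings.box_halfwidth_free, mode="free")
    res = random_search(evaluator, box0, names, N=settings.N,
                        iterations=settings.iterations, seed=settings.seed)
    res.updated_p = apply_block(base_p, res.best_lambda)
    res.best_cost_value = evaluator.detailed(
        np.array([res.best_lambda[n] for n in names]))
    return res
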
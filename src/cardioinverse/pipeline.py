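"""End-to-end drug screening workflow and the standard in-silico experiments.

The eight-step procedure: start from the immature base model and its base
maturation map; invert the control recording to a control parameterization;
invert the drugged recording starting from the control; update the maturation
map so it sends the control cell onto the mature reference; map both
parameterizations to the mature model; and report the per-current fractional
changes together with simulated mature traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from cardioinverse.costs import CostEvaluator, CostSpec, DEFAULT_ADJUSTABLE
from cardioinverse.features import FeatureSet, extract_features
from cardioinverse.inversion import (
    BoundingBox, InversionResult, SearchSettings, invert_traces, random_search,
)
from cardioinverse.maturation import MaturationMap, apply_map, paci_map, update_map, drug_effect_on_mature
from cardioinverse.models import (
    CellModel, PacingProtocol, EVAL_PROTOCOL, build_base_model, simulate, current_integrals,
)
from cardioinverse.parameters import ParameterVector, BlockVector, apply_block, GEOMETRY_KEY
from cardioinverse.synth import simulate_drug_dataset
from cardioinverse.trace import Trace

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    cost: CostSpec = CostSpec()
    settings: SearchSettings = SearchSettings(N=500, iterations=10)
    protocol: PacingProtocol = EVAL_PROTOCOL
    seed: int = 0


@dataclass
class PipelineReport:
    """Artifacts of the eight-step procedure."""

    blocks: Dict[str, float]                 # identified drug lambda per current
    percent_block: Dict[str, float]
    control_inversion: InversionResult
    drug_inversion: InversionResult
    p_im_control: ParameterVector
    p_im_drug: ParameterVector
    q_updated: MaturationMap
    p_m: ParameterVector
    p_m_drug: ParameterVector
    im_features: Dict[str, FeatureSet]       # control / drug
    m_features: Dict[str, FeatureSet]
    m_traces: Dict[str, Trace]
    seed: int


def run_pipeline(control: Trace, drugged: Trace,
                 config: Optional[PipelineConfig] = None,
                 model: Optional[CellModel] = None,
                 base_map: Optional[MaturationMap] = None) -> PipelineReport:
    """Identify drug-induced channel blocks and map them to the mature cell.

    ``control`` and ``drugged`` must be preprocessed single-beat traces.  The
    mature reference is the base model scaled by the base maturation map.
    """
    cfg = config or PipelineConfig()
    model = model or build_base_model()
    Q_b = base_map or paci_map()
    p_base = ParameterVector.ones(model.parameter_names)
    log.info("pipeline run: model=%s seed=%d N=%d iterations=%d cost=%s eps=%g",
             model.name, cfg.seed, cfg.settings.N, cfg.settings.iterations,
             cfg.cost.variant, cfg.cost.epsilon)

    # steps 4-5: invert control (free), then drug starting from the control
    ctrl_settings = SearchSettings(N=cfg.settings.N, iterations=cfg.settings.iterations,
                                   seed=cfg.seed, box_halfwidth_free=cfg.settings.box_halfwidth_free)
    res_c = invert_traces(control, model, p_base, cfg.cost, mode="free",
                          settings=ctrl_settings, protocol=cfg.protocol)
    p_im_c = res_c.updated_p
    drug_settings = SearchSettings(N=cfg.settings.N, iterations=cfg.settings.iterations,
                                   seed=cfg.seed + 1, drug_floor=cfg.settings.drug_floor)
    res_d = invert_traces(drugged, model, p_im_c, cfg.cost, mode="drug",
                          settings=drug_settings, protocol=cfg.protocol)
    p_im_d = res_d.updated_p

    # step 6: update the maturation map so Q p_im_c = p_M (mature reference)
    p_m_ref = apply_map(Q_b, ParameterVector.ones(model.parameter_names, geometry=True))
    q = update_map(p_im_c, p_m_ref)
    # step 7: mature version of the drugged cell
    p_m_d = apply_map(q, p_im_d)

    # step 8: compare mature control and drug parameterizations and traces
    blocks = {k: v for k, v in drug_effect_on_mature(p_m_ref, p_m_d).items()
              if k != GEOMETRY_KEY}
    for name in cfg.cost.adjustable:
        blocks.setdefault(name, 0.0)

    im_feats = {
        "control": extract_features(simulate(model, p_im_c, cfg.protocol)),
        "drug": extract_features(simulate(model, p_im_d, cfg.protocol)),
    }
    m_proto = PacingProtocol(n_prepace=cfg.protocol.n_prepace,
                             n_record=cfg.protocol.n_record, start_from="y0")
    m_traces = {
        "control": simulate(model, p_m_ref, m_proto),
        "drug": simulate(model, p_m_d, m_proto),
    }
    m_feats = {k: extract_features(v) for k, v in m_traces.items()}

    return PipelineReport(
        blocks=blocks,
        percent_block={k: -100.0 * v for k, v in blocks.items()},
        control_inversion=res_c,
        drug_inversion=res_d,
        p_im_control=p_im_c,
        p_im_drug=p_im_d,
        q_updated=q,
        p_m=p_m_ref,
        p_m_drug=p_m_d,
        im_features=im_feats,
        m_features=m_feats,
        m_traces=m_traces,
        seed=cfg.seed,
    )


def sensitivity_scan(model: CellModel, base_p: Optional[ParameterVector] = None,
                     spec: Optional[CostSpec] = None, delta: float = 0.1,
                     protocol: Optional[PacingProtocol] = None) -> Dict[str, float]:
    """Single-parameter +/-delta sensitivity of the cost function.

    For each adjustable parameter the cost (including the regularization
    penalty) is evaluated at lambda_i = +delta and -delta against the
    unperturbed target; the two values are summed.
    """
    spec = spec or CostSpec()
    base_p = base_p or ParameterVector.ones(model.parameter_names)
    proto = protocol or EVAL_PROTOCOL
    target = extract_features(simulate(model, base_p, proto))
    ev = CostEvaluator(model, base_p, target, spec, proto, mode="free")
    out = {}
    n = len(spec.adjustable)
    for i, name in enumerate(spec.adjustable):
        total = 0.0
        for sgn in (+1.0, -1.0):
            lam = np.zeros(n)
            lam[i] = sgn * delta
            total += ev(lam)
        out[name] = total
    return out


def pairwise_grid(model: CellModel, base_p: ParameterVector, target: Trace,
                  pair: Tuple[str, str], grid: Optional[np.ndarray] = None,
                  spec: Optional[CostSpec] = None,
                  protocol: Optional[PacingProtocol] = None,
                  mode: str = "free") -> Tuple[np.ndarray, Tuple[float, float]]:
    """Cost over a rectangular lambda-grid for one pair of currents.

    All other adjustable lambdas are held at zero.  Returns the cost matrix
    (rows: first member of the pair) and the argmin grid point.
    """
    spec = spec or CostSpec()
    proto = protocol or EVAL_PROTOCOL
    if grid is None:
        grid = np.linspace(-0.99, 0.0, 11) if mode == "drug" else np.linspace(-0.8, 0.2, 11)
    ev = CostEvaluator.for_trace(model, base_p, target, spec, proto, mode="free")
    names = list(spec.adjustable)
    ia, ib = names.index(pair[0]), names.index(pair[1])
    M = np.empty((len(grid), len(grid)))
    for i, la in enumerate(grid):
        for j, lb in enumerate(grid):
            lam = np.zeros(len(names))
            lam[ia] = la
            lam[ib] = lb
            M[i, j] = ev(lam)
    i0, j0 = np.unravel_index(np.argmin(M), M.shape)
    return M, (float(grid[i0]), float(grid[j0]))


def table1_experiment(model: Optional[CellModel] = None,
                      currents: Sequence[str] = ("I_K1", "I_CaL", "I_Kr", "I_Na", "I_to", "I_Ks"),
                      levels: Sequence[float] = (-0.1, -0.3, -0.5, -0.7),
                      settings: Optional[SearchSettings] = None,
                      spec: Optional[CostSpec] = None,
                      protocol: Optional[PacingProtocol] = None,
                      seed: int = 0) -> Dict:
    """Single-channel-block recovery experiment.

    For each current and block level, generates the single-block target and
    runs a drug-mode inversion with all six currents adjustable.  Returns the
    recovered lambda per (current, level) and the unperturbed per-current
    |I| integrals in nC/uF.
    """
    model = model or build_base_model()
    spec = spec or CostSpec()
    proto = protocol or EVAL_PROTOCOL
    settings = settings or SearchSettings(N=500, iterations=10)
    base_p = ParameterVector.ones(model.parameter_names)

    integrals = current_integrals(model, base_p, PacingProtocol(n_prepace=0, n_record=1,
                                                                start_from="paced",
                                                                dt_ms=proto.dt_ms))
    recovered: Dict[str, Dict[float, float]] = {}
    for cur in currents:
        recovered[cur] = {}
        for lev in levels:
            truth = BlockVector({cur: lev}, mode="drug")
            _, drugged, _ = simulate_drug_dataset(model, base_p, truth, protocol=proto)
            st = SearchSettings(N=settings.N, iterations=settings.iterations, seed=seed)
            res = invert_traces(drugged, model, base_p, spec, mode="drug",
                                settings=st, protocol=proto)
            recovered[cur][lev] = res.best_lambda[cur]
            log.info("table1 %s at %.1f -> %.3f", cur, lev, res.best_lambda[cur])
    return {"integrals_nC_per_uF": {c: integrals[c] for c in currents},
            "recovered": recovered}
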
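"""Identify a simulated multichannel drug block from its waveforms alone.

Simulates a Verapamil-like compound (50% L-type calcium block + 25% hERG
block) on the immature model, then inverts the drugged waveforms with the
shrinking-box random search and prints the identified per-current block next
to the ground truth.  Sensitive currents are recovered closely; the minor
currents I_to and I_Ks are weakly identifiable and tend toward zero under the
regularization penalty.
"""

import cardioinverse as ci
from cardioinverse.inversion import SearchSettings
from cardioinverse.models import EVAL_PROTOCOL

model = ci.build_base_model()
base_p = ci.ParameterVector.ones(model.parameter_names)
truth = ci.drug_presets()["verapamil_sim"]

control, drugged, _ = ci.simulate_drug_dataset(model, base_p, truth)
result = ci.invert_traces(drugged, model, base_p, mode="drug",
                          settings=SearchSettings(N=500, iterations=10, seed=1),
                          protocol=EVAL_PROTOCOL)

print(f"cost at optimum: {result.best_cost:.4f}  ({result.n_evals} draws)")
print(f"{'current':8s} {'true block':>12s} {'identified':>12s}")
for name, lam in result.best_lambda.values.items():
    print(f"{name:8s} {-100 * truth.get(name, 0.0) + 0.0:11.0f}% {-100 * lam + 0.0:11.1f}%")
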
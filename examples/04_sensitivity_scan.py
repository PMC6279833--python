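"""Which currents can waveform inversion actually see?

Perturbs each adjustable maximal conductance by +/-10% and sums the combined
voltage+calcium cost of the two perturbations.  Large values mean the cost
function is sensitive to that current; I_to and I_Ks come out nearly
invisible, which is why their block is not identifiable from these waveforms.
"""

import cardioinverse as ci
from cardioinverse.models import EVAL_PROTOCOL

model = ci.build_base_model()
scan = ci.sensitivity_scan(model, delta=0.1, protocol=EVAL_PROTOCOL)

top = max(scan.values())
print(f"{'current':8s} {'summed cost':>12s}")
for name, val in sorted(scan.items(), key=lambda kv: -kv[1]):
    bar = "#" * int(40 * val / top)
    print(f"{name:8s} {val:12.4f}  {bar}")
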
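"""Pace the immature base model and read off its waveform characteristics.

Builds the hiPSC-CM base model, paces it at 1 Hz to quasi-steady state,
simulates one beat, and prints the eight features the inversion cost uses.
The long APD (~400 ms at the 80% level) and the slow calcium upstroke are the
hallmarks of the immature phenotype.
"""

import cardioinverse as ci
from cardioinverse.models import PacingProtocol

model = ci.build_base_model()
trace = ci.simulate(model, protocol=PacingProtocol(n_prepace=0, n_record=1, start_from="paced"))
features = ci.extract_features(trace)

print(f"model: {model.name}")
print(f"resting potential : {trace.v.min():8.1f} mV")
print(f"peak potential    : {trace.v.max():8.1f} mV")
for name, value in features.as_dict().items():
    print(f"{name:9s} : {value:.6g}")
print("\nAPD_V,x is the duration between the x%-repolarization crossings;")
print("dcdt_max is the maximal calcium upstroke velocity in mM/ms.")
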
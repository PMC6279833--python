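"""Map the immature model to its mature counterpart and compare beats.

Applies the printed diagonal maturation map to the immature base model and
simulates both parameterizations.  The mature cell shows the adult phenotype:
a hyperpolarized resting potential, a shorter action potential and a much
faster calcium upstroke.
"""

import cardioinverse as ci
from cardioinverse.models import PacingProtocol

model = ci.build_base_model()
p_im = ci.ParameterVector.ones(model.parameter_names)
p_m = ci.apply_map(ci.paci_map(), p_im)

proto = PacingProtocol(n_prepace=30, n_record=1)
f_im = ci.extract_features(ci.simulate(model, p_im, proto))
f_m = ci.extract_features(ci.simulate(model, p_m, proto))

print(f"{'feature':10s} {'immature':>12s} {'mature':>12s}")
for name in ("apd_v30", "apd_v50", "apd_v80", "dcdt_max", "apd_ca80"):
    print(f"{name:10s} {getattr(f_im, name):12.4g} {getattr(f_m, name):12.4g}")
print("\nMaturation shortens the AP and accelerates the calcium transient;")
print("the map itself is diagonal, so drug blocks commute with it.")
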
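"""Single-factor sensitivity of the demand curve to the contact frequency.

The sensitivity function SF(beta) compares the relative change of the
total demand curve — read at five instants — with the relative change of
one parameter, in a Euclidean-style relative norm.  This script first
calibrates the machinery on a toy model with outputs proportional to the
parameter (exact answer sqrt(5)), then scans the within-community
contact frequency lambda0 on the synthetic case fixture.
"""

import numpy as np

from evacsi import (
    SensitivityConfig,
    initial_state,
    sensitivity_of,
    sensitivity_scan,
    tianjin_like_scenario,
)

sf = sensitivity_of(lambda b: [b, 2 * b, 3 * b, 4 * b, 5 * b], 0.37)
print(f"calibration: proportional toy model gives SF = {sf:.6f} (exact sqrt(5) = {np.sqrt(5):.6f})")

layout, params, anchor = tianjin_like_scenario(seed=0)
init = initial_state(layout, params, anchor)
cfg = SensitivityConfig()  # outputs at t = 24, 48, 72, 96, 120 h

res = sensitivity_scan("lambda0", (0.02, 1.0), 25, layout, init, cfg, params)
print(f"\nlambda0 scan over [0.02, 1.0], reference 0.25:")
for v, s in zip(res.values[::4], res.sf[::4]):
    print(f"  lambda0 = {v:5.3f}   SF = {s:6.3f}")
print(f"maximum SF = {res.maximum:.4f}, average SF = {res.average:.4f}")
print(
    "\nSF rises steeply at small lambda0 — when contacts are scarce the\n"
    "demand curve reacts strongly to adding them — then declines once\n"
    "contagion is fast enough that demand saturates within the horizon."
)
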
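"""Warning forcing: piecewise decay with upward jumps at each order.

Shows the warning influence w(t) for the two-order case schedule — a
hyperbolic decay restarting at each issuance — and how raising the
second order's strength reshapes the demand curve.
"""

import numpy as np

from evacsi import (
    WarningSchedule,
    aggregate,
    initial_state,
    integrate,
    set_param,
    tianjin_like_scenario,
    warning_level,
)

schedule = WarningSchedule(
    breakpoints=(0.0, 60.0),
    pieces=((0.01, 0.001), (0.2, 0.01)),
    mode="hyperbolic_reset",
)
print("w(t) for the two-order schedule (orders at t=0 and t=60 h):")
for t in (0.0, 10.0, 59.9, 60.0, 70.0, 120.0):
    print(f"  t = {t:6.1f} h   w = {warning_level(t, schedule):.5f} /h")
print("note the upward jump at t = 60: a stronger order restarts the decay higher\n")

layout, params, anchor = tianjin_like_scenario(seed=0)
init = initial_state(layout, params, anchor)
for a4 in (0.05, 0.2, 0.8):
    p = set_param(params, "a4", a4)
    curves = aggregate(integrate(layout, p, init, dt=1.0, horizon=120.0))
    print(
        f"second-order strength a4 = {a4:4.2f}: "
        f"evacuated fraction at t=72 h = {curves.frac_total[72]:.3f}"
    )
print(
    "\nA stronger second order pulls demand forward — the lever an\n"
    "authority can actually move during an evacuation."
)
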
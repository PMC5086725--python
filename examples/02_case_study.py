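"""The synthetic 61-community case: demand curves under four influences.

Generates the seeded layout emulating the 2015 Tianjin-explosions
setting (61 communities, 115,350 residents within 0.67-6.10 km of the
risk source, two warning orders at t = 0 and t = 60 h), integrates the
full model at the hourly step, and prints the features of the resulting
evacuation demand curves.
"""

import numpy as np

from evacsi import aggregate, initial_state, integrate, tianjin_like_scenario

layout, params, anchor = tianjin_like_scenario(seed=0)
init = initial_state(layout, params, anchor)
traj = integrate(layout, params, init, dt=1.0, horizon=120.0)
curves = aggregate(traj)

Q = layout.total_population
print(f"communities: {layout.n}, residents: {Q:,.0f}")
print(f"evacuated at t=0:   {curves.total[0]:7.0f}  ({100 * curves.frac_total[0]:.2f} %)")
print(f"evacuated at t=120: {curves.total[-1]:7.0f}  ({100 * curves.frac_total[-1]:.2f} %)")

inc = curves.hourly_increments / Q
peak = int(np.argmax(inc))
print(f"\nhourly increment peaks at {inc.max():.4f} of the population (hour {peak + 1})")
print(
    f"across the second order at t=60: {inc[59]:.4f} -> {inc[60]:.4f} "
    "(the stronger warning accelerates demand)"
)

ft = curves.frac_by_type[-1]
print(
    f"\nfinal fractions by type: impressionable {ft[0]:.3f} > "
    f"neutral {ft[1]:.3f} > standpat {ft[2]:.3f}"
)
fc = curves.frac_by_community
print(
    f"community 1 (0.67 km) leads at every hour: "
    f"{bool(np.all(fc[:, [0]] >= fc - 1e-12))}"
)
print(
    "\nThe total curve is S-shaped: demand grows slowly while few have\n"
    "evacuated, accelerates as social contagion compounds, and flattens\n"
    "as communities saturate; the t=60 order injects a visible kink."
)
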
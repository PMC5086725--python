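# evacsi

Disaster **evac**uation demand curves from a modified **S**usceptible–**I**nfective
metapopulation model.

When a disaster strikes, the time profile at which residents decide to
leave — the *evacuation demand curve* — drives every downstream planning
decision (staging, routing, congestion). `evacsi` is for researchers and
emergency-planning analysts who want a mechanistic, tunable generator of
such curves rather than a fitted S-curve: the decision to evacuate is
modelled as a contagion spreading through a set of communities, shaped by
individual disposition, geography and official warnings.

## The model

A risk area holds $N$ communities; community $j$ has $Q_{jk}$ residents of
behavioural type $k \in \{1,2,3\}$ ("Impressionable", "Neutral",
"Standpat"). $I_{jk}(t)$ residents have decided to evacuate,
$S_{jk} = Q_{jk} - I_{jk}$ have not; the decision is irreversible. The
dynamics are the $3N$ coupled ODEs

$$\frac{dI_{jk}}{dt} = \gamma_k\Big[\lambda_0 \frac{S_{jk}}{Q_j} I_j
\;+\; \frac{S_{jk}}{Q_j}\sum_k \sum_{i\ne j} I_{ik}\,\lambda(d_{ij})\,h(d_{i0})
\;+\; S_{jk}\,f(d_{j0},t) \;+\; S_{jk}\,w(t)\Big]$$

with $\gamma_1 > \gamma_2 > \gamma_3 > 0$ the per-type responsiveness, and
four influences:

- **within-community contagion** at contact frequency $\lambda_0$;
- **between-community contagion** through a Gaussian contact kernel
  $\lambda(d) = \lambda_0\alpha/(\sqrt{2\pi}\sigma)\, e^{-d^2/2\sigma^2}$,
  weighted by the sender's location weight $h(d) = a_1 d + b_1$ (evacuees
  from low-risk, distant communities are more persuasive — the driver of
  *shadow evacuation*);
- **geographic pressure** $f(d,t) = a_2/(d^2 + b_2 t + 10)$, decaying in
  distance to the risk source and in time;
- **warning forcing** $w(t)$, a piecewise function decaying within each
  warning degree (default $a_i/((t - t_i) + 10) + b_i$) and jumping upward
  when a stronger order is issued.

Integration is fixed-step forward Euler (hourly by default) with clamping
to $[0, Q_{jk}]$; the reduced single-community limit is the classic
logistic $I(t) = Q/(1 + (Q/I_0 - 1)e^{-\gamma\lambda_0 t})$, which serves
as the integrator's analytic oracle. A dimensionless single-factor
sensitivity function

$$SF(\beta) = \left\lVert \frac{O(\beta + \Delta\beta) - O(\beta)}{O(\beta)} \right\rVert_2 \Big/ \left|\frac{\Delta\beta}{\beta}\right|,
\qquad O(\beta) = \big(I(t_1),\dots,I(t_5)\big)$$

ranks parameters by their leverage on the total curve.

Because the motivating case's community map (the 2015 Tianjin port
explosions: 61 communities, ~115,350 residents within 0.67–6.10 km) is
not public, the package ships a seeded synthetic scenario generator that
reproduces the published facts and pins five communities to their
reported source distances.

## Worked example

```bash
python examples/02_case_study.py
```

```
communities: 61, residents: 115,350
evacuated at t=0:      1088  (0.94 %)
evacuated at t=120:  114168  (98.98 %)

hourly increment peaks at 0.0215 of the population (hour 61)
across the second order at t=60: 0.0183 -> 0.0215 (the stronger warning accelerates demand)

final fractions by type: impressionable 1.000 > neutral 0.996 > standpat 0.974
community 1 (0.67 km) leads at every hour: True
```

Under one percent of the population has decided to leave when the first
order is issued; contagion then compounds into an S-shaped curve, the
second order at $t = 60$ h visibly accelerates hourly demand
(0.0183 → 0.0215 of the population per hour), the "Impressionable" type
leads the other two throughout, and the community nearest the risk source
leads every other community at every hour. `examples/01_logistic_limit.py`,
`03_sensitivity_scan.py` and `04_warning_schedules.py` walk the other
capabilities; the `evacsi` CLI (`simulate`, `sensitivity`,
`scenario generate`) wraps the same functions for shell use:

```bash
evacsi simulate --seed 0 --out runs/      # trajectory.csv + summary.json
evacsi sensitivity --param lambda0 --range 0.02:1 --grid 25 --out runs/
evacsi scenario generate --preset tianjin --seed 0 --out layout.csv
```

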
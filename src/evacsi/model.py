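"""Metapopulation SI dynamics of evacuation decisions.

The risk area holds N communities, each split into three behavioural
types (k = 1 "Impressionable", k = 2 "Neutral", k = 3 "Standpat").  With
Q_jk residents of type k in community j, I_jk(t) of whom have decided to
evacuate (S_jk = Q_jk − I_jk have not), the decision dynamics are the
3N coupled ODEs

    dI_jk/dt = γ_k · [ λ0 · (S_jk/Q_j) · I_j
                       + (S_jk/Q_j) · Σ_k Σ_{i≠j} I_ik · λ(d_ij) · h(d_i0)
                       + S_jk · f(d_j0, t)
                       + S_jk · w(t) ]

i.e. within-community contagion, between-community contagion weighted by
the Gaussian contact kernel λ and the sender's location weight h, direct
geographic pressure f, and the official warning forcing w.  γ1 > γ2 > γ3
order the types' responsiveness.  Evacuation is irreversible, so every
I_jk(t) is non-decreasing and S_jk + I_jk = Q_jk is conserved exactly.

Integration is fixed-step forward Euler (the hourly iteration of the
source method), with post-step clamping to [0, Q_jk] guarding overshoot
at coarse steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .influence import (
    KernelParams,
    LocationParams,
    WarningSchedule,
    contact_kernel,
    geo_decay,
    location_weight,
    warning_level,
)

__all__ = [
    "CommunityLayout",
    "ModelParameters",
    "EvacuationState",
    "Trajectory",
    "DemandCurves",
    "initial_state",
    "rhs",
    "coupling_matrix",
    "integrate",
    "closed_form_logistic",
    "aggregate",
]

N_TYPES = 3


@dataclass(frozen=True)
class CommunityLayout:
    """Geometry and populations of the risk area.

    Attributes
    ----------
    dist_to_source : (n,) array
        Distances d_j0 from each community to the risk source, km;
        strictly positive.
    pairwise : (n, n) array
        Symmetric inter-community distances d_ij, km, zero diagonal.
    populations : (3, n) array
        Q_jk, residents of type k in community j (row k, column j);
        non-negative, continuous.
    """

    dist_to_source: NDArray[np.float64]
    pairwise: NDArray[np.float64]
    populations: NDArray[np.float64]

    def __post_init__(self) -> None:
        d0 = np.atleast_1d(np.asarray(self.dist_to_source, dtype=float))
        dij = np.asarray(self.pairwise, dtype=float)
        q = np.asarray(self.populations, dtype=float)
        n = d0.shape[0]
        if dij.shape != (n, n):
            raise ValueError(f"pairwise must be ({n}, {n}), got {dij.shape}")
        if q.shape != (N_TYPES, n):
            raise ValueError(f"populations must be ({N_TYPES}, {n}), got {q.shape}")
        if np.any(d0 <= 0):
            raise ValueError("dist_to_source must be strictly positive")
        if np.any(dij < 0):
            raise ValueError("pairwise distances must be >= 0")
        if not np.allclose(dij, dij.T):
            raise ValueError("pairwise matrix must be symmetric")
        if np.any(np.diag(dij) != 0):
            raise ValueError("pairwise diagonal must be zero")
        if np.any(q < 0):
            raise ValueError("populations must be >= 0")
        object.__setattr__(self, "dist_to_source", d0)
        object.__setattr__(self, "pairwise", dij)
        object.__setattr__(self, "populations", q)

    @property
    def n(self) -> int:
        return self.dist_to_source.shape[0]

    @property
    def pop_by_community(self) -> NDArray[np.float64]:
        """Q_j = Σ_k Q_jk."""
        return self.populations.sum(axis=0)

    @property
    def total_population(self) -> float:
        return float(self.populations.sum())


@dataclass(frozen=True)
class ModelParameters:
    """All rate parameters of the model.

    gamma holds the per-type effective transformation rates
    (γ1, γ2, γ3), constrained γ1 > γ2 > γ3 > 0.
    """

    gamma: tuple[float, float, float] = (0.5, 0.3, 0.2)
    kernel: KernelParams = field(default_factory=KernelParams)
    location: LocationParams = field(default_factory=LocationParams)
    warning: WarningSchedule = field(
        default_factory=lambda: WarningSchedule(
            breakpoints=(0.0,), pieces=((0.0, 0.0),)
        )
    )

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.gamma)
        if len(g) != N_TYPES:
            raise ValueError(f"gamma must have {N_TYPES} entries")
        if not (g[0] > g[1] > g[2] > 0):
            raise ValueError(f"need gamma1 > gamma2 > gamma3 > 0, got {g}")
        object.__setattr__(self, "gamma", g)


@dataclass(frozen=True)
class EvacuationState:
    """Evacuated counts I_jk at a single time (continuous counts)."""

    t: float
    I: NDArray[np.float64]

    def __post_init__(self) -> None:
        I = np.asarray(self.I, dtype=float)
        if I.ndim != 2 or I.shape[0] != N_TYPES:
            raise ValueError(f"I must be ({N_TYPES}, n), got {I.shape}")
        if np.any(I < 0):
            raise ValueError("evacuated counts must be >= 0")
        object.__setattr__(self, "I", I)

    def S(self, layout: CommunityLayout) -> NDArray[np.float64]:
        """Unevacuated counts S_jk = Q_jk − I_jk."""
        return layout.populations - self.I


@dataclass(frozen=True)
class Trajectory:
    """I_jk on a fixed time grid, with the inputs that produced it."""

    times: NDArray[np.float64]
    I: NDArray[np.float64]  # (T+1, 3, n)
    layout: CommunityLayout
    params: ModelParameters
    dt: float
    seed: int | None = None


def initial_state(
    layout: CommunityLayout,
    params: ModelParameters,
    anchor: tuple[int, int, float],
    power: int = 3,
) -> EvacuationState:
    """Initial evacuated counts from a single anchored observation.

    One group's initial count is known: ``anchor = (j_star, k_star,
    count)`` (0-based community and type indices).  Every other group is
    filled in by three proportionality rules: the per-type rate ratio
    γ_k/γ_1, an inverse power of distance to the risk source
    (d_anchor/d_j)^power — closer communities start with a larger
    evacuated fraction — and the group-size ratio Q_jk/Q_anchor:

        I_jk(0) = (γ_k/γ_1) · (d_{j*,0}/d_{j,0})^power
                  · (Q_jk/Q_{j*k*}) · count

    ``power`` is 3 by default; 1 or 2 soften the distance effect.
    Results are clamped to [0, Q_jk].
    """
    j_star, k_star, count = anchor
    q = layout.populations
    q_anchor = q[k_star, j_star]
    if q_anchor <= 0:
        raise ValueError("anchor group has no population")
    if count > q_anchor:
        raise ValueError(
            f"anchor count {count} exceeds its group population {q_anchor}"
        )
    if count < 0:
        raise ValueError("anchor count must be >= 0")
    gamma = np.asarray(params.gamma)
    d0 = layout.dist_to_source
    dist_ratio = (d0[j_star] / d0) ** power  # (n,)
    I0 = (
        (gamma / gamma[0])[:, None]
        * dist_ratio[None, :]
        * (q / q_anchor)
        * count
    )
    I0 = np.clip(I0, 0.0, q)
    return EvacuationState(t=0.0, I=I0)


def coupling_matrix(
    layout: CommunityLayout, kernel: KernelParams, location: LocationParams
) -> NDArray[np.float64]:
    """K[i, j] = λ(d_ij) · h(d_i0) for i ≠ j, zero diagonal.

    Row i carries the influence community i exerts on every other
    community: contact frequency by separation, weighted by the sender's
    own location weight.
    """
    K = contact_kernel(layout.pairwise, kernel)
    K = K * np.asarray(location_weight(layout.dist_to_source, location))[:, None]
    np.fill_diagonal(K, 0.0)
    return K


def _rhs_array(
    t: float,
    I: NDArray[np.float64],
    layout: CommunityLayout,
    params: ModelParameters,
    K: NDArray[np.float64],
) -> NDArray[np.float64]:
    """dI/dt as a (3, n) array; K is the precomputed coupling matrix."""
    Q = layout.populations
    S = Q - I
    Qj = layout.pop_by_community
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(Qj > 0, S / np.where(Qj > 0, Qj, 1.0), 0.0)  # S_jk / Q_j
    Ij = I.sum(axis=0)  # (n,)
    incoming = Ij @ K  # Σ_k Σ_{i≠j} I_ik λ(d_ij) h(d_i0), per community j
    f = geo_decay(layout.dist_to_source, t, params.location)  # (n,)
    w = warning_level(t, params.warning)  # scalar
    gamma = np.asarray(params.gamma)[:, None]
    dIdt = gamma * (
        params.kernel.lambda0 * share * Ij[None, :]
        + share * incoming[None, :]
        + S * np.asarray(f)[None, :]
        + S * w
    )
    return dIdt


def rhs(
    state: EvacuationState, layout: CommunityLayout, params: ModelParameters
) -> NDArray[np.float64]:
    """Instantaneous rates dI_jk/dt for a state.

    Every entry is non-negative, and exactly zero wherever S_jk = 0
    (saturated groups stop changing).
    """
    if state.I.shape != layout.populations.shape:
        raise ValueError(
            f"state shape {state.I.shape} does not match layout "
            f"{layout.populations.shape}"
        )
    if np.any(state.I > layout.populations + 1e-9):
        raise ValueError("evacuated counts exceed group populations")
    K = coupling_matrix(layout, params.kernel, params.location)
    return _rhs_array(state.t, state.I, layout, params, K)


def integrate(
    layout: CommunityLayout,
    params: ModelParameters,
    init: EvacuationState,
    dt: float = 1.0,
    horizon: float = 120.0,
    seed: int | None = None,
) -> Trajectory:
    """Forward-Euler integration of the 3N-equation system.

    ``I ← clip(I + dt · dI/dt, 0, Q)`` on the grid 0, dt, …, horizon.
    Every warning issuance time inside the horizon must lie on the grid,
    so that the jump in w(t) is seen by the iteration exactly at the
    issuance; otherwise a ValueError asks for a compatible dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if horizon < dt:
        raise ValueError("horizon must be >= dt")
    n_steps = int(round(horizon / dt))
    if abs(n_steps * dt - horizon) > 1e-9 * max(1.0, horizon):
        raise ValueError(f"horizon {horizon} is not a multiple of dt {dt}")
    for t_issue in params.warning.breakpoints:
        if 0 <= t_issue <= horizon:
            k = t_issue / dt
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"warning issuance at t={t_issue} h does not fall on the "
                    f"dt={dt} h grid; choose dt dividing every issuance time"
                )
    if init.I.shape != layout.populations.shape:
        raise ValueError("initial state does not match layout")

    K = coupling_matrix(layout, params.kernel, params.location)
    Q = layout.populations
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1,) + init.I.shape)
    I = np.clip(init.I, 0.0, Q)
    out[0] = I
    for step in range(n_steps):
        t = step * dt
        I = np.clip(I + dt * _rhs_array(t, I, layout, params, K), 0.0, Q)
        out[step + 1] = I
    return Trajectory(times=times, I=out, layout=layout, params=params, dt=dt, seed=seed)


def closed_form_logistic(
    t: ArrayLike, Q: float, I0: float, rate: float
) -> NDArray[np.float64] | float:
    """Logistic evacuated count I(t) = Q / (1 + (Q/I0 − 1)·e^(−rate·t)).

    Exact solution of the reduced model — one community, one type, no
    between-community, geographic or warning terms — where
    dI/dt = rate · (S/Q) · I with rate = γ·λ0.  Serves as the analytic
    oracle for the numerical integrator.
    """
    if not 0 < I0 < Q:
        raise ValueError(f"need 0 < I0 < Q, got I0={I0}, Q={Q}")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    t = np.asarray(t, dtype=float)
    out = Q / (1.0 + (Q / I0 - 1.0) * np.exp(-rate * t))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DemandCurves:
    """Aggregated evacuation demand curves from a trajectory.

    All curves share the trajectory grid; fractions are of the total
    population of the respective group.  ``hours``/``hourly_increments``
    give the total demand added over each whole-hour interval.
    """

    times: NDArray[np.float64]
    by_community: NDArray[np.float64]  # (T+1, n) I_j(t)
    by_type: NDArray[np.float64]  # (T+1, 3) I_k(t)
    total: NDArray[np.float64]  # (T+1,)  I(t)
    frac_by_community: NDArray[np.float64]
    frac_by_type: NDArray[np.float64]
    frac_total: NDArray[np.float64]
    hours: NDArray[np.float64]
    hourly_increments: NDArray[np.float64]


def aggregate(traj: Trajectory) -> DemandCurves:
    """Community-level, type-level and total demand curves.

    The regroupings are exact: Σ_j I_j(t) = Σ_k I_k(t) = I(t) at every
    grid point, and the hourly increments sum to I(T) − I(0).
    """
    by_comm = traj.I.sum(axis=1)  # (T+1, n)
    by_type = traj.I.sum(axis=2)  # (T+1, 3)
    total = by_comm.sum(axis=1)
    Qj = traj.layout.pop_by_community
    Qk = traj.layout.populations.sum(axis=1)
    Q = traj.layout.total_population
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_comm = np.where(Qj > 0, by_comm / np.where(Qj > 0, Qj, 1.0), 0.0)
        frac_type = np.where(Qk > 0, by_type / np.where(Qk > 0, Qk, 1.0), 0.0)
    frac_total = total / Q

    t_end = traj.times[-1]
    hours = np.arange(0.0, np.floor(t_end) + 0.5)
    totals_at_hours = np.interp(hours, traj.times, total)
    increments = np.diff(totals_at_hours)
    return DemandCurves(
        times=traj.times,
        by_community=by_comm,
        by_type=by_type,
        total=total,
        frac_by_community=frac_comm,
        frac_by_type=frac_type,
        frac_total=frac_total,
        hours=hours[1:],
        hourly_increments=increments,
    )
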
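"""Dimensionless single-factor local sensitivity analysis.

The model output for sensitivity purposes is the total demand curve
sampled at five instants, O(β) = (I(t1), …, I(t5)).  The sensitivity of
output to a parameter β is the ratio of the relative output change to
the relative parameter change, in a Euclidean-style relative norm:

    SF(β) = ‖(O(β+Δβ) − O(β)) / O(β)‖₂ / |Δβ/β|,   Δβ = rel_step·β

The forward difference approximates the Δβ → 0 limit; a central variant
is available.  SF is dimensionless and invariant under rescaling all
outputs by a common factor, so curves measured in people or in fractions
give the same value.  A parameter the model does not use yields SF = 0
identically, and a model whose every output is proportional to β yields
SF = √5 exactly — the two calibration points used in the tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.typing import NDArray

from .model import (
    CommunityLayout,
    EvacuationState,
    ModelParameters,
    aggregate,
    integrate,
)

__all__ = [
    "SensitivityConfig",
    "SensitivityResult",
    "model_output",
    "relative_norm",
    "set_param",
    "sensitivity_of",
    "sensitivity_at",
    "sensitivity_scan",
    "PARAMETER_NAMES",
]


@dataclass(frozen=True)
class SensitivityConfig:
    """Evaluation instants, step sizes and scheme for the SF.

    ``output_times`` are the five instants t1 < … < t5 (hours) at which
    the total demand curve is read; they must lie on the integration
    grid.  ``rel_step`` is the relative perturbation of the forward
    (or central) difference.
    """

    output_times: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0, 120.0)
    rel_step: float = 1e-3
    dt: float = 1.0
    scheme: str = "forward"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.output_times)
        if len(times) != 5:
            raise ValueError("output_times must hold exactly five instants")
        if times[0] <= 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("output_times must be strictly increasing and positive")
        if not 0 < self.rel_step < 0.5:
            raise ValueError("rel_step must be in (0, 0.5)")
        if self.scheme not in ("forward", "central"):
            raise ValueError("scheme must be 'forward' or 'central'")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        object.__setattr__(self, "output_times", times)


@dataclass(frozen=True)
class SensitivityResult:
    """SF values of one parameter over a grid, with summaries."""

    parameter: str
    values: NDArray[np.float64]
    sf: NDArray[np.float64]
    maximum: float
    average: float


def model_output(
    layout: CommunityLayout,
    params: ModelParameters,
    init: EvacuationState,
    cfg: SensitivityConfig,
) -> NDArray[np.float64]:
    """Total evacuated counts at the five output instants.

    Runs a full simulation to the last instant and reads the total
    demand curve at each t_i, which must fall on the dt grid.
    """
    horizon = cfg.output_times[-1]
    traj = integrate(layout, params, init, dt=cfg.dt, horizon=horizon)
    total = aggregate(traj).total
    out = np.empty(5)
    for i, t in enumerate(cfg.output_times):
        k = t / cfg.dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"output time {t} h is off the dt={cfg.dt} h grid")
        out[i] = total[int(round(k))]
    return out


def relative_norm(O_new: Sequence[float], O_old: Sequence[float]) -> float:
    """‖(O_new − O_old)/O_old‖₂ — Euclidean norm of componentwise relative changes."""
    O_new = np.asarray(O_new, dtype=float)
    O_old = np.asarray(O_old, dtype=float)
    if O_new.shape != O_old.shape:
        raise ValueError("output vectors must have equal length")
    if np.any(O_old <= 0):
        raise ValueError("reference outputs must be strictly positive")
    return float(np.sqrt(np.sum(((O_new - O_old) / O_old) ** 2)))


# name -> (getter, setter) over ModelParameters; setters return a new object
def _set_gamma(p: ModelParameters, k: int, v: float) -> ModelParameters:
    g = list(p.gamma)
    g[k] = v
    return dataclasses.replace(p, gamma=tuple(g))


def _set_kernel(p: ModelParameters, name: str, v: float) -> ModelParameters:
    return dataclasses.replace(p, kernel=dataclasses.replace(p.kernel, **{name: v}))


def _set_location(p: ModelParameters, name: str, v: float) -> ModelParameters:
    return dataclasses.replace(p, location=dataclasses.replace(p.location, **{name: v}))


def _set_warning(p: ModelParameters, piece: int, coeff: int, v: float) -> ModelParameters:
    if piece >= len(p.warning.pieces):
        raise ValueError(
            f"schedule has {len(p.warning.pieces)} pieces; no piece {piece}"
        )
    pieces = [list(ab) for ab in p.warning.pieces]
    pieces[piece][coeff] = v
    warning = dataclasses.replace(
        p.warning, pieces=tuple(tuple(ab) for ab in pieces)
    )
    return dataclasses.replace(p, warning=warning)


_SETTERS: dict[str, Callable[[ModelParameters, float], ModelParameters]] = {
    "lambda0": lambda p, v: _set_kernel(p, "lambda0", v),
    "alpha": lambda p, v: _set_kernel(p, "alpha", v),
    "sigma": lambda p, v: _set_kernel(p, "sigma", v),
    "gamma1": lambda p, v: _set_gamma(p, 0, v),
    "gamma2": lambda p, v: _set_gamma(p, 1, v),
    "gamma3": lambda p, v: _set_gamma(p, 2, v),
    "a1": lambda p, v: _set_location(p, "a1", v),
    "b1": lambda p, v: _set_location(p, "b1", v),
    "a2": lambda p, v: _set_location(p, "a2", v),
    "b2": lambda p, v: _set_location(p, "b2", v),
    # warning coefficients named after the two-degree case: piece 0 = (a3, b3),
    # piece 1 = (a4, b4)
    "a3": lambda p, v: _set_warning(p, 0, 0, v),
    "b3": lambda p, v: _set_warning(p, 0, 1, v),
    "a4": lambda p, v: _set_warning(p, 1, 0, v),
    "b4": lambda p, v: _set_warning(p, 1, 1, v),
}

PARAMETER_NAMES: tuple[str, ...] = tuple(_SETTERS)


def set_param(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """A copy of ``params`` with one named parameter replaced.

    All model invariants (γ ordering, jump-up property, positivity) are
    re-validated on construction, so an out-of-range value raises.
    """
    if name not in _SETTERS:
        raise KeyError(f"unknown parameter {name!r}; known: {PARAMETER_NAMES}")
    return _SETTERS[name](params, float(value))


def sensitivity_of(
    output_fn: Callable[[float], Sequence[float]],
    value: float,
    rel_step: float = 1e-3,
    scheme: str = "forward",
) -> float:
    """SF of an arbitrary 5-output model at a parameter value.

    Core finite-difference kernel shared by the evacuation model and by
    calibration tests with analytic toy models.
    """
    if value <= 0:
        raise ValueError("parameter value must be > 0 for a relative perturbation")
    if scheme == "forward":
        O_base = np.asarray(output_fn(value), dtype=float)
        O_pert = np.asarray(output_fn(value * (1.0 + rel_step)), dtype=float)
        return relative_norm(O_pert, O_base) / rel_step
    O_base = np.asarray(output_fn(value), dtype=float)
    O_plus = np.asarray(output_fn(value * (1.0 + rel_step)), dtype=float)
    O_minus = np.asarray(output_fn(value * (1.0 - rel_step)), dtype=float)
    if np.any(O_base <= 0):
        raise ValueError("reference outputs must be strictly positive")
    rel = (O_plus - O_minus) / O_base
    return float(np.sqrt(np.sum(rel**2))) / (2.0 * rel_step)


def sensitivity_at(
    param_name: str,
    value: float,
    layout: CommunityLayout,
    init: EvacuationState,
    cfg: SensitivityConfig,
    base_params: ModelParameters,
) -> float:
    """SF of the evacuation model for one parameter at one value."""

    def output_fn(v: float) -> NDArray[np.float64]:
        return model_output(layout, set_param(base_params, param_name, v), init, cfg)

    return sensitivity_of(output_fn, value, rel_step=cfg.rel_step, scheme=cfg.scheme)


def sensitivity_scan(
    param_name: str,
    value_range: tuple[float, float],
    n_grid: int,
    layout: CommunityLayout,
    init: EvacuationState,
    cfg: SensitivityConfig,
    base_params: ModelParameters,
) -> SensitivityResult:
    """SF over an even grid spanning ``value_range``, with max and mean.

    Every grid value (and its perturbed companion) must satisfy the
    model's parameter constraints; a range that breaks them — e.g. a γ1
    grid dipping below γ2 — is rejected up front.
    """
    lo, hi = value_range
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got {value_range}")
    values = np.linspace(lo, hi, n_grid)
    for v in (lo, hi):
        # constraint violations surface here rather than mid-scan
        set_param(base_params, param_name, v)
        set_param(base_params, param_name, v * (1.0 + cfg.rel_step))
    sf = np.array(
        [
            sensitivity_at(param_name, v, layout, init, cfg, base_params)
            for v in values
        ]
    )
    return SensitivityResult(
        parameter=param_name,
        values=values,
        sf=sf,
        maximum=float(sf.max()),
        average=float(sf.mean()),
    )
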
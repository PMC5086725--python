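"""Scalar influence functions of the evacuation-contagion model.

Four time/space-dependent influences drive the decision dynamics:

* :func:`contact_kernel` — between-community contact frequency, a scaled
  Gaussian in inter-community distance;
* :func:`location_weight` — persuasiveness weight of messages originating
  in a community, increasing with that community's distance to the risk
  source (evacuees from low-risk areas are more convincing);
* :func:`geo_decay` — direct location-driven evacuation pressure, decaying
  in both distance to the source and elapsed time;
* :func:`warning_level` — piecewise forcing representing official warning
  degrees, decaying within each degree and jumping upward when a stronger
  order is issued.

Distances are in kilometres, times in hours; every influence is returned
on an hour⁻¹ rate scale (dimensionless weights excepted).
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "KernelParams",
    "LocationParams",
    "WarningSchedule",
    "LinearScheduleReport",
    "contact_kernel",
    "location_weight",
    "geo_decay",
    "warning_level",
    "validate_linear_schedule",
]

#: Offset (hours) in the hyperbolic decay denominators a/((t - t_i) + 10) + b.
#: Part of the functional form of the warning and geographic influences.
DECAY_OFFSET = 10.0


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the Gaussian between-community contact kernel.

    Attributes
    ----------
    lambda0 : float
        Within-community contact frequency, contacts · hour⁻¹.
    alpha : float
        Dimensionless scaling of between-community contacts.
    sigma : float
        Kernel width, km.
    """

    lambda0: float = 0.25
    alpha: float = 0.01
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda0 < 0:
            raise ValueError(f"lambda0 must be >= 0, got {self.lambda0}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class LocationParams:
    """Coefficients of the location influences h(d) and f(d, t).

    ``h(d) = a1·d + b1`` weights messages by the sender community's
    distance to the risk source.  ``f(d, t)`` is the direct geographic
    pressure; the default coupled form is ``a2 / (d² + b2·t + 10)``, the
    separable alternative ``(a2/d²) · 1/(b2·t + 10)``.

    ``h_cap`` optionally bounds h(d) from above (h is otherwise unbounded
    in d); it is off by default.
    """

    a1: float = 1.0
    b1: float = 0.1
    a2: float = 0.01
    b2: float = 0.01
    f_mode: str = "coupled"
    h_cap: float | None = None

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "a2", "b2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.f_mode not in ("coupled", "separable"):
            raise ValueError(f"f_mode must be 'coupled' or 'separable', got {self.f_mode!r}")
        if self.h_cap is not None and self.h_cap <= 0:
            raise ValueError("h_cap, when set, must be > 0")


@dataclass(frozen=True)
class WarningSchedule:
    """Piecewise warning forcing w(t).

    Piece *i* is active on ``[breakpoints[i], breakpoints[i+1])`` and has
    coefficients ``pieces[i] = (a_i, b_i)``:

    ``hyperbolic_reset``
        ``a_i / ((t - t_i) + 10) + b_i`` — the decay clock restarts when
        each order is issued (default; each order injects a fresh effect).
    ``hyperbolic_global``
        ``a_i / (t + 10) + b_i`` — a single global decay clock.
    ``linear``
        ``a_i · t + b_i``.

    Before the first breakpoint w(t) equals ``baseline``.  In the
    hyperbolic modes, construction rejects schedules where a new piece
    does not start above the previous piece's value at the issuance time
    (a stronger order must raise the forcing).  In linear mode the
    slope/issuance-value orderings are checked instead
    (:func:`validate_linear_schedule`).
    """

    breakpoints: tuple[float, ...]
    pieces: tuple[tuple[float, float], ...]
    mode: str = "hyperbolic_reset"
    baseline: float = 0.0
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        object.__setattr__(self, "breakpoints", tuple(float(t) for t in self.breakpoints))
        object.__setattr__(
            self, "pieces", tuple((float(a), float(b)) for a, b in self.pieces)
        )
        if self.mode not in ("hyperbolic_reset", "hyperbolic_global", "linear"):
            raise ValueError(f"unknown warning mode {self.mode!r}")
        if len(self.breakpoints) != len(self.pieces):
            raise ValueError(
                f"{len(self.breakpoints)} breakpoints but {len(self.pieces)} pieces"
            )
        if len(self.breakpoints) == 0:
            raise ValueError("schedule needs at least one piece")
        bp = np.asarray(self.breakpoints)
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if bp[0] < 0:
            raise ValueError("breakpoints must be non-negative")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if not validate:
            return
        if self.mode == "linear":
            report = validate_linear_schedule(self)
            if not report.ok:
                raise ValueError(f"invalid linear schedule: {report.violation}")
        else:
            if any(a < 0 or b < 0 for a, b in self.pieces):
                raise ValueError("hyperbolic pieces need a >= 0 and b >= 0")
            self._check_jump_up()

    def _check_jump_up(self) -> None:
        """Each new degree must start above the outgoing degree's value."""
        for i in range(1, len(self.breakpoints)):
            t_i = self.breakpoints[i]
            start = _piece_value(t_i, i, self)
            prev = _piece_value(t_i, i - 1, self)
            if start <= prev:
                raise ValueError(
                    f"warning degree {i} starts at {start:.6g} at t={t_i:g}, "
                    f"not above the previous degree's value {prev:.6g}"
                )
        if self.breakpoints[0] > 0:
            start = _piece_value(self.breakpoints[0], 0, self)
            if start <= self.baseline:
                raise ValueError(
                    f"first warning degree starts at {start:.6g}, "
                    f"not above the baseline {self.baseline:.6g}"
                )


@dataclass(frozen=True)
class LinearScheduleReport:
    ok: bool
    violation: str | None = None


def _piece_value(t: ArrayLike, i: int, s: WarningSchedule) -> NDArray[np.float64]:
    t = np.asarray(t, dtype=float)
    a, b = s.pieces[i]
    if s.mode == "hyperbolic_reset":
        return a / ((t - s.breakpoints[i]) + DECAY_OFFSET) + b
    if s.mode == "hyperbolic_global":
        return a / (t + DECAY_OFFSET) + b
    return a * t + b


def contact_kernel(d: ArrayLike, p: KernelParams) -> NDArray[np.float64] | float:
    """Between-community contact frequency λ(d), hour⁻¹.

    ``λ(d) = λ0·α / (√(2π)·σ) · exp(−d² / (2σ²))`` — a Gaussian
    probability-density shape in the inter-community distance *d* (km),
    scaled by the within-community frequency λ0 and the dimensionless
    between-community factor α.  Strictly decreasing in d, vanishing as
    d → ∞; its integral over d ∈ [0, ∞) is λ0·α/2 (half-Gaussian mass).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = p.lambda0 * p.alpha / (np.sqrt(2.0 * np.pi) * p.sigma) * np.exp(
        -(d**2) / (2.0 * p.sigma**2)
    )
    return out if out.ndim else float(out)


def location_weight(d: ArrayLike, p: LocationParams) -> NDArray[np.float64] | float:
    """Persuasiveness weight h(d) = a1·d + b1 of a community at distance d.

    Messages from evacuees in communities far from the risk source (hence
    low-risk) carry more weight; h is non-decreasing in d.  If ``p.h_cap``
    is set, h is clipped to that ceiling.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = p.a1 * d + p.b1
    if p.h_cap is not None:
        out = np.minimum(out, p.h_cap)
    return out if out.ndim else float(out)


def geo_decay(
    d: ArrayLike, t: ArrayLike, p: LocationParams
) -> NDArray[np.float64] | float:
    """Direct geographic evacuation pressure f(d, t), hour⁻¹.

    Non-increasing in both the distance *d* (km) to the risk source and
    the elapsed time *t* (hours).  The coupled default is
    ``a2 / (d² + b2·t + 10)``; the separable mode
    ``(a2/d²) · 1/(b2·t + 10)`` requires d > 0.
    """
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if p.f_mode == "coupled":
        out = p.a2 / (d**2 + p.b2 * t + DECAY_OFFSET)
    else:
        if np.any(d == 0):
            raise ValueError("separable f(d, t) is undefined at d = 0")
        out = (p.a2 / d**2) / (p.b2 * t + DECAY_OFFSET)
    out = np.broadcast_arrays(out, d, t)[0]
    return out if np.ndim(out) else float(out)


def warning_level(t: ArrayLike, s: WarningSchedule) -> NDArray[np.float64] | float:
    """Warning forcing w(t), hour⁻¹, right-continuous at issuance times."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    bp = np.asarray(s.breakpoints)
    # piece index: last breakpoint <= t; -1 means before the first issuance
    idx = np.searchsorted(bp, t, side="right") - 1
    out = np.full(t.shape, s.baseline, dtype=float)
    for i in range(len(s.pieces)):
        mask = idx == i
        if np.any(mask):
            out[mask] = _piece_value(t[mask], i, s)
    return out if out.ndim else float(out)


def validate_linear_schedule(s: WarningSchedule) -> LinearScheduleReport:
    """Check the ordering constraints of a linear warning schedule.

    Successive degrees must have strictly increasing slopes
    (a1 < a2 < ...) and strictly increasing values at their issuance
    times (baseline < a1·t1 + b1 < a2·t2 + b2 < ...).  Returns a report
    naming the first violated inequality; a single piece passes the slope
    check vacuously.
    """
    if s.mode != "linear":
        raise ValueError("validate_linear_schedule applies to linear mode only")
    slopes = [a for a, _ in s.pieces]
    for i in range(1, len(slopes)):
        if not slopes[i - 1] < slopes[i]:
            return LinearScheduleReport(
                False,
                f"slope ordering violated: a_{i} = {slopes[i - 1]:g} "
                f"!< a_{i + 1} = {slopes[i]:g}",
            )
    values = [a * t + b for t, (a, b) in zip(s.breakpoints, s.pieces)]
    prev = s.baseline
    prev_name = "baseline"
    for i, v in enumerate(values, start=1):
        if not prev < v:
            return LinearScheduleReport(
                False,
                f"issuance-value ordering violated: {prev_name} = {prev:g} "
                f"!< a_{i}*t_{i}+b_{i} = {v:g}",
            )
        prev, prev_name = v, f"a_{i}*t_{i}+b_{i}"
    return LinearScheduleReport(True)
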
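"""NSC pool dynamics and the empirical-parameter unit conversions.

The neural-stem-cell pool is modelled as ``N(t) = N0 * exp(-k t)`` — an
exponential interpolation of the published human histology — while the
per-cell division rate ``r(t)`` rises linearly from its young-adult to its
aged-adult anchor (rodent time-lapse imaging: 1.37 vs 1.74 divisions per
48 h, i.e. 251 vs 318 per year).  The cumulative division count
``D(t) = integral_0^t r(s) ds`` is evaluated with the exact closed-form
piecewise-linear integral, so there is no quadrature error.

The conversion helpers reproduce the published arithmetic that turns raw
histology counts into model inputs (48-h division counts to annual rates;
cells per section to cells per mm of germinal tract).
"""

from __future__ import annotations

import numpy as np

from .params import DerivationConstants, DivisionSchedule, PopulationParams

__all__ = [
    "division_rate",
    "cumulative_divisions",
    "population_size",
    "annual_rate_from_48h",
    "cells_per_mm_from_section",
    "cells_per_tract_from_section",
]


def _check_ages(t) -> np.ndarray:
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 0):
        raise ValueError("ages must be finite and >= 0")
    return t_arr


def _as_input_shape(values: np.ndarray, t) -> "float | np.ndarray":
    if np.ndim(t) == 0:
        return float(values)
    return values


def division_rate(t, schedule: DivisionSchedule):
    """Division rate r(t) in divisions/cell/year at age(s) ``t``.

    Linear mode interpolates between the schedule anchors and clamps to the
    endpoint rates outside [t_start, t_end]; constant mode is r_young
    everywhere.
    """
    t_arr = _check_ages(t)
    if schedule.mode == "constant":
        r = np.full_like(t_arr, schedule.r_young)
    else:
        frac = (t_arr - schedule.t_start) / (schedule.t_end - schedule.t_start)
        frac = np.clip(frac, 0.0, 1.0)
        r = schedule.r_young + (schedule.r_aged - schedule.r_young) * frac
    return _as_input_shape(r, t)


def cumulative_divisions(t, schedule: DivisionSchedule):
    """Cumulative divisions D(t) = integral of r from 0 to t (closed form).

    The integrand is piecewise linear (clamped ramp), so the integral is
    evaluated exactly: rectangle before t_start, trapezoid inside the ramp,
    rectangle after t_end.  D(0) = 0 and D is strictly increasing.
    """
    t_arr = _check_ages(t)
    if schedule.mode == "constant":
        D = schedule.r_young * t_arr
        return _as_input_shape(D, t)

    a, b = schedule.t_start, schedule.t_end
    r0, r1 = schedule.r_young, schedule.r_aged
    slope = (r1 - r0) / (b - a)

    # segment up to the ramp start (rate r0)
    pre = r0 * np.minimum(t_arr, a)
    # segment inside the ramp: trapezoid of the linear rate
    s = np.clip(t_arr, a, b) - a
    ramp = r0 * s + 0.5 * slope * s**2
    # segment past the ramp end (rate r1)
    post = r1 * np.maximum(t_arr - b, 0.0)
    return _as_input_shape(pre + ramp + post, t)


def population_size(t, params: PopulationParams):
    """NSC count N(t) = N0 * exp(-k t): memoryless exponential decay."""
    t_arr = _check_ages(t)
    return _as_input_shape(params.N0 * np.exp(-params.k * t_arr), t)


def annual_rate_from_48h(
    divisions_per_48h: float,
    constants: DerivationConstants = DerivationConstants(),
) -> int:
    """Annualise a 48-hour time-lapse division count.

    Multiplies by the number of 48-h periods per year (default 183 = 366/2)
    and rounds to the nearest integer, reproducing the published annual
    rates: 1.37 -> 251 and 1.74 -> 318 divisions/cell/year.
    """
    if not np.isfinite(divisions_per_48h) or divisions_per_48h < 0:
        raise ValueError(
            f"divisions_per_48h must be finite and >= 0, got {divisions_per_48h!r}"
        )
    return int(round(divisions_per_48h * constants.periods_per_year))


def cells_per_mm_from_section(count: float, thickness_um: float) -> float:
    """Scale a per-section cell count to cells per mm of tissue.

    count * 1000/thickness_um; e.g. 144 cells per 200-um section -> 720
    cells per mm (and 22 cells per 30-um section -> 733, consistent to 2%).
    """
    if not np.isfinite(count) or count < 0:
        raise ValueError(f"count must be finite and >= 0, got {count!r}")
    return count * DerivationConstants.per_mm_scale(thickness_um)


def cells_per_tract_from_section(
    count: float,
    thickness_um: float,
    constants: DerivationConstants = DerivationConstants(),
) -> float:
    """Total cells in the germinal tract from a per-section count.

    The published chain: per-section count, scaled to per mm (x1000/
    thickness; x33 for 30-um sections), then by the 10-mm tract length.
    This is the derivation route for the initial NSC count N0; the final
    value still has to be supplied by the user because the extrapolation of
    the proliferative (KI67+) counts to birth is read off a graph.
    """
    return cells_per_mm_from_section(count, thickness_um) * constants.tract_length_mm
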
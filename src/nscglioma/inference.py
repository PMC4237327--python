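"""Calibration against age-grouped incidence data and bootstrap bands.

Two free parameters are fitted per scenario: the NSC decay constant ``k``
and the sequence multiplicity ``S``.  The initial pool size ``N0`` is held
fixed throughout because in the rare-event regime the incidence depends on
``N0`` and ``S`` only through their product, so the pair is not jointly
identifiable; every fit logs this.

Fitting minimises a relative-error-weighted sum of squared differences
between the model's bin-averaged incidence and the observed rates.  The
search is a bounded scalar optimisation over ``k``; for each candidate
``k`` the multiplicity ``S`` is profiled out in closed form (the incidence
is linear in ``S`` in the rare-event regime) and clipped to its ordering
cap ``n_min!``.

The bootstrap is parametric: per-bin event counts are drawn from a
binomial with the fitted model rate, empirical rates are rebuilt, the model
is refitted and rerun, and the 95% band is the pointwise percentile
envelope of the replicate incidence curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from . import pipeline
from .params import (
    DivisionSchedule,
    MutationParams,
    PopulationParams,
    SimulationGrid,
    ordering_cap,
)
from .pipeline import DEFAULT_SCALE, ModelCurves, run_model
from .tables import IncidenceTable

__all__ = [
    "CalibrationResult",
    "BootstrapResult",
    "bin_average_incidence",
    "fit",
    "nmin_sweep",
    "sweep_report",
    "calibrate_peak_age",
    "parametric_bootstrap",
    "GliomaIncidenceModel",
]

logger = logging.getLogger(__name__)

K_BOUNDS = (1e-4, 1.0)
DEFAULT_WEIGHT_FLOOR = 0.1  # per 100k py; guards relative weights on near-zero bins
DEFAULT_FEASIBLE_TOL = 0.05  # mean squared relative residual per bin
DEFAULT_PEAK_WINDOW = (75.0, 85.0)  # years; "peak at approximately 80"
_S_MIN = 1e-12


def bin_average_incidence(curves: ModelCurves, table: IncidenceTable) -> np.ndarray:
    """Time-average of the model incidence over each table bin.

    Trapezoidal mean of the incidence curve over [age_lo, age_hi), with an
    open-ended final bin closed at the grid horizon.  Every bin must lie
    inside the curve grid.
    """
    t = curves.t
    lo, hi = table.closed_edges(curves.grid.t_max)
    eps = 1e-9
    if lo[0] < t[0] - eps or hi[-1] > t[-1] + eps:
        raise ValueError(
            f"table bins [{lo[0]:g}, {hi[-1]:g}) extend beyond the curve grid "
            f"[{t[0]:g}, {t[-1]:g}]"
        )
    out = np.empty(len(table))
    for b in range(len(table)):
        mask = (t >= lo[b] - eps) & (t <= hi[b] + eps)
        tb = t[mask]
        if tb.size < 2:
            raise ValueError(f"bin [{lo[b]:g}, {hi[b]:g}) contains fewer than 2 grid points")
        out[b] = np.trapezoid(curves.incidence[mask], tb) / (tb[-1] - tb[0])
    return out


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a (k, S) calibration at a fixed n_min."""

    n_min: int
    k_hat: float
    S_hat: float
    objective: float
    peak_age_hat: float
    feasible: bool
    residuals: np.ndarray
    model_rates: np.ndarray
    observed: np.ndarray
    weights: np.ndarray
    curves: ModelCurves
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_min": self.n_min,
            "k_hat": self.k_hat,
            "S_hat": self.S_hat,
            "objective": self.objective,
            "peak_age_hat": self.peak_age_hat,
            "feasible": self.feasible,
        }


def _weights(observed: np.ndarray, floor: float) -> np.ndarray:
    return 1.0 / np.maximum(observed, floor) ** 2


def is_feasible(
    objective: float,
    peak_age_hat: float,
    n_bins: int,
    tol: float = DEFAULT_FEASIBLE_TOL,
    peak_window: tuple = DEFAULT_PEAK_WINDOW,
) -> bool:
    """Feasibility rule: small enough misfit and a peak in the stated window.

    ``tol`` bounds the mean (per-bin) weighted squared residual, so
    enlarging ``tol`` can only keep or gain feasibility.
    """
    return (objective <= tol * n_bins) and (peak_window[0] <= peak_age_hat <= peak_window[1])


def _fit_core(
    table: IncidenceTable,
    n_min: int,
    *,
    u: float,
    N0: float,
    S_init_cap: float | None = None,
    schedule: DivisionSchedule,
    grid: SimulationGrid,
    ordering_model: str = "factorial",
    n_onco: int = 29,
    G: int = 18440,
    k_bounds: tuple = K_BOUNDS,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    feasible_tol: float = DEFAULT_FEASIBLE_TOL,
    peak_window: tuple = DEFAULT_PEAK_WINDOW,
    scale: float = DEFAULT_SCALE,
    weights: np.ndarray | None = None,
) -> CalibrationResult:
    if len(table) == 0:
        raise ValueError("incidence table is empty")
    observed = table.rate
    if np.all(observed == 0.0):
        raise ValueError("all observed rates are zero; nothing to calibrate")
    if not (1 <= n_min <= n_onco):
        raise ValueError(f"n_min must lie in 1..{n_onco}, got {n_min}")

    logger.info(
        "calibrating (k, S) at n_min=%d with N0=%g held fixed: only the product "
        "N0*S is identified in the rare-event regime", n_min, N0,
    )

    # Default: relative-error weights from the observed rates.  Bootstrap
    # refits pass frozen weights instead, because recomputing 1/obs^2
    # weights from each noisy replicate correlates the weights with the
    # noise and biases the profiled amplitude downwards.
    w = _weights(observed, weight_floor) if weights is None else np.asarray(weights, dtype=float)
    cap = ordering_cap(n_min, ordering_model, n_onco)
    if S_init_cap is not None:
        cap = min(cap, S_init_cap)
    mut_unit = MutationParams(
        u=u, n_min=n_min, S=1.0, n_onco=n_onco, G=G, ordering_model=ordering_model
    )

    def profile(k: float) -> tuple[float, float, np.ndarray]:
        """Objective at k with S profiled out; returns (obj, S, model rates at S)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = run_model(grid, schedule, PopulationParams(N0=N0, k=k), mut_unit, scale)
        m = bin_average_incidence(curves, table)
        den = float(np.sum(w * m * m))
        num = float(np.sum(w * m * observed))
        if den <= 0 or num <= 0:
            S = _S_MIN
        else:
            S = min(max(num / den, _S_MIN), cap)
        resid = S * m - observed
        return float(np.sum(w * resid**2)), S, S * m

    # The objective is flat wherever the profiled S pins to its bounds (the
    # model curve then cannot approach the data at any scale), so a pure
    # bounded line search can stall on the plateau.  Scan a log-spaced k
    # grid first, then refine with bounded Brent inside the best bracket.
    k_grid = np.geomspace(k_bounds[0], k_bounds[1], 40)
    scan = np.array([profile(k)[0] for k in k_grid])
    i_best = int(np.argmin(scan))
    lo = k_grid[max(i_best - 1, 0)]
    hi = k_grid[min(i_best + 1, k_grid.size - 1)]
    res = minimize_scalar(
        lambda k: profile(k)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    k_hat = float(res.x) if res.fun <= scan[i_best] else float(k_grid[i_best])
    _, S_hat, _ = profile(k_hat)

    # rerun at the fitted (k, S) so the reported objective uses exact rates
    # (the profiling step assumed linearity of incidence in S)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mut_hat = MutationParams(
            u=u, n_min=n_min, S=S_hat, n_onco=n_onco, G=G, ordering_model=ordering_model
        )
        curves = run_model(grid, schedule, PopulationParams(N0=N0, k=k_hat), mut_hat, scale)
        model_rates = bin_average_incidence(curves, table)
        peak = pipeline.peak_age(curves)
    residuals = model_rates - observed
    objective = float(np.sum(w * residuals**2))

    return CalibrationResult(
        n_min=n_min,
        k_hat=k_hat,
        S_hat=S_hat,
        objective=objective,
        peak_age_hat=peak,
        feasible=is_feasible(objective, peak, len(table), feasible_tol, peak_window),
        residuals=residuals,
        model_rates=model_rates,
        observed=observed.copy(),
        weights=w,
        curves=curves,
        config=dict(
            u=u, N0=N0, schedule=schedule, grid=grid, ordering_model=ordering_model,
            n_onco=n_onco, G=G, k_bounds=tuple(k_bounds), weight_floor=weight_floor,
            feasible_tol=feasible_tol, peak_window=tuple(peak_window), scale=scale,
        ),
    )


def fit(table: IncidenceTable, n_min: int, **fixed) -> CalibrationResult:
    """Calibrate (k, S) against a table at a fixed n_min.

    Keyword arguments: ``u`` and ``N0`` (required), ``schedule``, ``grid``
    and the optimisation knobs of :func:`_fit_core`.
    """
    fixed.setdefault("schedule", DivisionSchedule())
    fixed.setdefault("grid", SimulationGrid())
    return _fit_core(table, n_min, **fixed)


def nmin_sweep(table: IncidenceTable, n_min_range, **fixed) -> list:
    """Independently calibrate each candidate n_min; results ordered by
    objective (best first).  An empty range returns an empty list."""
    results = [fit(table, int(n), **fixed) for n in n_min_range]
    return sorted(results, key=lambda r: r.objective)


def sweep_report(results) -> pd.DataFrame:
    """Feasibility report of a sweep as a DataFrame (objective-ordered)."""
    rows = [r.to_dict() for r in sorted(results, key=lambda r: r.objective)]
    return pd.DataFrame(
        rows, columns=["n_min", "k_hat", "S_hat", "objective", "peak_age_hat", "feasible"]
    )


def calibrate_peak_age(
    target_age: float = 80.0,
    *,
    n_min: int,
    S: float,
    u: float,
    N0: float,
    schedule: DivisionSchedule | None = None,
    grid: SimulationGrid | None = None,
    ordering_model: str = "factorial",
    n_onco: int = 29,
    k_bounds: tuple = K_BOUNDS,
    tol_years: float = 0.005,
    max_iter: int = 80,
) -> tuple[float, float, ModelCurves]:
    """Place the incidence peak at ``target_age`` by a 1-D search over k.

    The peak age decreases monotonically in k (faster NSC depletion pulls
    the incidence maximum earlier), so a bisection on k brackets the
    target.  Returns ``(k_hat, achieved_peak_age, curves)``.
    """
    schedule = schedule if schedule is not None else DivisionSchedule()
    grid = grid if grid is not None else SimulationGrid()
    mut = MutationParams(u=u, n_min=n_min, S=S, n_onco=n_onco, ordering_model=ordering_model)

    def peak_at(k: float) -> tuple[float, ModelCurves]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = run_model(grid, schedule, PopulationParams(N0=N0, k=k), mut)
            return pipeline.peak_age(curves), curves

    k_lo, k_hi = k_bounds
    p_lo, c_lo = peak_at(k_lo)   # small k -> late peak
    p_hi, c_hi = peak_at(k_hi)   # large k -> early peak
    if not (p_hi <= target_age <= p_lo):
        raise ValueError(
            f"target age {target_age:g} y is outside the attainable peak range "
            f"[{p_hi:g}, {p_lo:g}] y for k in {tuple(k_bounds)}"
        )
    best = (k_lo, p_lo, c_lo) if abs(p_lo - target_age) < abs(p_hi - target_age) else (k_hi, p_hi, c_hi)
    for _ in range(max_iter):
        k_mid = 0.5 * (k_lo + k_hi)
        p_mid, c_mid = peak_at(k_mid)
        if abs(p_mid - target_age) < abs(best[1] - target_age):
            best = (k_mid, p_mid, c_mid)
        if abs(p_mid - target_age) <= tol_years:
            break
        if p_mid > target_age:
            k_lo = k_mid
        else:
            k_hi = k_mid
        if k_hi - k_lo < 1e-12:
            break
    return best


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile confidence band for the incidence curve."""

    B: int
    sample_size: int
    level: float
    seed: int
    t: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    point: np.ndarray
    k_samples: np.ndarray
    S_samples: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.t,
                "incidence_per_100k_py": self.point,
                "ci_lower": self.lower,
                "ci_upper": self.upper,
            }
        )


def parametric_bootstrap(
    result: CalibrationResult,
    table: IncidenceTable,
    B: int = 1000,
    sample_size: int = 100_000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Parametric bootstrap band around a fitted incidence curve.

    Per replicate and per bin, the event count is drawn from
    Binomial(round(sample_size * bin width in years), model rate / scale) —
    the denominator is person-years at risk — the empirical rates are
    recomputed, the model refitted with the same fixed parameters, and the
    refitted incidence curve stored.  The band is the pointwise
    (1-level)/2 .. (1+level)/2 percentile envelope; identical seeds give
    bit-identical bands.
    """
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    if sample_size < 1:
        raise ValueError(f"sample_size must be >= 1, got {sample_size}")
    if not (0 < level < 1):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    cfg = result.config
    scale = cfg.get("scale", DEFAULT_SCALE)
    p = np.asarray(result.model_rates, dtype=float) / scale
    if np.any(p < 0):
        # rates can only be negative if the model left its validity regime
        raise ValueError("fitted model rates are negative; cannot resample")
    if np.any(p > 1):
        raise ValueError("fitted rates imply per-bin probability > 1; cannot resample")
    widths = table.widths(result.curves.grid.t_max)
    n_py = np.maximum(np.round(sample_size * widths).astype(np.int64), 1)

    rng = np.random.default_rng(seed)
    fit_kwargs = dict(cfg)
    fit_kwargs.setdefault("k_bounds", K_BOUNDS)
    # freeze the estimator's weights at the observed-table values so
    # replicate noise does not leak into the weighting
    fit_kwargs["weights"] = result.weights

    curves_stack = np.empty((B, result.curves.t.size))
    k_samples = np.empty(B)
    S_samples = np.empty(B)
    for b in range(B):
        counts = rng.binomial(n_py, p)
        emp_rates = counts / n_py * scale
        boot_table = IncidenceTable(
            age_lo=table.age_lo.copy(),
            age_hi=table.age_hi.copy(),
            rate=emp_rates,
            source="parametric-bootstrap",
            open_ended=table.open_ended,
        )
        r = _fit_core(boot_table, result.n_min, **fit_kwargs)
        curves_stack[b] = r.curves.incidence
        k_samples[b] = r.k_hat
        S_samples[b] = r.S_hat

    alpha = (1.0 - level) / 2.0
    lower = np.percentile(curves_stack, 100 * alpha, axis=0)
    upper = np.percentile(curves_stack, 100 * (1 - alpha), axis=0)
    return BootstrapResult(
        B=B, sample_size=sample_size, level=level, seed=seed,
        t=result.curves.t.copy(), lower=lower, upper=upper,
        point=result.curves.incidence.copy(),
        k_samples=k_samples, S_samples=S_samples,
    )


class GliomaIncidenceModel(BaseEstimator):
    """Scikit-learn style front end to the calibration.

    ``fit`` takes an :class:`IncidenceTable` (or a DataFrame with columns
    ``age_lo, age_hi, rate_per_100k_py``) and calibrates the NSC decay
    constant and sequence multiplicity; ``predict`` interpolates the fitted
    incidence curve at requested ages.

    Parameters mirror the library functions; ``u`` (per-gene per-division
    mutation probability) and ``N0`` (NSCs at birth) have no defaults and
    must be supplied.
    """

    def __init__(
        self,
        n_min: int = 5,
        u: float | None = None,
        N0: float | None = None,
        mode: str = "linear",
        r_young: float = 251.0,
        r_aged: float = 318.0,
        t_start: float = 0.0,
        t_end: float = 85.0,
        dt: float = 0.001,
        t_max: float = 100.0,
        ordering_model: str = "factorial",
        n_onco: int = 29,
        k_bounds: tuple = K_BOUNDS,
        weight_floor: float = DEFAULT_WEIGHT_FLOOR,
        feasible_tol: float = DEFAULT_FEASIBLE_TOL,
        peak_window: tuple = DEFAULT_PEAK_WINDOW,
        scale: float = DEFAULT_SCALE,
    ):
        self.n_min = n_min
        self.u = u
        self.N0 = N0
        self.mode = mode
        self.r_young = r_young
        self.r_aged = r_aged
        self.t_start = t_start
        self.t_end = t_end
        self.dt = dt
        self.t_max = t_max
        self.ordering_model = ordering_model
        self.n_onco = n_onco
        self.k_bounds = k_bounds
        self.weight_floor = weight_floor
        self.feasible_tol = feasible_tol
        self.peak_window = peak_window
        self.scale = scale

    def _table(self, X) -> IncidenceTable:
        if isinstance(X, IncidenceTable):
            return X
        if isinstance(X, pd.DataFrame):
            return IncidenceTable.from_frame(X)
        raise TypeError(
            "X must be an IncidenceTable or a DataFrame with columns "
            "age_lo, age_hi, rate_per_100k_py"
        )

    def fit(self, X, y=None):
        if self.u is None:
            raise ValueError(
                "u is required: supply the per-gene per-division mutation "
                "probability from a published estimate (e.g. Frank 2010)"
            )
        if self.N0 is None:
            raise ValueError("N0 (NSC count at birth) is required")
        table = self._table(X)
        result = _fit_core(
            table,
            self.n_min,
            u=self.u,
            N0=self.N0,
            schedule=DivisionSchedule(
                mode=self.mode, r_young=self.r_young, r_aged=self.r_aged,
                t_start=self.t_start, t_end=self.t_end,
            ),
            grid=SimulationGrid(dt=self.dt, t_max=self.t_max),
            ordering_model=self.ordering_model,
            n_onco=self.n_onco,
            k_bounds=self.k_bounds,
            weight_floor=self.weight_floor,
            feasible_tol=self.feasible_tol,
            peak_window=self.peak_window,
            scale=self.scale,
        )
        self.result_ = result
        self.k_ = result.k_hat
        self.S_ = result.S_hat
        self.objective_ = result.objective
        self.peak_age_ = result.peak_age_hat
        self.feasible_ = result.feasible
        self.curves_ = result.curves
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted incidence (per 100,000 person-years) at ages ``X``."""
        if not hasattr(self, "result_"):
            raise ValueError("this GliomaIncidenceModel instance is not fitted yet")
        ages = np.asarray(X, dtype=float).ravel()
        if np.any(ages < 0) or np.any(ages > self.curves_.t[-1]):
            raise ValueError("ages must lie inside the simulated grid")
        return np.interp(ages, self.curves_.t, self.curves_.incidence)
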
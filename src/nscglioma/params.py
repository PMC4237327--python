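"""Parameter containers for the multistage neural-stem-cell glioma model.

Every container is an immutable dataclass that validates its invariants at
construction, so downstream numerics can assume well-formed inputs.  The
biological meaning of each field:

* :class:`MutationParams` — the mutational machinery: per-gene per-division
  mutation probability ``u``, the pool of glioma proto-oncogenes among all
  protein-coding genes, the minimum number of oncogenic hits ``n_min``
  required for transformation, and the sequence multiplicity ``S`` (average
  number of distinct mutational sequences that transform).
* :class:`PopulationParams` — the exponentially declining neural-stem-cell
  (NSC) pool, ``N(t) = N0 * exp(-k t)``.
* :class:`DivisionSchedule` — the per-cell division rate ``r(t)``, either
  constant or linearly increasing with age (rodent-derived anchors of 251
  divisions/cell/year in young adults rising to 318 in aged adults).
* :class:`DerivationConstants` — unit-conversion constants used to turn the
  published histology counts into model parameters.
* :class:`SimulationGrid` — the uniform age grid the curves are computed on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Recognised reconstructions of the ordering factor applied to the Poisson
#: count probability (see :func:`nscglioma.mutation.prob_x_transforming`).
ORDERING_MODELS = ("factorial", "permutation", "complete")


def ordering_cap(x: int, ordering_model: str, n_onco: int) -> float:
    """Largest admissible sequence multiplicity ``S`` for ``x`` hits.

    Under the default ``factorial`` model the transforming fraction is
    ``S / x!`` (a fraction of the temporal orderings of the x hits), so S
    cannot exceed ``x!``.  Under ``permutation`` the denominator is the
    number of ordered gene sequences of length x drawn from the oncogene
    pool.  ``complete`` means every ordering transforms and S is unused.
    """
    if ordering_model not in ORDERING_MODELS:
        raise ValueError(
            f"unknown ordering_model {ordering_model!r}; expected one of {ORDERING_MODELS}"
        )
    if ordering_model == "complete":
        return math.inf
    if ordering_model == "factorial":
        return float(math.factorial(x))
    return float(math.perm(n_onco, x))


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class MutationParams:
    """Mutation-process parameters.

    Parameters
    ----------
    u : float
        Probability that a given gene mutates in one cell division
        (dimensionless, per gene per division).  There is no default: the
        value must be supplied explicitly from a published estimate of the
        somatic per-gene per-division mutation frequency (Frank 2010).
        ``u = 0`` is accepted as the degenerate no-mutation case.
    n_min : int
        Minimum number of oncogenic mutations required for transformation.
    S : float
        Sequence multiplicity: average number of distinct mutational
        sequences (gene sets and/or temporal orderings) that achieve
        transformation.  One scalar applied to every sequence length.
    n_onco : int
        Number of glioma proto-oncogenes (default 29).
    G : int
        Number of protein-coding genes (default 18,440; 522 of these are
        causally implicated in cancer, 29 in glioma).
    ordering_model : str
        Reconstruction of the ordering factor; see :func:`ordering_cap`.
    """

    u: float
    n_min: int
    S: float
    n_onco: int = 29
    G: int = 18440
    ordering_model: str = "factorial"

    def __post_init__(self) -> None:
        u = _require_finite("u", self.u)
        if not (0.0 <= u < 1e-3):
            raise ValueError(f"u must lie in [0, 1e-3), got {u!r}")
        for name in ("n_min", "n_onco", "G"):
            value = getattr(self, name)
            if int(value) != value:
                raise ValueError(f"{name} must be an integer, got {value!r}")
        if not (1 <= self.n_min <= self.n_onco <= self.G):
            raise ValueError(
                f"require 1 <= n_min <= n_onco <= G, got "
                f"n_min={self.n_min}, n_onco={self.n_onco}, G={self.G}"
            )
        S = _require_finite("S", self.S)
        if S <= 0:
            raise ValueError(f"S must be > 0, got {S!r}")
        cap = ordering_cap(self.n_min, self.ordering_model, self.n_onco)
        if S > cap:
            raise ValueError(
                f"S={S!r} exceeds the ordering cap {cap:g} "
                f"(= max multiplicity for x={self.n_min} hits under the "
                f"{self.ordering_model!r} ordering model)"
            )
        if self.u_o >= 0.1:
            raise ValueError(
                f"derived per-division oncogenic hit probability u_o = n_onco*u = "
                f"{self.u_o:g} is not small; the rare-mutation model does not apply"
            )

    @property
    def u_o(self) -> float:
        """Per-division probability that some glioma oncogene mutates."""
        return self.n_onco * self.u


@dataclass(frozen=True)
class PopulationParams:
    """Exponential NSC pool: ``N(t) = N0 * exp(-k t)``.

    ``N0`` (cells at birth) must be supplied; the published derivation chain
    (histology section counts scaled to the germinal tract) is encoded in
    :mod:`nscglioma.population` but does not pin a single printed value.
    ``k`` (1/year) is normally obtained by calibration against demographic
    incidence data.
    """

    N0: float
    k: float

    def __post_init__(self) -> None:
        N0 = _require_finite("N0", self.N0)
        if N0 <= 0:
            raise ValueError(f"N0 must be > 0, got {N0!r}")
        k = _require_finite("k", self.k)
        if k < 0:
            raise ValueError(f"k must be >= 0, got {k!r}")


@dataclass(frozen=True)
class DivisionSchedule:
    """Per-cell division rate r(t) in divisions/cell/year.

    ``linear`` mode interpolates from ``r_young`` at ``t_start`` to
    ``r_aged`` at ``t_end`` and clamps to the endpoint values outside that
    window; ``constant`` mode returns ``r_young`` everywhere.
    """

    mode: str = "linear"
    r_young: float = 251.0
    r_aged: float = 318.0
    t_start: float = 0.0
    t_end: float = 85.0

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "constant"):
            raise ValueError(f"mode must be 'linear' or 'constant', got {self.mode!r}")
        if not (self.r_young > 0 and self.r_aged > 0):
            raise ValueError("division rates must be > 0")
        if not self.t_start < self.t_end:
            raise ValueError(
                f"require t_start < t_end, got {self.t_start!r} >= {self.t_end!r}"
            )


@dataclass(frozen=True)
class DerivationConstants:
    """Constants for converting published histology counts to model inputs.

    periods_per_year
        Number of 48-hour observation periods per year used to annualise
        time-lapse division counts.  183 (= 366/2) reproduces both printed
        integer rates (1.37/48 h -> 251/yr and 1.74/48 h -> 318/yr);
        182.5 would round 1.37 down to 250.
    tract_length_mm
        Length of the germinal tract in mm (the x10 step of the published
        scaling chain: cells per section -> per mm -> whole tract).
    """

    periods_per_year: float = 183.0
    tract_length_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.periods_per_year <= 0 or self.tract_length_mm <= 0:
            raise ValueError("derivation constants must be positive")

    @staticmethod
    def per_mm_scale(thickness_um: float) -> float:
        """Sections per mm of tissue: 1000/thickness (e.g. 5 for 200 um,
        ~33 for 30 um)."""
        if thickness_um <= 0:
            raise ValueError(f"section thickness must be > 0, got {thickness_um!r}")
        return 1000.0 / float(thickness_um)


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform age grid 0..t_max with step dt (years).

    The default dt of 0.001 years keeps the numerical derivative of the
    prevalence (the incidence) second-order accurate on a sub-day scale.
    t_max must be an integer number of steps.
    """

    dt: float = 0.001
    t_max: float = 100.0

    def __post_init__(self) -> None:
        dt = _require_finite("dt", self.dt)
        if not (0.0 < dt <= 0.01):
            raise ValueError(f"dt must lie in (0, 0.01] years, got {dt!r}")
        t_max = _require_finite("t_max", self.t_max)
        if t_max <= 0:
            raise ValueError(f"t_max must be > 0, got {t_max!r}")
        steps = t_max / dt
        if abs(steps - round(steps)) > 1e-6:
            raise ValueError(
                f"t_max/dt = {steps!r} is not an integer number of steps"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    def ages(self) -> np.ndarray:
        """Grid of ages 0, dt, 2 dt, ..., t_max (n_steps + 1 points)."""
        return np.linspace(0.0, self.t_max, self.n_steps + 1)
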
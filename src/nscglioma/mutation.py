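"""Per-cell oncogenic-transformation probability from accumulated divisions.

A neural stem cell that has undergone ``d`` divisions has had ``d`` chances
for each of its genes to mutate.  With per-gene per-division mutation
probability ``u`` and ``n_onco`` glioma proto-oncogenes, the per-division
probability of an oncogenic hit is ``u_o = n_onco * u`` and the number of
hits after ``d`` divisions is Binomial(d, u_o).  Because ``d`` is large and
``u_o`` tiny, the Poisson distribution with intensity ``lambda = u_o * d``
is an excellent and much cheaper approximation.

Transformation additionally requires the hits to arrive in a permitted
temporal order: of the ``x!`` orderings of ``x`` hits, on average ``S``
transform, so the probability that a cell with ``x`` hits is transformed is
``(S / x!) * Poisson(x; lambda)``.  Summing over all admissible sequence
lengths ``x = n_min .. n_onco`` gives the per-cell transformation
probability ``P1`` — a multistage (Armitage-Doll-type) model that does not
commit to a single number of rate-limiting hits.

All probability arithmetic is carried out in log space; probabilities below
1e-300 are flushed to zero.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .params import MutationParams, ordering_cap

__all__ = [
    "oncogenic_hit_probability",
    "prob_x_hits_binomial",
    "prob_x_hits_poisson",
    "prob_x_transforming",
    "per_cell_transformation_prob",
]

_FLUSH = 1e-300


def oncogenic_hit_probability(params: MutationParams) -> float:
    """Per-division probability u_o that any one oncogene mutates.

    u_o = n_onco * u; the mutation rate is the same for every gene, so the
    oncogenic hit rate is simply proportional to the size of the oncogene
    pool.
    """
    return params.u_o


def prob_x_hits_binomial(x: int, d: float, u_o: float) -> float:
    """Exact probability of ``x`` oncogenic hits in ``d`` divisions.

    Binomial(x; d, u_o) evaluated in log space.  Fractional division counts
    (from integrating a continuous division rate) are rounded to the
    nearest integer; this exact form is the oracle against which the
    Poisson approximation is checked and is only intended for moderate d.
    ``x > d`` returns 0 (not an error).
    """
    if not (0.0 <= u_o <= 1.0):
        raise ValueError(f"u_o must lie in [0, 1], got {u_o!r}")
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"d must be a finite non-negative count, got {d!r}")
    if x < 0:
        raise ValueError(f"x must be >= 0, got {x!r}")
    n = int(round(d))
    if x > n:
        return 0.0
    p = float(np.exp(stats.binom.logpmf(x, n, u_o)))
    return p if p >= _FLUSH else 0.0


def prob_x_hits_poisson(x: int, lam):
    """Poisson probability of ``x`` oncogenic hits at intensity ``lam``.

    ``lam`` may be a scalar or an ndarray (vectorised over the age grid);
    the return matches its shape.  Computed as
    ``exp(x log lam - lam - log x!)``.
    """
    if x < 0 or int(x) != x:
        raise ValueError(f"x must be a non-negative integer, got {x!r}")
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(~np.isfinite(lam_arr)) or np.any(lam_arr < 0):
        raise ValueError("lambda must be finite and >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = x * np.log(lam_arr) - lam_arr - gammaln(x + 1)
    p = np.exp(logp)
    # lam == 0: pmf is 1 at x=0, else 0 (log produced -inf / nan there)
    p = np.where(lam_arr == 0.0, 1.0 if x == 0 else 0.0, p)
    p = np.where(p < _FLUSH, 0.0, p)
    if np.isscalar(lam) or np.ndim(lam) == 0:
        return float(p)
    return p


def _log_ordering_fraction(x: int, S: float, ordering_model: str, n_onco: int) -> float:
    """log of the fraction of hit sequences of length x that transform."""
    cap = ordering_cap(x, ordering_model, n_onco)
    if ordering_model == "complete":
        return 0.0
    if not (0 < S <= cap):
        raise ValueError(
            f"S must lie in (0, {cap:g}] for x={x} under the "
            f"{ordering_model!r} ordering model, got S={S!r}"
        )
    return math.log(S) - math.log(cap)


def prob_x_transforming(
    x: int,
    lam,
    S: float,
    ordering_model: str = "factorial",
    n_onco: int = 29,
):
    """Probability that a cell has ``x`` hits *and* they transform it.

    The Poisson count probability times the transforming ordering fraction:
    ``(S / x!) * Poisson(x; lam)`` under the default ``factorial`` model
    (``S / perm(n_onco, x)`` under ``permutation``; exactly the Poisson pmf
    under ``complete``).  ``S = x!`` therefore recovers the plain count
    probability, and the result is linear in ``S``.
    """
    if x < 1:
        raise ValueError(f"x must be >= 1 for a transforming sequence, got {x!r}")
    log_frac = _log_ordering_fraction(x, S, ordering_model, n_onco)
    p = prob_x_hits_poisson(x, lam) * math.exp(log_frac)
    if np.ndim(p) == 0:
        p = float(p)
        return p if p >= _FLUSH else 0.0
    return np.where(p < _FLUSH, 0.0, p)


def per_cell_transformation_prob(lam, params: MutationParams):
    """Per-cell transformation probability P1 at Poisson intensity ``lam``.

    P1(lam) = sum_{x = n_min}^{n_onco} (S / x!) Poisson(x; lam)
    (ordering fraction per ``params.ordering_model``).  Vectorised over
    ``lam``; returns a float for scalar input.  The truncation at
    x = n_onco is exact for the model (no more than n_onco distinct
    oncogenes can be hit) and numerically negligible for small lam anyway.
    """
    if params.n_min > params.n_onco:
        warnings.warn(
            "n_min exceeds the oncogene count; no sequence can transform",
            stacklevel=2,
        )
        out = np.zeros_like(np.asarray(lam, dtype=float))
        return float(out) if np.ndim(lam) == 0 else out

    lam_arr = np.asarray(lam, dtype=float)
    if np.any(~np.isfinite(lam_arr)) or np.any(lam_arr < 0):
        raise ValueError("lambda must be finite and >= 0")

    total = np.zeros_like(lam_arr)
    for x in range(params.n_min, params.n_onco + 1):
        total += prob_x_transforming(
            x, lam_arr, params.S, params.ordering_model, params.n_onco
        )
    total = np.clip(total, 0.0, 1.0)
    total = np.where(total < _FLUSH, 0.0, total)
    if np.ndim(lam) == 0:
        return float(total)
    return total
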
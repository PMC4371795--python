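"""Continuous (scalar) blow-magnitude generalisation of the cost model.

Instead of a Bernoulli blow, the agent holds a probability distribution over
blow magnitudes ``b >= 0``; the no-blow outcome is the missing mass (b = 0,
zero cost).  The blow cost becomes bivariate, ``c_b(r, b)``, and total cost is

    C_TOT(r) = C_R(r) + E_b[c_b(r, b)]

Two ways of evaluating the expectation are implemented:

* full-distribution coding — the exact mass-weighted sum over the support;
* expectation coding — the sparse approximation ``p_blow * c_b(r, E[b|blow])``
  in which only the expected magnitude enters the cost function.

The two coincide whenever ``c_b`` is linear in ``b``, and with a point-mass
belief the continuous model collapses exactly onto the discrete one.  They
diverge — and expectation coding becomes demonstrably suboptimal — when the
startle response loses effectiveness above a critical blow magnitude, the
regime :func:`effectiveness_violation_ranges` detects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .cost_core import (
    ConfigurationError,
    CostFamily,
    DomainError,
    EvaluationError,
    GRID_POINTS,
    Optimum,
    SOLVER_XTOL,
    minimise_on_interval,
)

__all__ = [
    "MagnitudeBelief",
    "BivariateBlowCost",
    "expected_blow_cost_full",
    "expected_blow_cost_expectation_coded",
    "optimal_startle_magnitude_model",
    "effectiveness_violation_ranges",
    "make_bivariate_cost",
    "bivariate_from_family",
    "BIVARIATE_FORMS",
]

logger = logging.getLogger(__name__)

DEFAULT_BELIEF_GRID = 256  # default support size when discretising densities
_MASS_TOL = 1e-9


@dataclass(frozen=True)
class MagnitudeBelief:
    """Probability mass over blow magnitudes; missing mass is the no-blow
    outcome (b = 0)."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        support = np.atleast_1d(np.asarray(self.support, dtype=float))
        probs = np.atleast_1d(np.asarray(self.probs, dtype=float))
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        if support.shape != probs.shape or support.ndim != 1:
            raise DomainError("support and probs must be 1-d arrays of equal length")
        if not np.all(np.isfinite(support)) or np.any(support < 0):
            raise DomainError("blow magnitudes must be finite and >= 0")
        if not np.all(np.isfinite(probs)) or np.any(probs < -_MASS_TOL):
            raise DomainError("probability mass must be finite and >= 0")
        if probs.sum() > 1.0 + _MASS_TOL:
            raise DomainError(f"total blow mass {probs.sum():.6g} exceeds 1")

    @property
    def p_blow(self) -> float:
        """Total probability that any blow occurs."""
        return float(np.clip(self.probs.sum(), 0.0, 1.0))

    @property
    def mean_b(self) -> float:
        """E[b | blow] — expected magnitude conditional on a blow; 0 when no
        blow mass."""
        p = self.probs.sum()
        if p <= 0.0:
            return 0.0
        return float(np.dot(self.support, self.probs) / p)

    @classmethod
    def point_mass(cls, b: float, p_blow: float) -> "MagnitudeBelief":
        """Degenerate belief: a blow of magnitude ``b`` with probability
        ``p_blow`` — the discrete model's belief."""
        return cls(support=np.array([b]), probs=np.array([p_blow]))

    def scaled_to(self, p_blow: float) -> "MagnitudeBelief":
        """Same conditional magnitude distribution, total mass ``p_blow``."""
        total = self.probs.sum()
        if total <= 0:
            raise DomainError("cannot rescale a zero-mass belief")
        return MagnitudeBelief(self.support, self.probs * (p_blow / total))

    def to_dict(self) -> dict:
        return {"support": self.support.tolist(), "probs": self.probs.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MagnitudeBelief":
        return cls(np.asarray(d["support"], float), np.asarray(d["probs"], float))


@dataclass(frozen=True)
class BivariateBlowCost:
    """Blow cost ``c_b(r, b)`` (direct + opportunity) as a function of startle
    magnitude ``r`` and blow magnitude ``b``; ``c_b(r, 0) = 0`` for all r."""

    c_b: Callable[[np.ndarray, np.ndarray], np.ndarray]
    label: str = "custom"
    spec: dict | None = field(default=None, compare=False)

    def __call__(self, r, b) -> np.ndarray:
        out = np.asarray(self.c_b(np.asarray(r, float), np.asarray(b, float)), float)
        if not np.all(np.isfinite(out)):
            raise EvaluationError(f"bivariate blow cost {self.label!r} non-finite")
        return out

    def validate_zero_at_no_blow(self, r_probe) -> None:
        vals = self(np.asarray(r_probe, float), 0.0)
        if np.any(np.abs(vals) > 1e-12):
            raise ConfigurationError("c_b(r, 0) must be 0 for all r (no blow, no cost)")


# ---------------------------------------------------------------------------
# Expected blow cost under the two coding schemes
# ---------------------------------------------------------------------------


def expected_blow_cost_full(
    cost: BivariateBlowCost, belief: MagnitudeBelief, r
) -> float | np.ndarray:
    """Exact expected blow cost:  sum_b p(B=b) * c_b(r, b)."""
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    vals = cost(r_arr[:, None], belief.support[None, :])
    out = vals @ belief.probs
    return float(out[0]) if np.ndim(r) == 0 else out


def expected_blow_cost_expectation_coded(
    cost: BivariateBlowCost, belief: MagnitudeBelief, r
) -> float | np.ndarray:
    """Sparse approximation:  p_blow * c_b(r, E[b | blow]).

    Exact for ``c_b`` linear in ``b``; returns 0 (logged) for a zero-mass
    belief, where no expectation is defined.
    """
    p = belief.p_blow
    if p <= 0.0:
        logger.debug("expectation coding on zero blow mass: cost is 0")
        return 0.0 if np.ndim(r) == 0 else np.zeros(np.shape(r), dtype=float)
    out = p * cost(np.asarray(r, float), belief.mean_b)
    return float(out) if np.ndim(r) == 0 else out


def optimal_startle_magnitude_model(
    cost: BivariateBlowCost,
    belief: MagnitudeBelief,
    startle_costs: CostFamily,
    coding: str = "full",
    *,
    n_grid: int = GRID_POINTS,
    xtol: float = SOLVER_XTOL,
) -> Optimum:
    """Minimise startle-side cost plus the chosen blow-cost functional over r.

    Only the startle-side components (C_R,d + eta*C_R,f) of ``startle_costs``
    are used; the blow side comes entirely from ``cost`` and ``belief``.
    """
    if coding == "full":
        blow = lambda r: expected_blow_cost_full(cost, belief, r)
    elif coding == "expectation":
        blow = lambda r: expected_blow_cost_expectation_coded(cost, belief, r)
    else:
        raise ConfigurationError(f"coding must be 'full' or 'expectation', got {coding!r}")
    lo, hi = startle_costs.r_domain
    r0, c0 = minimise_on_interval(
        lambda r: startle_costs.startle_cost(r) + np.asarray(blow(r), float),
        lo,
        hi,
        n_grid=n_grid,
        xtol=xtol,
    )
    return Optimum(r0=r0, c0=c0)


def effectiveness_violation_ranges(
    cost: BivariateBlowCost,
    r_domain: tuple[float, float],
    b_domain: tuple[float, float],
    n_grid: int = 101,
) -> list[tuple[float, float]]:
    """Maximal b-intervals where startle fails to reduce blow cost.

    A magnitude ``b`` violates the effectiveness condition when
    ``∂c_b/∂r >= 0`` for some ``r`` in ``r_domain`` — the continuous-model
    analogue of the blow cost failing to decrease with startle vigour.
    Lattice points with ``b = 0`` are excluded (no blow implies no cost, so
    the derivative is trivially zero there).  A degenerate single-point
    ``r_domain`` yields no derivative and an empty list.
    """
    if n_grid < 3:
        raise DomainError("n_grid must be >= 3 per axis")
    r_lo, r_hi = r_domain
    if r_hi <= r_lo:
        return []
    b_lo, b_hi = b_domain
    if b_hi < b_lo:
        raise DomainError(f"invalid b_domain {b_domain!r}")
    h = (r_hi - r_lo) / (10.0 * n_grid)
    r = np.clip(np.linspace(r_lo, r_hi, n_grid), r_lo + h, r_hi - h)
    b = np.linspace(b_lo, b_hi, n_grid)
    b = b[b > 0.0]
    if b.size == 0:
        return []
    d = (cost(r[:, None] + h, b[None, :]) - cost(r[:, None] - h, b[None, :])) / (2 * h)
    violated = np.any(d >= -1e-12, axis=0)  # any r where startle does not help
    intervals: list[tuple[float, float]] = []
    start = None
    for bi, flag in zip(b, violated):
        if flag and start is None:
            start = bi
        elif not flag and start is not None:
            intervals.append((float(start), float(prev)))
            start = None
        prev = bi
    if start is not None:
        intervals.append((float(start), float(b[-1])))
    return intervals


# ---------------------------------------------------------------------------
# Parametric bivariate forms
# ---------------------------------------------------------------------------


def _linear_protection(params: dict, r_max: float):
    """c_b(r, b) = b * (1 - g_max * r / r_max): startle always helps."""
    p = {"g_max": 0.9}
    p.update(params)
    if not (0.0 <= p["g_max"] <= 1.0):
        raise ConfigurationError("g_max must lie in [0, 1]")

    def c_b(r, b):
        return b * (1.0 - p["g_max"] * np.asarray(r, float) / r_max)

    return c_b, p


def _saturating_protection(params: dict, r_max: float):
    """c_b(r, b) = b * (1 - g(r) * h(b)) with protection g(r) = g_max*r/r_max
    and effectiveness h(b) = clip((b_crit - b)/ramp, 0, 1): full protection up
    to b_crit - ramp, none at or above b_crit — the regime where a startle no
    longer mitigates a very strong blow."""
    p = {"g_max": 0.9, "b_crit": 2.0, "ramp": 0.6}
    p.update(params)
    if not (0.0 <= p["g_max"] <= 1.0):
        raise ConfigurationError("g_max must lie in [0, 1]")
    if p["ramp"] <= 0 or p["b_crit"] <= 0:
        raise ConfigurationError("b_crit and ramp must be > 0")

    def c_b(r, b):
        b = np.asarray(b, float)
        h = np.clip((p["b_crit"] - b) / p["ramp"], 0.0, 1.0)
        return b * (1.0 - (p["g_max"] * np.asarray(r, float) / r_max) * h)

    return c_b, p


BIVARIATE_FORMS: dict[str, Callable] = {
    "linear-protection": _linear_protection,
    "saturating-protection": _saturating_protection,
}


def make_bivariate_cost(
    form: str = "saturating-protection",
    params: Mapping[str, float] | None = None,
    *,
    r_max: float = 1.0,
) -> BivariateBlowCost:
    if form not in BIVARIATE_FORMS:
        raise ConfigurationError(
            f"unknown bivariate form {form!r}; registered: {sorted(BIVARIATE_FORMS)}"
        )
    fn, resolved = BIVARIATE_FORMS[form](dict(params or {}), r_max)
    return BivariateBlowCost(
        c_b=fn,
        label=form,
        spec={"form": form, "params": resolved, "r_max": r_max},
    )


def bivariate_from_family(family: CostFamily) -> BivariateBlowCost:
    """Lift a discrete-model blow cost to the bivariate form.

    ``c_b(r, b) = [C_B,d(r) + eta*C_B,f(r)]`` for any ``b > 0`` and 0 at
    ``b = 0``; with a point-mass belief the continuous model then reproduces
    the discrete model exactly.
    """

    def c_b(r, b):
        r = np.asarray(r, float)
        b = np.asarray(b, float)
        base = np.asarray(family.blow_cost(r), float)
        return np.where(b > 0.0, base, 0.0)

    return BivariateBlowCost(c_b=c_b, label="from-discrete-family")
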
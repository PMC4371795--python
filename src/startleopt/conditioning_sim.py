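"""Trial-by-trial conditioning and extinction simulations.

A protocol is an ordered list of trials (CS+, CS− or context; US present or
absent with a scalar magnitude; startle probe present or absent).  A learner
tracks, per stimulus, the CS→blow association P(B|CS) and an estimate of blow
magnitude, via either a conjugate beta-bernoulli update (normatively
Bayesian) or the Rescorla–Wagner delta rule.  On probe trials the probe
posterior is computed from the current association and the cost-minimising
startle magnitude is solved under both blow-cost codings
(full-distribution and expectation); the per-trial record is the emitted
trajectory.

The Davis–Astrachan scenario contrasts conditioning with a medium- versus a
very-high-magnitude US under a blow cost whose protection saturates: under
expectation coding the high-US group's startle first rises and then falls
during extinction — demonstrably suboptimal behaviour that the
full-distribution coding never produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bayes_inference import ForwardModel, posterior_with_probe, posterior_without_probe
from .cost_core import (
    ConfigurationError,
    CostFamily,
    family_to_dict,
    make_cost_family,
)
from .magnitude_model import (
    BivariateBlowCost,
    MagnitudeBelief,
    effectiveness_violation_ranges,
    expected_blow_cost_full,
    make_bivariate_cost,
    optimal_startle_magnitude_model,
)

__all__ = [
    "Trial",
    "Protocol",
    "LearnerState",
    "SimulationModel",
    "Trajectory",
    "update_association",
    "run_protocol",
    "acquisition_extinction_protocol",
    "davis_astrachan_scenario",
    "DavisAstrachanResult",
    "classify_shape",
    "load_protocol",
    "save_protocol",
    "TRAJECTORY_COLUMNS",
]

CS_KINDS = ("CS+", "CS-", "context")
LEARNING_RULES = ("beta-bernoulli", "rescorla-wagner")

TRAJECTORY_COLUMNS = [
    "trial",
    "cs",
    "us",
    "b",
    "p_assoc",
    "mean_b",
    "p_post",
    "r0_full",
    "r0_exp",
    "cost_full",
    "cost_exp",
]


@dataclass(frozen=True)
class Trial:
    cs: str
    us_present: bool = False
    us_magnitude: float = 0.0
    probe_present: bool = True

    def __post_init__(self) -> None:
        if self.cs not in CS_KINDS:
            raise ConfigurationError(f"cs must be one of {CS_KINDS}, got {self.cs!r}")
        if self.us_magnitude < 0:
            raise ConfigurationError("us_magnitude must be >= 0")
        if self.us_magnitude > 0 and not self.us_present:
            raise ConfigurationError("us_magnitude > 0 requires us_present")

    def to_dict(self) -> dict:
        return {
            "cs": self.cs,
            "us_present": self.us_present,
            "us_magnitude": self.us_magnitude,
            "probe_present": self.probe_present,
        }


@dataclass(frozen=True)
class Protocol:
    """Ordered trial sequence plus the learning rule and its parameters."""

    trials: tuple[Trial, ...]
    rule: str = "beta-bernoulli"
    rule_params: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "rule_params", dict(self.rule_params))
        if self.rule not in LEARNING_RULES:
            raise ConfigurationError(
                f"unknown learning rule {self.rule!r}; known: {LEARNING_RULES}"
            )
        if self.rule == "rescorla-wagner":
            alpha = self.rule_params.get("alpha", 0.2)
            if not (0.0 < alpha <= 1.0):
                raise ConfigurationError(f"RW learning rate alpha must be in (0, 1], got {alpha!r}")
        else:
            a0 = self.rule_params.get("prior_a", 1.0)
            b0 = self.rule_params.get("prior_b", 1.0)
            if a0 <= 0 or b0 <= 0:
                raise ConfigurationError("beta pseudo-counts must be > 0")

    def __len__(self) -> int:
        return len(self.trials)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "rule_params": dict(self.rule_params),
            "seed": self.seed,
            "trials": [t.to_dict() for t in self.trials],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Protocol":
        return cls(
            trials=tuple(Trial(**t) for t in d["trials"]),
            rule=d.get("rule", "beta-bernoulli"),
            rule_params=d.get("rule_params", {}),
            seed=int(d.get("seed", 0)),
        )


def load_protocol(path) -> Protocol:
    with open(path) as fh:
        return Protocol.from_dict(yaml.safe_load(fh))


def save_protocol(protocol: Protocol, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(protocol.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Learning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LearnerState:
    """Per-stimulus learner state for either rule.

    Rescorla–Wagner keeps a direct association strength ``v`` and magnitude
    trace ``m`` (prediction of the observed US magnitude, 0 on omission);
    beta-bernoulli keeps conjugate pseudo-counts and a pseudo-count mean of
    observed magnitudes.  ``mag_counts`` is the empirical distribution of
    magnitudes on reinforced trials, used by the full-distribution coding.
    """

    rule: str
    v: float = 0.0
    m: float = 0.0
    a: float = 1.0
    b: float = 1.0
    m_sum: float = 0.0
    n_obs: int = 0
    mag_counts: tuple[tuple[float, int], ...] = ()

    @property
    def association(self) -> float:
        if self.rule == "rescorla-wagner":
            return self.v
        return self.a / (self.a + self.b)

    @property
    def magnitude(self) -> float:
        if self.rule == "rescorla-wagner":
            return self.m
        # pseudo-count mean with the beta prior's weight and prior mean 0;
        # a + b already carries prior pseudo-counts plus one per trial seen
        return self.m_sum / (self.a + self.b)

    def conditional_magnitudes(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical distribution of US magnitudes on reinforced trials."""
        if not self.mag_counts:
            return np.array([0.0]), np.array([0.0])
        mags = np.array([m for m, _ in self.mag_counts], dtype=float)
        counts = np.array([c for _, c in self.mag_counts], dtype=float)
        return mags, counts / counts.sum()


def _initial_state(rule: str, params: Mapping[str, float]) -> LearnerState:
    if rule == "rescorla-wagner":
        return LearnerState(rule=rule, v=float(params.get("v0", 0.0)), m=float(params.get("m0", 0.0)))
    return LearnerState(
        rule=rule,
        a=float(params.get("prior_a", 1.0)),
        b=float(params.get("prior_b", 1.0)),
    )


def update_association(
    state: LearnerState, trial: Trial, rule: str | None = None, **params
) -> LearnerState:
    """One learning step for the trial's stimulus.

    rescorla-wagner: ``v <- v + alpha * (lam - v)`` with ``lam = 1`` on US
    trials and 0 otherwise; the magnitude trace follows the same recursion on
    the observed ``us_magnitude`` (0 on omission).  beta-bernoulli: conjugate
    count update, association is the posterior mean; the magnitude estimate
    is the pseudo-count mean of observed magnitudes under the same prior
    weight.
    """
    rule = rule or state.rule
    if rule not in LEARNING_RULES:
        raise ConfigurationError(f"unknown learning rule {rule!r}")
    us = 1.0 if trial.us_present else 0.0
    b_obs = trial.us_magnitude if trial.us_present else 0.0
    counts = dict(state.mag_counts)
    if trial.us_present:
        counts[trial.us_magnitude] = counts.get(trial.us_magnitude, 0) + 1
    mag_counts = tuple(sorted(counts.items()))
    if rule == "rescorla-wagner":
        alpha = float(params.get("alpha", 0.2))
        if not (0.0 < alpha <= 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1], got {alpha!r}")
        return replace(
            state,
            v=state.v + alpha * (us - state.v),
            m=state.m + alpha * (b_obs - state.m),
            mag_counts=mag_counts,
        )
    return replace(
        state,
        a=state.a + us,
        b=state.b + (1.0 - us),
        m_sum=state.m_sum + b_obs,
        n_obs=state.n_obs + 1,
        mag_counts=mag_counts,
    )


# ---------------------------------------------------------------------------
# Simulation model and trajectory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationModel:
    """Everything besides the protocol: startle-side costs, bivariate blow
    cost, forward model, and optional seeded log-normal response noise
    (off by default; the model is normative)."""

    family: CostFamily
    blow_cost: BivariateBlowCost
    forward_model: ForwardModel = ForwardModel(p_s_given_b=0.9, p_s=0.9)
    p_nos_given_b: float = 0.0
    noise_sigma: float = 0.0

    def to_dict(self) -> dict:
        d: dict = {
            "forward_model": self.forward_model.to_dict(),
            "p_nos_given_b": self.p_nos_given_b,
            "noise_sigma": self.noise_sigma,
        }
        if self.family.spec is not None:
            d["family"] = family_to_dict(self.family)
        if self.blow_cost.spec is not None:
            d["blow_cost"] = dict(self.blow_cost.spec)
        return d


def default_simulation_model(**overrides) -> SimulationModel:
    """Shipped default: quadratic-exponential startle costs with the
    saturating-protection bivariate blow cost."""
    family = overrides.pop("family", make_cost_family())
    blow_cost = overrides.pop("blow_cost", make_bivariate_cost("saturating-protection"))
    return SimulationModel(family=family, blow_cost=blow_cost, **overrides)


@dataclass
class Trajectory:
    """Per-trial simulation record with the protocol and model that made it.

    ``cost_full`` and ``cost_exp`` are the full-distribution (true) total
    cost evaluated at ``r0_full`` and ``r0_exp`` respectively, so
    ``cost_full <= cost_exp`` row-wise witnesses the suboptimality of
    expectation coding.
    """

    frame: pd.DataFrame
    protocol: Protocol
    model: SimulationModel

    def __len__(self) -> int:
        return len(self.frame)

    def save(self, csv_path) -> Path:
        csv_path = Path(csv_path)
        self.frame.to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"protocol": self.protocol.to_dict(), "model": self.model.to_dict()},
                indent=2,
            )
        )
        return csv_path


def run_protocol(protocol: Protocol, model: SimulationModel) -> Trajectory:
    """Simulate a protocol trial by trial; deterministic given the seed.

    The startle decision on each trial uses the learner state *before* that
    trial's outcome (the CS precedes the US), so the first probe after
    acquisition already reflects the learned association.  On probe trials
    the probe posterior feeds both blow-cost codings; on non-probe trials the
    posterior is the CS-alone value (≈ 0 when P(¬S|B) ≈ 0).
    """
    rng = np.random.default_rng(protocol.seed)
    states: dict[str, LearnerState] = {}
    rows = []
    family = model.family
    for idx, trial in enumerate(protocol.trials):
        state = states.get(trial.cs)
        if state is None:
            state = _initial_state(protocol.rule, protocol.rule_params)
        assoc = state.association
        m_est = state.magnitude
        fm_t = replace(model.forward_model, p_b_given_cs=assoc)
        if trial.probe_present:
            p_post = posterior_with_probe(fm_t).p_blow
        else:
            p_post = posterior_without_probe(fm_t, model.p_nos_given_b).p_blow
        mags, cond = state.conditional_magnitudes()
        full_belief = MagnitudeBelief(mags, cond * p_post)
        exp_belief = MagnitudeBelief.point_mass(max(m_est, 0.0), p_post)
        opt_full = optimal_startle_magnitude_model(
            model.blow_cost, full_belief, family, coding="full"
        )
        opt_exp = optimal_startle_magnitude_model(
            model.blow_cost, exp_belief, family, coding="expectation"
        )
        # true (full-distribution) cost incurred by the expectation-coded choice
        cost_exp_true = float(
            family.startle_cost(opt_exp.r0)
            + expected_blow_cost_full(model.blow_cost, full_belief, opt_exp.r0)
        )
        r0_full, r0_exp = opt_full.r0, opt_exp.r0
        if model.noise_sigma > 0:
            noise = rng.lognormal(mean=0.0, sigma=model.noise_sigma)
            r0_full *= noise
            r0_exp *= noise
        rows.append(
            {
                "trial": idx,
                "cs": trial.cs,
                "us": int(trial.us_present),
                "b": trial.us_magnitude,
                "p_assoc": assoc,
                "mean_b": m_est,
                "p_post": p_post,
                "r0_full": r0_full,
                "r0_exp": r0_exp,
                "cost_full": opt_full.c0,
                "cost_exp": cost_exp_true,
            }
        )
        states[trial.cs] = update_association(
            state, trial, protocol.rule, **protocol.rule_params
        )
    frame = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return Trajectory(frame=frame, protocol=protocol, model=model)


# ---------------------------------------------------------------------------
# Protocol builders and the Davis–Astrachan comparison
# ---------------------------------------------------------------------------


def acquisition_extinction_protocol(
    n_acq: int = 10,
    n_ext: int = 30,
    us_magnitude: float = 1.0,
    *,
    cs: str = "CS+",
    rule: str = "rescorla-wagner",
    rule_params: Mapping[str, float] | None = None,
    seed: int = 0,
    probe_during_acquisition: bool = True,
) -> Protocol:
    """``n_acq`` reinforced CS trials followed by ``n_ext`` non-reinforced
    extinction trials, probed throughout by default."""
    trials = [
        Trial(cs=cs, us_present=True, us_magnitude=us_magnitude,
              probe_present=probe_during_acquisition)
        for _ in range(n_acq)
    ] + [Trial(cs=cs, us_present=False, probe_present=True) for _ in range(n_ext)]
    return Protocol(
        trials=tuple(trials),
        rule=rule,
        rule_params=dict(rule_params or {"alpha": 0.2}),
        seed=seed,
    )


def classify_shape(series: Sequence[float], tol: float = 1e-6) -> str:
    """Classify a trajectory segment by its run of signed changes.

    Differences with |d| <= tol are treated as no change.  Labels:
    ``flat``, ``monotone-decreasing``, ``monotone-increasing``,
    ``rise-then-fall``, ``other``.
    """
    arr = np.asarray(list(series), dtype=float)
    d = np.diff(arr)
    signs = np.sign(d) * (np.abs(d) > tol)
    runs: list[int] = []
    for s in signs:
        if s != 0 and (not runs or runs[-1] != s):
            runs.append(int(s))
    if not runs:
        return "flat"
    if runs == [-1]:
        return "monotone-decreasing"
    if runs == [1]:
        return "monotone-increasing"
    if runs == [1, -1]:
        return "rise-then-fall"
    return "other"


@dataclass
class DavisAstrachanResult:
    medium: Trajectory
    high: Trajectory
    n_acq: int
    shapes: dict[str, str]

    def extinction(self, which: str, column: str) -> np.ndarray:
        traj = self.medium if which == "medium" else self.high
        return traj.frame[column].to_numpy()[self.n_acq:]

    def end_of_acquisition(self, which: str, column: str = "r0_exp") -> float:
        traj = self.medium if which == "medium" else self.high
        return float(traj.frame[column].to_numpy()[self.n_acq - 1])


def davis_astrachan_scenario(
    medium_b: float = 1.0,
    high_b: float = 2.5,
    *,
    model: SimulationModel | None = None,
    n_acq: int = 10,
    n_ext: int = 30,
    rule: str = "rescorla-wagner",
    rule_params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> DavisAstrachanResult:
    """Medium- versus high-magnitude US conditioning under a saturating
    blow-protection cost.

    Preconditions (checked): the blow cost has a non-empty
    startle-ineffectiveness range, ``high_b`` lies inside it and ``medium_b``
    below it.  Returns both trajectories plus extinction-shape labels for the
    expectation-coded and full-coded startle series.
    """
    model = model or default_simulation_model()
    b_hi = max(high_b, medium_b) * 1.5
    violations = effectiveness_violation_ranges(
        model.blow_cost, model.family.r_domain, (0.0, b_hi), n_grid=301
    )
    if not violations:
        raise ConfigurationError(
            "blow cost has no startle-ineffectiveness range; the comparison needs one"
        )
    if not any(lo <= high_b <= hi for lo, hi in violations):
        raise ConfigurationError(
            f"high_b={high_b} does not lie inside a violation interval {violations}"
        )
    first_violation = min(lo for lo, _ in violations)
    if medium_b >= first_violation:
        raise ConfigurationError(
            f"medium_b={medium_b} must lie below the first violation interval "
            f"(starts at {first_violation:.4g})"
        )
    rule_params = dict(rule_params or {"alpha": 0.2})
    trajs = {}
    for name, b_us in (("medium", medium_b), ("high", high_b)):
        protocol = acquisition_extinction_protocol(
            n_acq=n_acq, n_ext=n_ext, us_magnitude=b_us,
            rule=rule, rule_params=rule_params, seed=seed,
        )
        trajs[name] = run_protocol(protocol, model)
    result = DavisAstrachanResult(
        medium=trajs["medium"], high=trajs["high"], n_acq=n_acq, shapes={}
    )
    result.shapes = {
        "medium": classify_shape(result.extinction("medium", "r0_exp")),
        "high": classify_shape(result.extinction("high", "r0_exp")),
        "medium_full": classify_shape(result.extinction("medium", "r0_full")),
        "high_full": classify_shape(result.extinction("high", "r0_full")),
    }
    return result
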
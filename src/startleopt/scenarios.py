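"""Scenario catalogue, qualitative-prediction report, and cost-curve figures.

Each scenario encodes one experimental paradigm of startle modulation as a
manipulation of a single model quantity — the learned association, the
context prior P(B), the opportunity-cost scale eta, or the US magnitude —
and an expected qualitative direction of the cost-minimising startle
magnitude.  Running a scenario computes the actual direction from the model
and compares it with the expectation; paradigms whose net direction is
genuinely indeterminate (opposing prior and opportunity-cost effects) are
reported descriptively without a verdict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .bayes_inference import (
    ForwardModel,
    STARTLE_EPSILON,
    posterior_context_only,
    posterior_with_probe,
    posterior_without_probe,
)
from .conditioning_sim import davis_astrachan_scenario
from .cost_core import (
    BlowBelief,
    ConfigurationError,
    CostFamily,
    audit_assumptions,
    make_cost_family,
    optimal_startle,
    scale_opportunity,
    total_cost,
)

__all__ = [
    "Scenario",
    "ScenarioOutcome",
    "PredictionReport",
    "SCENARIOS",
    "run_scenario",
    "run_all",
    "render_cost_panels",
    "PanelResult",
]

DIRECTION_TOL = 1e-6  # |dr0| below this counts as no change (solver floor)


def _default_family() -> CostFamily:
    return make_cost_family()


def _default_fm(**kw) -> ForwardModel:
    base = {"p_s_given_b": 0.95, "p_s": 0.5, "p_b_given_cs": 0.0, "p_b_prior": 0.05}
    base.update(kw)
    return ForwardModel(**base)


def _r0(family: CostFamily, p: float) -> float:
    return optimal_startle(family, BlowBelief(p)).r0


def _direction(r0_base: float, r0_new: float, tol: float = DIRECTION_TOL) -> str:
    if r0_new > r0_base + tol:
        return "increase"
    if r0_new < r0_base - tol:
        return "decrease"
    return "no-change"


@dataclass(frozen=True)
class Scenario:
    """A registered paradigm: defaults, expected direction, and a runner
    returning ``(computed_direction, details)``."""

    name: str
    axis: str
    expected: str
    determinate: bool
    phenomenon: str  # the experimental observation the scenario models
    defaults: Mapping[str, float]
    runner: Callable[[dict], tuple[str, dict]]


@dataclass
class ScenarioOutcome:
    name: str
    expected: str
    computed: str
    determinate: bool
    passed: bool | None
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "expected": self.expected,
            "computed": self.computed,
            "determinate": self.determinate,
            "passed": self.passed,
            "details": self.details,
        }


@dataclass
class PredictionReport:
    outcomes: list[ScenarioOutcome]

    @property
    def all_passed(self) -> bool:
        return all(o.passed for o in self.outcomes if o.determinate)

    def to_dict(self) -> dict:
        return {
            "all_determinate_passed": self.all_passed,
            "scenarios": [o.to_dict() for o in self.outcomes],
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


# ---------------------------------------------------------------------------
# Scenario runners
# ---------------------------------------------------------------------------


def _fear_potentiated(p: dict) -> tuple[str, dict]:
    family = _default_family()
    post_plus = posterior_with_probe(_default_fm(p_b_given_cs=p["assoc_cs_plus"]))
    post_minus = posterior_with_probe(_default_fm(p_b_given_cs=p["assoc_cs_minus"]))
    r_plus, r_minus = _r0(family, post_plus.p_blow), _r0(family, post_minus.p_blow)
    return _direction(r_minus, r_plus), {
        "posterior_cs_plus": post_plus.p_blow,
        "posterior_cs_minus": post_minus.p_blow,
        "r0_cs_plus": r_plus,
        "r0_cs_minus": r_minus,
    }


def _cs_alone(p: dict) -> tuple[str, dict]:
    family = _default_family()
    fm = _default_fm(p_b_given_cs=p["assoc_cs_plus"])
    post = posterior_without_probe(fm, p["p_nos_given_b"])
    r0 = _r0(family, post.p_blow)
    computed = "near-zero" if post.p_blow < STARTLE_EPSILON and r0 < 1e-3 else "nonzero"
    return computed, {"posterior": post.p_blow, "r0": r0}


def _prior_shift(p: dict) -> tuple[str, dict]:
    family = _default_family()
    post_lo = posterior_context_only(_default_fm(p_b_prior=p["prior_base"]))
    post_hi = posterior_context_only(_default_fm(p_b_prior=p["prior_new"]))
    r_lo, r_hi = _r0(family, post_lo.p_blow), _r0(family, post_hi.p_blow)
    return _direction(r_lo, r_hi), {
        "posterior_base": post_lo.p_blow,
        "posterior_new": post_hi.p_blow,
        "r0_base": r_lo,
        "r0_new": r_hi,
    }


def _eta_shift(p: dict) -> tuple[str, dict]:
    family = _default_family()
    r_base = _r0(family, p["p_blow"])
    r_new = _r0(scale_opportunity(family, p["eta_new"]), p["p_blow"])
    return _direction(r_base, r_new), {
        "p_blow": p["p_blow"],
        "r0_eta_base": r_base,
        "r0_eta_new": r_new,
    }


def _food_deprivation(p: dict) -> tuple[str, dict]:
    family = _default_family()
    base = posterior_context_only(_default_fm(p_b_prior=p["prior_base"])).p_blow
    cue = posterior_context_only(_default_fm(p_b_prior=p["prior_food_cue"])).p_blow
    r_base = _r0(family, base)
    r_satiated = _r0(scale_opportunity(family, p["eta_satiated"]), cue)
    r_deprived = _r0(scale_opportunity(family, p["eta_deprived"]), cue)
    sat = _direction(r_base, r_satiated)
    dep = _direction(r_base, r_deprived)
    computed = "dissociation" if (sat == "decrease" and dep == "increase") else "other"
    return computed, {
        "r0_base": r_base,
        "r0_satiated": r_satiated,
        "r0_deprived": r_deprived,
        "satiated_direction": sat,
        "deprived_direction": dep,
    }


def _reward_with_safety(p: dict) -> tuple[str, dict]:
    family = _default_family()
    base = posterior_context_only(_default_fm(p_b_prior=p["prior_base"])).p_blow
    new = posterior_context_only(_default_fm(p_b_prior=p["prior_new"])).p_blow
    r_base = _r0(family, base)
    r_new = _r0(scale_opportunity(family, p["eta_new"]), new)
    return _direction(r_base, r_new), {"r0_base": r_base, "r0_new": r_new}


def _davis_astrachan(p: dict) -> tuple[str, dict]:
    result = davis_astrachan_scenario(
        medium_b=p["medium_b"], high_b=p["high_b"], seed=int(p["seed"])
    )
    ok = (
        result.shapes["medium"] == "monotone-decreasing"
        and result.shapes["high"] == "rise-then-fall"
        and result.shapes["high_full"] != "rise-then-fall"
    )
    return ("dissociation" if ok else "other"), {
        "shapes": dict(result.shapes),
        "end_acq_r0_medium": result.end_of_acquisition("medium"),
        "end_acq_r0_high": result.end_of_acquisition("high"),
    }


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario(
            "fear_potentiated",
            axis="p_blow",
            expected="increase",
            determinate=True,
            phenomenon="startle probe during a CS+ elicits a larger response "
            "than during a CS- (fear-potentiated startle)",
            defaults={"assoc_cs_plus": 0.4, "assoc_cs_minus": 0.02},
            runner=_fear_potentiated,
        ),
        Scenario(
            "cs_alone",
            axis="p_blow",
            expected="near-zero",
            determinate=True,
            phenomenon="a CS+ presented without a startle probe elicits no startle",
            defaults={"assoc_cs_plus": 0.4, "p_nos_given_b": 5e-4},
            runner=_cs_alone,
        ),
        Scenario(
            "context_prior",
            axis="prior",
            expected="increase",
            determinate=True,
            phenomenon="contextual/trace conditioning, prior shocks, instructed "
            "fear and species-typical dangerous lighting raise the context "
            "prior of a blow and potentiate startle",
            defaults={"prior_base": 0.05, "prior_new": 0.2},
            runner=_prior_shift,
        ),
        Scenario(
            "positive_picture",
            axis="prior",
            expected="decrease",
            determinate=True,
            phenomenon="a few seconds into positively valenced pictures, "
            "startle is reduced (lower prior probability of a blow)",
            defaults={"prior_base": 0.2, "prior_new": 0.05},
            runner=_prior_shift,
        ),
        Scenario(
            "reward_anticipation",
            axis="eta",
            expected="increase",
            determinate=True,
            phenomenon="anticipating positive pictures or financial gains "
            "increases startle (higher opportunity cost at constant blow "
            "probability)",
            defaults={"p_blow": 0.3, "eta_new": 2.0},
            runner=_eta_shift,
        ),
        Scenario(
            "instructed_attention",
            axis="eta",
            expected="increase",
            determinate=True,
            phenomenon="instructed attention to a stimulus increases startle "
            "(opportunity cost of missing the attended stimulus)",
            defaults={"p_blow": 0.3, "eta_new": 1.5},
            runner=_eta_shift,
        ),
        Scenario(
            "food_deprivation",
            axis="eta",
            expected="dissociation",
            determinate=True,
            phenomenon="food cues reduce startle in satiated subjects but can "
            "increase it under deprivation, when the opportunity-cost rise "
            "dominates the prior drop",
            defaults={
                "prior_base": 0.2,
                "prior_food_cue": 0.15,
                "eta_satiated": 1.0,
                "eta_deprived": 4.0,
            },
            runner=_food_deprivation,
        ),
        Scenario(
            "reward_with_safety",
            axis="eta",
            expected="ambiguous",
            determinate=False,
            phenomenon="positive-valence anticipation lowers the blow prior "
            "while raising opportunity cost; the net direction depends on "
            "which effect dominates and carries no verdict",
            defaults={"prior_base": 0.2, "prior_new": 0.12, "eta_new": 1.6},
            runner=_reward_with_safety,
        ),
        Scenario(
            "davis_astrachan",
            axis="us_magnitude",
            expected="dissociation",
            determinate=True,
            phenomenon="medium-US conditioning yields monotonically decreasing "
            "startle in extinction; very-high-US conditioning yields a "
            "rise-then-fall (Davis & Astrachan), reproduced only under "
            "expectation coding",
            defaults={"medium_b": 1.0, "high_b": 2.5, "seed": 0},
            runner=_davis_astrachan,
        ),
    ]
}


def run_scenario(
    name: str, overrides: Mapping | None = None, *, outdir=None
) -> ScenarioOutcome:
    """Run one registered scenario and classify its direction.

    ``overrides`` may replace any key of the scenario's default parameters;
    unknown keys are rejected.  When ``outdir`` is given, a small JSON
    artefact with the computed details is written there.
    """
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; registered: {sorted(SCENARIOS)}"
        )
    scenario = SCENARIOS[name]
    params = dict(scenario.defaults)
    for key, value in dict(overrides or {}).items():
        if key not in params:
            raise ConfigurationError(
                f"override {key!r} not in scenario {name!r} schema {sorted(params)}"
            )
        params[key] = value
    computed, details = scenario.runner(params)
    passed = (computed == scenario.expected) if scenario.determinate else None
    outcome = ScenarioOutcome(
        name=name,
        expected=scenario.expected,
        computed=computed,
        determinate=scenario.determinate,
        passed=passed,
        details=details,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"scenario_{name}.json").write_text(
            json.dumps(outcome.to_dict(), indent=2)
        )
    return outcome


def run_all(report_path=None, *, outdir=None) -> PredictionReport:
    """Run every registered scenario with defaults and collate the report."""
    report = PredictionReport(
        outcomes=[run_scenario(name, outdir=outdir) for name in SCENARIOS]
    )
    if report_path is not None:
        report.save(report_path)
    return report


# ---------------------------------------------------------------------------
# Cost-curve panels
# ---------------------------------------------------------------------------


@dataclass
class PanelResult:
    paths: list[Path]
    r0_a: float
    r0_b: float
    r0_c: float
    r0_d: float


def render_cost_panels(
    family: CostFamily | None = None,
    beliefs: tuple[float, float] = (0.2, 0.6),
    etas: tuple[float, float] = (1.0, 2.0),
    out_path="cost_panels.png",
) -> PanelResult:
    """Render the four canonical cost-curve panels with minimiser markers.

    (A) startle cost, expected blow cost and their total at the lower blow
    probability; (B) the same at the higher probability — the minimiser
    moves right; (C) direct and opportunity components at the lower eta;
    (D) opportunity costs scaled up by the higher eta — the minimiser moves
    right again.  Refuses (with the audit report) families failing the
    assumption audit.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    family = family or _default_family()
    report = audit_assumptions(family)
    if not report.passed:
        names = ", ".join(c.name for c in report.failures())
        raise ConfigurationError(f"family fails assumption audit: {names}")

    p_lo, p_hi = beliefs
    eta_lo, eta_hi = etas
    fam_lo = scale_opportunity(family, eta_lo)
    fam_hi = scale_opportunity(family, eta_hi)
    lo, hi = family.r_domain
    r = np.linspace(lo, hi, 512)

    r0_a = optimal_startle(fam_lo, BlowBelief(p_lo)).r0
    r0_b = optimal_startle(fam_lo, BlowBelief(p_hi)).r0
    r0_c = optimal_startle(fam_lo, BlowBelief(p_lo)).r0
    r0_d = optimal_startle(fam_hi, BlowBelief(p_lo)).r0

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), constrained_layout=True)
    panels = [
        (axes[0, 0], fam_lo, p_lo, r0_a, f"A  blow probability p={p_lo}"),
        (axes[0, 1], fam_lo, p_hi, r0_b, f"B  blow probability p={p_hi}"),
        (axes[1, 0], fam_lo, p_lo, r0_c, f"C  opportunity scale eta={eta_lo}"),
        (axes[1, 1], fam_hi, p_lo, r0_d, f"D  opportunity scale eta={eta_hi}"),
    ]
    for ax, fam, p, r0, title in panels:
        startle = np.asarray(fam.startle_cost(r))
        blow = p * np.asarray(fam.blow_cost(r))
        tot = np.asarray(total_cost(fam, BlowBelief(p), r))
        ax.plot(r, startle, color="0.7", label="startle cost")
        ax.plot(r, blow, color="0.35", label="expected blow cost")
        if title.startswith(("C", "D")):
            ax.plot(r, fam.eta * np.asarray(fam._component("c_r_forgone", r)),
                    color="0.7", ls=":", label="startle opportunity")
            ax.plot(r, p * fam.eta * np.asarray(fam._component("c_b_forgone", r)),
                    color="0.35", ls=":", label="blow opportunity")
        ax.plot(r, tot, color="k", label="total cost")
        ax.axvline(r0, color="k", ls="--", lw=0.8)
        ax.plot([r0], [float(total_cost(fam, BlowBelief(p), r0))], "kv", ms=8)
        ax.set_title(title, loc="left", fontsize=10)
        ax.set_xlabel("startle magnitude r")
        ax.set_ylabel("cost")
    axes[0, 0].legend(fontsize=8, frameon=False)

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return PanelResult(paths=[out_path], r0_a=r0_a, r0_b=r0_b, r0_c=r0_c, r0_d=r0_d)
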
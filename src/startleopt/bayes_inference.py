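"""Blow-probability inference from forward-model factors.

The probability of an imminent blow given sensory input X is obtained by
Bayes' theorem from a forward model of sensory input.  With a startle probe S
and a conditioned stimulus CS+ believed independent of S,

    P(B | X = {S, CS+}) = P(S|B) * P(B|CS+) / P(S)

so the quantity fear conditioning changes — the learned association
P(B|CS+) — propagates directly into the blow probability that the cost model
then acts on.  When the probe is absent the same factorisation yields
P(¬S|B) * P(B|CS+) / P(¬S), which is near zero because a blow essentially
never arrives unannounced (P(¬S|B) ≈ 0): a CS presented on its own elicits no
startle.  Context manipulations (contextual conditioning, prior shocks,
instructed fear, ambient light) act through the context prior P(B) instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .cost_core import BlowBelief, DomainError

__all__ = [
    "ForwardModel",
    "posterior_with_probe",
    "posterior_without_probe",
    "posterior_context_only",
    "startle_elicited",
    "STARTLE_EPSILON",
]

logger = logging.getLogger(__name__)

# Probe posterior below this threshold counts as "no startle elicited";
# the no-probe prediction is qualitative, so the cut-off is configurable.
STARTLE_EPSILON = 1e-3


def _check_prob(name: str, value: float, *, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (math.isfinite(value) and lo <= value <= hi):
        raise DomainError(f"{name} must lie in [{lo}, {hi}], got {value!r}")


@dataclass(frozen=True)
class ForwardModel:
    """Forward-model factors from which blow posteriors are assembled.

    p_s_given_b: P(S|B), probability of the startle stimulus given an
        imminent blow (close to 1: blows announce themselves).
    p_s: P(S), marginal probability of the startle stimulus; must be > 0.
    p_b_given_cs: P(B|CS+), the learned CS→blow association (the CS− value
        when modelling a CS−).
    p_b_prior: P(B), the context prior used when no CS is present.
    """

    p_s_given_b: float = 0.95
    p_s: float = 0.5
    p_b_given_cs: float = 0.0
    p_b_prior: float = 0.05

    def __post_init__(self) -> None:
        _check_prob("p_s_given_b", self.p_s_given_b)
        _check_prob("p_s", self.p_s)
        _check_prob("p_b_given_cs", self.p_b_given_cs)
        _check_prob("p_b_prior", self.p_b_prior)
        if self.p_s <= 0.0:
            raise DomainError("p_s must be > 0")

    def to_dict(self) -> dict:
        return {
            "p_s_given_b": self.p_s_given_b,
            "p_s": self.p_s,
            "p_b_given_cs": self.p_b_given_cs,
            "p_b_prior": self.p_b_prior,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForwardModel":
        return cls(**{k: float(v) for k, v in d.items()})


def _clamped_belief(raw: float, what: str) -> BlowBelief:
    # The likelihood-ratio-scaled association can exceed 1 for extreme
    # forward models; clamp (with a warning) so the result stays a
    # probability.  Shipped scenarios never reach the clamp.
    if raw > 1.0:
        logger.warning("%s posterior %.6g exceeds 1; clamping", what, raw)
        raw = 1.0
    return BlowBelief(p_blow=raw)


def posterior_with_probe(fm: ForwardModel) -> BlowBelief:
    """P(B | X = {S, CS+}) = P(S|B) * P(B|CS+) / P(S), clamped to [0, 1].

    Monotonically non-decreasing in the learned association ``p_b_given_cs``.
    """
    raw = fm.p_s_given_b * fm.p_b_given_cs / fm.p_s
    return _clamped_belief(raw, "probe+CS")


def posterior_without_probe(fm: ForwardModel, p_nos_given_b: float) -> BlowBelief:
    """P(B | X = {¬S, CS+}) = P(¬S|B) * P(B|CS+) / P(¬S).

    ``p_nos_given_b`` is P(¬S|B); the result is exactly 0 when it is 0 and
    near zero whenever it is near zero — the CS presented alone does not
    elicit startle.
    """
    _check_prob("p_nos_given_b", p_nos_given_b)
    p_nos = 1.0 - fm.p_s
    if p_nos <= 0.0:
        raise DomainError("P(¬S) = 1 - p_s must be > 0")
    raw = p_nos_given_b * fm.p_b_given_cs / p_nos
    return _clamped_belief(raw, "CS-alone")


def posterior_context_only(fm: ForwardModel) -> BlowBelief:
    """P(B | X = {S}) = P(S|B) * P(B) / P(S) — the probe posterior driven by
    the context prior alone (context conditioning, prior shock exposure,
    instructed fear, ambient light/darkness)."""
    raw = fm.p_s_given_b * fm.p_b_prior / fm.p_s
    return _clamped_belief(raw, "context")


def startle_elicited(belief: BlowBelief, epsilon: float = STARTLE_EPSILON) -> bool:
    """Whether the blow posterior is large enough to count as eliciting a
    startle (the near-zero prediction is qualitative)."""
    return belief.p_blow > epsilon
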
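"""Author submission policies.

Three deterministic rules decide whether a study is submitted:

* ``quality_threshold`` — submit iff quality >= q0, blind to the outcome
  sign (the "equal quality assumption": authors judge only the research).
* ``probability_threshold`` — submit iff the acceptance probability, read
  off the sign's own curve, is >= p0 (the "equal probability assumption").
* ``expected_utility`` — submit iff p * reward >= cost, the rational-choice
  rule weighing the effort of submission against the kudos of publication;
  algebraically identical to a probability threshold at p0 = cost / reward.

All thresholds are inclusive.  Under a biased curve pair the probability
threshold translates into a *higher* implied quality bar for negative
studies than for positive ones — the mechanism by which equal observed
acceptance rates can coexist with editorial bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit as sp_logit

from .curves import CurvePair, SIGNS

__all__ = [
    "QUALITY_THRESHOLD",
    "PROBABILITY_THRESHOLD",
    "EXPECTED_UTILITY",
    "SubmissionPolicy",
    "InvalidPolicyError",
    "NoFiniteThresholdError",
    "submits",
    "effective_quality_threshold",
]

QUALITY_THRESHOLD = "quality_threshold"
PROBABILITY_THRESHOLD = "probability_threshold"
EXPECTED_UTILITY = "expected_utility"
_KINDS = (QUALITY_THRESHOLD, PROBABILITY_THRESHOLD, EXPECTED_UTILITY)


class InvalidPolicyError(ValueError):
    """Policy fields do not match its kind or are out of range."""


class NoFiniteThresholdError(ValueError):
    """The policy admits no finite quality threshold (cost/reward outside (0,1))."""


@dataclass(frozen=True)
class SubmissionPolicy:
    """A deterministic author submission rule.

    Exactly the fields belonging to ``kind`` must be set; use the
    :meth:`quality_threshold`, :meth:`probability_threshold` and
    :meth:`expected_utility` constructors.
    """

    kind: str
    q0: float | None = None
    p0: float | None = None
    cost: float | None = None
    reward: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidPolicyError(f"unknown policy kind {self.kind!r}")
        expected = {
            QUALITY_THRESHOLD: ("q0",),
            PROBABILITY_THRESHOLD: ("p0",),
            EXPECTED_UTILITY: ("cost", "reward"),
        }[self.kind]
        for name in ("q0", "p0", "cost", "reward"):
            value = getattr(self, name)
            if name in expected and value is None:
                raise InvalidPolicyError(f"{self.kind} policy requires {name}")
            if name not in expected and value is not None:
                raise InvalidPolicyError(f"{self.kind} policy does not take {name}")
        if self.kind == QUALITY_THRESHOLD and not np.isfinite(self.q0):
            raise InvalidPolicyError("q0 must be finite")
        if self.kind == PROBABILITY_THRESHOLD and not (0.0 < self.p0 < 1.0):
            raise InvalidPolicyError(f"p0 must lie in (0, 1), got {self.p0}")
        if self.kind == EXPECTED_UTILITY:
            if not (np.isfinite(self.cost) and self.cost >= 0):
                raise InvalidPolicyError(f"cost must be >= 0, got {self.cost}")
            if not (np.isfinite(self.reward) and self.reward > 0):
                raise InvalidPolicyError(f"reward must be > 0, got {self.reward}")

    @classmethod
    def quality_threshold(cls, q0: float) -> "SubmissionPolicy":
        return cls(kind=QUALITY_THRESHOLD, q0=float(q0))

    @classmethod
    def probability_threshold(cls, p0: float) -> "SubmissionPolicy":
        return cls(kind=PROBABILITY_THRESHOLD, p0=float(p0))

    @classmethod
    def expected_utility(cls, cost: float, reward: float) -> "SubmissionPolicy":
        return cls(kind=EXPECTED_UTILITY, cost=float(cost), reward=float(reward))

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for name in ("q0", "p0", "cost", "reward"):
            value = getattr(self, name)
            if value is not None:
                d[name] = value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubmissionPolicy":
        d = dict(d)
        kind = d.pop("kind", None)
        if kind is None:
            raise InvalidPolicyError("policy dict requires a 'kind' field")
        try:
            return cls(kind=kind, **{k: float(v) for k, v in d.items()})
        except TypeError as exc:
            raise InvalidPolicyError(str(exc)) from exc


def submits(
    policy: SubmissionPolicy, quality, sign: str, curves: CurvePair
):
    """Whether a study of this quality and sign is submitted under ``policy``.

    Vectorized over ``quality``; thresholds are inclusive ("at least equal
    to").  The quality rule is sign-blind; the probability and utility rules
    read the acceptance probability off the sign's own curve.
    """
    if sign not in SIGNS:
        raise ValueError(f"sign must be one of {SIGNS}, got {sign!r}")
    q = np.asarray(quality, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("quality must be finite")
    if policy.kind == QUALITY_THRESHOLD:
        out = q >= policy.q0
    else:
        # probability bar, or its expected-utility reduction p*reward >= cost
        # <=> p >= cost/reward.  Compared on the logit scale with a 1e-12
        # tolerance so a study sitting exactly at the bar is included despite
        # float rounding; degenerate cost/reward ratios decide uniformly.
        ratio = policy.p0 if policy.kind == PROBABILITY_THRESHOLD else (
            policy.cost / policy.reward
        )
        if ratio <= 0.0:
            out = np.ones_like(q, dtype=bool)
        elif ratio >= 1.0:
            out = np.zeros_like(q, dtype=bool)
        else:
            lp = curves.curve_for(sign).linear_predictor(q)
            out = lp >= float(sp_logit(ratio)) - 1e-12
    return bool(out) if np.isscalar(quality) else out


def effective_quality_threshold(
    policy: SubmissionPolicy, sign: str, curves: CurvePair
) -> float:
    """Minimal quality at which ``submits`` is true for this sign.

    For the probability and utility rules this is the sign's curve inverted
    at the probability bar, so a biased pair yields a higher bar for
    negative studies.
    """
    if policy.kind == QUALITY_THRESHOLD:
        return float(policy.q0)
    curve = curves.curve_for(sign)
    if policy.kind == PROBABILITY_THRESHOLD:
        return curve.quality_at(policy.p0)
    ratio = policy.cost / policy.reward
    if not (0.0 < ratio < 1.0):
        raise NoFiniteThresholdError(
            f"cost/reward = {ratio} lies outside (0, 1); no finite quality threshold"
        )
    return curve.quality_at(ratio)
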
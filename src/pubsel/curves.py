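"""Quality acceptance curves and their calibration.

The model's primitive object is the *quality acceptance curve*: the
probability that a journal accepts a submitted manuscript as a function of
the manuscript's quality, measured on an arbitrary 0-100 scale, with one
curve per outcome sign (positive / negative headline result).  The curves
are deliberately stylised: all that matters for the argument is that they
are strictly increasing in quality and that, at every quality, the positive
curve lies above the negative one whenever editors discriminate.

The only implemented family is the two-parameter logistic,

    p(q) = expit((q - location) / scale),

the minimal monotone family consistent with the four figure anchors the
default model is calibrated to (see :func:`calibrate`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "SIGNS",
    "AcceptanceCurve",
    "CurvePair",
    "FigureAnchors",
    "CalibratedModel",
    "CalibrationError",
    "DEFAULT_ANCHORS",
    "acceptance_probability",
    "quality_at",
    "calibrate",
    "calibrate_default",
    "curve_points",
]

POSITIVE = "positive"
NEGATIVE = "negative"
SIGNS = (POSITIVE, NEGATIVE)

#: Slope used when degenerate (no-bias, sign-symmetric) anchors leave the
#: common scale unidentified; in quality units.
DEGENERATE_SCALE = 10.0


class CalibrationError(ValueError):
    """Anchors are inconsistent with a common-scale monotone logistic pair."""


def _require_finite(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


@dataclass(frozen=True)
class AcceptanceCurve:
    """A monotone map from quality (0-100 scale) to acceptance probability.

    Parameters
    ----------
    location:
        Quality at which the acceptance probability is exactly 0.5.
    scale:
        Slope parameter in quality units; must be positive.  Smaller values
        give a steeper curve.
    sign:
        Outcome sign this curve applies to, ``"positive"`` or ``"negative"``.
    family:
        Curve family; only ``"logistic"`` is implemented.
    """

    location: float
    scale: float
    sign: str
    family: str = "logistic"

    def __post_init__(self) -> None:
        if self.family != "logistic":
            raise ValueError(f"unknown curve family {self.family!r}")
        if not (np.isfinite(self.location) and np.isfinite(self.scale)):
            raise ValueError("location and scale must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}, got {self.sign!r}")

    def linear_predictor(self, quality):
        """(q - location) / scale, the logit of the acceptance probability."""
        q = _require_finite(quality, "quality")
        return (q - self.location) / self.scale

    def probability(self, quality):
        """Acceptance probability at ``quality``; strictly in (0, 1)."""
        out = expit(self.linear_predictor(quality))
        return float(out) if np.isscalar(quality) else out

    def quality_at(self, p):
        """Quality at which the curve reaches probability ``p`` (exact inverse)."""
        arr = _require_finite(p, "p")
        if np.any(arr <= 0) or np.any(arr >= 1):
            raise ValueError(f"p must lie strictly in (0, 1), got {p!r}")
        out = self.location + self.scale * logit(arr)
        return float(out) if np.isscalar(p) else out

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "location": self.location,
            "scale": self.scale,
            "sign": self.sign,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcceptanceCurve":
        return cls(
            location=float(d["location"]),
            scale=float(d["scale"]),
            sign=str(d["sign"]),
            family=str(d.get("family", "logistic")),
        )


def acceptance_probability(curve: AcceptanceCurve, quality):
    """Probability that a study of this quality is accepted, per ``curve``."""
    return curve.probability(quality)


def quality_at(curve: AcceptanceCurve, p):
    """Inverse of :func:`acceptance_probability` in quality units."""
    return curve.quality_at(p)


@dataclass(frozen=True)
class CurvePair:
    """The positive- and negative-outcome acceptance curves of one journal.

    With a common scale, ``negative.location - positive.location`` is the
    constant editorial bias on the quality axis: a positive gap means a
    negative study needs that much more quality to enjoy the same odds of
    acceptance as a positive one.
    """

    positive: AcceptanceCurve
    negative: AcceptanceCurve

    def __post_init__(self) -> None:
        if self.positive.sign != POSITIVE or self.negative.sign != NEGATIVE:
            raise ValueError("curves must carry matching signs")

    def curve_for(self, sign: str) -> AcceptanceCurve:
        if sign == POSITIVE:
            return self.positive
        if sign == NEGATIVE:
            return self.negative
        raise ValueError(f"sign must be one of {SIGNS}, got {sign!r}")

    @property
    def common_scale(self) -> bool:
        return np.isclose(self.positive.scale, self.negative.scale, rtol=0, atol=1e-12)

    @property
    def location_gap(self) -> float:
        """negative.location - positive.location (>= 0 under editorial bias)."""
        return self.negative.location - self.positive.location

    def to_dict(self) -> dict:
        return {"positive": self.positive.to_dict(), "negative": self.negative.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "CurvePair":
        return cls(
            positive=AcceptanceCurve.from_dict(d["positive"]),
            negative=AcceptanceCurve.from_dict(d["negative"]),
        )


@dataclass(frozen=True)
class FigureAnchors:
    """The five printed quantities the default model is calibrated to.

    ``p_threshold`` is the horizontal probability submission threshold;
    ``q_pos_at_threshold`` / ``q_neg_at_threshold`` are the qualities at
    which each curve reaches it.  ``p_pos_at_q0`` / ``p_neg_at_q0`` are the
    two curves' acceptance probabilities at the (implied) common quality
    submission threshold q0.
    """

    p_threshold: float = 0.20
    q_pos_at_threshold: float = 46.0
    q_neg_at_threshold: float = 66.0
    p_pos_at_q0: float = 0.27
    p_neg_at_q0: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_threshold", "p_pos_at_q0", "p_neg_at_q0"):
            p = getattr(self, name)
            if not (np.isfinite(p) and 0.0 < p < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {p}")
        for name in ("q_pos_at_threshold", "q_neg_at_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return {
            "p_threshold": self.p_threshold,
            "q_pos_at_threshold": self.q_pos_at_threshold,
            "q_neg_at_threshold": self.q_neg_at_threshold,
            "p_pos_at_q0": self.p_pos_at_q0,
            "p_neg_at_q0": self.p_neg_at_q0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FigureAnchors":
        return cls(**{k: float(v) for k, v in d.items()})


DEFAULT_ANCHORS = FigureAnchors()


@dataclass(frozen=True)
class CalibratedModel:
    """A common-scale curve pair plus the implied quality submission threshold."""

    curves: CurvePair
    q0: float
    anchors: FigureAnchors = field(default=DEFAULT_ANCHORS)

    def to_dict(self) -> dict:
        return {
            "curves": self.curves.to_dict(),
            "q0": self.q0,
            "anchors": self.anchors.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibratedModel":
        return cls(
            curves=CurvePair.from_dict(d["curves"]),
            q0=float(d["q0"]),
            anchors=FigureAnchors.from_dict(d["anchors"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibratedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def calibrate(anchors: FigureAnchors) -> CalibratedModel:
    """Solve for the unique common-scale logistic pair hitting all anchors.

    The four logit equations are

        logit(p_threshold) = (q_pos_at_threshold - m_pos) / s
                           = (q_neg_at_threshold - m_neg) / s
        logit(p_pos_at_q0) = (q0 - m_pos) / s
        logit(p_neg_at_q0) = (q0 - m_neg) / s

    with closed form

        s     = (q_neg_at_threshold - q_pos_at_threshold)
                / (logit(p_pos_at_q0) - logit(p_neg_at_q0))
        m_pos = q_pos_at_threshold - s * logit(p_threshold)
        m_neg = m_pos + (q_neg_at_threshold - q_pos_at_threshold)
        q0    = m_pos + s * logit(p_pos_at_q0)

    Raises
    ------
    CalibrationError
        If the anchors violate the curve ordering (``p_pos_at_q0 <
        p_neg_at_q0`` or ``q_neg_at_threshold < q_pos_at_threshold``) or
        imply a non-positive scale.  In the doubly degenerate sign-symmetric
        case (zero quality gap and equal probabilities) the slope is
        unidentified and a fallback scale of 10 quality units is used.
    """
    gap = anchors.q_neg_at_threshold - anchors.q_pos_at_threshold
    dlogit = logit(anchors.p_pos_at_q0) - logit(anchors.p_neg_at_q0)
    if gap < 0:
        raise CalibrationError(
            "infeasible anchors: q_neg_at_threshold < q_pos_at_threshold "
            f"({anchors.q_neg_at_threshold} < {anchors.q_pos_at_threshold})"
        )
    if dlogit < 0:
        raise CalibrationError(
            "infeasible anchors: p_pos_at_q0 < p_neg_at_q0 "
            f"({anchors.p_pos_at_q0} < {anchors.p_neg_at_q0})"
        )
    if (gap == 0) != (dlogit == 0):
        which = (
            "q_pos_at_threshold == q_neg_at_threshold but p_pos_at_q0 != p_neg_at_q0"
            if gap == 0
            else "p_pos_at_q0 == p_neg_at_q0 but q_pos_at_threshold != q_neg_at_threshold"
        )
        raise CalibrationError(
            f"infeasible anchors: {which} admits no positive common scale"
        )
    s = DEGENERATE_SCALE if gap == 0 else gap / dlogit
    m_pos = anchors.q_pos_at_threshold - s * logit(anchors.p_threshold)
    m_neg = m_pos + gap
    q0 = m_pos + s * logit(anchors.p_pos_at_q0)
    pair = CurvePair(
        positive=AcceptanceCurve(location=m_pos, scale=s, sign=POSITIVE),
        negative=AcceptanceCurve(location=m_neg, scale=s, sign=NEGATIVE),
    )
    return CalibratedModel(curves=pair, q0=q0, anchors=anchors)


def calibrate_default() -> CalibratedModel:
    """The package's default world: calibration to the five default anchors."""
    return calibrate(DEFAULT_ANCHORS)


def curve_points(
    curves: CurvePair, qualities: Iterable[float] | None = None
) -> pd.DataFrame:
    """Tabulate both curves on a quality grid (for replotting the figures).

    Returns a frame with columns ``quality``, ``p_positive``, ``p_negative``.
    Default grid: 0 to 100 in steps of 0.5.
    """
    q = np.arange(0.0, 100.5, 0.5) if qualities is None else np.asarray(
        list(qualities), dtype=float
    )
    return pd.DataFrame(
        {
            "quality": q,
            "p_positive": curves.positive.probability(q),
            "p_negative": curves.negative.probability(q),
        }
    )
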
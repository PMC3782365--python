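"""Synthetic study populations.

A population is a :class:`pandas.DataFrame` with one row per study and
columns

* ``quality`` — float in [0, 100],
* ``sign``    — ``"positive"`` or ``"negative"``,
* ``submitted``, ``accepted`` — nullable booleans, unset (``pd.NA``) until
  the selection process has run.

Two generation modes realise the statistical structures the bias argument
turns on.  ``sign_first`` draws the sign as Bernoulli(prop_positive) and
then the quality from a per-sign distribution; the per-sign distributions
being identical is exactly the "identical distribution assumption".
``quality_first`` draws quality from a single distribution and then makes a
positive outcome more likely for higher-quality studies through a logistic
link, P(positive | q) = expit((q - coupling_location) / coupling_scale) —
the coupled world in which quality causes positivity.

Quality distributions are specified as small dicts, e.g.::

    {"kind": "uniform", "low": 0, "high": 100}
    {"kind": "truncnorm", "mean": 50, "sd": 15}      # truncated to [0, 100]
    {"kind": "beta", "a": 2, "b": 5}                 # scaled to [0, 100]
    {"kind": "point", "at": 50.0}

Truncation is analytic (the truncated law's own inverse CDF), never by
rejection, so the moments used in tests are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .curves import NEGATIVE, POSITIVE

__all__ = [
    "QUALITY_RANGE",
    "QualityDistribution",
    "make_distribution",
    "PopulationConfig",
    "InvalidConfigError",
    "EmptySelectionError",
    "generate_population",
    "quality_summary",
    "write_population",
    "read_population",
]

QUALITY_RANGE = (0.0, 100.0)


class InvalidConfigError(ValueError):
    """A population config or distribution spec is malformed."""


class EmptySelectionError(ValueError):
    """A summary was requested over an empty set of studies."""


class QualityDistribution:
    """A quality-score law on [0, 100], built from a spec dict.

    Wraps a frozen scipy distribution (or a point mass) and records the
    spec for serialization.  ``sample`` draws by inverse CDF from uniforms
    supplied by the caller's generator, so streams are reproducible.
    """

    def __init__(self, spec: Mapping) -> None:
        spec = dict(spec)
        kind = spec.get("kind")
        lo, hi = QUALITY_RANGE
        if kind == "uniform":
            low = float(spec.get("low", lo))
            high = float(spec.get("high", hi))
            if not (lo <= low < high <= hi):
                raise InvalidConfigError(
                    f"uniform bounds must satisfy 0 <= low < high <= 100, got {spec}"
                )
            self._frozen = stats.uniform(loc=low, scale=high - low)
            self.support = (low, high)
        elif kind == "truncnorm":
            mean, sd = float(spec["mean"]), float(spec["sd"])
            if sd <= 0:
                raise InvalidConfigError(f"truncnorm sd must be > 0, got {sd}")
            self._frozen = stats.truncnorm(
                (lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd
            )
            self.support = QUALITY_RANGE
        elif kind == "beta":
            a, b = float(spec["a"]), float(spec["b"])
            if a <= 0 or b <= 0:
                raise InvalidConfigError(f"beta shapes must be > 0, got {spec}")
            self._frozen = stats.beta(a, b, loc=lo, scale=hi - lo)
            self.support = QUALITY_RANGE
        elif kind == "point":
            at = float(spec["at"])
            if not (lo <= at <= hi):
                raise InvalidConfigError(f"point mass must lie in [0, 100], got {at}")
            self._frozen = None
            self.support = (at, at)
        else:
            raise InvalidConfigError(f"unknown distribution kind {kind!r}")
        self.kind = kind
        self.spec = spec

    @property
    def is_point(self) -> bool:
        return self.kind == "point"

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.is_point:
            return np.full(n, self.support[0])
        return self._frozen.ppf(rng.random(n))

    def pdf(self, q) -> np.ndarray:
        if self.is_point:
            raise InvalidConfigError("a point mass has no density")
        return self._frozen.pdf(q)

    def cdf(self, q) -> np.ndarray:
        if self.is_point:
            return np.where(np.asarray(q, dtype=float) >= self.support[0], 1.0, 0.0)
        return self._frozen.cdf(q)

    def mean(self) -> float:
        return self.support[0] if self.is_point else float(self._frozen.mean())


def make_distribution(spec: Mapping | QualityDistribution) -> QualityDistribution:
    if isinstance(spec, QualityDistribution):
        return spec
    return QualityDistribution(spec)


_UNIFORM = {"kind": "uniform", "low": 0.0, "high": 100.0}


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of one synthetic study population.

    ``sign_first`` mode uses ``prop_positive``, ``quality_dist_pos`` and
    ``quality_dist_neg``; ``quality_first`` mode uses ``quality_dist``,
    ``coupling_location`` and ``coupling_scale``.
    """

    n: int
    mode: str = "sign_first"
    prop_positive: float = 0.5
    quality_dist_pos: Mapping = field(default_factory=lambda: dict(_UNIFORM))
    quality_dist_neg: Mapping = field(default_factory=lambda: dict(_UNIFORM))
    quality_dist: Mapping = field(default_factory=lambda: dict(_UNIFORM))
    coupling_location: float = 50.0
    coupling_scale: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sign_first", "quality_first"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if int(self.n) <= 0:
            raise InvalidConfigError(f"n must be positive, got {self.n}")
        if not (0.0 <= self.prop_positive <= 1.0):
            raise InvalidConfigError(
                f"prop_positive must lie in [0, 1], got {self.prop_positive}"
            )
        if self.coupling_scale <= 0:
            raise InvalidConfigError("coupling_scale must be > 0")
        # fail early on bad distribution specs
        if self.mode == "sign_first":
            make_distribution(self.quality_dist_pos)
            make_distribution(self.quality_dist_neg)
        else:
            make_distribution(self.quality_dist)

    @property
    def identical_distributions(self) -> bool:
        """Whether the identical-distribution assumption holds (sign_first)."""
        return self.mode == "sign_first" and dict(self.quality_dist_pos) == dict(
            self.quality_dist_neg
        )

    def to_dict(self) -> dict:
        d = {"n": int(self.n), "mode": self.mode, "seed": int(self.seed)}
        if self.mode == "sign_first":
            d.update(
                prop_positive=self.prop_positive,
                quality_dist_pos=dict(self.quality_dist_pos),
                quality_dist_neg=dict(self.quality_dist_neg),
            )
        else:
            d.update(
                quality_dist=dict(self.quality_dist),
                coupling_location=self.coupling_location,
                coupling_scale=self.coupling_scale,
            )
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationConfig":
        known = {
            "n", "mode", "prop_positive", "quality_dist_pos", "quality_dist_neg",
            "quality_dist", "coupling_location", "coupling_scale", "seed",
        }
        extra = set(d) - known
        if extra:
            raise InvalidConfigError(f"unknown population config fields: {sorted(extra)}")
        return cls(**dict(d))


def _empty_flags(n: int) -> pd.api.extensions.ExtensionArray:
    return pd.array([pd.NA] * n, dtype="boolean")


def generate_population(
    config: PopulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw a study population; deterministic given the seed.

    ``seed`` overrides ``config.seed`` when given.  Submission and
    acceptance flags are left unset.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(config.n)
    if config.mode == "sign_first":
        positive = rng.random(n) < config.prop_positive
        quality = np.empty(n)
        dist_pos = make_distribution(config.quality_dist_pos)
        dist_neg = make_distribution(config.quality_dist_neg)
        # one uniform per study keeps the stream layout independent of the mix
        u = rng.random(n)
        if dist_pos.is_point:
            quality[positive] = dist_pos.support[0]
        else:
            quality[positive] = dist_pos._frozen.ppf(u[positive])
        if dist_neg.is_point:
            quality[~positive] = dist_neg.support[0]
        else:
            quality[~positive] = dist_neg._frozen.ppf(u[~positive])
    else:
        dist = make_distribution(config.quality_dist)
        quality = dist.sample(rng, n)
        p_pos = expit((quality - config.coupling_location) / config.coupling_scale)
        positive = rng.random(n) < p_pos
    return pd.DataFrame(
        {
            "quality": quality,
            "sign": np.where(positive, POSITIVE, NEGATIVE),
            "submitted": _empty_flags(n),
            "accepted": _empty_flags(n),
        }
    )


def quality_summary(
    studies: pd.DataFrame, by_sign: bool = False, submitted_only: bool = False
) -> pd.DataFrame:
    """Count, mean and standard deviation of quality, overall or per sign.

    With ``submitted_only`` the summary is restricted to submitted studies.
    A sign absent from the selection yields a count of 0 and missing
    moments rather than a fabricated value.  An entirely empty selection
    raises :class:`EmptySelectionError`.
    """
    if len(studies) == 0:
        raise EmptySelectionError("no studies to summarise")
    selected = studies
    if submitted_only:
        selected = studies[studies["submitted"].fillna(False).astype(bool)]
    if len(selected) == 0:
        raise EmptySelectionError("no studies left after filtering to submitted")
    if not by_sign:
        q = selected["quality"]
        return pd.DataFrame(
            {"n": [len(q)], "mean": [q.mean()], "sd": [q.std(ddof=1)]},
            index=pd.Index(["all"], name="group"),
        )
    rows = {}
    for sign in (POSITIVE, NEGATIVE):
        q = selected.loc[selected["sign"] == sign, "quality"]
        rows[sign] = {
            "n": len(q),
            "mean": q.mean() if len(q) else np.nan,
            "sd": q.std(ddof=1) if len(q) > 1 else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sign"
    out["n"] = out["n"].astype(int)
    return out


def write_population(
    studies: pd.DataFrame, csv_path, config: PopulationConfig | None = None
) -> None:
    """Write a population CSV plus a JSON sidecar recording config and seed."""
    studies.to_csv(csv_path, index=False)
    if config is not None:
        sidecar = str(csv_path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"config": config.to_dict(), "seed": int(config.seed)}, fh, indent=2)


def read_population(csv_path) -> pd.DataFrame:
    """Read a population CSV back with nullable boolean flags."""
    df = pd.read_csv(csv_path)
    for col in ("submitted", "accepted"):
        if col in df.columns:
            df[col] = df[col].astype("boolean")
        else:
            df[col] = _empty_flags(len(df))
    return df
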
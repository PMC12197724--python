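"""Probability distributions for exposure parameters and concentrations.

A :class:`DistributionSpec` describes one uncertain quantity — an exposure
parameter (body weight, ingestion rate, ...) or a soil concentration — as one
of five families: ``point``, ``normal``, ``lognormal``, ``uniform`` or
``triangular``, with optional hard truncation bounds.  Sampling is done by
inverse-CDF on a uniform restricted to the truncation interval, so truncation
is honoured exactly (no rejection loop) and copula-coupled sampling only needs
the ``ppf``.

Two parameterisation conventions, chosen for how each family is used:

* ``normal`` — ``value``/``sd`` are the *parent* mean and standard deviation;
  truncation then clips the tails.  Used for exposure parameters, whose
  handbooks report parent moments with plausibility bounds.
* ``lognormal`` — ``value``/``sd`` are the arithmetic mean and SD of the
  *truncated* law.  The underlying (mu, sigma) are solved by moment matching,
  so a survey summary (mean, SD, min, max) converts directly into a sampling
  law whose realised moments reproduce the summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

__all__ = [
    "DistributionSpec",
    "truncated_normal_moments",
    "truncated_lognormal_moments",
    "fit_truncated_normal",
    "fit_truncated_lognormal",
]

_KINDS = ("point", "normal", "lognormal", "uniform", "triangular")


def truncated_normal_moments(mean: float, sd: float, low: float, high: float) -> tuple[float, float]:
    """Mean and SD of a normal(mean, sd) conditioned on [low, high]."""
    a = (low - mean) / sd
    b = (high - mean) / sd
    za, zb = ndtr(a), ndtr(b)
    z = zb - za
    if z <= 0:
        raise ValueError("truncation interval has no probability mass")
    pa, pb = _phi(a), _phi(b)
    m = mean + sd * (pa - pb) / z
    var = sd**2 * (1 + (a * pa - b * pb) / z - ((pa - pb) / z) ** 2)
    return m, math.sqrt(max(var, 0.0))


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)


def truncated_lognormal_moments(mu: float, sigma: float, low: float, high: float) -> tuple[float, float]:
    """Arithmetic mean and SD of lognormal(mu, sigma) conditioned on [low, high]."""
    la, lb = math.log(low), math.log(high)
    z = ndtr((lb - mu) / sigma) - ndtr((la - mu) / sigma)
    if z <= 0:
        raise ValueError("truncation interval has no probability mass")

    def partial(k: int) -> float:
        shift = k * sigma**2
        return math.exp(k * mu + 0.5 * k * shift) * (
            ndtr((lb - mu - shift) / sigma) - ndtr((la - mu - shift) / sigma)
        ) / z

    m1 = partial(1)
    m2 = partial(2)
    return m1, math.sqrt(max(m2 - m1**2, 0.0))


@lru_cache(maxsize=256)
def fit_truncated_normal(mean: float, sd: float, low: float, high: float) -> tuple[float, float]:
    """Parent (mean, sd) whose [low, high]-truncated normal has the target moments."""
    _check_target(mean, sd, low, high)

    def resid(p):
        m, s = truncated_normal_moments(p[0], abs(p[1]), low, high)
        return [(m - mean) / max(abs(mean), sd), (s - sd) / sd]

    sol = optimize.least_squares(resid, [mean, sd], method="lm")
    if not sol.success or sol.cost > 1e-8:
        raise ValueError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} on [{low}, {high}]"
        )
    return float(sol.x[0]), float(abs(sol.x[1]))


@lru_cache(maxsize=256)
def fit_truncated_lognormal(mean: float, sd: float, low: float, high: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose truncated lognormal has the target arithmetic moments."""
    _check_target(mean, sd, low, high)
    if low <= 0:
        raise ValueError("lognormal support requires low > 0")
    s0 = math.sqrt(math.log(1 + (sd / mean) ** 2))
    m0 = math.log(mean) - 0.5 * s0**2

    def resid(p):
        m, s = truncated_lognormal_moments(p[0], abs(p[1]), low, high)
        return [(m - mean) / mean, (s - sd) / sd]

    sol = optimize.least_squares(resid, [m0, s0], method="lm")
    if not sol.success or sol.cost > 1e-8:
        raise ValueError(
            f"cannot match truncated-lognormal moments mean={mean}, sd={sd} on [{low}, {high}]"
        )
    return float(sol.x[0]), float(abs(sol.x[1]))


def _check_target(mean: float, sd: float, low: float, high: float) -> None:
    if not (low < high):
        raise ValueError(f"truncation bounds must be ordered, got [{low}, {high}]")
    if not (low <= mean <= high):
        raise ValueError(f"target mean {mean} outside truncation bounds [{low}, {high}]")
    if sd <= 0:
        raise ValueError("target sd must be positive")


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain scalar quantity.

    Parameters
    ----------
    kind:
        ``point``, ``normal``, ``lognormal``, ``uniform`` or ``triangular``.
    value:
        Point value / parent mean (normal) / truncated arithmetic mean
        (lognormal) / mode (triangular).  Unused for ``uniform``.
    sd:
        Standard deviation (normal: parent; lognormal: truncated arithmetic).
    low, high:
        Truncation bounds; required for lognormal/uniform/triangular,
        optional for normal, ignored for point.
    """

    kind: str
    value: float | None = None
    sd: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "point":
            if self.value is None:
                raise ValueError("point distribution needs a value")
        elif self.kind in ("normal", "lognormal"):
            if self.value is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.kind} distribution needs value and positive sd")
            if (self.low is None) != (self.high is None):
                raise ValueError("give both truncation bounds or neither")
            if self.kind == "lognormal" and self.low is None:
                object.__setattr__(self, "low", 0.0)
                object.__setattr__(self, "high", math.inf)
        elif self.kind == "uniform":
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError("uniform distribution needs ordered low < high")
        elif self.kind == "triangular":
            if self.low is None or self.high is None or self.value is None:
                raise ValueError("triangular distribution needs low, mode (value) and high")
            if not self.low <= self.value <= self.high or self.low >= self.high:
                raise ValueError("triangular requires low <= mode <= high, low < high")
        if self.low is not None and self.high is not None and self.low >= self.high:
            raise ValueError(f"truncation bounds must be ordered, got [{self.low}, {self.high}]")

    # -- sampling ---------------------------------------------------------
    def ppf(self, u):
        """Quantile function (vectorised), truncation included."""
        u = np.asarray(u, dtype=float)
        if self.kind == "point":
            return np.full_like(u, self.value)
        if self.kind == "uniform":
            return self.low + u * (self.high - self.low)
        if self.kind == "triangular":
            lo, mode, hi = self.low, self.value, self.high
            fc = (mode - lo) / (hi - lo)
            left = lo + np.sqrt(u * (hi - lo) * (mode - lo))
            right = hi - np.sqrt((1 - u) * (hi - lo) * (hi - mode))
            return np.where(u < fc, left, right)
        if self.kind == "normal":
            if self.low is None:
                return self.value + self.sd * ndtri(u)
            a = ndtr((self.low - self.value) / self.sd)
            b = ndtr((self.high - self.value) / self.sd)
            return self.value + self.sd * ndtri(a + u * (b - a))
        # lognormal: moment-matched on the truncated law
        mu, sigma = self._lognormal_params()
        if math.isinf(self.high):
            a = ndtr((math.log(self.low) - mu) / sigma) if self.low > 0 else 0.0
            b = 1.0
        else:
            a = ndtr((math.log(self.low) - mu) / sigma) if self.low > 0 else 0.0
            b = ndtr((math.log(self.high) - mu) / sigma)
        return np.exp(mu + sigma * ndtri(a + u * (b - a)))

    def sample(self, rng: np.random.Generator, n: int):
        """Draw ``n`` values; deterministic for a given generator state."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.kind == "point":
            return np.full(n, float(self.value))
        return self.ppf(rng.uniform(0.0, 1.0, size=n))

    # -- moments ----------------------------------------------------------
    def mean(self) -> float:
        """Analytic mean of the (truncated) distribution."""
        if self.kind == "point":
            return float(self.value)
        if self.kind == "uniform":
            return 0.5 * (self.low + self.high)
        if self.kind == "triangular":
            return (self.low + self.value + self.high) / 3.0
        if self.kind == "normal":
            if self.low is None:
                return float(self.value)
            return truncated_normal_moments(self.value, self.sd, self.low, self.high)[0]
        return float(self.value)  # lognormal: moment-matched by construction

    def scaled(self, k: float) -> "DistributionSpec":
        """The distribution of k*X (positive k); supports linearity checks."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        sc = lambda v: None if v is None else (v * k if math.isfinite(v) else v)
        return replace(self, value=sc(self.value), sd=sc(self.sd), low=sc(self.low), high=sc(self.high))

    def _lognormal_params(self) -> tuple[float, float]:
        if math.isinf(self.high) and self.low == 0.0:
            s = math.sqrt(math.log(1 + (self.sd / self.value) ** 2))
            return math.log(self.value) - 0.5 * s**2, s
        return fit_truncated_lognormal(self.value, self.sd, self.low, self.high)


def point(value: float) -> DistributionSpec:
    return DistributionSpec("point", value=value)
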
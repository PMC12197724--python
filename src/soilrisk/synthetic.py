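"""Seeded synthetic soil surveys with the statistical structure of a
province-wide agricultural topsoil campaign.

The default calibration (``data/survey_calibration.csv``) emulates a
740-sample karst-region survey: per-metal concentrations follow truncated
lognormals whose post-truncation mean/SD and hard min/max match the published
summary statistics, and pH follows a truncated normal on [3.84, 8.06].
Concentrations of Cd are rank-coupled to pH through a Gaussian copula
(default correlation -0.3): acidic soils carry more mobile Cd, so low-pH
samples exceed their screening value far more often — the qualitative
gradient the real survey shows across pH classes.

Region labels follow the prefecture sampling weights of the campaign design;
coordinates are synthetic (unit square).  An optional hotspot mode couples
concentration ranks to a smooth intensity field without touching the
marginal distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import spearmanr

from .distributions import DistributionSpec, fit_truncated_normal
from .exceptions import DomainError
from .reference import METALS
from .surveys import Survey

logger = logging.getLogger(__name__)

DEFAULT_N = 740


def _load_calibration() -> pd.DataFrame:
    with resources.as_file(resources.files("soilrisk.data") / "survey_calibration.csv") as p:
        return pd.read_csv(p).set_index("variable")


def _load_region_weights() -> dict[str, int]:
    with resources.as_file(resources.files("soilrisk.data") / "region_weights.csv") as p:
        df = pd.read_csv(p)
    return dict(zip(df["region"], df["count"]))


@dataclass(frozen=True)
class GeneratorSpec:
    """Calibration of the synthetic survey generator.

    ``conc`` holds truncated-lognormal specs per metal (value/sd are the
    target post-truncation moments); ``ph`` is a truncated normal whose
    value/sd are the parent parameters.  ``ph_cd_correlation`` is the
    Gaussian-copula correlation between pH and Cd (negative: acid soils are
    Cd-richer in rank).
    """

    n: int = DEFAULT_N
    conc: dict[str, DistributionSpec] = field(default_factory=dict)
    ph: DistributionSpec | None = None
    ph_cd_correlation: float = -0.3
    region_weights: dict[str, int] = field(default_factory=dict)
    spatial_hotspots: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not -1 < self.ph_cd_correlation < 1:
            raise DomainError("ph_cd_correlation must lie in (-1, 1)")

    @classmethod
    def default(cls, n: int = DEFAULT_N, seed: int | None = None, **kwargs) -> "GeneratorSpec":
        """Calibration matched to the bundled survey summary statistics."""
        cal = _load_calibration()
        conc = {
            m: DistributionSpec(
                "lognormal",
                value=cal.loc[m, "mean"],
                sd=cal.loc[m, "sd"],
                low=cal.loc[m, "min"],
                high=cal.loc[m, "max"],
            )
            for m in METALS
        }
        ph = DistributionSpec(
            "normal",
            value=cal.loc["pH", "mean"],
            sd=cal.loc["pH", "sd"],
            low=cal.loc["pH", "min"],
            high=cal.loc["pH", "max"],
        )
        return cls(
            n=n, conc=conc, ph=ph, region_weights=_load_region_weights(), seed=seed, **kwargs
        )


def _proportional_counts(weights: dict[str, int], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n samples to regions."""
    total = sum(weights.values())
    raw = {r: n * w / total for r, w in weights.items()}
    counts = {r: int(v) for r, v in raw.items()}
    short = n - sum(counts.values())
    for r in sorted(raw, key=lambda r: raw[r] - counts[r], reverse=True)[:short]:
        counts[r] += 1
    return counts


def _hotspot_intensity(x, y):
    # one southwestern hotspot plus a weaker central one
    return np.exp(-(((x - 0.25) ** 2 + (y - 0.3) ** 2) / 0.02)) + 0.6 * np.exp(
        -(((x - 0.5) ** 2 + (y - 0.55) ** 2) / 0.05)
    )


def generate_survey(spec: GeneratorSpec | None = None, seed: int | None = None) -> Survey:
    """Generate a survey; deterministic for a given (spec, seed)."""
    spec = spec or GeneratorSpec.default()
    if not spec.conc or spec.ph is None:
        spec = replace(
            GeneratorSpec.default(n=spec.n, seed=spec.seed),
            ph_cd_correlation=spec.ph_cd_correlation,
            spatial_hotspots=spec.spatial_hotspots,
        )
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = spec.n

    metals = [m for m in METALS if m in spec.conc]
    # Gaussian copula: pH and Cd correlated, everything else independent
    z = rng.standard_normal((n, len(metals) + 1))
    rho = spec.ph_cd_correlation
    if "Cd" in metals and rho != 0.0:
        j = metals.index("Cd") + 1
        z[:, j] = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, j]
    u = ndtr(z)

    data = {"pH": spec.ph.ppf(u[:, 0])}
    for i, m in enumerate(metals):
        data[m] = spec.conc[m].ppf(u[:, i + 1])
        lo, hi = spec.conc[m].low, spec.conc[m].high
        # inverse-CDF sampling respects truncation; clip only guards rounding
        np.clip(data[m], lo, hi, out=data[m])

    df = pd.DataFrame(data)
    df.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(n)])

    if spec.region_weights:
        counts = _proportional_counts(spec.region_weights, n)
        labels = np.repeat(list(counts), list(counts.values()))
        df.insert(1, "region", rng.permutation(labels))

    x = rng.uniform(0, 1, n)
    y = rng.uniform(0, 1, n)
    if spec.spatial_hotspots:
        # couple concentration ranks to the intensity field without touching
        # the marginals: the hottest coordinates get the highest total load
        load = sum(
            (df[m] - df[m].mean()) / df[m].std(ddof=1) for m in metals
        ) + rng.standard_normal(n)
        order = np.argsort(np.argsort(-load.to_numpy()))
        hot = np.argsort(-_hotspot_intensity(x, y))
        x, y = x[hot][order], y[hot][order]
    df.insert(2, "x", x)
    df.insert(3, "y", y)

    return Survey(df.reset_index(drop=True), provenance=f"synthetic:{seed}")


def fit_generator(survey: Survey, min_samples: int = 30) -> GeneratorSpec:
    """Moment-matched generator spec recovered from a survey.

    Per metal: a truncated lognormal over the observed [min, max] whose
    truncated mean/SD equal the observed ones; pH: parent normal parameters
    solved from the observed truncated moments.  A zero-variance column
    degrades to a point spec with a warning.
    """
    if survey.n < min_samples:
        raise DomainError(f"fit_generator needs >= {min_samples} samples, got {survey.n}")
    df = survey.frame
    conc = {}
    for m in survey.metals:
        col = df[m].to_numpy(dtype=float)
        sd = float(col.std(ddof=1))
        if sd == 0.0:
            warnings.warn(f"{m} has zero variance; fitted as a point distribution", stacklevel=2)
            conc[m] = DistributionSpec("point", value=float(col[0]))
            continue
        spec_m = DistributionSpec(
            "lognormal",
            value=float(col.mean()),
            sd=sd,
            low=float(col.min()),
            high=float(col.max()),
        )
        try:
            spec_m._lognormal_params()
        except ValueError:
            # moments unattainable under truncation (e.g. heavier-than-uniform
            # dispersion inside the observed range): drop the bounds
            warnings.warn(
                f"{m}: observed moments infeasible under truncation; fitting "
                "an untruncated lognormal",
                stacklevel=2,
            )
            spec_m = DistributionSpec("lognormal", value=float(col.mean()), sd=sd)
        conc[m] = spec_m
    ph_col = df["pH"].to_numpy(dtype=float)
    lo, hi = float(ph_col.min()), float(ph_col.max())
    try:
        parent_mean, parent_sd = fit_truncated_normal(
            float(ph_col.mean()), float(ph_col.std(ddof=1)), lo, hi
        )
    except ValueError:
        warnings.warn(
            "pH: observed moments infeasible under truncation; using them as "
            "parent parameters",
            stacklevel=2,
        )
        parent_mean, parent_sd = float(ph_col.mean()), float(ph_col.std(ddof=1))
    ph = DistributionSpec("normal", value=parent_mean, sd=parent_sd, low=lo, high=hi)

    rho = 0.0
    if "Cd" in survey.metals and conc["Cd"].kind != "point":
        rs = spearmanr(ph_col, df["Cd"].to_numpy(dtype=float)).statistic
        if np.isfinite(rs):
            rho = float(np.clip(2 * np.sin(np.pi * rs / 6), -0.999, 0.999))  # copula rho from rank corr

    weights = (
        df["region"].value_counts().to_dict() if "region" in df.columns else {}
    )
    return GeneratorSpec(
        n=survey.n, conc=conc, ph=ph, ph_cd_correlation=rho, region_weights=weights
    )
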
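"""Reference tables: screening values, backgrounds, toxicity and exposure data.

The package ships editable defaults under ``soilrisk/data``:

* ``screening.csv`` — GB15618-2018 agricultural-soil risk screening values
  S_i by metal and pH class (the four right-closed classes
  ``<=5.5``, ``(5.5,6.5]``, ``(6.5,7.5]``, ``>7.5``).
* ``background.csv`` — Guizhou geochemical background values B_i.
* ``toxic_response.csv`` — Hakanson toxic response factors T_i.
* ``exposure_parameters.csv`` — population exposure parameters (point value
  plus an optional sampling distribution for Monte Carlo work).
* ``toxicity.csv`` — chronic reference doses RfD and carcinogenic slope
  factors SF by metal and pathway.  Absent cells are genuinely absent
  (the pathway is skipped), not zero.
* ``ttd_endpoints_synthetic.csv`` — target-organ toxicity doses (TTD) by
  metal and organ.  This table is a synthetic stand-in: organ-specific
  endpoint doses calibrated so the bundled defaults reproduce published
  multi-organ hazard aggregates for an As/Cd/Cr/Pb mixture (Hg endpoints
  are lacking in the toxicological literature and are absent).

Every table can be overridden by a user CSV with the same columns; each
override is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .distributions import DistributionSpec
from .exceptions import DomainError, SchemaError

logger = logging.getLogger(__name__)

METALS = ("As", "Cd", "Cr", "Hg", "Pb")
PATHWAYS = ("ing", "inh", "dermal")
ORGANS = ("neurological", "renal", "cardiovascular", "hematological", "testicular")
PH_CLASSES = ("<=5.5", "(5.5,6.5]", "(6.5,7.5]", ">7.5")
_PH_EDGES = (0.0, 5.5, 6.5, 7.5, 14.0)

# exposure parameter vocabulary (units in comments)
EXPOSURE_PARAMETERS = (
    "R_ing",   # soil ingestion rate, mg/d
    "R_inh",   # inhalation rate, m3/d
    "EF",      # exposure frequency, d/yr
    "ED",      # exposure duration, yr
    "BW",      # body weight, kg
    "AT_nc",   # averaging time, non-carcinogenic, d
    "AT_ca",   # averaging time, carcinogenic, d
    "SA",      # exposed skin area, cm2
    "AF",      # soil-to-skin adherence factor, mg/(cm2 d)
    "ABS",     # dermal absorption fraction, unitless
    "PEF",     # particle emission factor, m3/kg
)


def ph_class(ph):
    """Map pH to its screening-value class; right-closed boundaries.

    Accepts a scalar or array; pH must lie in the open interval (0, 14).
    """
    arr = np.asarray(ph, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr >= 14):
        raise DomainError(f"pH must lie in (0, 14), got {ph!r}")
    idx = np.searchsorted(_PH_EDGES[1:-1], arr, side="left")
    if arr.ndim == 0:
        return PH_CLASSES[int(idx)]
    return np.asarray(PH_CLASSES, dtype=object)[idx]


def _data_path(name: str):
    return resources.files("soilrisk.data").joinpath(name)


def _read_builtin(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def _read(name: str, override) -> pd.DataFrame:
    if override is None:
        return _read_builtin(name)
    logger.info("reference table %s overridden by %s", name, override)
    return pd.read_csv(override)


@dataclass(frozen=True)
class ReferenceStandards:
    """Screening values, background values and toxic response factors."""

    screening: pd.DataFrame          # index metal, columns pH class
    background: Mapping[str, float]  # metal -> B_i, mg/kg
    toxic_response: Mapping[str, float]  # metal -> T_i

    def screening_value(self, metal: str, ph=None, ph_cls: str | None = None):
        """S_i for a metal at a given pH (or explicit pH class). Vectorised over pH."""
        if metal not in self.screening.index:
            raise SchemaError(f"no screening values for metal {metal!r}")
        row = self.screening.loc[metal]
        if ph_cls is not None:
            if ph_cls not in row.index:
                raise SchemaError(f"unknown pH class {ph_cls!r}; expected one of {PH_CLASSES}")
            return float(row[ph_cls])
        cls = ph_class(ph)
        if isinstance(cls, str):
            return float(row[cls])
        return row.reindex(cls).to_numpy(dtype=float)

    def self_check(self) -> None:
        """Verify the invariants: positive, complete over metals x classes."""
        missing = [
            (m, c) for m in METALS for c in PH_CLASSES
            if m not in self.screening.index or pd.isna(self.screening.loc[m, c])
        ]
        if missing:
            raise SchemaError(f"screening table incomplete: {missing}")
        if (self.screening.loc[list(METALS)] <= 0).any().any():
            raise SchemaError("screening values must be positive")
        for m in METALS:
            if self.background.get(m, 0) <= 0:
                raise SchemaError(f"background value missing or non-positive for {m}")
            if self.toxic_response.get(m, 0) <= 0:
                raise SchemaError(f"toxic response factor missing or non-positive for {m}")


@dataclass(frozen=True)
class ExposureProfile:
    """Exposure parameters for one population (point values + distributions)."""

    population: str
    parameters: Mapping[str, DistributionSpec]

    def point(self, name: str) -> float:
        try:
            return float(self.parameters[name].value)
        except KeyError:
            raise SchemaError(
                f"exposure parameter {name!r} missing for population {self.population!r}"
            ) from None

    def point_values(self, averaging: str = "nc") -> dict[str, float]:
        """Deterministic parameter set with AT resolved by averaging mode."""
        return self._resolve({k: self.point(k) for k in self.parameters}, averaging)

    def distributions(self, averaging: str = "nc") -> dict[str, DistributionSpec]:
        return self._resolve(dict(self.parameters), averaging)

    @staticmethod
    def _resolve(params: dict, averaging: str) -> dict:
        if averaging not in ("nc", "ca"):
            raise DomainError(f"averaging must be 'nc' or 'ca', got {averaging!r}")
        params["AT"] = params.pop("AT_nc" if averaging == "nc" else "AT_ca")
        params.pop("AT_nc", None)
        params.pop("AT_ca", None)
        return params

    def validate(self) -> None:
        missing = [p for p in EXPOSURE_PARAMETERS if p not in self.parameters]
        if missing:
            raise SchemaError(f"profile {self.population!r} missing parameters {missing}")
        for name, spec in self.parameters.items():
            if spec.value is not None and spec.value <= 0:
                raise DomainError(f"exposure parameter {name} must be positive")
        abs_frac = self.point("ABS")
        if not 0 < abs_frac <= 1:
            raise DomainError(f"ABS must lie in (0, 1], got {abs_frac}")


@dataclass(frozen=True)
class ToxicityTable:
    """RfD / SF by (metal, pathway) and TTD by (metal, organ); absence is explicit."""

    rfd: Mapping[tuple[str, str], float]
    sf: Mapping[tuple[str, str], float]
    ttd: Mapping[tuple[str, str], float]

    def rfd_for(self, metal: str, pathway: str) -> float | None:
        return self.rfd.get((metal, pathway))

    def sf_for(self, metal: str, pathway: str) -> float | None:
        return self.sf.get((metal, pathway))

    def ttd_for(self, metal: str, organ: str) -> float | None:
        return self.ttd.get((metal, organ))

    @property
    def organs(self) -> tuple[str, ...]:
        seen = tuple(dict.fromkeys(o for _, o in self.ttd))
        return tuple(o for o in ORGANS if o in seen) + tuple(
            o for o in seen if o not in ORGANS
        )

    def validate(self) -> None:
        for table, name in ((self.rfd, "RfD"), (self.sf, "SF"), (self.ttd, "TTD")):
            for key, v in table.items():
                if not v > 0:
                    raise DomainError(f"{name}{key} must be positive, got {v}")
                if key[0] not in METALS:
                    raise SchemaError(
                        f"unknown metal {key[0]!r} in {name} table; accepted: {METALS}"
                    )
        for metal, pathway in self.rfd:
            if pathway not in PATHWAYS:
                raise SchemaError(
                    f"unknown pathway {pathway!r}; accepted: {PATHWAYS}"
                )


@dataclass(frozen=True)
class ReferenceTables:
    standards: ReferenceStandards
    profiles: Mapping[str, ExposureProfile]
    toxicity: ToxicityTable
    bands: Mapping[str, list]

    def classify(self, index: str, value: float) -> str:
        """Band label for an index value; boundaries belong to the lower band."""
        try:
            bands = self.bands[index]
        except KeyError:
            raise SchemaError(
                f"unknown index {index!r}; accepted: {sorted(self.bands)}"
            ) from None
        for upper, label in bands:
            if value <= upper:
                return label
        return bands[-1][1]


def _parse_exposure(df: pd.DataFrame) -> dict[str, ExposureProfile]:
    profiles = {}
    for pop, grp in df.groupby("population", sort=False):
        params = {}
        for row in grp.itertuples(index=False):
            kind = row.kind if isinstance(row.kind, str) and row.kind else "point"
            low = None if pd.isna(row.low) else float(row.low)
            high = None if pd.isna(row.high) else float(row.high)
            sd = None if pd.isna(row.sd) else float(row.sd)
            if kind == "point":
                spec = DistributionSpec("point", value=float(row.value))
            else:
                spec = DistributionSpec(kind, value=float(row.value), sd=sd, low=low, high=high)
            params[row.parameter] = spec
        prof = ExposureProfile(pop, params)
        prof.validate()
        profiles[pop] = prof
    return profiles


def load_reference_tables(
    screening=None,
    background=None,
    toxic_response=None,
    exposure=None,
    toxicity=None,
    ttd=None,
    bands=None,
) -> ReferenceTables:
    """Load reference tables from bundled defaults, with optional CSV overrides.

    Each keyword accepts a path to a user CSV replacing the corresponding
    bundled file (same columns); overrides are logged.
    """
    scr = _read("screening.csv", screening)
    bad = set(scr["metal"]) - set(METALS)
    if bad:
        raise SchemaError(f"unknown metals in screening table: {sorted(bad)}; accepted: {METALS}")
    screening_df = scr.pivot(index="metal", columns="ph_class", values="value").reindex(
        columns=list(PH_CLASSES)
    )
    bg = _read("background.csv", background).set_index("metal")["value"].to_dict()
    tr = _read("toxic_response.csv", toxic_response).set_index("metal")["value"].to_dict()
    standards = ReferenceStandards(screening_df, bg, tr)
    standards.self_check()

    profiles = _parse_exposure(_read("exposure_parameters.csv", exposure))

    tox_df = _read("toxicity.csv", toxicity)
    rfd = {
        (r.metal, r.pathway): float(r.rfd)
        for r in tox_df.itertuples(index=False)
        if not pd.isna(r.rfd)
    }
    sf = {
        (r.metal, r.pathway): float(r.sf)
        for r in tox_df.itertuples(index=False)
        if not pd.isna(r.sf)
    }
    ttd_df = _read("ttd_endpoints_synthetic.csv", ttd)
    ttd_map = {(r.metal, r.organ): float(r.value) for r in ttd_df.itertuples(index=False)}
    tox = ToxicityTable(rfd, sf, ttd_map)
    tox.validate()

    if bands is None:
        with resources.as_file(_data_path("classification_bands.yaml")) as p:
            band_map = yaml.safe_load(p.read_text())
    else:
        logger.info("classification bands overridden by %s", bands)
        band_map = yaml.safe_load(open(bands).read())
    band_map = {k: [(float(u), str(l)) for u, l in v] for k, v in band_map.items()}

    return ReferenceTables(standards, profiles, tox, band_map)
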
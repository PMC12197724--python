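"""USEPA three-pathway average daily doses and deterministic risk indices.

Doses (mg of metal per kg body weight per day):

* ingestion:   ``ADD = C * R_ing * EF * ED / (BW * AT) * 1e-6``
* inhalation:  ``ADD = C * R_inh * EF * ED / (PEF * BW * AT)``
* dermal:      ``ADD = C * AF * SA * ABS * EF * ED / (BW * AT) * 1e-6``

Non-carcinogenic hazard: ``HI_i = sum_pathways ADD/RfD`` and
``THI = sum_i HI_i`` (>1 flags possible risk).  Carcinogenic:
``CR_i = sum_pathways ADD * SF`` and ``TCR = sum_i CR_i`` (1e-6..1e-4 is the
conventional acceptability band).  A pathway with no RfD/SF entry contributes
exactly zero and is logged once per call.

All formulas accept scalars or numpy arrays for the concentration and the
parameters, so the same code path serves single-value assessment, per-sample
vectorisation and Monte Carlo propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .reference import METALS, PATHWAYS, ExposureProfile, ToxicityTable
from .surveys import Survey

logger = logging.getLogger(__name__)

HI_THRESHOLD = 1.0
CR_UPPER = 1e-4   # above: significant cancer risk
CR_LOWER = 1e-6   # below: negligible

_PATHWAY_PARAMS = {
    "ing": ("R_ing", "EF", "ED", "BW", "AT"),
    "inh": ("R_inh", "EF", "ED", "PEF", "BW", "AT"),
    "dermal": ("AF", "SA", "ABS", "EF", "ED", "BW", "AT"),
}


def _params_of(profile, averaging: str) -> Mapping:
    if isinstance(profile, ExposureProfile):
        return profile.point_values(averaging)
    return profile  # already a mapping name -> scalar/array (AT resolved)


def _check_params(params: Mapping, pathway: str) -> None:
    for name in _PATHWAY_PARAMS[pathway]:
        if name not in params:
            raise DomainError(f"missing exposure parameter {name!r} for pathway {pathway!r}")
        v = np.asarray(params[name], dtype=float)
        if np.any(~(v > 0)):
            raise DomainError(f"exposure parameter {name!r} must be strictly positive")


def average_daily_dose(c, params: Mapping, pathway: str):
    """ADD for one pathway; ``params`` must contain the resolved ``AT``."""
    if pathway not in _PATHWAY_PARAMS:
        raise DomainError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    _check_params(params, pathway)
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be non-negative")
    p = params
    denom = p["BW"] * p["AT"]
    if pathway == "ing":
        return c * p["R_ing"] * p["EF"] * p["ED"] / denom * 1e-6
    if pathway == "inh":
        return c * p["R_inh"] * p["EF"] * p["ED"] / (p["PEF"] * denom)
    return c * p["AF"] * p["SA"] * p["ABS"] * p["EF"] * p["ED"] / denom * 1e-6


def add_ingestion(c, profile, averaging: str = "nc"):
    """Soil-ingestion ADD, mg/(kg d)."""
    return average_daily_dose(c, _params_of(profile, averaging), "ing")


def add_inhalation(c, profile, averaging: str = "nc"):
    """Resuspended-particle inhalation ADD, mg/(kg d)."""
    return average_daily_dose(c, _params_of(profile, averaging), "inh")


def add_dermal(c, profile, averaging: str = "nc"):
    """Dermal-contact ADD, mg/(kg d)."""
    return average_daily_dose(c, _params_of(profile, averaging), "dermal")


@dataclass(frozen=True)
class RiskResult:
    """Deterministic risk for one population at one concentration vector."""

    population: str
    hi: pd.DataFrame        # metals x pathways (NaN where no RfD)
    hi_metal: pd.Series     # HI_i = sum over pathways
    thi: float
    cr: pd.DataFrame        # metals x pathways (NaN where no SF)
    cr_metal: pd.Series     # CR_i; NaN for metals with no SF at all
    tcr: float

    @property
    def hi_flags(self) -> pd.Series:
        return self.hi_metal > HI_THRESHOLD

    @property
    def cr_flags(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"above_1e-4": self.cr_metal > CR_UPPER, "below_1e-6": self.cr_metal < CR_LOWER}
        )


def _risk_components(conc: Mapping[str, object], nc_params, ca_params, tox: ToxicityTable):
    """Per (metal, pathway) HI and CR terms; missing tox entries -> None."""
    hi, cr, skipped = {}, {}, []
    for metal, c in conc.items():
        for pathway in PATHWAYS:
            rfd = tox.rfd_for(metal, pathway)
            sf = tox.sf_for(metal, pathway)
            if rfd is not None:
                hi[(metal, pathway)] = average_daily_dose(c, nc_params, pathway) / rfd
            if sf is not None:
                cr[(metal, pathway)] = average_daily_dose(c, ca_params, pathway) * sf
            if rfd is None and sf is None:
                skipped.append((metal, pathway))
    if skipped:
        logger.info("no RfD/SF for %s; these pathways contribute 0", skipped)
    return hi, cr


def assess(
    conc: Mapping[str, float],
    profile: ExposureProfile,
    tox: ToxicityTable,
) -> RiskResult:
    """Deterministic HI/THI and CR/TCR for one concentration vector."""
    metals = [m for m in METALS if m in conc] or list(conc)
    nc = profile.point_values("nc")
    ca = profile.point_values("ca")
    hi_terms, cr_terms = _risk_components({m: conc[m] for m in metals}, nc, ca, tox)

    hi = pd.DataFrame(np.nan, index=metals, columns=list(PATHWAYS))
    cr = pd.DataFrame(np.nan, index=metals, columns=list(PATHWAYS))
    for (m, p), v in hi_terms.items():
        hi.loc[m, p] = float(v)
    for (m, p), v in cr_terms.items():
        cr.loc[m, p] = float(v)
    hi_metal = hi.sum(axis=1, min_count=1).fillna(0.0)
    cr_metal = cr.sum(axis=1, min_count=1)  # NaN when the metal has no SF at all
    return RiskResult(
        population=profile.population,
        hi=hi,
        hi_metal=hi_metal,
        thi=float(hi_metal.sum()),
        cr=cr,
        cr_metal=cr_metal,
        tcr=float(cr_metal.sum(skipna=True)),
    )


def survey_assess(
    survey: Survey,
    profile: ExposureProfile,
    tox: ToxicityTable,
) -> pd.DataFrame:
    """Per-sample THI/TCR and per-metal HI/CR over a survey (vectorised)."""
    nc = profile.point_values("nc")
    ca = profile.point_values("ca")
    conc = {m: survey.frame[m].to_numpy(dtype=float) for m in survey.metals}
    hi_terms, cr_terms = _risk_components(conc, nc, ca, tox)
    out = pd.DataFrame({"sample_id": survey.frame["sample_id"]})
    thi = np.zeros(survey.n)
    tcr = np.zeros(survey.n)
    for m in survey.metals:
        hi_m = sum(
            (v for (mm, _), v in hi_terms.items() if mm == m), np.zeros(survey.n)
        )
        out[f"HI_{m}"] = hi_m
        thi += hi_m
        cr_list = [v for (mm, _), v in cr_terms.items() if mm == m]
        if cr_list:
            cr_m = sum(cr_list[1:], cr_list[0])
            out[f"CR_{m}"] = cr_m
            tcr += cr_m
    out["THI"] = thi
    out["TCR"] = tcr
    out["population"] = profile.population
    return out


def table_by_population(
    conc: Mapping[str, float],
    profiles: Mapping[str, ExposureProfile],
    tox: ToxicityTable,
) -> pd.DataFrame:
    """Long-format HI/CR table (metal x population x pathway) plus THI/TCR rows."""
    rows = []
    for pop, profile in profiles.items():
        res = assess(conc, profile, tox)
        for m in res.hi.index:
            rows.append(
                {
                    "metal": m,
                    "population": pop,
                    **{f"HI_{p}": res.hi.loc[m, p] for p in PATHWAYS},
                    "HI": res.hi_metal[m],
                    **{f"CR_{p}": res.cr.loc[m, p] for p in PATHWAYS},
                    "CR": res.cr_metal[m],
                }
            )
        rows.append(
            {
                "metal": "THI/TCR",
                "population": pop,
                **{f"HI_{p}": res.hi[p].sum(min_count=1) for p in PATHWAYS},
                "HI": res.thi,
                **{f"CR_{p}": res.cr[p].sum(min_count=1) for p in PATHWAYS},
                "CR": res.tcr,
            }
        )
    return pd.DataFrame(rows)
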
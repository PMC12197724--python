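"""Target-organ toxicity dose (TTD) modification of the hazard index.

The classical HI divides a metal's dose by a single chronic reference dose,
i.e. by the threshold of its *most sensitive* endpoint only.  The TTD
mixtures method instead apportions hazard by target organ: for each organ the
hazard quotients ``ADD_ing / TTD(metal, organ)`` of all metals affecting that
organ are summed dose-additively, so simultaneous sub-threshold insults to
the same organ by several metals are no longer invisible.  Only the oral
ingestion dose feeds the method by default (the dominant pathway); other
pathways can be switched on.

Hg carries no endpoint entries in the bundled table (organ-specific
toxicity data for it are lacking) and is skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .deterministic import RiskResult, average_daily_dose
from .exceptions import DomainError
from .reference import METALS, ExposureProfile, ToxicityTable

logger = logging.getLogger(__name__)

__all__ = ["ttd_hazard", "ttd_vs_traditional", "TTDResult", "TTDComparison"]


@dataclass(frozen=True)
class TTDResult:
    """Multi-organ hazard for one population."""

    population: str
    matrix: pd.DataFrame      # metals x organs, HI_TTD entries (NaN where no endpoint)
    per_metal: pd.Series      # cumulative over organs
    per_organ: pd.Series      # cumulative over metals
    thi_ttd: float
    metal_shares: pd.Series   # % of THI_TTD, sums to 100
    organ_shares: pd.Series   # % of THI_TTD, sums to 100


def ttd_hazard(
    conc: Mapping[str, float],
    profile: ExposureProfile,
    tox: ToxicityTable,
    pathways: tuple[str, ...] = ("ing",),
) -> TTDResult:
    """Per-(metal, organ) hazard quotients and their marginal aggregates."""
    if not tox.ttd:
        raise DomainError("TTD endpoint table is empty")
    organs = tox.organs
    metals = [m for m in METALS if m in conc] or list(conc)
    params = profile.point_values("nc")
    dose = {
        m: sum(average_daily_dose(conc[m], params, p) for p in pathways) for m in metals
    }
    matrix = pd.DataFrame(np.nan, index=metals, columns=list(organs))
    for m in metals:
        entries = [(o, tox.ttd_for(m, o)) for o in organs if tox.ttd_for(m, o) is not None]
        if not entries:
            logger.warning("metal %s has no TTD endpoints; excluded from TTD hazard", m)
            continue
        for organ, ttd in entries:
            matrix.loc[m, organ] = dose[m] / ttd
    per_metal = matrix.sum(axis=1, min_count=1).dropna()
    per_organ = matrix.sum(axis=0, min_count=1).dropna()
    thi_ttd = float(per_metal.sum())
    if not thi_ttd > 0:
        raise DomainError("THI_TTD is zero; no metal/organ endpoint applies")
    return TTDResult(
        population=profile.population,
        matrix=matrix,
        per_metal=per_metal,
        per_organ=per_organ,
        thi_ttd=thi_ttd,
        metal_shares=100.0 * per_metal / thi_ttd,
        organ_shares=100.0 * per_organ / thi_ttd,
    )


@dataclass(frozen=True)
class TTDComparison:
    population: str
    total_ratio: float          # THI_TTD / THI
    per_metal_ratios: pd.Series  # HI_TTD / HI, metals present in both


def ttd_vs_traditional(ttd: TTDResult, risk: RiskResult) -> TTDComparison:
    """Amplification of the multi-organ hazard over the single-endpoint HI."""
    if ttd.population != risk.population:
        raise DomainError(
            f"population mismatch: TTD is {ttd.population!r}, risk is {risk.population!r}"
        )
    if not risk.thi > 0:
        raise DomainError("THI is zero; amplification ratio undefined")
    common = [m for m in ttd.per_metal.index if m in risk.hi_metal.index and risk.hi_metal[m] > 0]
    return TTDComparison(
        population=ttd.population,
        total_ratio=ttd.thi_ttd / risk.thi,
        per_metal_ratios=ttd.per_metal[common] / risk.hi_metal[common],
    )
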
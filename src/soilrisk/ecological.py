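"""Hakanson potential ecological risk: per-metal Er and the aggregate RI.

``Er = T_i * C_i / S_i`` weights the concentration ratio by the metal's
toxic response factor T_i; ``RI`` is the plain sum over metals.  The
denominator defaults to the pH-class screening value (as the governing
equation is written); classical Hakanson practice divides by the
geochemical background instead, so ``denominator="background"`` is offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .reference import ReferenceTables, ph_class
from .surveys import Survey

__all__ = ["ecological_risk_single", "risk_index", "survey_ecological", "EcoRiskResult"]


def ecological_risk_single(c, s, t):
    """Er = T * C / S; vectorised; all inputs must be positive."""
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    for name, a in (("concentration", c), ("reference value", s), ("toxic response factor", t)):
        if np.any(~(a > 0)):
            raise DomainError(f"{name} must be positive")
    return t * c / s


def risk_index(er_values) -> float:
    """RI = sum of the per-metal Er values (exact sum)."""
    er = np.asarray(list(er_values) if not isinstance(er_values, np.ndarray) else er_values, dtype=float)
    if er.size == 0:
        raise DomainError("risk_index needs at least one Er value")
    if np.any(er < 0):
        raise DomainError("Er values must be non-negative")
    return float(er.sum())


@dataclass(frozen=True)
class EcoRiskResult:
    per_sample: pd.DataFrame   # tidy: sample_id, metal, Er, Er_label
    ri: pd.Series              # per-sample RI
    ri_labels: pd.Series
    mean_er: pd.Series         # survey-level mean Er per metal
    mean_ri: float
    mean_ri_label: str
    denominator: str


def survey_ecological(
    survey: Survey,
    tables: ReferenceTables,
    denominator: str = "screening",
) -> EcoRiskResult:
    """Per-sample Er/RI over a survey with Hakanson band labels."""
    if denominator not in ("screening", "background"):
        raise DomainError(
            f"denominator must be 'screening' or 'background', got {denominator!r}"
        )
    std = tables.standards
    df = survey.frame
    classes = ph_class(df["pH"].to_numpy())

    rows = []
    for m in survey.metals:
        c = df[m].to_numpy(dtype=float)
        if denominator == "screening":
            s = std.screening.loc[m].reindex(classes).to_numpy(dtype=float)
        else:
            s = std.background[m]
        er = ecological_risk_single(c, s, std.toxic_response[m])
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": df["sample_id"],
                    "metal": m,
                    "Er": er,
                    "Er_label": [tables.classify("er", v) for v in er],
                }
            )
        )
    per_sample = pd.concat(rows, ignore_index=True)
    er_wide = per_sample.pivot(index="sample_id", columns="metal", values="Er").loc[
        df["sample_id"]
    ]
    ri = er_wide.sum(axis=1)
    ri_labels = ri.map(lambda v: tables.classify("ri", v))
    mean_er = er_wide.mean(axis=0)
    mean_ri = float(mean_er.sum())
    return EcoRiskResult(
        per_sample=per_sample,
        ri=ri,
        ri_labels=ri_labels,
        mean_er=mean_er,
        mean_ri=mean_ri,
        mean_ri_label=tables.classify("ri", mean_ri),
        denominator=denominator,
    )
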
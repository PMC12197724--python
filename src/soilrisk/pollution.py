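"""Pollution indices: single-factor PI, Nemerow composite, geoaccumulation.

* ``PI = C_i / S_i`` against the pH-class screening value.
* ``P_N = sqrt((mean(PI)^2 + max(PI)^2) / 2)`` — the Nemerow composite,
  weighted toward the worst single pollutant.
* ``Igeo = log2(C_i / (1.5 B_i))`` against the geochemical background, the
  1.5 absorbing lithogenic variability.

`survey_pollution` applies all three over a survey and adds the descriptive
statistics and exceedance rates a survey report needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .reference import PH_CLASSES, ReferenceStandards, ReferenceTables, ph_class
from .surveys import Survey

__all__ = [
    "single_factor_index",
    "nemerow_index",
    "geoaccumulation_index",
    "survey_pollution",
    "PollutionResult",
]


def _require_positive(name, value):
    arr = np.asarray(value, dtype=float)
    if np.any(~(arr > 0)):
        raise DomainError(f"{name} must be positive, got {value!r}")
    return arr


def single_factor_index(c, s):
    """PI = C/S; vectorised; inputs must be positive."""
    c = _require_positive("concentration", c)
    s = _require_positive("screening value", s)
    return c / s


def nemerow_index(pi_values) -> float:
    """Nemerow composite over one sample's per-metal PI values."""
    pi = np.asarray(list(pi_values) if not isinstance(pi_values, np.ndarray) else pi_values, dtype=float)
    if pi.size == 0:
        raise DomainError("nemerow_index needs at least one PI value")
    if np.any(~(pi > 0)):
        raise DomainError("PI values must be positive")
    return float(np.sqrt((pi.mean() ** 2 + pi.max() ** 2) / 2.0))


def geoaccumulation_index(c, b):
    """Igeo = log2(C / (1.5 B)); vectorised; inputs must be positive."""
    c = _require_positive("concentration", c)
    b = _require_positive("background value", b)
    return np.log2(c / (1.5 * b))


@dataclass(frozen=True)
class PollutionResult:
    """Pollution assessment of one survey."""

    per_sample: pd.DataFrame        # tidy: sample_id, metal, conc, ph_class, PI, PI_label, Igeo, Igeo_label
    nemerow: pd.Series              # per-sample P_N
    nemerow_labels: pd.Series
    survey_nemerow: float           # P_N of the per-metal mean PIs (survey level)
    survey_nemerow_label: str
    summary: pd.DataFrame           # min/max/mean/sd/cv per metal (+ pH)
    exceedance_screening: pd.DataFrame  # % above S_i, per pH class and total
    exceedance_background: pd.Series    # % above B_i
    mean_pi: pd.Series              # per-metal mean PI
    mean_igeo: pd.Series


def survey_pollution(
    survey: Survey,
    tables: ReferenceTables,
    sd_ddof: int = 1,
) -> PollutionResult:
    """All pollution indices, summary statistics and exceedance rates.

    Exceedance is reported both against the pH-class screening values (per
    class and overall) and against the background values, since the two
    comparisons answer different questions (regulatory risk vs enrichment).
    ``sd_ddof=1`` uses the sample (n-1) standard deviation.
    """
    std = tables.standards
    df = survey.frame
    metals = survey.metals
    classes = ph_class(df["pH"].to_numpy())

    rows = []
    for m in metals:
        c = df[m].to_numpy(dtype=float)
        s = std.screening.loc[m].reindex(classes).to_numpy(dtype=float)
        pi = single_factor_index(c, s)
        igeo = geoaccumulation_index(c, std.background[m])
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": df["sample_id"],
                    "metal": m,
                    "conc": c,
                    "ph_class": classes,
                    "screening": s,
                    "PI": pi,
                    "PI_label": [tables.classify("pi", v) for v in pi],
                    "Igeo": igeo,
                    "Igeo_label": [tables.classify("igeo", v) for v in igeo],
                }
            )
        )
    per_sample = pd.concat(rows, ignore_index=True)

    pi_wide = per_sample.pivot(index="sample_id", columns="metal", values="PI").loc[
        df["sample_id"]
    ]
    p_n = pi_wide.apply(lambda r: nemerow_index(r.to_numpy()), axis=1)
    p_n_labels = p_n.map(lambda v: tables.classify("nemerow", v))

    mean_pi = pi_wide.mean(axis=0)
    survey_pn = nemerow_index(mean_pi.to_numpy())

    stats_cols = [*metals, "pH"] if "pH" in df.columns else list(metals)
    summary = pd.DataFrame(
        {
            "min": df[stats_cols].min(),
            "max": df[stats_cols].max(),
            "mean": df[stats_cols].mean(),
            "sd": df[stats_cols].std(ddof=sd_ddof),
        }
    )
    summary["cv_pct"] = 100.0 * summary["sd"] / summary["mean"]

    exc_rows = {}
    for cls in PH_CLASSES:
        in_cls = classes == cls
        if in_cls.sum() == 0:
            exc_rows[cls] = {m: np.nan for m in metals}
            continue
        exc_rows[cls] = {
            m: 100.0
            * float(
                (df.loc[in_cls, m].to_numpy() > std.screening_value(m, ph_cls=cls)).mean()
            )
            for m in metals
        }
    total = {
        m: 100.0
        * float(
            (
                df[m].to_numpy()
                > std.screening.loc[m].reindex(classes).to_numpy(dtype=float)
            ).mean()
        )
        for m in metals
    }
    exc_screening = pd.DataFrame({**exc_rows, "total": total}).T
    exc_background = pd.Series(
        {m: 100.0 * float((df[m] > std.background[m]).mean()) for m in metals},
        name="exceedance_background_pct",
    )

    mean_igeo = per_sample.groupby("metal")["Igeo"].mean().reindex(list(metals))

    return PollutionResult(
        per_sample=per_sample,
        nemerow=p_n,
        nemerow_labels=p_n_labels,
        survey_nemerow=survey_pn,
        survey_nemerow_label=tables.classify("nemerow", survey_pn),
        summary=summary,
        exceedance_screening=exc_screening,
        exceedance_background=exc_background,
        mean_pi=mean_pi,
        mean_igeo=mean_igeo,
    )
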
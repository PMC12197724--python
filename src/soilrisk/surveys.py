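"""Soil-survey data model and CSV I/O.

A survey is one row per composite topsoil sample: an identifier, optional
region label and planar coordinates, soil pH, and dry-weight concentrations
(mg/kg) of a subset of {As, Cd, Cr, Hg, Pb}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError
from .reference import METALS

META_COLUMNS = ("sample_id", "region", "x", "y", "pH")


@dataclass(frozen=True)
class SoilSample:
    """One georeferenced sample."""

    sample_id: str
    pH: float
    conc: Mapping[str, float]  # metal -> mg/kg dry soil
    region: str | None = None
    x: float | None = None
    y: float | None = None


@dataclass(frozen=True)
class Survey:
    """An ordered collection of samples backed by a DataFrame."""

    frame: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self):
        _validate_frame(self.frame)

    @property
    def metals(self) -> tuple[str, ...]:
        return tuple(m for m in METALS if m in self.frame.columns)

    @property
    def n(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[SoilSample]:
        for row in self.frame.itertuples(index=False):
            yield SoilSample(
                sample_id=row.sample_id,
                pH=row.pH,
                conc={m: getattr(row, m) for m in self.metals},
                region=getattr(row, "region", None),
                x=getattr(row, "x", None),
                y=getattr(row, "y", None),
            )

    def concentrations(self) -> pd.DataFrame:
        """n x metals concentration matrix indexed by sample_id."""
        return self.frame.set_index("sample_id")[list(self.metals)]

    def mean_concentrations(self) -> dict[str, float]:
        return {m: float(self.frame[m].mean()) for m in self.metals}


def _validate_frame(df: pd.DataFrame) -> None:
    if "sample_id" not in df.columns or "pH" not in df.columns:
        raise SchemaError("survey frame needs 'sample_id' and 'pH' columns")
    metals = [m for m in METALS if m in df.columns]
    if not metals:
        raise SchemaError(f"survey frame needs at least one metal column of {METALS}")
    if len(df) == 0:
        raise ValidationError("survey is empty")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample ids: {sorted(set(dup))[:5]}")
    problems = []
    ph_bad = ~((df["pH"] > 0) & (df["pH"] < 14))
    for sid in df.loc[ph_bad, "sample_id"]:
        problems.append(f"sample {sid}: pH outside (0, 14)")
    for m in metals:
        col = pd.to_numeric(df[m], errors="coerce")
        bad = ~(col > 0)
        for sid in df.loc[bad, "sample_id"]:
            problems.append(f"sample {sid}: non-positive or missing {m} concentration")
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row value(s): " + "; ".join(problems[:10])
        )


def read_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Survey:
    """Read a sample table from CSV/TSV.

    ``schema`` maps file column names to the canonical names
    (``sample_id``, ``region``, ``x``, ``y``, ``pH``, and metal symbols);
    unmapped canonical names are matched case-insensitively.  A missing
    ``sample_id`` column is synthesised from the row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)
    if schema:
        missing = [c for c in schema if c not in raw.columns]
        if missing:
            raise SchemaError(f"schema maps absent column(s) {missing}; file has {list(raw.columns)}")
        raw = raw.rename(columns=dict(schema))
    # case-insensitive fallback for canonical names
    canon = {c.lower(): c for c in (*META_COLUMNS, *METALS)}
    raw = raw.rename(columns={c: canon[c.lower()] for c in raw.columns if c.lower() in canon})
    if "pH" not in raw.columns:
        raise SchemaError(f"missing required column 'pH'; file has {list(raw.columns)}")
    if not any(m in raw.columns for m in METALS):
        raise SchemaError(f"no metal concentration column found among {METALS}")
    if "sample_id" not in raw.columns:
        raw.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(len(raw))])
    raw["sample_id"] = raw["sample_id"].astype(str)
    keep = [c for c in (*META_COLUMNS, *METALS) if c in raw.columns]
    return Survey(raw[keep].reset_index(drop=True), provenance or str(path))


def write_survey(survey: Survey, path: str | Path) -> Path:
    """Write the survey to CSV; numeric fields round-trip bit-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    survey.frame.to_csv(path, index=False)
    return path
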
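"""End-to-end orchestration: run selected stages, write CSVs + JSON + report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import deterministic, ecological, montecarlo, pollution, ttd
from .exceptions import DomainError
from .reference import ReferenceTables, load_reference_tables
from .surveys import Survey, read_survey, write_survey
from .synthetic import GeneratorSpec, generate_survey

logger = logging.getLogger(__name__)

STAGES = ("pollution", "eco", "deterministic", "montecarlo", "ttd")


@dataclass
class RunConfig:
    """What to run, on what input, and where to write it."""

    outdir: str | Path = "results"
    input: str | Path | None = None          # survey CSV; None -> synthetic
    stages: tuple[str, ...] = STAGES
    n_synthetic: int = 740
    seed: int = montecarlo.DEFAULT_SEED
    iterations: int = montecarlo.DEFAULT_ITERATIONS
    populations: tuple[str, ...] = ("adults", "children")
    eco_denominator: str = "screening"
    table_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise DomainError(f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}")
        if not self.stages:
            raise DomainError("at least one stage is required")
        for name, path in self.table_overrides.items():
            if not Path(path).exists():
                raise DomainError(f"override file for {name!r} does not exist: {path}")


def _fmt(x):
    return float(f"{x:.6g}") if isinstance(x, (int, float, np.floating)) else x


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the machine-readable aggregates."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = load_reference_tables(**config.table_overrides)

    if config.input is not None:
        survey = read_survey(config.input)
    else:
        survey = generate_survey(GeneratorSpec.default(n=config.n_synthetic), seed=config.seed)
        write_survey(survey, outdir / "survey.csv")
    logger.info("survey: %d samples from %s", survey.n, survey.provenance)

    mean_conc = survey.mean_concentrations()
    profiles = {p: tables.profiles[p] for p in config.populations}
    aggregates: dict = {
        "provenance": survey.provenance,
        "n_samples": survey.n,
        "seed": config.seed,
        "mean_concentrations": {k: _fmt(v) for k, v in mean_conc.items()},
    }
    report = [
        "# Soil heavy-metal risk assessment report",
        "",
        f"Input: {survey.provenance} ({survey.n} samples, metals {', '.join(survey.metals)})",
        "",
    ]

    if "pollution" in config.stages:
        res = pollution.survey_pollution(survey, tables)
        res.per_sample.to_csv(outdir / "pollution_per_sample.csv", index=False)
        res.summary.to_csv(outdir / "pollution_summary.csv")
        res.exceedance_screening.to_csv(outdir / "exceedance_screening.csv")
        aggregates["pollution"] = {
            "survey_nemerow": _fmt(res.survey_nemerow),
            "survey_nemerow_label": res.survey_nemerow_label,
            "mean_PI": {m: _fmt(v) for m, v in res.mean_pi.items()},
            "mean_Igeo": {m: _fmt(v) for m, v in res.mean_igeo.items()},
            "exceedance_screening_total_pct": {
                m: _fmt(v) for m, v in res.exceedance_screening.loc["total"].items()
            },
            "exceedance_background_pct": {
                m: _fmt(v) for m, v in res.exceedance_background.items()
            },
        }
        report += [
            "## Pollution indices",
            "",
            f"Survey-level Nemerow index P_N = {res.survey_nemerow:.3g}"
            f" ({res.survey_nemerow_label}).",
            "",
            res.summary.to_markdown(floatfmt=".4g"),
            "",
        ]

    if "eco" in config.stages:
        res = ecological.survey_ecological(survey, tables, config.eco_denominator)
        res.per_sample.to_csv(outdir / "ecological_per_sample.csv", index=False)
        aggregates["ecological"] = {
            "mean_Er": {m: _fmt(v) for m, v in res.mean_er.items()},
            "mean_RI": _fmt(res.mean_ri),
            "mean_RI_label": res.mean_ri_label,
            "denominator": res.denominator,
        }
        report += [
            "## Ecological risk",
            "",
            f"Mean RI = {res.mean_ri:.3g} ({res.mean_ri_label}; denominator:"
            f" {res.denominator}).",
            "",
        ]

    det_results = {}
    if "deterministic" in config.stages or "ttd" in config.stages:
        table = deterministic.table_by_population(mean_conc, profiles, tables.toxicity)
        det_results = {
            pop: deterministic.assess(mean_conc, prof, tables.toxicity)
            for pop, prof in profiles.items()
        }
    if "deterministic" in config.stages:
        table.to_csv(outdir / "deterministic_table.csv", index=False)
        per_sample = pd.concat(
            [
                deterministic.survey_assess(survey, prof, tables.toxicity)
                for prof in profiles.values()
            ],
            ignore_index=True,
        )
        per_sample.to_csv(outdir / "deterministic_per_sample.csv", index=False)
        aggregates["deterministic"] = {
            pop: {
                "THI": _fmt(r.thi),
                "TCR": _fmt(r.tcr),
                "HI": {m: _fmt(v) for m, v in r.hi_metal.items()},
                "CR": {m: _fmt(v) for m, v in r.cr_metal.dropna().items()},
                "pct_THI_above_1": _fmt(
                    100.0
                    * float(
                        (per_sample.loc[per_sample["population"] == pop, "THI"] > 1).mean()
                    )
                ),
                "pct_TCR_above_1e-4": _fmt(
                    100.0
                    * float(
                        (per_sample.loc[per_sample["population"] == pop, "TCR"] > 1e-4).mean()
                    )
                ),
            }
            for pop, r in det_results.items()
        }
        report += ["## Deterministic risk (at survey-mean concentrations)", ""]
        for pop, r in det_results.items():
            report.append(f"- {pop}: THI = {r.thi:.3g}, TCR = {r.tcr:.3g}")
        report.append("")

    if "montecarlo" in config.stages:
        from .distributions import DistributionSpec

        conc_model = {
            m: DistributionSpec(
                "lognormal",
                value=float(survey.frame[m].mean()),
                sd=float(survey.frame[m].std(ddof=1)),
                low=float(survey.frame[m].min()),
                high=float(survey.frame[m].max()),
            )
            for m in survey.metals
        }
        mc = montecarlo.run_monte_carlo(
            conc_model, profiles, tables.toxicity, n=config.iterations, seed=config.seed
        )
        mc.summary().to_csv(outdir / "montecarlo_summary.csv", index=False)
        aggregates["montecarlo"] = {
            pop: {
                "mean_HI": {m: _fmt(v) for m, v in d.hi.mean(axis=0).items()},
                "mean_CR": {m: _fmt(v) for m, v in d.cr.mean(axis=0).items()},
                "P(THI>1)_pct": _fmt(100 * mc.exceedance_probability(1.0, pop, "thi")),
                "P(TCR>1e-4)_pct": _fmt(100 * mc.exceedance_probability(1e-4, pop, "tcr")),
                "HI_contribution_pct": {
                    m: _fmt(v) for m, v in mc.contribution_shares(pop, "hi").items()
                },
            }
            for pop, d in mc.populations.items()
        }
        report += [
            "## Monte Carlo risk",
            "",
            f"{mc.n_iterations} iterations, seed {mc.seed}.",
            "",
        ]
        for pop in profiles:
            report.append(
                f"- {pop}: P(THI>1) = {mc.exceedance_probability(1.0, pop, 'thi'):.2%},"
                f" P(TCR>1e-4) = {mc.exceedance_probability(1e-4, pop, 'tcr'):.2%}"
            )
        report.append("")

    if "ttd" in config.stages:
        ttd_rows = []
        aggregates["ttd"] = {}
        for pop, prof in profiles.items():
            res = ttd.ttd_hazard(mean_conc, prof, tables.toxicity)
            comp = ttd.ttd_vs_traditional(res, det_results[pop])
            long = (
                res.matrix.stack()
                .rename("HI_TTD")
                .rename_axis(["metal", "organ"])
                .reset_index()
            )
            long.insert(0, "population", pop)
            ttd_rows.append(long)
            aggregates["ttd"][pop] = {
                "THI_TTD": _fmt(res.thi_ttd),
                "per_metal": {m: _fmt(v) for m, v in res.per_metal.items()},
                "per_organ": {o: _fmt(v) for o, v in res.per_organ.items()},
                "metal_shares_pct": {m: _fmt(v) for m, v in res.metal_shares.items()},
                "organ_shares_pct": {o: _fmt(v) for o, v in res.organ_shares.items()},
                "amplification_vs_THI": _fmt(comp.total_ratio),
            }
            report += [
                f"## TTD multi-organ hazard ({pop})",
                "",
                f"THI_TTD = {res.thi_ttd:.3g} "
                f"({comp.total_ratio:.3g}x the single-endpoint THI).",
                "",
            ]
        pd.concat(ttd_rows, ignore_index=True).to_csv(outdir / "ttd_per_organ.csv", index=False)

    (outdir / "aggregates.json").write_text(json.dumps(aggregates, indent=2))
    (outdir / "report.md").write_text("\n".join(report))
    return aggregates
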
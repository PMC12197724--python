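"""Monte Carlo propagation of exposure and concentration uncertainty.

Every uncertain input (exposure parameter or soil concentration) is a
:class:`~soilrisk.distributions.DistributionSpec`; each of the ``n``
iterations draws one value per input and evaluates the same dose/risk
formulas as the deterministic module, yielding empirical distributions of
HI and CR per metal, THI and TCR, with exceedance probabilities and
per-metal contribution shares.

Point-mass specs reproduce the deterministic results exactly, which pins the
Monte Carlo engine to the deterministic one by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .deterministic import _risk_components
from .distributions import DistributionSpec
from .exceptions import DomainError
from .reference import METALS, ExposureProfile, ToxicityTable
from .surveys import Survey

logger = logging.getLogger(__name__)

DEFAULT_ITERATIONS = 10_000
DEFAULT_SEED = 20170740  # survey vintage + sample count; reproducible shipped results


def sample_parameters(
    specs: Mapping[str, DistributionSpec],
    n: int,
    seed_or_rng,
) -> pd.DataFrame:
    """``n`` independent draws per parameter; deterministic under a fixed seed."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = {}
    for name, spec in specs.items():
        if not isinstance(spec, DistributionSpec):
            raise DomainError(f"parameter {name!r} has no valid distribution spec")
        out[name] = spec.sample(rng, n)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class PopulationDraws:
    hi: pd.DataFrame    # n x metals
    cr: pd.DataFrame    # n x metals (only metals with any SF)
    thi: np.ndarray
    tcr: np.ndarray


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical risk distributions per population."""

    populations: Mapping[str, PopulationDraws]
    n_iterations: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        """Mean and 5th/50th/95th percentiles of HI and CR per metal and of THI/TCR."""
        rows = []
        for pop, d in self.populations.items():
            for kind, frame in (("HI", d.hi), ("CR", d.cr)):
                for m in frame.columns:
                    rows.append(self._stats(pop, m, kind, frame[m].to_numpy()))
            rows.append(self._stats(pop, "total", "THI", d.thi))
            rows.append(self._stats(pop, "total", "TCR", d.tcr))
        return pd.DataFrame(rows)

    @staticmethod
    def _stats(pop, metal, kind, x):
        return {
            "population": pop,
            "metal": metal,
            "kind": kind,
            "mean": float(np.mean(x)),
            "p5": float(np.percentile(x, 5)),
            "p50": float(np.percentile(x, 50)),
            "p95": float(np.percentile(x, 95)),
        }

    def draws(self, population: str, metric: str, metal: str | None = None) -> np.ndarray:
        d = self.populations[population]
        if metric == "thi":
            return d.thi
        if metric == "tcr":
            return d.tcr
        if metric == "hi":
            return d.hi[metal].to_numpy()
        if metric == "cr":
            return d.cr[metal].to_numpy()
        raise DomainError(f"unknown metric {metric!r}; expected thi|tcr|hi|cr")

    def exceedance_probability(
        self, threshold: float, population: str, metric: str = "thi", metal: str | None = None
    ) -> float:
        """Fraction of draws strictly above ``threshold``."""
        x = self.draws(population, metric, metal)
        return float(np.mean(x > threshold))

    def contribution_shares(self, population: str, kind: str = "hi") -> pd.Series:
        """Per-metal % contribution of mean HI (or CR) to THI (TCR); sums to 100."""
        d = self.populations[population]
        frame = d.hi if kind == "hi" else d.cr
        if frame.shape[1] < 2:
            raise DomainError("contribution shares need at least two metals")
        return contribution_shares(frame.mean(axis=0))

    def cumulative_distribution(
        self, population: str, metric: str, metal: str | None = None, points: int = 200
    ) -> pd.DataFrame:
        """Empirical CDF table (value, cumulative probability)."""
        x = np.sort(self.draws(population, metric, metal))
        q = np.linspace(0, 1, points, endpoint=False) + 1.0 / points
        return pd.DataFrame({"value": np.quantile(x, q), "cum_prob": q})


def contribution_shares(means: Mapping[str, float] | pd.Series) -> pd.Series:
    """share_i = 100 * mean_i / sum_j mean_j (sums to 100 by construction)."""
    s = pd.Series(dict(means), dtype=float)
    total = s.sum()
    if not total > 0:
        raise DomainError("contribution shares undefined for a zero total")
    return 100.0 * s / total


def _concentration_draws(conc, metals, n, rng) -> dict[str, np.ndarray]:
    if isinstance(conc, Survey):
        rows = rng.integers(0, conc.n, size=n)  # bootstrap keeps inter-metal correlation
        mat = conc.concentrations().to_numpy(dtype=float)[rows]
        return {m: mat[:, i] for i, m in enumerate(conc.metals)}
    out = {}
    for m in metals:
        spec = conc[m]
        if isinstance(spec, (int, float)):
            spec = DistributionSpec("point", value=float(spec))
        out[m] = spec.sample(rng, n)
    return out


def run_monte_carlo(
    conc,
    profiles: Mapping[str, ExposureProfile],
    tox: ToxicityTable,
    n: int = DEFAULT_ITERATIONS,
    seed: int | None = DEFAULT_SEED,
) -> MonteCarloResult:
    """Propagate distributions through the dose/risk formulas.

    Parameters
    ----------
    conc:
        Concentration model — a mapping metal -> DistributionSpec (or plain
        number for a point value), or a :class:`Survey` whose rows are
        bootstrap-resampled.
    profiles:
        Populations to simulate (name -> :class:`ExposureProfile`); each
        parameter's distribution is used where present, its point value
        otherwise.
    """
    if n < 100:
        warnings.warn("fewer than 100 iterations gives unstable percentiles", stacklevel=2)
    metals = (
        conc.metals if isinstance(conc, Survey) else [m for m in METALS if m in conc] or list(conc)
    )
    ss = np.random.SeedSequence(seed)
    pops = {}
    for child, (pop, profile) in zip(ss.spawn(len(profiles)), profiles.items()):
        rng = np.random.default_rng(child)
        c_draws = _concentration_draws(conc, metals, n, rng)
        base = sample_parameters(profile.parameters, n, rng)
        nc = ExposureProfile._resolve({k: base[k].to_numpy() for k in base}, "nc")
        ca = ExposureProfile._resolve({k: base[k].to_numpy() for k in base}, "ca")
        hi_terms, cr_terms = _risk_components(c_draws, nc, ca, tox)
        hi = pd.DataFrame(index=range(n))
        cr = pd.DataFrame(index=range(n))
        for m in metals:
            parts = [v for (mm, _), v in hi_terms.items() if mm == m]
            hi[m] = sum(parts[1:], parts[0]) if parts else 0.0
            parts = [v for (mm, _), v in cr_terms.items() if mm == m]
            if parts:
                cr[m] = sum(parts[1:], parts[0])
        pops[pop] = PopulationDraws(
            hi=hi,
            cr=cr,
            thi=hi.to_numpy().sum(axis=1),
            tcr=cr.to_numpy().sum(axis=1) if cr.shape[1] else np.zeros(n),
        )
    return MonteCarloResult(populations=pops, n_iterations=n, seed=seed)
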
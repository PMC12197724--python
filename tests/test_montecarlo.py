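"""Monte Carlo engine: determinism, degenerate equivalence, consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilrisk.deterministic import assess
from soilrisk.distributions import DistributionSpec
from soilrisk.exceptions import DomainError
from soilrisk.montecarlo import contribution_shares, run_monte_carlo, sample_parameters
from soilrisk.reference import ExposureProfile
from soilrisk.synthetic import GeneratorSpec, generate_survey

CONC_SPECS = {
    "As": DistributionSpec("lognormal", value=9.08, sd=5.38, low=1.19, high=24.87),
    "Cd": DistributionSpec("lognormal", value=0.36, sd=0.16, low=0.08, high=0.75),
    "Cr": DistributionSpec("lognormal", value=73.06, sd=29.21, low=15.97, high=149.82),
    "Hg": DistributionSpec("lognormal", value=0.13, sd=0.06, low=0.02, high=0.29),
    "Pb": DistributionSpec("lognormal", value=28.14, sd=8.09, low=11.42, high=49.38),
}


def _point_profiles(tables):
    out = {}
    for pop, prof in tables.profiles.items():
        params = {
            k: DistributionSpec("point", value=s.value if s.kind != "uniform" else s.mean())
            for k, s in prof.parameters.items()
        }
        out[pop] = ExposureProfile(pop, params)
    return out


def test_sample_parameters_point_and_truncnorm(rng):
    specs = {
        "a": DistributionSpec("point", value=2.0),
        "b": DistributionSpec("normal", value=100, sd=10, low=80, high=120),
    }
    draws = sample_parameters(specs, 100_000, rng)
    assert (draws["a"] == 2.0).all()
    m_ref = float(stats.truncnorm.stats(-2, 2, loc=100, scale=10, moments="m"))
    se = draws["b"].std(ddof=1) / np.sqrt(len(draws))
    assert draws["b"].mean() == pytest.approx(m_ref, abs=3 * se)


def test_sample_parameters_deterministic():
    specs = {"b": DistributionSpec("normal", value=100, sd=10, low=80, high=120)}
    a = sample_parameters(specs, 1000, 42)
    b = sample_parameters(specs, 1000, 42)
    pd.testing.assert_frame_equal(a, b)


def test_run_twice_identical(tables):
    kw = dict(n=500, seed=7)
    a = run_monte_carlo(CONC_SPECS, tables.profiles, tables.toxicity, **kw)
    b = run_monte_carlo(CONC_SPECS, tables.profiles, tables.toxicity, **kw)
    for pop in a.populations:
        pd.testing.assert_frame_equal(a.populations[pop].hi, b.populations[pop].hi)
        assert (a.populations[pop].tcr == b.populations[pop].tcr).all()


def test_degenerate_point_mass_equals_deterministic(tables, mean_conc):
    """All-point specs reproduce the deterministic results to machine precision."""
    profiles = _point_profiles(tables)
    mc = run_monte_carlo(mean_conc, profiles, tables.toxicity, n=200, seed=1)
    for pop, prof in profiles.items():
        det = assess(mean_conc, prof, tables.toxicity)
        d = mc.populations[pop]
        assert np.all(d.thi == det.thi)
        assert np.all(d.tcr == det.tcr)
        for m in d.hi.columns:
            assert np.all(d.hi[m].to_numpy() == det.hi_metal[m])


def test_exceedance_probability_counts(tables):
    mc = run_monte_carlo(CONC_SPECS, tables.profiles, tables.toxicity, n=2000, seed=3)
    thi = mc.populations["children"].thi
    for thr in (0.5, 1.0, 2.0):
        assert mc.exceedance_probability(thr, "children", "thi") == pytest.approx(
            np.sum(thi > thr) / len(thi)
        )
    assert mc.exceedance_probability(thi.max() + 1, "children", "thi") == 0.0
    assert mc.exceedance_probability(-1.0, "children", "thi") == 1.0


def test_contribution_shares():
    s = contribution_shares({"A": 2.0, "B": 2.0})
    assert s["A"] == s["B"] == 50.0
    mc_shares = contribution_shares({"As": 5.18e-2, "Cr": 5.18e-2, "Pb": 1e-3})
    assert mc_shares.sum() == pytest.approx(100.0, abs=1e-9)
    with pytest.raises(DomainError):
        contribution_shares({"A": 0.0, "B": 0.0})


def test_linearity_in_concentration(tables):
    """Scaling the concentration distribution by k scales every draw by k."""
    conc = {"Cr": CONC_SPECS["Cr"]}
    scaled = {"Cr": CONC_SPECS["Cr"].scaled(2.0)}
    prof = {"adults": tables.profiles["adults"]}
    a = run_monte_carlo(conc, prof, tables.toxicity, n=1000, seed=11)
    b = run_monte_carlo(scaled, prof, tables.toxicity, n=1000, seed=11)
    ratio = b.populations["adults"].hi["Cr"] / a.populations["adults"].hi["Cr"]
    assert ratio.to_numpy() == pytest.approx(2.0, rel=1e-9)


def test_monte_carlo_consistency_across_n(tables):
    """Mean estimates at n=1e4 and n=1e5 agree within 3 combined SEs."""
    prof = {"adults": tables.profiles["adults"]}
    small = run_monte_carlo(CONC_SPECS, prof, tables.toxicity, n=10_000, seed=21)
    large = run_monte_carlo(CONC_SPECS, prof, tables.toxicity, n=100_000, seed=22)
    xs = small.populations["adults"].hi["Cr"].to_numpy()
    xl = large.populations["adults"].hi["Cr"].to_numpy()
    se = np.sqrt(xs.var(ddof=1) / len(xs) + xl.var(ddof=1) / len(xl))
    assert abs(xs.mean() - xl.mean()) < 3 * se


def test_bootstrap_concentration_model(tables):
    survey = generate_survey(GeneratorSpec.default(n=50), seed=5)
    mc = run_monte_carlo(survey, tables.profiles, tables.toxicity, n=1000, seed=5)
    d = mc.populations["adults"]
    assert d.hi.shape == (1000, 5)
    assert (d.thi > 0).all()


def test_low_iteration_warning(tables):
    with pytest.warns(UserWarning, match="iterations"):
        run_monte_carlo(CONC_SPECS, {"adults": tables.profiles["adults"]},
                        tables.toxicity, n=50, seed=1)


def test_summary_and_cdf_shapes(tables):
    mc = run_monte_carlo(CONC_SPECS, tables.profiles, tables.toxicity, n=500, seed=2)
    summ = mc.summary()
    assert {"mean", "p5", "p50", "p95"} <= set(summ.columns)
    cdf = mc.cumulative_distribution("adults", "hi", "Cr", points=50)
    assert len(cdf) == 50
    assert cdf["value"].is_monotonic_increasing
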
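"""Synthetic survey generator: calibration, determinism, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from soilrisk.distributions import DistributionSpec
from soilrisk.exceptions import DomainError
from soilrisk.pollution import survey_pollution
from soilrisk.synthetic import GeneratorSpec, fit_generator, generate_survey

TARGETS = {
    "As": (9.08, 5.38, 1.19, 24.87),
    "Cd": (0.36, 0.16, 0.08, 0.75),
    "Cr": (73.06, 29.21, 15.97, 149.82),
    "Hg": (0.13, 0.06, 0.02, 0.29),
    "Pb": (28.14, 8.09, 11.42, 49.38),
}


def test_default_calibration_moments_at_n740():
    """At the survey's own size the sample means land within 5% of targets."""
    survey = generate_survey(GeneratorSpec.default(), seed=20170740)
    assert survey.n == 740
    for m, (mean, sd, lo, hi) in TARGETS.items():
        col = survey.frame[m]
        assert col.mean() == pytest.approx(mean, rel=0.05)
        assert col.std(ddof=1) == pytest.approx(sd, rel=0.15)  # SD noisier than mean
    assert survey.frame["pH"].mean() == pytest.approx(6.14, rel=0.05)


def test_large_n_convergence():
    """At n=1e5 the mean and CV converge to the calibration within 2%."""
    survey = generate_survey(GeneratorSpec.default(n=100_000), seed=4)
    for m, (mean, sd, lo, hi) in TARGETS.items():
        col = survey.frame[m]
        assert col.mean() == pytest.approx(mean, rel=0.02)
        cv = 100 * col.std(ddof=1) / col.mean()
        assert cv == pytest.approx(100 * sd / mean, rel=0.02)


def test_truncation_bounds_hard():
    survey = generate_survey(GeneratorSpec.default(n=5000), seed=8)
    for m, (_, _, lo, hi) in TARGETS.items():
        assert survey.frame[m].min() >= lo
        assert survey.frame[m].max() <= hi
    assert survey.frame["pH"].between(3.84, 8.06).all()


def test_single_sample_valid():
    survey = generate_survey(GeneratorSpec.default(n=1), seed=1)
    assert survey.n == 1
    sample = next(iter(survey))
    assert 3.84 <= sample.pH <= 8.06
    assert all(v > 0 for v in sample.conc.values())


def test_seed_determinism():
    a = generate_survey(GeneratorSpec.default(), seed=123)
    b = generate_survey(GeneratorSpec.default(), seed=123)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    c = generate_survey(GeneratorSpec.default(), seed=124)
    assert not a.frame.equals(c.frame)
    assert a.provenance == "synthetic:123"


def test_ph_cd_gradient(tables):
    """Negative pH-Cd coupling: Cd exceeds its screening value far more often
    in the most acidic class than in the near-neutral one."""
    survey = generate_survey(GeneratorSpec.default(n=2000), seed=6)
    res = survey_pollution(survey, tables)
    exc = res.exceedance_screening
    assert exc.loc["<=5.5", "Cd"] > exc.loc["(6.5,7.5]", "Cd"]


def test_fit_recovers_moments():
    """generate -> fit -> generate is a fixed point up to sampling error."""
    survey = generate_survey(GeneratorSpec.default(n=2000), seed=13)
    spec = fit_generator(survey)
    regen = generate_survey(spec, seed=14)
    for m in survey.metals:
        obs = survey.frame[m]
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert regen.frame[m].mean() == pytest.approx(obs.mean(), abs=3 * np.sqrt(2) * se)
        assert spec.conc[m].value == pytest.approx(obs.mean(), rel=1e-9)
    assert spec.ph_cd_correlation < 0  # sign of the coupling recovered


def test_fit_zero_variance_becomes_point():
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(40)],
            "pH": np.linspace(5.0, 7.0, 40),
            "As": np.linspace(2, 12, 40),
            "Cd": np.full(40, 0.3),
        }
    )
    from soilrisk.surveys import Survey

    with pytest.warns(UserWarning, match="zero variance"):
        spec = fit_generator(Survey(df))
    assert spec.conc["Cd"].kind == "point"
    assert spec.conc["Cd"].value == 0.3


def test_fit_requires_enough_samples(toy_survey):
    with pytest.raises(DomainError, match="30"):
        fit_generator(toy_survey)


def test_infeasible_truncation_raises():
    spec = GeneratorSpec.default()
    bad = dict(spec.conc)
    # target mean outside the truncation bounds cannot be moment-matched
    bad["As"] = DistributionSpec("lognormal", value=30.0, sd=0.5, low=1.19, high=24.87)
    from dataclasses import replace

    with pytest.raises(ValueError):
        generate_survey(replace(spec, conc=bad, n=10), seed=1)


def test_region_weights_proportional():
    survey = generate_survey(GeneratorSpec.default(n=740), seed=2)
    counts = survey.frame["region"].value_counts()
    # design weights: ZY 148 and QDN 151 dominate; LPS 21 is the smallest
    assert counts["QDN"] >= counts["ZY"] > counts["QN"] > counts["LPS"]
    assert counts.sum() == 740


def test_hotspot_mode_preserves_marginals():
    base = generate_survey(GeneratorSpec.default(n=600), seed=17)
    from dataclasses import replace

    hot = generate_survey(replace(GeneratorSpec.default(n=600), spatial_hotspots=True), seed=17)
    for m in base.metals:
        assert sorted(base.frame[m]) == pytest.approx(sorted(hot.frame[m]))
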
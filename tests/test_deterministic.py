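"""Average daily doses and deterministic HI/CR: limits, linearity, oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soilrisk.deterministic import (
    add_dermal,
    add_ingestion,
    add_inhalation,
    assess,
    survey_assess,
)
from soilrisk.exceptions import DomainError
from soilrisk.reference import ExposureProfile
from soilrisk.distributions import DistributionSpec
from soilrisk.synthetic import GeneratorSpec, generate_survey


def _point_profile(**over):
    base = dict(
        R_ing=100, R_inh=14.5, EF=350, ED=24, BW=64.4, AT_nc=8760, AT_ca=8760,
        SA=5700, AF=0.07, ABS=0.001, PEF=1.36e9,
    )
    base.update(over)
    return ExposureProfile(
        "test", {k: DistributionSpec("point", value=v) for k, v in base.items()}
    )


def test_zero_concentration_gives_zero_dose():
    p = _point_profile()
    assert add_ingestion(0.0, p) == 0.0
    assert add_inhalation(0.0, p) == 0.0
    assert add_dermal(0.0, p) == 0.0


@given(st.floats(min_value=1e-3, max_value=1e3), st.floats(min_value=0.1, max_value=10))
def test_doses_linear_in_concentration(c, k):
    p = _point_profile()
    for dose in (add_ingestion, add_inhalation, add_dermal):
        assert dose(k * c, p) == pytest.approx(k * dose(c, p))


def test_inhalation_vanishes_with_pef():
    doses = [add_inhalation(10.0, _point_profile(PEF=pef)) for pef in (1e6, 1e9, 1e12, 1e18)]
    assert doses[0] > doses[1] > doses[2] > doses[3]
    assert doses[3] == pytest.approx(0.0, abs=1e-15)


def test_dermal_scales_with_skin_area():
    assert add_dermal(10.0, _point_profile(SA=2 * 5700)) == pytest.approx(
        2 * add_dermal(10.0, _point_profile())
    )


def test_invalid_parameter_named():
    with pytest.raises(DomainError, match="BW"):
        add_ingestion(1.0, _point_profile(BW=0))
    with pytest.raises(DomainError, match="PEF"):
        add_inhalation(1.0, _point_profile(PEF=-1))


def test_aggregates_are_exact_sums(mean_conc, tables):
    for pop in ("adults", "children"):
        r = assess(mean_conc, tables.profiles[pop], tables.toxicity)
        assert r.thi == pytest.approx(float(r.hi_metal.sum()), rel=1e-14)
        assert r.tcr == pytest.approx(float(r.cr_metal.sum(skipna=True)), rel=1e-14)
        # per-metal HI is the exact sum of its pathway terms
        for m in r.hi.index:
            assert r.hi_metal[m] == pytest.approx(
                float(r.hi.loc[m].sum(skipna=True)), rel=1e-14
            )


def test_missing_toxicity_contributes_zero(mean_conc, tables):
    r = assess(mean_conc, tables.profiles["adults"], tables.toxicity)
    assert np.isnan(r.hi.loc["Hg", "inh"])       # no Hg inhalation RfD
    assert np.isnan(r.cr_metal["Hg"])            # no Hg slope factor at all
    assert r.cr.loc["Cd"].count() == 2           # ing + inh only
    # dropping Hg's contribution changes THI by exactly HI(Hg)
    no_hg = {m: c for m, c in mean_conc.items() if m != "Hg"}
    r2 = assess(no_hg, tables.profiles["adults"], tables.toxicity)
    assert r.thi - r2.thi == pytest.approx(r.hi_metal["Hg"], rel=1e-12)


def test_children_riskier_than_adults(mean_conc, tables):
    """Under the bundled profiles every child HI/CR exceeds the adult one."""
    ra = assess(mean_conc, tables.profiles["adults"], tables.toxicity)
    rc = assess(mean_conc, tables.profiles["children"], tables.toxicity)
    assert (rc.hi_metal > ra.hi_metal).all()
    assert (rc.cr_metal.dropna() > ra.cr_metal.dropna()).all()
    assert rc.thi > ra.thi and rc.tcr > ra.tcr


def test_survey_assess_matches_scalar_oracle(tables):
    """Vectorised per-sample risk equals a plain-Python per-row evaluation."""
    survey = generate_survey(GeneratorSpec.default(n=25), seed=9)
    tox = tables.toxicity
    for pop in ("adults", "children"):
        prof = tables.profiles[pop]
        table = survey_assess(survey, prof, tox).set_index("sample_id")
        p = prof.point_values("nc")
        for row in survey.frame.itertuples():
            thi = 0.0
            for m in survey.metals:
                c = getattr(row, m)
                ing = c * p["R_ing"] * p["EF"] * p["ED"] / (p["BW"] * p["AT"]) * 1e-6
                inh = c * p["R_inh"] * p["EF"] * p["ED"] / (p["PEF"] * p["BW"] * p["AT"])
                der = (
                    c * p["AF"] * p["SA"] * p["ABS"] * p["EF"] * p["ED"]
                    / (p["BW"] * p["AT"]) * 1e-6
                )
                for pathway, dose in (("ing", ing), ("inh", inh), ("dermal", der)):
                    rfd = tox.rfd_for(m, pathway)
                    if rfd is not None:
                        thi += dose / rfd
            assert table.loc[row.sample_id, "THI"] == pytest.approx(thi, rel=1e-12)


def test_flags(mean_conc, tables):
    rc = assess(mean_conc, tables.profiles["children"], tables.toxicity)
    assert not rc.hi_flags.any()                       # all HI < 1 at the mean
    assert rc.cr_flags.loc["Cr", "above_1e-4"]         # child CR(Cr) > 1e-4
    assert not rc.cr_flags.loc["Pb", "above_1e-4"]
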
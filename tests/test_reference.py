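"""Reference tables: pH classes, bundled defaults, overrides, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soilrisk.distributions import DistributionSpec
from soilrisk.exceptions import DomainError, SchemaError
from soilrisk.reference import (
    METALS,
    PH_CLASSES,
    ExposureProfile,
    load_reference_tables,
    ph_class,
)

# GB15618-2018 agricultural-soil screening values by pH class (mg/kg)
SCREENING = {
    "<=5.5": {"As": 30, "Cd": 0.30, "Cr": 250, "Hg": 0.50, "Pb": 80},
    "(5.5,6.5]": {"As": 30, "Cd": 0.4, "Cr": 250, "Hg": 0.50, "Pb": 100},
    "(6.5,7.5]": {"As": 25, "Cd": 0.6, "Cr": 300, "Hg": 0.6, "Pb": 140},
    ">7.5": {"As": 20, "Cd": 0.8, "Cr": 350, "Hg": 1.0, "Pb": 240},
}
BACKGROUND = {"As": 20, "Cd": 0.66, "Cr": 95.9, "Hg": 0.1, "Pb": 35.2}
TOXIC_RESPONSE = {"As": 10, "Cd": 30, "Cr": 2, "Hg": 40, "Pb": 5}


@pytest.mark.parametrize(
    "ph,expected",
    [
        (5.5, "<=5.5"),       # boundary closed on the right
        (0.1, "<=5.5"),
        (6.14, "(5.5,6.5]"),  # the survey-mean pH
        (6.5, "(5.5,6.5]"),
        (7.5, "(6.5,7.5]"),
        (8.06, ">7.5"),       # the survey maximum
        (13.9, ">7.5"),
    ],
)
def test_ph_class_boundaries(ph, expected):
    assert ph_class(ph) == expected


@pytest.mark.parametrize("bad", [0.0, 14.0, -1.0, 15.0])
def test_ph_class_domain(bad):
    with pytest.raises(DomainError):
        ph_class(bad)


@given(st.floats(min_value=1e-6, max_value=13.999999))
def test_ph_class_partitions(ph):
    """Every admissible pH maps to exactly one of the four classes."""
    cls = ph_class(ph)
    assert cls in PH_CLASSES
    lowers = {"<=5.5": 0.0, "(5.5,6.5]": 5.5, "(6.5,7.5]": 6.5, ">7.5": 7.5}
    uppers = {"<=5.5": 5.5, "(5.5,6.5]": 6.5, "(6.5,7.5]": 7.5, ">7.5": 14.0}
    assert lowers[cls] < ph <= uppers[cls] or (cls == "<=5.5" and ph <= 5.5)


def test_ph_class_vectorised():
    out = ph_class(np.array([5.0, 6.0, 7.0, 8.0]))
    assert list(out) == ["<=5.5", "(5.5,6.5]", "(6.5,7.5]", ">7.5"]


def test_bundled_defaults_match_published_values(tables):
    """Self-check of every screening/background/toxic-response default."""
    for cls, row in SCREENING.items():
        for metal, value in row.items():
            assert tables.standards.screening_value(metal, ph_cls=cls) == pytest.approx(value)
    for metal in METALS:
        assert tables.standards.background[metal] == pytest.approx(BACKGROUND[metal])
        assert tables.standards.toxic_response[metal] == pytest.approx(TOXIC_RESPONSE[metal])


def test_screening_lookup_uses_ph(tables):
    assert tables.standards.screening_value("Cd", ph=5.0) == 0.30
    assert tables.standards.screening_value("Cd", ph=7.0) == 0.6
    vals = tables.standards.screening_value("Pb", ph=np.array([5.0, 8.0]))
    assert list(vals) == [80, 240]


def test_toxicity_absence_pattern(tables):
    """Absent cells are absent, not zero: no Hg inhalation/SF, no Cd/Pb dermal SF."""
    tox = tables.toxicity
    assert tox.rfd_for("Hg", "inh") is None
    assert tox.rfd_for("Pb", "inh") is None
    assert all(tox.sf_for("Hg", p) is None for p in ("ing", "inh", "dermal"))
    assert tox.sf_for("Cd", "dermal") is None
    assert tox.sf_for("Pb", "dermal") is None
    assert tox.sf_for("Pb", "inh") is not None
    assert tox.ttd_for("Hg", "hematological") is None  # Hg endpoints lacking
    assert tox.ttd_for("Pb", "renal") > 0


def test_screening_override_and_vocabulary(tmp_path, tables):
    path = tmp_path / "screening.csv"
    rows = ["metal,ph_class,value"]
    for cls, row in SCREENING.items():
        for metal, v in row.items():
            vv = 0.5 if (metal, cls) == ("Cd", "<=5.5") else v
            rows.append(f'{metal},"{cls}",{vv}')
    path.write_text("\n".join(rows))
    t = load_reference_tables(screening=path)
    assert t.standards.screening_value("Cd", ph_cls="<=5.5") == 0.5

    bad = tmp_path / "bad.csv"
    bad.write_text('metal,ph_class,value\nUnobtainium,"<=5.5",1\n')
    with pytest.raises(SchemaError, match="As"):
        load_reference_tables(screening=bad)


def test_profile_validation():
    with pytest.raises(SchemaError, match="BW"):
        ExposureProfile("x", {"R_ing": DistributionSpec("point", value=100)}).validate()


def test_profile_point_values_resolve_averaging(tables):
    prof = tables.profiles["adults"]
    nc = prof.point_values("nc")
    ca = prof.point_values("ca")
    assert "AT" in nc and "AT_nc" not in nc
    assert nc["AT"] > 0 and ca["AT"] > 0
    with pytest.raises(DomainError):
        prof.point_values("lifetime")


def test_classification_boundaries(tables):
    assert tables.classify("pi", 1.0) == "unpolluted"   # boundary to lower band
    assert tables.classify("pi", 1.01) == "mild"
    assert tables.classify("nemerow", 1.77) == "light"
    assert tables.classify("ri", 79.9) == "low"
    with pytest.raises(SchemaError):
        tables.classify("nope", 1.0)


def test_classification_monotone(tables):
    """Larger index values never map to a lower band."""
    for index in ("pi", "er", "ri", "nemerow", "igeo"):
        bands = tables.bands[index]
        order = {label: i for i, (_, label) in enumerate(bands)}
        grid = np.linspace(-2.0 if index == "igeo" else 0.01, 400.0, 500)
        labels = [order[tables.classify(index, v)] for v in grid]
        assert labels == sorted(labels)
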
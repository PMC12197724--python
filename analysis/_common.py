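"""Shared bits for the analysis drivers: paths, seed, survey loading."""

from pathlib import Path

from soilrisk.surveys import read_survey, write_survey
from soilrisk.synthetic import GeneratorSpec, generate_survey

SEED = 20170740
OUT = Path(__file__).resolve().parents[1] / "results"

# Survey-mean concentrations (mg/kg) of the reference survey, used where the
# deterministic assessment is run at the mean.
MEAN_CONC = {"As": 9.08, "Cd": 0.36, "Cr": 73.06, "Hg": 0.13, "Pb": 28.14}


def load_or_generate():
    path = OUT / "survey.csv"
    if path.exists():
        return read_survey(path)
    survey = generate_survey(GeneratorSpec.default(), seed=SEED)
    write_survey(survey, path)
    return survey
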
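#!/usr/bin/env python
"""Pollution indices over the synthetic survey: PI, Nemerow P_N, Igeo,
exceedance rates against screening and background values.

Reads results/survey.csv (run 01 first; regenerated here if absent).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import OUT, load_or_generate

from soilrisk.pollution import survey_pollution
from soilrisk.reference import load_reference_tables


def main():
    survey = load_or_generate()
    tables = load_reference_tables()
    res = survey_pollution(survey, tables)

    res.per_sample.to_csv(OUT / "pollution_per_sample.csv", index=False)
    res.summary.to_csv(OUT / "pollution_summary.csv")
    res.exceedance_screening.to_csv(OUT / "exceedance_screening.csv")
    res.exceedance_background.to_csv(OUT / "exceedance_background.csv")

    print("Summary statistics (mg/kg):\n")
    print(res.summary.round(3).to_string())
    print("\nExceedance vs background values (%):")
    print(res.exceedance_background.round(2).to_string())
    print("\nExceedance vs pH-class screening values (%):")
    print(res.exceedance_screening.round(2).to_string())
    print(
        f"\nSurvey-level Nemerow index P_N = {res.survey_nemerow:.3f} "
        f"({res.survey_nemerow_label}); per-sample median P_N = {res.nemerow.median():.3f}."
    )
    print("Mean Igeo per metal:", dict(res.mean_igeo.round(3)))


if __name__ == "__main__":
    sys.exit(main())
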
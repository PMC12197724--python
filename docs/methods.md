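# Methods

## Scope and data model

The package assesses heavy-metal contamination of agricultural topsoil and
the resulting human health risk for five metals (As, Cd, Cr, Hg, Pb). A
survey is a table of composite samples with pH and dry-weight concentrations
in mg/kg; regions and coordinates are carried as metadata only (no
geostatistics — kriging/interpolation mapping is out of scope).

## Reference tables and their provenance

All constants live in editable data files under `soilrisk/data`, never in
the formulas:

- **Screening values** (`screening.csv`): GB15618-2018 agricultural-soil risk
  screening values by metal and pH class. The four classes are right-closed
  (`pH ≤ 5.5`, `5.5 < pH ≤ 6.5`, `6.5 < pH ≤ 7.5`, `pH > 7.5`); pH 5.5
  belongs to the most acidic class.
- **Background values** (`background.csv`): Guizhou soil geochemical
  backgrounds (CNEMC).
- **Exposure parameters** (`exposure_parameters.csv`): point values and
  sampling distributions per population. The defaults follow the USEPA
  exposure-factor conventions used throughout the Chinese soil-risk
  literature: soil ingestion 100/200 mg d⁻¹ (adults/children), inhalation
  14.5/7.5 m³ d⁻¹, exposure frequency 350 d yr⁻¹, duration 24/6 yr, body
  weight 64.4/19.2 kg, skin area 5700/2800 cm², adherence 0.07/0.2
  mg cm⁻² d⁻¹, dermal absorption 0.001, particle emission factor
  1.36 × 10⁹ m³ kg⁻¹.
- **Toxicity** (`toxicity.csv`): chronic reference doses and slope factors by
  pathway. Absent cells are genuinely absent — Hg has no inhalation RfD and
  no slope factor, Pb no inhalation RfD, Cd/Pb no dermal slope factor — and
  absent pathways contribute exactly zero (logged once per run), never a
  silent zero in a denominator.
- **TTD endpoints** (`ttd_endpoints_synthetic.csv`): organ-specific toxicity
  doses for As, Cd, Cr and Pb over five organ systems (neurological, renal,
  cardiovascular, hematological, testicular). Published organ-endpoint
  compilations disagree and Hg lacks usable endpoints altogether, so this
  table is a synthetic stand-in: the organ attributions follow the
  toxicological consensus (As drives neurological and cardiovascular hazard,
  Pb renal, Cr hematological and testicular) and the magnitudes are
  calibrated so that the bundled defaults reproduce published multi-organ
  hazard aggregates for this mixture. Users with their own endpoint
  compilation should override the file.

## Averaging time

Both averaging times ship in the exposure table and both equal ED × 365 d:
the carcinogenic dose is averaged over the exposure duration, not over a
70-year lifetime. This is deliberate — it is the convention the reference
risk figures embed (their carcinogenic and non-carcinogenic doses coincide),
and it is conservative. Analysts preferring the lifetime convention only
need to edit `AT_ca` in the exposure table; the `averaging` argument of the
dose functions already separates the two modes.

## Pollution and ecological indices

`PI`, `P_N` and `Igeo` are computed per sample; the Nemerow index is also
reported at survey level (per-metal mean PIs fed through the same formula),
since the two aggregations answer different questions and neither dominates
in practice. Exceedance rates are reported both against the pH-class
screening values (per class and total) and against the background values.
Classification bands for every index live in `classification_bands.yaml`;
boundary values fall to the lower band, matching the printed inequalities.

The ecological-risk denominator defaults to the screening value, exactly as
the governing equation `Er = T·C/S` is stated in the index's modern
soil-survey usage; classical Hakanson practice divides by background, and a
`denominator="background"` switch provides it. Standard deviations use the
sample (n−1) convention.

## Monte Carlo engine

Each uncertain input is a `DistributionSpec` (point, normal, lognormal,
uniform, triangular; optional hard truncation). Sampling is inverse-CDF on a
uniform restricted to the truncation interval, so truncation is exact and
seed determinism is bit-for-bit. Defaults: 10,000 iterations, seed 20170740.

Parameter distributions were chosen mean-preserving, since nothing in the
deterministic parameterisation justifies shifting central tendencies:
symmetric truncated normals (CV 10–20%, bounds at ±3 SD) on the ingestion
and inhalation rates, body weight and skin area; uniform(335, 365) on
exposure frequency; points for duration, adherence, absorption and the
emission factor. Concentrations default to truncated lognormals
moment-matched to the survey summary (below); bootstrap resampling of an
actual survey (preserving inter-metal correlation) and point concentrations
are the alternatives. Parameters are drawn independently — no correlation
structure is imposed — and exceedance probabilities use strict inequality
(boundary mass is negligible at 10⁴ draws).

Degenerate point-mass specs reproduce the deterministic results to machine
precision because both paths share one implementation of the dose formulas.

## Synthetic survey generator

The generator emulates the statistical structure the analysis assumes,
calibrated to the published summary of a 740-sample provincial campaign
(`survey_calibration.csv`):

- **Concentrations**: truncated lognormals on the published [min, max],
  with the underlying (μ, σ) solved so the *post-truncation* mean and SD
  equal the published ones (closed-form truncated-lognormal moments +
  least squares). Lognormality is the natural choice for strictly positive,
  right-skewed soil concentrations with CVs of 29–59%. Notably, the fitted
  laws reproduce the published background-exceedance rates (e.g. Hg ~62%,
  Cr ~21%) without those rates entering the calibration — evidence the
  marginal model is apt.
- **pH**: truncated normal, parent mean 6.14 and SD 0.96 on [3.84, 8.06].
- **pH–Cd dependence**: a Gaussian copula couples Cd to pH with rank
  correlation −0.3 (direction from the observed acid-soil Cd enrichment;
  the magnitude is a documented free knob). Combined with the pH-dependent
  screening values this yields the strongly decreasing Cd exceedance
  gradient across pH classes that real calcareous-terrain surveys show.
- **Regions**: prefecture labels assigned by largest-remainder apportionment
  of the campaign's design weights (which sum to 739 for the nominal 740
  samples; the apportionment absorbs the off-by-one). Coordinates are
  uniform on the unit square; an optional hotspot mode reorders samples so
  high concentrations cluster at two smooth intensity bumps without touching
  any marginal distribution.

`fit_generator` inverts the construction (observed moments → spec) so
generate → fit → generate is a fixed point up to sampling error; observed
moments that no truncated family can attain (possible in adversarial data)
fall back to untruncated fits with a warning. What the generator does *not*
emulate: real spatial autocorrelation, inter-metal correlation beyond the
pH–Cd pair, measurement error, and region-specific means — conclusions
about those features cannot be drawn from synthetic runs.

## TTD hazard

Only the ingestion pathway feeds the TTD method by default (it carries ~90%
of the non-carcinogenic dose); a `pathways` argument can add the others.
Hazard quotients `ADD_ing/TTD(metal, organ)` are summed both per metal and
per organ; the two marginal totals agree exactly by construction and the
package asserts it. With the bundled endpoints the multi-organ totals exceed
the single-endpoint THI by a factor ≈2.7–2.8, and each metal's cumulative
multi-organ hazard is at least its ingestion HI (every endpoint dose is at
most the chronic RfD).

## Numerical conventions

- Full precision is carried everywhere; reports render 3 significant
  figures in scientific notation. Comparisons against 3-s.f. published
  values use 2% relative tolerance (deterministic) or 3 standard errors
  (Monte Carlo means).
- Aggregates (THI, TCR, RI, THI_TTD) are exact sums of their parts; the
  machine-readable JSON and the CSVs serialise the same objects.
- Problem sizes: tests run the generator at n = 740 (the survey's own size)
  and n = 10⁵ for convergence checks, and the Monte Carlo engine at 10⁴
  draws, matching the study design.

## Known limitations

- No bioavailability adjustment: total concentrations drive all doses,
  which overestimates absorbed dose.
- No sensitivity analysis (Sobol/rank-correlation tornado); the Monte Carlo
  result quantifies output variability, not driver attribution.
- No source apportionment, no spatial interpolation.
- Published per-sample exceedance statistics (e.g. Monte Carlo exceedance
  probabilities, survey-level Nemerow index of the real data) depend on the
  unpublished per-sample joint distribution; the synthetic survey reproduces
  them qualitatively (direction and order of magnitude), not exactly.
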
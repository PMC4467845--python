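# seadose

Dietary radiological dose and heavy-metal intake assessment from seafood
surveys.

Coastal populations that rely on marine fish ingest the naturally
occurring radionuclides (²²⁶Ra, ²³²Th via its ²²⁸Ra progeny, and ⁴⁰K)
and trace metals that fish accumulate from their environment.  `seadose`
implements the complete measurement-to-risk chain used in environmental
radioactivity surveys of foodstuff:

1. **Gamma-spectrometry quantification.**  Activity concentrations are
   measured through the strong, independent gamma lines of short-lived
   progeny, which under secular equilibrium carry the parent activity:
   *A = N / (t · ε(E) · P<sub>γ</sub> · b · m)* with net peak area *N*,
   live time *t*, full-energy-peak efficiency *ε* (polynomial fit in
   ln ε vs ln E), emission intensity *P<sub>γ</sub>*, branching factor
   *b* and dry sample mass *m*.  Per-line estimates are pooled by
   inverse-variance weighting; detection capability follows the Currie
   criterion, MDA = (2.71 + 4.65 √B)/(t ε P<sub>γ</sub> m); uncertainties
   combine counting statistics, efficiency (4%), mass (1.5%) and
   intensity (1%) in quadrature.
2. **Intake, dose and risk.**  Per sample and nuclide:
   daily intake *D*<sub>int</sub> = *A*<sub>s</sub>·*A*<sub>if</sub>/365 (Bq/d, equivalently
   *A*<sub>s</sub>·*A*<sub>p</sub>·*F*<sub>c</sub>/(*M*<sub>p</sub>·365) from production statistics),
   committed effective dose *D*<sub>eff</sub> = *A*<sub>s</sub>·*A*<sub>if</sub>·*D*<sub>cf</sub> (µSv/y),
   total dose as the sum over nuclides, and lifetime cancer risk
   LCR = *D*<sub>int</sub>·365·*A*<sub>ls</sub>·*R*<sub>c</sub> with USEPA mortality risk
   coefficients and a 70 y lifespan.
3. **Metal screening.**  Estimated daily intake
   EDI = *C*<sub>metal</sub>·*W*/*m* (µg per kg body weight per day, 130 g fish
   per day, 70 kg adult) from location-mean concentrations with
   non-detects excluded, screened against a tolerable-daily-intake (TDI)
   registry.
4. **Group statistics.**  One-way ANOVA from explicit sums of squares
   and Tukey HSD with an embedded studentized-range table, for
   location-effect significance.

The package ships the activity and trace-element tables of a
three-site Indian mackerel (*Rastrelliger kanagurta*) survey of the
Straits of Malacca as its bundled example dataset, together with the
matching exposure defaults for Peninsular Malaysia (1,472,240 short
tons landed per year, 19.15 million adults, 68% consumed fraction,
47.4 kg/y per-capita fish intake).  A synthetic-data module emulates
the survey design (3 locations × 3 replicates, fish + water, Poisson
peak counts, censored metal tables) so every stage is testable without
external data.

## Worked example

```python
from seadose import default_bundle, dose_risk_report
from seadose.datasets import load_malacca_activity

bundle = default_bundle()
report = dose_risk_report(load_malacca_activity(), bundle)
print(report[["sample_code", "daily_intake_Ra-226",
              "effective_dose_Ra-226", "total_effective_dose",
              "lcr_Ra-226"]].head(3).round(4).to_string(index=False))
```

```
sample_code  daily_intake_Ra-226  effective_dose_Ra-226  total_effective_dose  lcr_Ra-226
    Fi_Bl-1               1.0116               103.3889              283.3629      0.0002
    Fi_Bl-2               1.0597               108.2995              286.3775      0.0003
    Fi_Bl-3               0.9792               100.0709              261.7286      0.0002
```

Sample Fi_Bl-1 (Bagan Lalang, 7.79 Bq/kg ²²⁶Ra) yields a daily ²²⁶Ra
intake of 1.01 Bq, an annual committed dose of 103.4 µSv from ²²⁶Ra and
283.4 µSv in total, with a ²²⁶Ra lifetime cancer risk of 2.5 × 10⁻⁴.
The report also carries location-mean and overall-mean rows; the
overall mean total dose of 226.8 µSv/y sits below the 290 µSv/y
worldwide average ingestion dose, and every metal EDI screens below its
TDI (see `examples/metals_screening.py`).

Each script in `examples/` is a short narrative of one capability:
dose/risk from the bundled survey, metal screening, gamma-peak
quantification, location significance testing, and an end-to-end
synthetic survey.

A thin CLI mirrors the stages:

```sh
seadose simulate --seed 1 --out-dir scratch/
seadose dose scratch/activity.csv --out scratch/dose.csv
seadose metals scratch/metals.csv --out scratch/edi.csv
```

Reference data (gamma lines, dose/risk coefficients, TDIs, exposure
parameters) are overridable key-by-key from a YAML/JSON config file via
`load_reference_bundle`; units are carried in key names
(e.g. `exposure: {lifespan_y: 80}`).

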
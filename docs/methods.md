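# Methods

## Model and assumptions

`seadose` models one exposure pathway: ingestion of radionuclides and
trace metals through consumption of marine fish.  The computation is a
deterministic chain from measured concentrations to population-level
intake, dose and risk figures:

* **Secular equilibrium.**  ²²⁶Ra and ²³²Th (via ²²⁸Ra) cannot be
  quantified directly by gamma spectrometry at environmental levels;
  their short-lived progeny (²¹⁴Pb, ²¹⁴Bi; ²¹²Pb, ²⁰⁸Tl, ²²⁸Ac) are
  assumed in secular equilibrium with the parent after 6–8 weeks of
  sealed storage, so each progeny line yields an independent estimate
  of the parent activity.  ⁴⁰K is measured directly at 1460.8 keV.
* **Dry-weight basis.**  All concentrations are per kg of dried sample;
  no wet-weight conversion is applied anywhere.
* **Single adult reference receptor.**  One population-average intake,
  70 kg body mass, 70 y lifespan; no age stratification and no
  age-specific dose coefficients.
* **Fish pathway only.**  Water activities are carried through reports
  for context but never enter the dose/risk equations; there are no
  external, inhalation or radon pathways.

## Equations

Per sample and parent chain, with activity concentration $A_s$ (Bq/kg):

$$D_{int} = A_s \cdot A_{if} / 365 \quad\text{[Bq/d]}$$
$$D_{eff} = A_s \cdot A_{if} \cdot D_{cf} \cdot 10^6 \quad[\mu\text{Sv/y}]$$
$$D_{eff}^{total} = \sum_{chains} D_{eff}$$
$$LCR = (D_{int}\cdot 365) \cdot A_{ls} \cdot R_c$$

and for each metal, from the location-mean concentration $C$ (mg/kg):

$$EDI = C \cdot W / m \quad[\mu\text{g kg}^{-1}\text{bw d}^{-1}]$$

The annual radionuclide intake in the risk equation is exactly
$D_{int}\cdot 365 = A_s\cdot A_{if}$, making intake, dose and risk
mutually consistent by construction (an identity the tests verify on
random inputs).

## Parameters, units, defaults

| parameter | symbol | default | unit | note |
|---|---|---|---|---|
| annual fish production | $A_p$ | 1,472,240 | short tons/y | Peninsular Malaysia, 2012 |
| short-ton conversion | — | 907.188 | kg | stored explicitly, overridable |
| consumed fraction | $F_c$ | 0.68 | — | 32% wastage/export |
| adult population | $M_p$ | 19.15 × 10⁶ | persons | intake divisor for the whole pipeline |
| per-capita fish intake | $A_{if}$ | 47.4 | kg/y | see note below |
| daily fish consumption | $W$ | 130 | g/d | metal intake only |
| adult body mass | $m$ | 70 | kg | |
| reference lifespan | $A_{ls}$ | 70 | y | |
| dose coefficients | $D_{cf}$ | 2.8e-7 / 2.3e-7 / 6.2e-9 | Sv/Bq | Ra-226 / Th-232 / K-40 |
| risk coefficients | $R_c$ | 9.56e-9 / 2.45e-9 / 5.89e-10 | per Bq | USEPA mortality |
| TDIs | — | As 2.14, Hg 0.57, Pb 3.60, Al 143, Cr 143, Mn 157, Co 20, Cu 142 | µg/kg bw/d | |

**The 47.4 kg/y convention.**  Deriving the per-capita intake from the
production figures gives 47.43 kg/y; the published assessment worked
with the rounded 3-significant-figure value 47.4 and used it in every
downstream equation.  The default parameter set therefore carries 47.4
explicitly (so the reference dose and risk tables reproduce to their
printed precision), and daily intake is computed as
$A_s\cdot A_{if}/365$ — numerically identical to the production-based
form when $A_{if}$ is derived.  Setting `per_capita_intake_kg_y=None`
switches to the exact derived value; doses then shift in their last
printed digit (≤0.07%).

**Total dose.**  A literal reading of the total-dose formula would
multiply the summed per-chain doses by $(A_{if}\cdot F_c)$ a second
time; since $A_{if}$ already contains $F_c$ through the production
identity and the reference table totals equal the plain sum of the
per-chain doses, the implementation sums without reapplying $F_c$.

## Spectrometry numerics

* **Efficiency curve:** least-squares polynomial of ln ε against ln E,
  default order 4 (configurable); evaluation outside the calibration
  range raises unless extrapolation is explicitly allowed; the RMS
  ln-space residual is reported.
* **Quantification lines:** only the strong, independent ("primary")
  lines are used by default — 351.9/609.3 keV for the ²²⁶Ra chain,
  238.6/583.2/911.2 keV for the ²³²Th chain, 1460.8 keV for ⁴⁰K.
* **Branching:** the 583.2 keV ²⁰⁸Tl intensity is treated as photons
  per parent decay (branching factor 1), matching the tabulated
  intensities as used for quantification.  Users wanting
  chain-consistent treatment can enable the ²¹²Bi→²⁰⁸Tl branch
  (0.3594) via `default_gamma_lines(tl208_chain_branching=True)` or the
  `options` config section; whether tabulated intensities should be
  branch-corrected is genuinely ambiguous, so it is configurable rather
  than guessed.
* **Pooling:** inverse-variance weighted mean across lines (the
  standard rule for independent estimates of one value); an unweighted
  mean is available when uncertainties are absent.  The pooled value is
  always bounded by the input values and its uncertainty never exceeds
  the smallest input uncertainty (property-tested).
* **MDA:** Currie's 95%-confidence expression
  (2.71 + 4.65√B)/(t·ε·P_γ·b·m); the chain-level MDA is the best
  (smallest) line-level MDA among contributing lines.  `below_mda`
  flags values under the detection limit; they still enter means, with
  a warning.
* **Uncertainty budget:** quadrature of counting statistics (per
  peak), efficiency 4%, mass 1.5%, intensity 1% — totals span 4.4% (at
  0.5% counting) to 10.9% (at 10% counting).  Each component is
  overridable; whether real surveys include further components is why
  the budget is configurable.

## Statistics

ANOVA is computed from the defining sums of squares (no model-matrix
machinery), with the p-value from the F upper tail.  Tukey HSD uses
the studentized-range quantile $q(\alpha;k,\nu)$ from an embedded table
(α ∈ {0.05, 0.01}, k ≤ 10, ν from 2 to 120 plus the asymptote,
interpolated linearly in 1/ν — accurate to a few parts in 10³, which
tests verify against `scipy.stats.studentized_range`), applied to
$\sqrt{MS_{within}/n_h}$ with harmonic mean group size $n_h$
(Tukey–Kramer), so unbalanced designs are handled.  Degenerate inputs
(one group, a group with fewer than two values, all values identical)
raise rather than return an undefined F.

## Non-detects

Metal non-detects are excluded from location means by default — the
only rule that reproduces the reference averages (e.g. Cr at a site
with one detect and one non-detect).  Zero-substitution and half-LOD
substitution (default LOD 0.0002 mg/kg, the ICP-MS limit for most
elements) are exposed as options.  An element with no detected
replicate at a location yields no EDI row.  The EDI is computed from
the unrounded location mean, not a displayed 4-significant-figure
average — required to match the reference values in the fourth decimal.
A location/element EDI equal to its TDI is classified `below_tdi` (the
boundary is inclusive).

## Printed-table comparisons and aggregation

Published tables round half-up at display precision, and their summary
rows average the displayed (rounded) entries rather than the unrounded
values.  `aggregate(..., display_rounding=True)` mirrors that
convention; comparisons in the test suite accept a value when half-up
rounding at the printed precision reproduces the printed cell, with a
0.5% relative fallback.  Default aggregation is plain arithmetic means
of unrounded values (uncertainty columns averaged the same way, as in
the reference tables).

## Synthetic data

The generator emulates the survey design, not the physics of a full
spectrum: 3 locations × 3 replicates × (fish + water), per-peak Poisson
counts for the six primary lines (no channel-level spectrum synthesis,
peak search, coincidence summing or self-absorption), and a censored
metal table.  Choices:

* **Lognormal replicate noise** (default 10% relative dispersion):
  activities are positive and right-skewed; the lognormal is
  parameterised so its mean equals the location truth exactly, and a
  truncated-normal option exists.  Zero dispersion returns the truths
  identically, which is what ties the synthetic pipeline to the
  reference tables in the end-to-end test.
* **Detector model:** ln-ln efficiency (0.8856, −0.7) — about 4% at
  352 keV falling as E^−0.7 — 86,400 s live time, sample masses uniform
  in 0.120–0.218 kg, and an expected under-peak continuum of 2,000
  counts per line; background and gross counts are independent Poisson
  draws of equal duration and the net area is their difference, floored
  at zero.
* **Counting-statistics model** for assigned uncertainties:
  0.15/√A clipped to 0.5–10%, so high-activity ⁴⁰K gets sub-percent
  counting errors and trace-level water activities saturate at 10%,
  reproducing the 4.4–10.9% combined range.
* **Metal profiles** are centred on the survey-wide element means with
  detect probabilities reflecting the observed censoring (Hg and Pb
  mostly non-detect).
* **Seeding:** one scenario seed feeds fixed per-purpose child streams
  (activity/peaks/metals), so regenerating one table never perturbs
  another.

What passing synthetic tests do **not** show: real spectra have
interfering lines, summing and matrix effects; real replicate scatter
is not exactly lognormal; real censoring is threshold-driven, not
Bernoulli.  The synthetic path validates the computational chain, not
the measurement physics.

## Problem sizes in the test suite

The property-based checks run at desk scale chosen to give stable
verdicts: 1,000 seeded single-sample round trips for 3σ recovery
coverage (binomial SE ≪ the 1% margin), 100 random datasets for the
ANOVA oracle, 500 seeded scenarios for location-mean recovery.  The
recovery check measures distance in units of the *known* generative
standard error (dispersion·truth/√n); with three replicates an
*estimated* SE would make the deviation t₂-distributed, whose 3-SE
coverage is only ≈90% — a property of Student's t, not of the
pipeline.

## Known limitations

* No spectrum processing: inputs begin at net peak areas.
* No decay-chain database beyond the bundled lines; unknown nuclides in
  input tables are rejected rather than approximated.
* The studentized-range table covers α ∈ {0.05, 0.01} and k ≤ 10 only.
* Risk coefficients are linear no-threshold mortality coefficients; no
  morbidity risk, no dose-rate effectiveness adjustment.
* The metals module computes intake screening only — no target hazard
  quotients or carcinogenic slope factors, and no nutritional-adequacy
  assessment of essential elements.
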
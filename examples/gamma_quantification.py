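"""Gamma-peak areas to activity concentrations.

Simulates a day-long HPGe count of one fish sample (Poisson peak counts
for the six strong progeny lines), then runs the quantification chain:
efficiency curve -> per-line activity with a quadrature uncertainty
budget -> inverse-variance pooling per parent chain -> Currie MDA
screening.  Under secular equilibrium the progeny lines measure the
Ra-226, Th-232 and K-40 parents directly.
"""

from seadose import LocationTruth, ScenarioConfig, generate_peak_table, quantify_sample

site = LocationTruth(
    "Demo site", "De",
    fish_bq_per_kg={"Ra-226": 7.8, "Th-232": 6.2, "K-40": 360.0},
    water_bq_per_kg={"Ra-226": 1.0, "Th-232": 0.3, "K-40": 16.0},
)
config = ScenarioConfig(
    seed=7, locations=(site,), replicates_per_location=1, replicate_dispersion=0.0
)
peaks, truth = generate_peak_table(config, return_truth=True)
curve = config.detector.efficiency_curve()

print("line                      net counts   activity (Bq/kg)")
for p in peaks:
    from seadose import line_activity

    value, unc = line_activity(p, curve)
    label = f"{p.line.progeny_nuclide} @ {p.line.energy_kev:.1f} keV"
    print(f"{label:<26}{p.net_counts:>10.0f}   {value:8.2f} +/- {unc:.2f}")

print()
activities = quantify_sample(peaks, curve)
for chain, meas in activities.items():
    t = truth["Fi_De-1"][chain]
    print(
        f"{chain:>7}: {meas.value:8.2f} +/- {meas.uncertainty:5.2f} Bq/kg "
        f"(true {t:7.2f}, MDA {meas.mda:.3f}, lines: {len(meas.contributing_lines)})"
    )
print()
print("Pooled values agree with the simulated truth within their combined")
print("uncertainties; the MDA column is the Currie 95% detection limit.")
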
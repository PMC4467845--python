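"""End-to-end pipeline on a fully synthetic survey.

Generates a 3-site x 3-replicate survey (activities with 10% replicate
dispersion plus a metal table with non-detects), runs the complete
measurement-to-risk pipeline and prints the assembled report summary.
"""

from seadose import ScenarioConfig, default_bundle, generate_activity_dataset, generate_metal_dataset
from seadose.io import run_pipeline

config = ScenarioConfig(seed=2024)
bundle = default_bundle()
records = generate_activity_dataset(config)
metals = generate_metal_dataset(config)
report = run_pipeline(records, metals, bundle, seed=config.seed)

summary = report.dose_risk[report.dose_risk.sample_code.str.startswith("Mean")]
print(summary.round(2).to_string(index=False))
print()
print("Statistics (location effect per nuclide):")
for chain, entry in report.statistics.items():
    print(f"  {chain}: p = {entry['p_value']:.3g}, significant = {entry['significant']}")
print(f"Warnings: {len(report.warnings)}")
print()
print("Because the synthetic truths are centred on the bundled survey's")
print("location means, the simulated summary rows land close to the real")
print("survey's dose table; dispersion and seeds control the scatter.")
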
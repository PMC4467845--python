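"""Dose and risk from the bundled Straits of Malacca fish survey.

Loads the bundled activity concentrations (Bq/kg dry weight) of Ra-226,
Th-232 and K-40 in Indian mackerel from three landing sites, and runs
the intake -> committed effective dose -> lifetime cancer risk chain
with the default Malaysian exposure parameters (47.4 kg fish per person
per year, 70 y lifespan).
"""

import pandas as pd

from seadose import default_bundle, dose_risk_report
from seadose.datasets import load_malacca_activity

pd.set_option("display.width", 200)
pd.set_option("display.max_columns", 99)

bundle = default_bundle()
records = load_malacca_activity()
report = dose_risk_report(records, bundle)

print(report.round(4).to_string(index=False))
print()
overall = report[report.sample_code == "Over all mean"].iloc[0]
print(f"Mean total committed effective dose: {overall.total_effective_dose:.1f} uSv/y")
print("Each row gives, per nuclide, the daily activity intake (Bq/d), the")
print("annual committed effective dose (uSv/y) and the lifetime cancer risk;")
print("'total' sums the three per-nuclide doses.  The overall mean sits well")
print("below the 290 uSv/y worldwide average ingestion dose.")
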
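"""Bundled survey dataset.

Activity concentrations (Bq/kg dry weight) of Ra-226, Th-232 and K-40 in
Indian mackerel (Rastrelliger kanagurta) and surface seawater from three
landing sites on the Straits of Malacca (Bagan Lalang, Port Klang,
Pantai Remis; three replicates each), and the matching trace-element
concentration table (mg/kg dry weight, ICP-MS) with non-detects.  These
are the inputs on which the default exposure scenario was assessed and
serve as the package's worked example.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dose import SampleRecord
from .io import read_activity_table, read_metal_table
from .metals import MetalRecord

__all__ = [
    "load_malacca_activity",
    "load_malacca_metals",
    "malacca_activity_frame",
    "malacca_metals_frame",
]

#: Heavy metals screened against tolerable daily intakes.
SCREENED_ELEMENTS = ("Al", "Cr", "Mn", "Co", "Cu", "As", "Hg", "Pb")


def _data_path(name: str):
    return resources.files("seadose") / "data" / name


def load_malacca_activity() -> list[SampleRecord]:
    """Fish and water activity records of the Straits of Malacca survey."""
    with resources.as_file(_data_path("malacca_activity.csv")) as path:
        return read_activity_table(path)


def load_malacca_metals() -> list[MetalRecord]:
    """Trace-element records of the Straits of Malacca survey."""
    with resources.as_file(_data_path("malacca_metals.csv")) as path:
        return read_metal_table(path)


def malacca_activity_frame() -> pd.DataFrame:
    with resources.as_file(_data_path("malacca_activity.csv")) as path:
        return pd.read_csv(path)


def malacca_metals_frame() -> pd.DataFrame:
    with resources.as_file(_data_path("malacca_metals.csv")) as path:
        return pd.read_csv(path)
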
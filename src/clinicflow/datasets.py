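"""Bundled reference tables from the original clinic study.

These are the study's published measurement tables, shipped as plain CSV:

- ``reference_decomposed_waits()`` — per-server waiting times (minutes)
  split into before/after-attendance components, one column per scenario.
  Note: in the published tables scenario 2's senior-staff total appears
  once as 64.17 and once as 46.17; only 64.17 is consistent with the
  published weighted mean (49.83), so 64.17 is carried here.
- ``reference_weighted_means()`` — the published 2:2:1 weighted mean per
  scenario column.
- ``observed_station_waits()`` — observed per-station mean/SD of waits
  from the clinic checklist (the per-station sample sizes were not
  published; ``n`` carries the overall checklist size of 375).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "reference_decomposed_waits",
    "reference_weighted_means",
    "observed_station_waits",
]


def _path(name: str) -> Path:
    return Path(resources.files("clinicflow").joinpath("data", name))


def reference_decomposed_waits() -> pd.DataFrame:
    return pd.read_csv(_path("reference_decomposed_waits.csv"))


def reference_weighted_means() -> pd.DataFrame:
    return pd.read_csv(_path("reference_weighted_means.csv"))


def observed_station_waits() -> pd.DataFrame:
    return pd.read_csv(_path("observed_station_waits.csv"))
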
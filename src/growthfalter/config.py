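"""Analysis conventions shared by every pipeline stage.

All ages are handled in days internally; a "month" is the WHO convention of
30.4167 days. Measurements taken in the first week of life are analysed as
birth ("month 0") measurements, and monthly-grid ages accept measurements
within a two-week window.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

#: Days per month used throughout (WHO convention).
MONTH_DAYS: float = 30.4167


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable conventions for age handling and plausibility filtering.

    Parameters
    ----------
    month_days:
        Length of one month in days.
    birth_window_days:
        Measurements at or below this age are treated as birth measurements.
    grid_window_days:
        Half-width of the window around each monthly target age within which
        a measurement may populate that month of the grid.
    laz_bound:
        Plausibility bound: measurements with ``|LAZ| > laz_bound`` are
        excluded (the boundary itself is kept).
    """

    month_days: float = MONTH_DAYS
    birth_window_days: float = 7.0
    grid_window_days: float = 14.0
    laz_bound: float = 6.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = AnalysisConfig()
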
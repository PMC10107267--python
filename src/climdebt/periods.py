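"""Five-year period definitions for the 1990-2019 study span."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PeriodDef:
    """One 5-year aggregation period.

    ``median_year`` (start + 2) is the time coordinate used by every
    regression against time.
    """

    index: int
    start_year: int
    end_year: int

    @property
    def median_year(self) -> float:
        return self.start_year + (self.end_year - self.start_year) / 2.0

    def contains(self, year) -> bool:
        return (self.start_year <= year) & (year <= self.end_year)


def make_periods(start: int = 1990, n_periods: int = 6, length: int = 5) -> list[PeriodDef]:
    """Consecutive non-overlapping periods; defaults cover 1990-2019 in six."""
    return [PeriodDef(i, start + i * length, start + (i + 1) * length - 1)
            for i in range(n_periods)]


def median_years(periods: list[PeriodDef]) -> np.ndarray:
    return np.array([p.median_year for p in periods], dtype=float)


def period_of_year(year, periods: list[PeriodDef]):
    """Period index for each year; raises if any year falls outside all periods."""
    year = np.asarray(year)
    start = periods[0].start_year
    length = periods[0].end_year - periods[0].start_year + 1
    idx = (year - start) // length
    if np.any((idx < 0) | (idx >= len(periods))):
        bad = year[(idx < 0) | (idx >= len(periods))]
        raise ValueError(f"year(s) outside all periods: {np.unique(bad)[:5]}")
    return idx.astype(int)
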
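"""Century-month code (CMC) helpers.

All dates in the package are integer century-month codes — months since
January 1900, the DHS convention: ``cmc = (year - 1900) * 12 + month``
with ``month`` in 1..12, so January 2000 is 1201.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cmc", "cmc_year", "cmc_month", "month_range"]


def cmc(year, month):
    """Century-month code for a calendar (year, month in 1..12)."""
    return (np.asarray(year) - 1900) * 12 + np.asarray(month)


def cmc_year(code):
    """Calendar year of a century-month code."""
    return 1900 + (np.asarray(code) - 1) // 12


def cmc_month(code):
    """Calendar month (1..12) of a century-month code."""
    return (np.asarray(code) - 1) % 12 + 1


def month_range(year_start: int, year_end: int) -> np.ndarray:
    """All CMCs from January of ``year_start`` to December of ``year_end``."""
    return np.arange(cmc(year_start, 1), cmc(year_end, 12) + 1)
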
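"""Attributable-fraction and comparative-impact accounting.

The fraction of the outcome burden attributable to an exposure above its
theoretical minimum risk exposure level (TMREL) is

    AF = 1 - 1 / exp(beta * (mean_exposure - TMREL))

with beta the fitted log-odds per ug/m3.  Negative excess exposure is
clamped to zero (no protective attribution).  The AF confidence interval
substitutes the Wald CI bounds of beta into the same monotone formula.
Source comparison reports the fire share of the PM2.5-linked burden and
the per-unit excess-risk ratio between sources on the OR-minus-1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "attributable_fraction",
    "AFResult",
    "af_result",
    "compare_sources",
    "SourceComparison",
    "stratified_af",
]

#: TMRELs used in the main analysis, ug/m3
TMREL_FIRE = 0.0
TMREL_NONFIRE = 10.0  # WHO air-quality guideline level


def attributable_fraction(beta: float, mean_exposure: float, tmrel: float) -> float:
    """AF = 1 - exp(-beta * max(mean_exposure - tmrel, 0))."""
    if mean_exposure < 0:
        raise ValueError("mean exposure must be non-negative")
    excess = max(mean_exposure - tmrel, 0.0)
    return 1.0 - float(np.exp(-beta * excess))


@dataclass
class AFResult:
    source: str
    beta: float
    mean_exposure: float
    tmrel: float
    af: float
    af_lower: Optional[float] = None
    af_upper: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def af_result(
    source: str,
    beta: float,
    mean_exposure: float,
    tmrel: float,
    beta_ci: Optional[tuple] = None,
) -> AFResult:
    """AF with a CI propagated through the monotone formula from beta's CI."""
    af = attributable_fraction(beta, mean_exposure, tmrel)
    lo = hi = None
    if beta_ci is not None:
        lo = attributable_fraction(beta_ci[0], mean_exposure, tmrel)
        hi = attributable_fraction(beta_ci[1], mean_exposure, tmrel)
    return AFResult(source, beta, mean_exposure, tmrel, af, lo, hi)


@dataclass
class SourceComparison:
    fire_share: float  # AF_fire / (AF_fire + AF_nonfire)
    excess_risk_ratio_pct: float  # per-unit OR-1 excess of fire over non-fire, %
    af_fire: float
    af_nonfire: float

    def to_dict(self) -> dict:
        return asdict(self)


def compare_sources(
    af_fire: float, af_nonfire: float, beta_fire: float, beta_nonfire: float
) -> SourceComparison:
    """Fire share of the PM2.5-linked burden and per-unit excess-risk ratio.

    The excess-risk comparison is on the OR-minus-1 scale per unit
    exposure: ``(exp(beta_fire) - 1) / (exp(beta_nonfire) - 1) - 1``,
    reported as a percentage.
    """
    if af_fire == 0.0 and af_nonfire == 0.0:
        raise ValueError("both attributable fractions are zero; share undefined")
    share = af_fire / (af_fire + af_nonfire)
    er_fire = np.exp(beta_fire) - 1.0
    er_nonfire = np.exp(beta_nonfire) - 1.0
    ratio_pct = float((er_fire / er_nonfire - 1.0) * 100.0)
    return SourceComparison(float(share), ratio_pct, af_fire, af_nonfire)


def stratified_af(
    data: pd.DataFrame,
    group_col: str,
    beta_fire: float,
    beta_nonfire: float,
    fire_col: str = "fire",
    nonfire_col: str = "nonfire",
    tmrel_fire: float = TMREL_FIRE,
    tmrel_nonfire: float = TMREL_NONFIRE,
) -> pd.DataFrame:
    """Per-stratum AFs from stratum mean exposures (shared coefficients)."""
    rows = []
    for lev, sub in data.groupby(group_col):
        aff = attributable_fraction(beta_fire, sub[fire_col].mean(), tmrel_fire)
        afn = attributable_fraction(beta_nonfire, sub[nonfire_col].mean(), tmrel_nonfire)
        rows.append(
            {
                group_col: lev,
                "mean_fire": sub[fire_col].mean(),
                "mean_nonfire": sub[nonfire_col].mean(),
                "af_fire": aff,
                "af_nonfire": afn,
                "fire_share": aff / (aff + afn) if (aff + afn) > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def impact_table(results: list) -> pd.DataFrame:
    """Serialise AFResult objects to a tidy frame (CSV-ready)."""
    return pd.DataFrame([r.to_dict() for r in results])
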
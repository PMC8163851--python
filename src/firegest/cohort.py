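"""Self-comparison matched case-control cohort construction.

Each mother contributes one matched set: her most recent pregnancy loss
inside the study period (the case) against all of her live births with
valid exposure (the controls).  Because gestational duration is recalled
and losses terminate early, every control's exposure is averaged over a
window of the *case's* gestation length starting at the control's own
conception month, so case and controls see windows of identical length.

Sensitivity-analysis eligibility flags (case type, singleton controls,
surviving-infant controls, parity matching, bidirectional controls,
transported fire smoke, recall period) are attached per set so that
subset re-fits are simple row filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposureSeries
from .synthetic import AGE_BANDS, age_band, age_group3
from .timeaxis import cmc, cmc_month, cmc_year

__all__ = [
    "select_cases",
    "match_controls",
    "flag_subsets",
    "build_matched_cohort",
    "MatchedCohort",
    "SUBSET_FLAGS",
    "write_matched",
    "read_matched",
]

#: window-mean exposure columns attached to every matched event
WINDOW_VARS = ("fire", "nonfire", "total", "temperature", "humidity", "burned_frac", "dry_matter")

SUBSET_FLAGS = (
    "miscarriage",
    "stillbirth",
    "controls_singleton",
    "controls_survived12",
    "parity_matched",
    "bidirectional",
    "transported_fire",
    "recall_lt3",
    "recall_lt4",
    "recall_lt5",
    "recall_lt6",
)

MISCARRIAGE_MAX_GESTATION = 4  # loss with gestation < 5 months


@dataclass
class MatchedCohort:
    """Long-format matched sets with window means and subset flags."""

    data: pd.DataFrame
    n_sets: int
    n_cases_unmatched: int  # in-period cases dropped for lack of a valid control

    @property
    def n_events(self) -> int:
        return len(self.data)


def select_cases(events: pd.DataFrame, period: tuple) -> pd.DataFrame:
    """One case per mother: her most recent in-period pregnancy loss.

    ``period`` is ``(start_year, end_year)``; a loss is in-period when its
    termination month falls inside.  Ties within a month are broken by
    input record order (the later record wins), which is deterministic.
    """
    start, end = cmc(period[0], 1), cmc(period[1], 12)
    losses = events[
        (events["outcome"] == "loss")
        & (events["termination_cmc"] >= start)
        & (events["termination_cmc"] <= end)
    ]
    if losses.empty:
        return losses
    # stable sort: last record per mother with the max termination month wins
    idx = (
        losses.reset_index()
        .sort_values(["mother_id", "termination_cmc", "index"], kind="stable")
        .groupby("mother_id")["index"]
        .last()
    )
    return events.loc[idx.to_numpy()]


def _window_means(df: pd.DataFrame, series: ExposureSeries, point_col: str) -> pd.DataFrame:
    """Window means for each row over [conception, conception+window-1]."""
    out = {}
    valid_all = np.ones(len(df), dtype=bool)
    for var in WINDOW_VARS:
        vals, valid = series.window_means(
            var,
            df[point_col].to_numpy(),
            df["conception_cmc"].to_numpy(),
            df["window_months"].to_numpy(),
        )
        out[var] = vals
        valid_all &= valid
    out["exposure_valid"] = valid_all
    return df.assign(**out)


def match_controls(
    cases: pd.DataFrame,
    events: pd.DataFrame,
    series: ExposureSeries,
    point_col: str = "cluster_id",
) -> MatchedCohort:
    """Window-matched same-mother controls for each selected case.

    Controls are all live births of the case's mother whose exposure is
    valid over a window of the case's gestation length starting at the
    control's own conception month.  Sets with no valid control are
    dropped (their count is reported, mirroring the exclusion of cases
    that cannot be matched).
    """
    cases = cases.copy()
    cases["window_months"] = cases["gestation_months"].astype(int)
    cases["role"] = "case"

    ctrl = events[events["outcome"] == "live"].merge(
        cases[["mother_id", "gestation_months"]].rename(
            columns={"gestation_months": "window_months"}
        ),
        on="mother_id",
        how="inner",
    )
    ctrl["role"] = "control"

    cases = _window_means(cases, series, point_col)
    ctrl = _window_means(ctrl, series, point_col)
    cases = cases[cases["exposure_valid"]]
    ctrl = ctrl[ctrl["exposure_valid"]]

    matched_mothers = np.intersect1d(cases["mother_id"], ctrl["mother_id"])
    n_unmatched = int(cases["mother_id"].nunique() - matched_mothers.size)
    cases = cases[cases["mother_id"].isin(matched_mothers)]
    ctrl = ctrl[ctrl["mother_id"].isin(matched_mothers)]

    data = pd.concat([cases, ctrl], ignore_index=True)
    data["set_id"] = data["mother_id"]
    data["is_case"] = (data["role"] == "case").astype(int)
    data = data.sort_values(["set_id", "is_case"], ascending=[True, False], kind="stable")

    # analysis covariates: maternal age recomputed at the end of each
    # event's matched exposure window (for the case this is its own
    # termination month; controls are classified at the same gestational
    # offset as the case, so all members of a set are age-rated at
    # comparable points of pregnancy)
    data["age_years"] = (
        data["conception_cmc"] + data["window_months"] - 1 - data["mother_birth_cmc"]
    ) / 12.0
    # ordered so the youngest band is the reference level in fits
    data["age_band"] = pd.Categorical(
        age_band(data["age_years"]), categories=AGE_BANDS, ordered=True
    )
    data["age_group3"] = age_group3(data["age_years"])
    data["conception_month"] = cmc_month(data["conception_cmc"])
    data["conception_year"] = cmc_year(data["conception_cmc"])
    return MatchedCohort(data.reset_index(drop=True), int(matched_mothers.size), n_unmatched)


def flag_subsets(cohort: MatchedCohort, recall_years: Sequence[int] = (3, 4, 5, 6)) -> MatchedCohort:
    """Attach per-set sensitivity-analysis eligibility flags.

    * ``miscarriage`` / ``stillbirth``: case gestation < 5 / >= 5 months;
    * ``controls_singleton``: every control a singleton birth;
    * ``controls_survived12``: every control survived > 12 months with
      known status (unknown survival excludes under this flag only);
    * ``parity_matched``: case and controls all nulliparous with every
      control after the case, or all multiparous;
    * ``bidirectional``: at least one control terminating before and one
      after the case's termination;
    * ``transported_fire``: zero burned area in every window month at the
      mother's cell, while smoke may still be present (advected);
    * ``recall_lt{n}``: survey minus termination below n years (in whole
      months) for the case and every control.
    """
    d = cohort.data
    g = d.groupby("set_id")
    is_ctrl = d["is_case"] == 0

    case_gest = d["gestation_months"].where(d["is_case"] == 1).groupby(d["set_id"]).max()
    case_term = d["termination_cmc"].where(d["is_case"] == 1).groupby(d["set_id"]).max()
    case_parity = d["parity_before"].where(d["is_case"] == 1).groupby(d["set_id"]).max()

    sets = pd.DataFrame(index=case_gest.index)
    sets["miscarriage"] = case_gest <= MISCARRIAGE_MAX_GESTATION
    sets["stillbirth"] = ~sets["miscarriage"]

    singleton_ok = d["singleton"].astype(bool) | (d["is_case"] == 1)
    sets["controls_singleton"] = singleton_ok.groupby(d["set_id"]).all()

    surv_ok = ((d["survival_months"] > 12) & d["survival_months"].notna()) | (d["is_case"] == 1)
    sets["controls_survived12"] = surv_ok.groupby(d["set_id"]).all()

    ct = case_term.reindex(d["set_id"]).to_numpy()
    cp = case_parity.reindex(d["set_id"]).to_numpy()
    null_ok = pd.Series(
        np.where(
            is_ctrl,
            (d["parity_before"] == 0) & (cp == 0) & (d["termination_cmc"] > ct),
            d["parity_before"] == 0,
        ),
        index=d.index,
    )
    multi_ok = pd.Series(d["parity_before"] >= 1, index=d.index)
    sets["parity_matched"] = null_ok.groupby(d["set_id"]).all() | multi_ok.groupby(
        d["set_id"]
    ).all()

    before = pd.Series(is_ctrl & (d["termination_cmc"].to_numpy() < ct), index=d.index)
    after = pd.Series(is_ctrl & (d["termination_cmc"].to_numpy() > ct), index=d.index)
    sets["bidirectional"] = before.groupby(d["set_id"]).any() & after.groupby(d["set_id"]).any()

    # window-mean burned fraction is zero iff every window month is zero
    sets["transported_fire"] = (d["burned_frac"] <= 0).groupby(d["set_id"]).all()

    recall_months = d["survey_cmc"] - d["termination_cmc"]
    for ny in recall_years:
        sets[f"recall_lt{ny}"] = (recall_months < 12 * ny).groupby(d["set_id"]).all()

    data = cohort.data.merge(sets, left_on="set_id", right_index=True, how="left")
    return MatchedCohort(data, cohort.n_sets, cohort.n_cases_unmatched)


def build_matched_cohort(
    events: pd.DataFrame,
    series: ExposureSeries,
    period: tuple,
    point_col: str = "cluster_id",
    recall_years: Sequence[int] = (3, 4, 5, 6),
) -> MatchedCohort:
    """select_cases -> match_controls -> flag_subsets in one call."""
    cases = select_cases(events, period)
    cohort = match_controls(cases, events, series, point_col=point_col)
    return flag_subsets(cohort, recall_years=recall_years)


def write_matched(cohort: MatchedCohort, path) -> None:
    cohort.data.to_csv(path, index=False)


def read_matched(path) -> MatchedCohort:
    data = pd.read_csv(path)
    n_sets = data["set_id"].nunique()
    return MatchedCohort(data, n_sets, 0)
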
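import numpy as np
import pandas as pd
import pytest

from firegest import cohort as ch
from firegest.exposure import ExposureSeries
from firegest.timeaxis import cmc


def _event(mother, outcome, conception, gestation, **kw):
    row = dict(
        mother_id=mother,
        cluster_id=kw.pop("cluster_id", 0),
        lat=21.0,
        lon=81.0,
        outcome=outcome,
        conception_cmc=conception,
        termination_cmc=conception + gestation - 1,
        gestation_months=gestation,
        singleton=kw.pop("singleton", True),
        survival_months=kw.pop("survival_months", 60.0 if outcome == "live" else np.nan),
        parity_before=kw.pop("parity_before", 0),
        mother_birth_cmc=kw.pop("mother_birth_cmc", conception - 300),
        survey_cmc=kw.pop("survey_cmc", cmc(2015, 6)),
        education="primary",
        residence="rural",
        insurance="no",
    )
    row.update(kw)
    return row


@pytest.fixture()
def flat_series():
    """Two points, constant fields, months 1998-01..2015-12."""
    months = np.arange(cmc(1998, 1), cmc(2015, 12) + 1)
    n = months.size
    data = {
        "fire": np.vstack([np.full(n, 2.0), np.full(n, 0.5)]),
        "nonfire": np.full((2, n), 40.0),
        "total": np.full((2, n), 42.0),
        "temperature": np.full((2, n), 25.0),
        "humidity": np.full((2, n), 60.0),
        "burned_frac": np.vstack([np.full(n, 1.0), np.zeros(n)]),
        "dry_matter": np.zeros((2, n)),
    }
    return ExposureSeries(months, data, np.array([21.0, 22.0]), np.array([81.0, 82.0]))


class TestSelectCases:
    def test_most_recent_in_period_loss(self):
        ev = pd.DataFrame(
            [
                _event(1, "loss", cmc(2005, 3), 4),
                _event(1, "loss", cmc(2010, 6), 3),
                _event(1, "live", cmc(2007, 1), 9),
            ]
        )
        cases = ch.select_cases(ev, (2000, 2014))
        assert len(cases) == 1
        assert cases.iloc[0]["conception_cmc"] == cmc(2010, 6)

    def test_out_of_period_mother_excluded(self):
        ev = pd.DataFrame([_event(1, "loss", cmc(1998, 2), 3)])
        assert ch.select_cases(ev, (2000, 2014)).empty

    def test_same_month_tie_broken_by_record_order(self):
        same = cmc(2008, 5)
        ev = pd.DataFrame(
            [
                dict(_event(1, "loss", same, 4), singleton=True),
                dict(_event(1, "loss", same, 4), singleton=False),  # later record wins
            ]
        )
        cases = ch.select_cases(ev, (2000, 2014))
        assert len(cases) == 1
        assert cases.iloc[0]["singleton"] == False  # noqa: E712


class TestMatchControls:
    def test_control_window_is_case_gestation(self, flat_series):
        ev = pd.DataFrame(
            [
                _event(1, "loss", cmc(2008, 5), 4),
                _event(1, "live", cmc(2005, 1), 9),
            ]
        )
        ev["_point"] = 0
        cases = ch.select_cases(ev, (2000, 2014))
        cohort = ch.match_controls(cases, ev, flat_series, point_col="_point")
        ctrl = cohort.data[cohort.data["role"] == "control"]
        assert (ctrl["window_months"] == 4).all()

    def test_mother_without_live_birth_dropped(self, flat_series):
        ev = pd.DataFrame([_event(1, "loss", cmc(2008, 5), 4)])
        ev["_point"] = 0
        cases = ch.select_cases(ev, (2000, 2014))
        cohort = ch.match_controls(cases, ev, flat_series, point_col="_point")
        assert cohort.n_sets == 0
        assert cohort.n_cases_unmatched == 1

    def test_control_with_missing_exposure_dropped(self, flat_series):
        last = int(flat_series.months[-1])
        ev = pd.DataFrame(
            [
                _event(1, "loss", cmc(2008, 5), 9),
                _event(1, "live", cmc(2005, 1), 9),
                # window of length 9 from here runs past the series end
                _event(1, "live", last - 7, 9),
            ]
        )
        ev["_point"] = 0
        cases = ch.select_cases(ev, (2000, 2014))
        cohort = ch.match_controls(cases, ev, flat_series, point_col="_point")
        assert cohort.n_sets == 1
        assert (cohort.data["role"] == "control").sum() == 1

    def test_count_identity(self, small_matched):
        d = small_matched.data
        n_cases = int((d["is_case"] == 1).sum())
        n_controls = int((d["is_case"] == 0).sum())
        assert n_cases == small_matched.n_sets
        assert n_cases + n_controls == len(d)
        # every (case, control) pair shares the window length
        assert (d.groupby("set_id")["window_months"].nunique() == 1).all()


class TestFlags:
    def _cohort(self, events, series):
        events = events.copy()
        events["_point"] = events["cluster_id"]
        cases = ch.select_cases(events, (2000, 2014))
        return ch.flag_subsets(ch.match_controls(cases, events, series, point_col="_point"))

    def test_case_type_split_at_five_months(self, flat_series):
        ev = pd.DataFrame(
            [
                _event(1, "loss", cmc(2008, 5), 5),
                _event(1, "live", cmc(2005, 1), 9),
                _event(2, "loss", cmc(2008, 5), 4),
                _event(2, "live", cmc(2005, 1), 9),
            ]
        )
        got = self._cohort(ev, flat_series).data.groupby("set_id")[["miscarriage", "stillbirth"]].first()
        assert bool(got.loc[1, "stillbirth"]) and not got.loc[1, "miscarriage"]
        assert bool(got.loc[2, "miscarriage"]) and not got.loc[2, "stillbirth"]

    def test_bidirectional_needs_controls_both_sides(self, flat_series):
        ev = pd.DataFrame(
            [
                _event(1, "loss", cmc(2008, 5), 4),
                _event(1, "live", cmc(2009, 1), 9),  # only after the case
                _event(2, "loss", cmc(2008, 5), 4),
                _event(2, "live", cmc(2005, 1), 9),
                _event(2, "live", cmc(2010, 1), 9),
            ]
        )
        got = self._cohort(ev, flat_series).data.groupby("set_id")["bidirectional"].first()
        assert not got.loc[1]
        assert got.loc[2]

    def test_transported_fire_requires_zero_burning_with_smoke(self, flat_series):
        # point 1 has burned_frac == 0 throughout but fire PM2.5 = 0.5
        ev = pd.DataFrame(
            [
                _event(1, "loss", cmc(2008, 5), 4, cluster_id=1),
                _event(1, "live", cmc(2005, 1), 9, cluster_id=1),
                _event(2, "loss", cmc(2008, 5), 4, cluster_id=0),
                _event(2, "live", cmc(2005, 1), 9, cluster_id=0),
            ]
        )
        got = self._cohort(ev, flat_series)
        flags = got.data.groupby("set_id")["transported_fire"].first()
        fire = got.data.groupby("set_id")["fire"].first()
        assert flags.loc[1] and fire.loc[1] > 0
        assert not flags.loc[2]

    def test_parity_matched_definitions(self, flat_series):
        ev = pd.DataFrame(
            [
                # nulliparous set: case before first delivery
                _event(1, "loss", cmc(2004, 5), 4, parity_before=0),
                _event(1, "live", cmc(2006, 1), 9, parity_before=0),
                # mismatched: control before the case
                _event(2, "loss", cmc(2008, 5), 4, parity_before=1),
                _event(2, "live", cmc(2005, 1), 9, parity_before=0),
                # multiparous set
                _event(3, "loss", cmc(2008, 5), 4, parity_before=2),
                _event(3, "live", cmc(2005, 1), 9, parity_before=1),
            ]
        )
        got = self._cohort(ev, flat_series).data.groupby("set_id")["parity_matched"].first()
        assert got.loc[1] and not got.loc[2] and got.loc[3]

    def test_recall_flags(self, flat_series):
        survey = cmc(2015, 6)
        ev = pd.DataFrame(
            [
                _event(1, "loss", cmc(2012, 1), 4, survey_cmc=survey),
                _event(1, "live", cmc(2011, 1), 9, survey_cmc=survey),
                _event(2, "loss", cmc(2004, 1), 4, survey_cmc=survey),
                _event(2, "live", cmc(2011, 1), 9, survey_cmc=survey),
            ]
        )
        got = self._cohort(ev, flat_series).data.groupby("set_id")[["recall_lt4", "recall_lt6"]].first()
        assert got.loc[1, "recall_lt4"] and got.loc[1, "recall_lt6"]
        assert not got.loc[2, "recall_lt4"] and not got.loc[2, "recall_lt6"]

    def test_surviving_infant_flag_excludes_unknown(self, flat_series):
        ev = pd.DataFrame(
            [
                _event(1, "loss", cmc(2008, 5), 4),
                _event(1, "live", cmc(2005, 1), 9, survival_months=np.nan),
                _event(2, "loss", cmc(2008, 5), 4),
                _event(2, "live", cmc(2005, 1), 9, survival_months=40.0),
                _event(3, "loss", cmc(2008, 5), 4),
                _event(3, "live", cmc(2005, 1), 9, survival_months=6.0),
            ]
        )
        got = self._cohort(ev, flat_series).data.groupby("set_id")["controls_survived12"].first()
        assert not got.loc[1] and got.loc[2] and not got.loc[3]

    def test_subset_counts_monotone(self, small_matched):
        """Adding a filter never increases the number of eligible sets."""
        d = small_matched.data
        sets = d.groupby("set_id").first()
        n_all = len(sets)
        for flag in ch.SUBSET_FLAGS:
            assert sets[flag].sum() <= n_all
        # intersections are no larger than their parts
        both = (sets["miscarriage"] & sets["controls_singleton"]).sum()
        assert both <= sets["miscarriage"].sum()
        assert both <= sets["controls_singleton"].sum()
        # recall windows nest
        assert sets["recall_lt3"].sum() <= sets["recall_lt4"].sum() <= sets["recall_lt5"].sum() <= sets["recall_lt6"].sum()
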
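"""Capture-history construction: survey years, gap-filling, covariates, augmentation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import jollyseber as js
from jollyseber.catalog import (
    STATE_ALIVE,
    STATE_DEAD,
    STATE_NOT_ENTERED,
    STATE_UNKNOWN,
    CatalogError,
)


def rec(iid, y, m, d, sex="U", birth_year=None, death=None):
    return js.SightingRecord(iid, dt.date(y, m, d), sex, birth_year, death)


class TestSurveyYear:
    @pytest.mark.parametrize(
        "date, expected",
        [
            (dt.date(1989, 12, 15), 1990),  # December belongs to the next survey year
            (dt.date(1990, 11, 30), 1990),  # last day inside the window
            (dt.date(1990, 12, 1), 1991),
            (dt.date(1995, 6, 1), 1995),
        ],
    )
    def test_assignment(self, date, expected):
        assert js.survey_year(date) == expected


class TestCompression:
    def test_multiple_sightings_one_cell(self):
        records = [rec("w1", 1995, m, 5) for m in (2, 6, 10)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        assert ch.histories.sum() == 1
        assert ch.histories[0, 1995 - 1990] == 1

    def test_out_of_window_individuals_excluded(self):
        records = [rec("early", 1985, 5, 1), rec("inwin", 1992, 5, 1)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        assert ch.ids == ["inwin"]

    def test_spanning_individual_kept_with_zero_history(self):
        # seen before and after the window: a real row, known alive throughout
        records = [rec("span", 1989, 5, 1), rec("span", 2001, 5, 1), rec("x", 1995, 5, 1)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        assert "span" in ch.ids
        assert ch.histories[ch.ids.index("span")].sum() == 0

    def test_december_sighting_lands_in_next_column(self):
        ch = js.compress_to_survey_years([rec("w", 1989, 12, 15)], 1990, 1999)
        assert ch.histories[0, 0] == 1

    def test_empty_records_error(self):
        with pytest.raises(CatalogError):
            js.compress_to_survey_years([], 1990, 1999)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["a", "b", "c"]),
                st.dates(dt.date(1990, 1, 1), dt.date(1999, 11, 30)),
            ),
            min_size=1,
            max_size=20,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_and_duplication_invariance(self, pairs, rnd):
        records = [js.SightingRecord(i, d) for i, d in pairs]
        base = js.compress_to_survey_years(records, 1990, 1999)
        shuffled = records + [records[0]]
        rnd.shuffle(shuffled)
        again = js.compress_to_survey_years(shuffled, 1990, 1999)
        assert base.ids == again.ids
        np.testing.assert_array_equal(base.histories, again.histories)


class TestKnownStates:
    def test_gap_fill_between_sightings(self):
        records = [rec("w", 1991, 5, 1), rec("w", 1993, 5, 1)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        ks = js.build_known_states(ch, records)
        assert ks.states[0, 1992 - 1990] == STATE_ALIVE
        assert ks.states[0, 0] == STATE_UNKNOWN

    def test_pre_study_sighting_extends_alive_backward(self):
        records = [rec("w", 1992, 5, 1)]
        pre = [rec("w", 1989, 6, 1)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        ks = js.build_known_states(ch, records, pre)
        assert ks.states[0, 0] == STATE_ALIVE  # 1990
        assert ks.states[0, 1] == STATE_ALIVE  # 1991

    def test_not_entered_before_birth_year(self):
        records = [rec("w", 1995, 5, 1, birth_year=1995)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        ks = js.build_known_states(ch, records)
        assert (ks.states[0, :5] == STATE_NOT_ENTERED).all()
        assert ks.states[0, 5] == STATE_ALIVE

    def test_death_is_absorbing(self):
        d = dt.date(1996, 4, 1)
        records = [rec("w", 1993, 5, 1, death=d)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        ks = js.build_known_states(ch, records)
        assert (ks.states[0, 1996 - 1990 :] == STATE_DEAD).all()
        assert ks.states[0, 1993 - 1990] == STATE_ALIVE

    def test_death_before_live_sighting_errors(self):
        records = [rec("w", 1995, 5, 1, death=dt.date(1993, 4, 1)), rec("w", 1992, 5, 1)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        with pytest.raises(CatalogError):
            js.build_known_states(ch, records)

    def test_unknown_age_years_before_first_sighting_stay_unknown(self):
        records = [rec("w", 1995, 5, 1)]  # no birth year
        ch = js.compress_to_survey_years(records, 1990, 1999)
        ks = js.build_known_states(ch, records)
        assert (ks.states[0, :5] == STATE_UNKNOWN).all()

    def test_monotone_pattern_enforced(self):
        with pytest.raises(CatalogError):
            js.KnownStateMatrix(np.array([[2, 1, 0]]))  # alive then not-entered


class TestCovariates:
    def test_known_age_progression_and_cap(self):
        records = [rec("w", 1992, 5, 1, birth_year=1992), rec("w", 2000, 5, 1)]
        ch = js.compress_to_survey_years(records, 1990, 2005)
        cov = js.build_covariates(records, ch)
        y = lambda yr: yr - 1990
        assert cov.age[0, y(1994)] == 2 and cov.adult[0, y(1994)] == 0
        assert cov.age[0, y(2000)] == 5 and cov.adult[0, y(2000)] == 1

    def test_unknown_age_treated_as_five_plus(self):
        records = [rec("w", 1995, 5, 1)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        cov = js.build_covariates(records, ch)
        assert (cov.age[0] == 5).all() and (cov.adult[0] == 1).all()

    def test_sex_coding(self):
        records = [rec("f", 1995, 5, 1, sex="F"), rec("m", 1995, 5, 1, sex="M"), rec("u", 1995, 5, 1)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        cov = js.build_covariates(records, ch)
        sex = {i: cov.sex[k] for k, i in enumerate(ch.ids)}
        assert sex["f"] == 1.0 and sex["m"] == 0.0 and np.isnan(sex["u"])

    def test_sighting_before_birth_errors(self):
        records = [rec("w", 1993, 5, 1, birth_year=1995)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        with pytest.raises(CatalogError):
            js.build_covariates(records, ch)


class TestAugmentation:
    def test_row_counts_and_zero_rows(self):
        records = [rec(f"w{k}", 1995, 5, 1) for k in range(5)]
        ch = js.compress_to_survey_years(records, 1990, 1999)
        aug = js.augment(ch, 200)
        assert aug.n_individuals == 205 and aug.n_augmented == 200
        assert not aug.histories[5:].any()
        assert js.augment(ch, 0) is ch

    def test_catalog_data_augment_extends_everything(self, tiny_data):
        n_real = tiny_data.histories.n_real
        n = tiny_data.histories.n_individuals
        assert n - n_real == 10
        assert np.isnan(tiny_data.covariates.sex[n_real:]).all()
        assert (tiny_data.covariates.age[n_real:] == 5).all()
        assert (tiny_data.covariates.adult[n_real:] == 1).all()
        assert (tiny_data.known_states.states[n_real:] == STATE_UNKNOWN).all()


class TestRoundTrip:
    def test_capture_history_csv_round_trip(self, tiny_data, tmp_path):
        path = tmp_path / "ch.csv"
        tiny_data.histories.to_csv(path)
        back = js.CaptureHistoryMatrix.from_csv(path)
        assert back.ids == tiny_data.histories.ids
        assert back.n_augmented == tiny_data.histories.n_augmented
        np.testing.assert_array_equal(back.histories, tiny_data.histories.histories)
        np.testing.assert_array_equal(back.years, tiny_data.histories.years)

    def test_known_state_csv_round_trip(self, tiny_data, tmp_path):
        path = tmp_path / "ks.csv"
        h = tiny_data.histories
        tiny_data.known_states.to_csv(path, h.ids, h.years)
        back = js.KnownStateMatrix.from_csv(path)
        np.testing.assert_array_equal(back.states, tiny_data.known_states.states)

    def test_sightings_csv_round_trip(self, tmp_path):
        records = [
            rec("w1", 1995, 5, 1, sex="F", birth_year=1995),
            rec("w2", 1989, 12, 2, sex="M", death=dt.date(1996, 4, 1)),
            rec("w3", 1993, 7, 9),
        ]
        path = tmp_path / "sightings.csv"
        import pandas as pd

        pd.DataFrame(
            {
                "id": [r.individual_id for r in records],
                "date": [r.date.isoformat() for r in records],
                "sex": [r.sex for r in records],
                "birth_year": [r.birth_year for r in records],
                "death_date": [r.death_date.isoformat() if r.death_date else "" for r in records],
            }
        ).to_csv(path, index=False)
        assert js.read_sightings(path) == records

    def test_unparseable_date_reports_rows(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,date,sex,birth_year,death_date\nw1,not-a-date,U,,\n")
        with pytest.raises(CatalogError, match="row 0"):
            js.read_sightings(path)


@given(st.data())
@settings(max_examples=40, deadline=None)
def test_known_states_always_monotone(data):
    """Any constructible known-state matrix follows the 1*2*3* pattern per row."""
    n_ind = data.draw(st.integers(1, 4))
    records = []
    for k in range(n_ind):
        years = data.draw(
            st.lists(st.integers(1988, 2001), min_size=1, max_size=5, unique=True)
        )
        by = data.draw(st.one_of(st.none(), st.just(min(years))))
        death = data.draw(st.booleans())
        dd = dt.date(max(years) + 1, 4, 1) if death else None
        for y in years:
            records.append(js.SightingRecord(f"w{k}", dt.date(y, 6, 1), "U", by, dd))
    ch = js.compress_to_survey_years(records, 1990, 1999)
    if ch.n_individuals == 0:
        return
    ks = js.build_known_states(ch, records)
    for row in ks.states:
        known = row[row != STATE_UNKNOWN]
        assert (np.diff(known) >= 0).all()
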
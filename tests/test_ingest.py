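"""Cleaning rules: validation, live filter, deduplication, summaries."""

import numpy as np
import pandas as pd
import pytest

from koalasight.grid import StudyWindow
from koalasight.ingest import (
    clean_pipeline,
    deduplicate,
    drop_invalid,
    filter_live,
    read_sightings,
    reporter_stats,
    summarize_attributes,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=[
        "id", "date", "x", "y", "sex", "age_class",
        "physical_location", "status", "reporter_id",
    ])


WINDOW = StudyWindow(10.0, 10.0)


def row(id, date="2000-06-15", x=5.0, y=5.0, sex="unknown", age="adult",
        loc="tree", status="alive_sighting", rep="r1"):
    return (id, date, x, y, sex, age, loc, status, rep)


class TestReadSightings:
    def test_well_formed_rows_unflagged(self):
        df, report = read_sightings(make_table([row(f"a{i}") for i in range(5)]), WINDOW)
        assert len(df) == 5 and report.n_input == 5
        assert df["coord_valid"].all() and df["date_valid"].all()

    def test_out_of_window_coordinate_flagged(self):
        df, _ = read_sightings(make_table([row("a", x=25.0), row("b")]), WINDOW)
        assert not df.loc[df["id"] == "a", "coord_valid"].item()
        assert df.loc[df["id"] == "b", "coord_valid"].item()

    def test_unparseable_date_flagged_not_dropped(self):
        df, _ = read_sightings(make_table([row("a", date="not-a-date")]), WINDOW)
        assert len(df) == 1 and not df["date_valid"].item()

    def test_missing_mandatory_column_named(self):
        bad = make_table([row("a")]).drop(columns=["date"])
        with pytest.raises(ValueError, match="date"):
            read_sightings(bad, WINDOW)


class TestFilterLive:
    def test_mixed_statuses_counted(self):
        rows = (
            [row(f"d{i}", status="dead") for i in range(3)]
            + [row(f"i{i}", status="injured") for i in range(2)]
            + [row(f"a{i}") for i in range(5)]
        )
        df, report = filter_live(make_table(rows))
        assert len(df) == 5
        assert report.n_excluded_status == 5

    def test_all_alive_is_identity(self):
        table = make_table([row(f"a{i}") for i in range(4)])
        df, report = filter_live(table)
        assert len(df) == 4 and report.n_excluded_status == 0

    def test_matches_brute_force_recount(self, default_scenario_data):
        table = default_scenario_data.records
        df, _ = filter_live(table)
        assert len(df) == (table["status"] == "alive_sighting").sum()


class TestDeduplicate:
    def test_identical_triplet_keeps_smallest_id(self):
        table = make_table([row("c"), row("a"), row("b")])
        df, report = deduplicate(table)
        assert list(df["id"]) == ["a"]
        assert report.n_excluded_duplicate == 2

    def test_same_location_different_days_both_kept(self):
        table = make_table([row("a", date="2000-06-15"), row("b", date="2000-06-16")])
        df, _ = deduplicate(table)
        assert len(df) == 2

    def test_multi_animal_flag_exempts(self):
        table = make_table([row("a"), row("b")])
        table["multi_animal"] = [True, True]
        df, report = deduplicate(table)
        assert len(df) == 2 and report.n_excluded_duplicate == 0

    def test_injected_duplicates_recovered_exactly(self, default_scenario_data):
        data = default_scenario_data
        live, _ = filter_live(data.records)
        _, report = deduplicate(live)
        assert report.n_excluded_duplicate == data.injection_log.n_duplicates_injected


class TestPipelineProperties:
    def test_filter_order_does_not_change_retained_set(self, default_scenario_data):
        table = default_scenario_data.records
        a, _ = deduplicate(filter_live(table)[0])
        b, _ = filter_live(deduplicate(table)[0])
        assert sorted(a["id"]) == sorted(b["id"])

    def test_report_reconciles(self, default_scenario_data):
        data = default_scenario_data
        window = data.window
        df, report = clean_pipeline(data.records, window)
        assert report.n_retained == len(df)
        assert (
            report.n_input
            == report.n_retained
            + report.n_excluded_coords
            + report.n_excluded_status
            + report.n_excluded_duplicate
        )
        log = data.injection_log
        assert report.n_excluded_coords == log.n_corrupt_injected
        assert report.n_excluded_status == log.n_nonlive
        assert report.n_excluded_duplicate == log.n_duplicates_injected

    def test_summaries_invariant_to_row_order(self, default_scenario_data):
        table = default_scenario_data.records
        shuffled = table.sample(frac=1.0, random_state=99).reset_index(drop=True)
        a = summarize_attributes(table).sort_values(["attribute", "level"]).reset_index(drop=True)
        b = summarize_attributes(shuffled).sort_values(["attribute", "level"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestSummaries:
    def test_sexed_denominator_convention(self):
        table = make_table([
            row("a", sex="male"), row("b", sex="female"),
            row("c", sex="unknown"), row("d", sex="unknown"),
        ])
        out = summarize_attributes(table)
        male_sexed = out.query("attribute == 'sex_of_sexed' and level == 'male'")
        assert male_sexed["proportion"].item() == pytest.approx(0.5)
        male_all = out.query("attribute == 'sex' and level == 'male'")
        assert male_all["proportion"].item() == pytest.approx(0.25)

    def test_empty_input_zero_counts(self):
        out = summarize_attributes(make_table([]))
        assert out.empty or (out["count"] == 0).all()


class TestReporterStats:
    def test_single_reporter(self):
        table = make_table([row(f"a{i}", rep="r1") for i in range(3)])
        per_year, overall = reporter_stats(table)
        assert per_year["n_reporters"].item() == 1
        assert per_year["sightings_per_reporter"].item() == pytest.approx(3.0)

    def test_two_years(self):
        rows = (
            [row("a", date="2000-01-01", rep="r1"), row("b", date="2000-02-01", rep="r2")]
            + [row(f"c{i}", date="2001-03-01", rep=f"s{i % 4}") for i in range(8)]
        )
        per_year, overall = reporter_stats(make_table(rows))
        means = dict(zip(per_year["year"], per_year["sightings_per_reporter"]))
        assert means[2000] == pytest.approx(1.0)
        assert means[2001] == pytest.approx(2.0)
        assert overall["mean_sightings_per_reporter"] == pytest.approx(1.5)

    def test_matches_groupby_recount(self, default_scenario_data):
        table, _ = clean_pipeline(
            default_scenario_data.records, default_scenario_data.window
        )
        per_year, _ = reporter_stats(table)
        years = pd.to_datetime(table["date"].astype(str)).dt.year
        brute = table.assign(year=years).groupby("year")["reporter_id"].nunique()
        assert dict(zip(per_year["year"], per_year["n_reporters"])) == brute.to_dict()
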
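#!/usr/bin/env python
"""Clean the record table and describe who was sighted and who reported.

Applies the exclusion rules (invalid coordinates/dates, non-live
records, same-day same-location repeats), then tabulates attributes
and per-year reporter participation.  Outputs under results/analysis/.
"""

from pathlib import Path

from koalasight.ingest import clean_pipeline, reporter_stats, summarize_attributes
from koalasight.synthetic import SimulationScenario
from koalasight.grid import StudyWindow

DATA = Path("results/synthetic")
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scenario = SimulationScenario.from_yaml(DATA / "scenario.yaml")
    window = StudyWindow(scenario.window_width_km, scenario.window_height_km)
    records, report = clean_pipeline(DATA / "records.csv", window)
    records.to_csv(OUT / "records_clean.csv", index=False)
    report.to_json(OUT / "cleaning_report.json")

    attrs = summarize_attributes(records)
    attrs.to_csv(OUT / "attribute_summary.csv", index=False)
    per_year, overall = reporter_stats(records)
    per_year.to_csv(OUT / "reporter_stats_by_year.csv", index=False)

    print(
        f"cleaning: {report.n_input} rows in -> {report.n_retained} retained "
        f"({report.n_excluded_coords} bad coordinates, "
        f"{report.n_excluded_status} non-live, "
        f"{report.n_excluded_duplicate} duplicates)"
    )
    unknown = attrs.query("attribute == 'sex' and level == 'unknown'")
    print(f"sex unknown: {unknown['proportion'].item():.0%} of sightings")
    print(
        f"reporters: mean {overall['mean_reporters_per_year']:.0f}/year "
        f"(range {overall['range_reporters_per_year'][0]}-"
        f"{overall['range_reporters_per_year'][1]}), "
        f"{overall['mean_sightings_per_reporter']:.2f} sightings per reporter"
    )


if __name__ == "__main__":
    main()
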
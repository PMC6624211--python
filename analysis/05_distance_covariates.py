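#!/usr/bin/env python
"""Distance-transform rasters for every road and habitat class.

Each raster holds the exact Euclidean distance (km) from the 1 km
cell centres to the nearest feature of one class; habitat polygons
have distance zero inside.  These are the covariates Z(u) for the
bias inference step.
"""

from pathlib import Path

from koalasight.covariates import distance_raster
from koalasight.grid import FeatureSet, StudyWindow, read_geojson
from koalasight.synthetic import SimulationScenario

DATA = Path("results/synthetic")
OUT = Path("results/analysis")


def main() -> None:
    scenario = SimulationScenario.from_yaml(DATA / "scenario.yaml")
    window = StudyWindow(scenario.window_width_km, scenario.window_height_km)
    classes = [name for name, _ in scenario.road_specs] + [
        name for name, _, _ in scenario.habitat_specs
    ]
    for name in classes:
        geoms, _ = read_geojson(DATA / f"{name}.geojson")
        if not geoms:
            print(f"{name}: no features, skipped")
            continue
        rast = distance_raster(FeatureSet(geoms, name), window)
        rast.to_ascii(OUT / f"dist_{name}.asc")
        print(
            f"{name}: {len(geoms)} features, distance range "
            f"[{rast.values.min():.2f}, {rast.values.max():.2f}] km"
        )


if __name__ == "__main__":
    main()
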
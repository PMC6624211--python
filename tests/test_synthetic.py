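"""Generator correctness: windows, roads, the Poisson simulator, records."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from koalasight.covariates import distance_raster
from koalasight.grid import StudyWindow
from koalasight.synthetic import (
    SimulationScenario,
    make_window,
    simulate_ipp,
    simulate_records,
    simulate_roads,
)
from koalasight.validation import vertical_line_covariate


class TestMakeWindow:
    def test_square_window_area_and_mask(self):
        w = make_window(10, 10)
        assert w.area == 100
        assert w.mask().sum() == 100
        assert np.allclose(w.cell_areas(), 1.0)

    def test_noninteger_window_ceil_covers_and_clips(self):
        w = make_window(240.75, 240)
        assert (w.nx, w.ny) == (241, 240)
        # clipped cell areas reconstruct the polygon area exactly
        assert w.cell_areas().sum() == pytest.approx(57780.0)
        assert w.mask().sum() == 241 * 240

    @pytest.mark.parametrize("dims", [(0, 5), (5, 0), (-1, 3)])
    def test_degenerate_dimensions_rejected(self, dims):
        with pytest.raises(ValueError, match="positive"):
            make_window(*dims)


class TestSimulateRoads:
    def test_seed_determinism(self, window10):
        a = simulate_roads(window10, "tertiary", 5, seed=1)
        b = simulate_roads(window10, "tertiary", 5, seed=1)
        assert len(a) == len(b) == 5
        for ga, gb in zip(a, b):
            assert ga.equals_exact(gb, tolerance=0.0)

    def test_zero_segments_empty_and_distance_undefined(self, window10):
        fs = simulate_roads(window10, "primary", 0, seed=3)
        assert len(fs) == 0
        with pytest.raises(ValueError, match="empty feature set"):
            distance_raster(fs, window10)

    def test_segments_clipped_to_window(self, window10):
        fs = simulate_roads(window10, "secondary", 50, seed=9)
        for seg in fs:
            x, y = np.asarray(seg.coords).T
            assert window10.contains(x, y).all()


class TestSimulateIpp:
    def test_homogeneous_mean_count(self, window10):
        """CSR at rate 2/km² on 100 km²: mean count near 200 over seeds."""
        counts = [
            simulate_ipp(window10, None, np.log(2.0), 0.0, seed).n
            for seed in range(500)
        ]
        se = np.sqrt(200 / 500)
        assert abs(np.mean(counts) - 200) < 3 * se

    def test_homogeneous_counts_match_poisson_distribution(self):
        """KS test of simulated counts against the Poisson CDF."""
        w = StudyWindow(5.0, 5.0)
        counts = np.array(
            [simulate_ipp(w, None, 0.0, 0.0, s).n for s in range(1000)]
        )
        # exact discrete comparison: chi-square on binned Poisson(25) pmf
        lam = 25.0
        edges = np.arange(10, 41)
        obs = np.histogram(
            np.clip(counts, edges[0], edges[-1]),
            bins=np.concatenate([[-0.5], edges + 0.5]),
        )[0]
        pmf = np.concatenate(
            [[stats.poisson.cdf(edges[0], lam)],
             stats.poisson.pmf(edges[1:], lam)]
        )
        pmf[-1] += stats.poisson.sf(edges[-1], lam)
        chi2 = stats.chisquare(obs, 1000 * pmf / pmf.sum())
        assert chi2.pvalue > 0.01

    def test_negative_slope_pulls_events_toward_feature(self, window10):
        """beta = -3 on distance-to-line: events sit at lower Z than the window."""
        cov = vertical_line_covariate(window10, [5.0])
        z_window_mean = cov.values.mean()
        z_events = []
        for seed in range(100):
            pat = simulate_ipp(window10, cov, 2.0, -3.0, seed)
            if pat.n:
                z_events.append(cov.sample(pat.x, pat.y).mean())
        assert np.mean(z_events) < z_window_mean

    def test_nonfinite_envelope_rejected(self, window10, ramp_raster):
        with pytest.raises(ValueError, match="non-finite"):
            simulate_ipp(window10, ramp_raster, 500.0, 500.0, 1)

    def test_determinism(self, window10, ramp_raster):
        a = simulate_ipp(window10, ramp_raster, 1.0, -0.5, 11)
        b = simulate_ipp(window10, ramp_raster, 1.0, -0.5, 11)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


@pytest.fixture(scope="module")
def scenario():
    return SimulationScenario(seed=5, n_years=10)


@pytest.fixture(scope="module")
def pattern(scenario):
    w = StudyWindow(scenario.window_width_km, scenario.window_height_km)
    return simulate_ipp(w, None, np.log(0.3), 0.0, 21)


class TestSimulateRecords:
    def test_clean_generation_row_count_equals_pattern(self, pattern):
        sc = SimulationScenario(seed=5, duplicate_fraction=0.0, corrupt_fraction=0.0)
        table, log = simulate_records(pattern, sc, 1)
        assert len(table) == pattern.n
        assert log.n_duplicates_injected == 0 and log.n_corrupt_injected == 0

    def test_uniform_seasonality_passes_gof(self, pattern):
        """Uniform monthly profile: chi-square GOF rarely rejected."""
        sc = SimulationScenario(
            seed=5, seasonal_profile=tuple([1 / 12] * 12),
            duplicate_fraction=0.0, corrupt_fraction=0.0,
        )
        rejections = 0
        for seed in range(100):
            table, _ = simulate_records(pattern, sc, seed)
            months = pd.to_datetime(table["date"]).dt.month
            obs = months.value_counts().reindex(range(1, 13), fill_value=0)
            p = stats.chisquare(obs.to_numpy()).pvalue
            rejections += p < 0.01
        assert rejections <= 2

    def test_sex_unknown_share_near_57_percent(self):
        w = StudyWindow(100.0, 100.0)
        pat = simulate_ipp(w, None, 0.0, 0.0, 3)  # ~10,000 points
        sc = SimulationScenario(seed=5, duplicate_fraction=0.0, corrupt_fraction=0.0)
        table, _ = simulate_records(pat, sc, 2)
        share = (table["sex"] == "unknown").mean()
        assert abs(share - 0.57) < 0.02

    def test_injected_duplicates_are_exact_and_unique(self, pattern, scenario):
        table, log = simulate_records(pattern, scenario, 7)
        dup_counts = table.groupby(["x", "y", "date"]).size()
        extra = int((dup_counts - 1).clip(lower=0).sum())
        assert extra == log.n_duplicates_injected
        # every multi-row location/date group carries a live status
        dups = dup_counts[dup_counts > 1].index
        indexed = table.set_index(["x", "y", "date"]).sort_index()
        for key in dups:
            grp = indexed.loc[key]
            assert (grp["status"] == "alive_sighting").all()

    def test_bit_reproducible(self, pattern, scenario):
        t1, _ = simulate_records(pattern, scenario, 9)
        t2, _ = simulate_records(pattern, scenario, 9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError, match="seasonal_profile"):
            SimulationScenario(seasonal_profile=tuple([1 / 6] * 6))
        with pytest.raises(ValueError, match="sums to"):
            SimulationScenario(
                attribute_probs={
                    "sex": {"male": 0.5, "female": 0.4, "unknown": 0.2},
                    **{k: v for k, v in SimulationScenario().attribute_probs.items()
                       if k != "sex"},
                }
            )


def test_scenario_yaml_roundtrip(tmp_path):
    sc = SimulationScenario(seed=77, intensity_slope_beta=-0.4)
    sc.to_yaml(tmp_path / "sc.yaml")
    back = SimulationScenario.from_yaml(tmp_path / "sc.yaml")
    assert back == sc
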
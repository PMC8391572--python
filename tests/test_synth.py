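"""Synthetic stimuli, jury/survey simulation and the toy exposure grid."""

import numpy as np
import pandas as pd
import pytest

from parloud import synth
from parloud.annoyance import long_term_pct_ha
from parloud.temporal import a_weighted_level, time_varying_loudness


def _band(spec, freq):
    return spec.levels_db[np.argmin(np.abs(spec.centers_hz - freq))]


class TestTemplates:
    @pytest.mark.parametrize("maker", [synth.aircraft_spectrum, synth.road_spectrum])
    def test_calibration_round_trip(self, maker):
        spec = maker(68.0)
        assert spec.a_weighted_level() == pytest.approx(68.0, abs=0.01)

    def test_aircraft_high_frequency_character(self):
        spec = synth.aircraft_spectrum(70.0)
        assert _band(spec, 4000.0) > _band(spec, 125.0)

    def test_road_broadband_spread(self):
        spec = synth.road_spectrum(70.0)
        sel = (spec.centers_hz >= 100.0) & (spec.centers_hz <= 5000.0)
        assert np.ptp(spec.levels_db[sel]) <= 15.0
        assert _band(spec, 125.0) >= _band(spec, 8000.0)

    def test_templates_deterministic(self):
        a1, a2 = synth.aircraft_spectrum(73.0), synth.aircraft_spectrum(73.0)
        np.testing.assert_array_equal(a1.levels_db, a2.levels_db)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError):
            synth.aircraft_spectrum(110.0)


class TestFlyover:
    def test_laeq_round_trip(self):
        au = synth.flyover_waveform(68.0, duration_s=5.0, seed=0)
        assert a_weighted_level(au) == pytest.approx(68.0, abs=0.1)

    def test_seed_reproducibility(self):
        a = synth.flyover_waveform(70.0, duration_s=5.0, seed=3)
        b = synth.flyover_waveform(70.0, duration_s=5.0, seed=3)
        np.testing.assert_array_equal(a.left, b.left)
        np.testing.assert_array_equal(a.right, b.right)

    def test_peak_loudness_in_middle_third(self, consts):
        au = synth.flyover_waveform(72.0, duration_s=5.0, seed=1)
        tr = time_varying_loudness(au, consts, hop_s=0.02)
        n = tr.short_term.size
        peak = int(np.argmax(tr.short_term))
        assert n // 3 <= peak < 2 * n // 3

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            synth.flyover_waveform(70.0, duration_s=2.0)


class TestJuryDesign:
    def test_85_conditions(self):
        design = synth.jury_design()
        assert len(design) == 85
        counts = design.condition.value_counts()
        assert counts["aircraft_alone"] == 5
        assert counts["road_alone"] == 5
        assert counts["aircraft_with_road"] == 25
        assert counts["road_with_aircraft"] == 25
        assert counts["combined"] == 25

    def test_level_grids(self):
        design = synth.jury_design()
        assert set(design.aircraft_dba.dropna()) == {63.0, 68.0, 73.0, 78.0, 83.0}
        assert set(design.road_dba.dropna()) == {55.0, 60.0, 65.0, 70.0, 75.0}


class TestSimulateRatings:
    def test_zero_noise_gives_identical_subjects(self):
        r = synth.simulate_ratings([5.0, 20.0], n_subjects=10, noise_sd=0.0, rng=0)
        assert np.all(r == r[:, [0]])

    def test_ratings_clipped_to_scale(self):
        r = synth.simulate_ratings(
            np.linspace(0, 60, 31), n_subjects=50, noise_sd=3.0, rng=1
        )
        assert r.min() >= 0 and r.max() <= 10
        assert r.dtype.kind == "i"

    def test_jury_simulation_deterministic_under_seed(self, consts):
        design = synth.jury_design().head(8)
        a = synth.simulate_jury(design, 5, 0.5, seed=9, constants=consts)
        b = synth.simulate_jury(design, 5, 0.5, seed=9, constants=consts)
        pd.testing.assert_frame_equal(a, b)

    def test_partial_rating_below_single_rating(self, consts):
        # masking lowers the rated source's loudness, hence its rating
        design = pd.DataFrame(
            {
                "condition": ["aircraft_alone", "aircraft_with_road"],
                "rated_source": ["aircraft", "aircraft"],
                "aircraft_dba": [68.0, 68.0],
                "road_dba": [np.nan, 75.0],
            }
        )
        loud = synth.condition_loudness(design, consts)
        assert loud[1] < loud[0]


@pytest.fixture(scope="module")
def grid():
    return synth.receiver_grid(nx=8, ny=8)


class TestSurvey:
    def test_seed_reproducibility(self, grid, consts):
        a = synth.simulate_survey(grid, seed=4, constants=consts)
        b = synth.simulate_survey(grid, seed=4, constants=consts)
        pd.testing.assert_frame_equal(a, b)

    def test_group_assignment_bounds(self, grid, consts):
        from parloud.mapping import exposure_group

        assert exposure_group(49.9) == "less than 50 dBA"
        assert exposure_group(70.1) == "Over 70 dBA"

    def test_indoor_corrections_applied(self, grid, consts):
        df = synth.simulate_survey(grid, seed=0, constants=consts)
        np.testing.assert_allclose(
            df.aircraft_outdoor_dba - df.aircraft_indoor_dba, 15.0
        )
        np.testing.assert_allclose(df.road_outdoor_dba - df.road_indoor_dba, 15.8)


class TestReceiverGrid:
    def test_cell_size_default_10m(self):
        grid = synth.receiver_grid(nx=5, ny=5)
        assert grid.cell_m == 10.0
        assert grid.shape == (5, 5)

    def test_road_axis_has_maximum_road_level(self):
        grid = synth.receiver_grid(nx=30, ny=10, road_x_m=105.0)
        col = np.argmax(grid.road_dba[0])
        assert abs((col + 0.5) * 10.0 - 105.0) <= 10.0

    def test_fixed_decay_per_distance_doubling(self):
        grid = synth.receiver_grid(
            nx=40, ny=1, road_x_m=5.0, road_decay_db_per_doubling=4.0,
            reference_m=10.0,
        )
        # cells 20 m and 40 m from the road axis differ by one doubling
        row = grid.road_dba[0]
        x = (np.arange(40) + 0.5) * 10.0
        i20, i40 = np.argmin(np.abs(x - 25.0)), np.argmin(np.abs(x - 45.0))
        assert row[i20] - row[i40] == pytest.approx(4.0, abs=0.01)

    def test_fields_smooth_and_bounded(self):
        grid = synth.receiver_grid(nx=20, ny=20)
        for layer in (grid.aircraft_dba, grid.road_dba):
            assert np.all(np.isfinite(layer))
            assert np.max(np.abs(np.diff(layer, axis=0))) < 10.0
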
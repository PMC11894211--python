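"""Synthetic scene generator: calendars, signatures, scenes, anomalies."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

import ricesar as rs
from ricesar.scene import RICE_MIN_DB_RANGE, RICE_PEAK_DB_RANGE, _sample_rice_params
from ricesar.stack import CLASS_CODES, SOS_SENTINEL


class TestGenerateCalendar:
    def test_nominal_2017_season(self):
        cal = rs.generate_calendar(dt.date(2017, 8, 9), 14, 12, 0.0, 0)
        assert len(cal) == 14
        assert cal.start == dt.date(2017, 8, 9)
        assert cal.end == dt.date(2018, 1, 12)

    def test_no_drop_is_arithmetic_sequence(self):
        d0 = dt.date(2020, 8, 5)
        cal = rs.generate_calendar(d0, 10, 12, 0.0, 3)
        assert [cal.offset_of(d) for d in cal.dates] == [12 * i for i in range(10)]

    def test_seed_determinism_with_drops(self):
        d0 = dt.date(2017, 8, 9)
        a = rs.generate_calendar(d0, 14, 12, 0.2, 42)
        b = rs.generate_calendar(d0, 14, 12, 0.2, 42)
        assert a.dates == b.dates

    def test_drops_preserve_cadence_multiples(self):
        cal = rs.generate_calendar(dt.date(2017, 8, 9), 16, 12, 0.25, 5)
        gaps = np.diff([d.toordinal() for d in cal.dates])
        assert np.all(gaps % 12 == 0)

    def test_insufficient_depth_rejected(self):
        with pytest.raises(ValueError, match="insufficient temporal depth"):
            rs.generate_calendar(dt.date(2017, 8, 9), 9, 12, 0.0, 0)


class TestRiceSignature:
    def test_noiseless_argmin_at_sos_acquisition(self, calendar_2017, rng):
        for _ in range(20):
            sos = calendar_2017.dates[rng.integers(2, 8)]
            m = rs.sample_rice_model(rng, sos)
            m = dataclasses.replace(m, noise_sd_db=0.0, speckle_looks=None)
            series = rs.simulate_rice_signature(m, calendar_2017)
            assert int(np.argmin(series)) == calendar_2017.nearest_index(sos)

    def test_seed_bitwise_repeatability(self, calendar_2017):
        m = rs.sample_rice_model(np.random.default_rng(0), dt.date(2017, 10, 8))
        a = rs.simulate_rice_signature(m, calendar_2017, seed=11)
        b = rs.simulate_rice_signature(m, calendar_2017, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_sos_outside_calendar_rejected(self, calendar_2017):
        m = rs.sample_rice_model(np.random.default_rng(0), dt.date(2018, 1, 10))
        with pytest.raises(ValueError, match="outside calendar span"):
            rs.simulate_rice_signature(m, calendar_2017)

    def test_prior_rise_mean_and_envelopes(self, rng):
        rise, peak, flood, pre, rise_days = _sample_rice_params(rng, 10_000, rs.RicePriors())
        assert abs(np.mean(peak - flood) - 5.07) < 0.2
        assert flood.min() >= RICE_MIN_DB_RANGE[0] and flood.max() <= RICE_MIN_DB_RANGE[1]
        assert peak.min() >= RICE_PEAK_DB_RANGE[0] and peak.max() <= RICE_PEAK_DB_RANGE[1]
        assert np.all(pre > flood)


class TestNonRiceSignature:
    def test_urban_constant(self, calendar_2017):
        s = rs.simulate_nonrice_signature("urban", calendar_2017)
        np.testing.assert_allclose(s, -8.0)

    def test_water_constant(self, calendar_2017):
        s = rs.simulate_nonrice_signature("water", calendar_2017)
        np.testing.assert_allclose(s, -22.0)

    def test_vegetation_range_below_rice_rise(self, calendar_2017, rng):
        for _ in range(20):
            s = rs.simulate_nonrice_signature("nonrice_veg", calendar_2017, rng)
            assert s.max() - s.min() < 2.69

    def test_unknown_kind_rejected(self, calendar_2017):
        with pytest.raises(ValueError, match="unknown non-rice class"):
            rs.simulate_nonrice_signature("forest", calendar_2017)


class TestBuildScene:
    def test_class_fractions_exact(self, small_scene):
        cfg, stack, truth = small_scene
        n = np.prod(cfg.grid_shape)
        for cname, frac in cfg.class_fractions.items():
            count = int((truth.class_raster == CLASS_CODES[cname]).sum())
            assert abs(count - frac * n) <= 0.01 * n

    def test_seed_determinism(self):
        cfg = rs.SceneConfig(grid_shape=(32, 32))
        s1, t1 = rs.build_scene(cfg, 99)
        s2, t2 = rs.build_scene(cfg, 99)
        np.testing.assert_array_equal(s1.values_db, s2.values_db)
        np.testing.assert_array_equal(t1.class_raster, t2.class_raster)
        np.testing.assert_array_equal(t1.sos_raster, t2.sos_raster)

    def test_sos_support_restricted_to_two_dates(self):
        cfg = rs.SceneConfig(
            grid_shape=(32, 32),
            sos_start=dt.date(2017, 9, 26),
            sos_end=dt.date(2017, 10, 8),
        )
        _, truth = rs.build_scene(cfg, 0)
        support = np.unique(truth.sos_raster[truth.rice_mask])
        assert set(support.tolist()) == {4, 5}  # 26 Sep and 8 Oct acquisitions

    def test_sos_defined_exactly_on_rice(self, small_scene):
        _, _, truth = small_scene
        assert np.all(truth.sos_raster[truth.rice_mask] >= 0)
        assert np.all(truth.sos_raster[~truth.rice_mask] == SOS_SENTINEL)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            rs.SceneConfig(class_fractions={"rice": 0.5, "water": 0.2})

    def test_districts_cover_all_pixels(self, small_scene):
        _, _, truth = small_scene
        assert truth.district_raster.min() >= 1
        assert len(np.unique(truth.district_raster)) == 5

    def test_noiseless_min_peak_pairs_inside_printed_rectangles(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        rice = truth.rice_mask
        v = stack.values_db[:, rice]
        mins, maxs = v.min(axis=0), v.max(axis=0)
        assert mins.min() >= RICE_MIN_DB_RANGE[0] - 1e-9
        assert mins.max() <= RICE_MIN_DB_RANGE[1] + 1e-9
        assert maxs.min() >= RICE_PEAK_DB_RANGE[0] - 1e-9
        assert maxs.max() <= RICE_PEAK_DB_RANGE[1] + 1e-9


class TestAtmosphericAnomalies:
    def test_zero_rate_leaves_stack_unchanged(self, small_scene):
        _, stack, _ = small_scene
        out, mask = rs.add_atmospheric_anomalies(stack, 0.0, 4.0, 0)
        np.testing.assert_array_equal(out.values_db, stack.values_db)
        assert mask.sum() == 0

    def test_anomaly_count_near_binomial_expectation(self):
        # 10 interior dates x 1000 pixels = 10^4 interior cells at rate 0.05.
        cfg = rs.SceneConfig(grid_shape=(25, 40), n_acquisitions=12)
        stack, _ = rs.build_scene(cfg, 0)
        out, mask = rs.add_atmospheric_anomalies(stack, 0.05, 4.0, 1)
        n_cells = (stack.n_dates - 2) * 25 * 40
        sigma = np.sqrt(n_cells * 0.05 * 0.95)
        assert abs(int(mask.sum()) - 0.05 * n_cells) <= 3 * sigma

    def test_anomalies_isolated_in_time(self, small_scene):
        _, stack, _ = small_scene
        _, mask = rs.add_atmospheric_anomalies(stack, 0.2, 4.0, 3)
        assert not np.any(mask[:-1] & mask[1:])
        assert not mask[0].any() and not mask[-1].any()

    def test_perturbation_is_plus_minus_magnitude(self, small_scene):
        _, stack, _ = small_scene
        out, mask = rs.add_atmospheric_anomalies(stack, 0.1, 4.0, 5)
        delta = out.values_db - stack.values_db
        np.testing.assert_allclose(np.abs(delta[mask]), 4.0)
        assert np.all(delta[~mask] == 0)
        assert (delta[mask] > 0).any() and (delta[mask] < 0).any()

    def test_invalid_rate_rejected(self, small_scene):
        _, stack, _ = small_scene
        with pytest.raises(ValueError, match="rate"):
            rs.add_atmospheric_anomalies(stack, 0.5, 4.0, 0)
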
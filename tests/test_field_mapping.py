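import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from vitisense.field_mapping import (
    MAP_CATALOG,
    SensorRecord,
    SurveyTrack,
    detrend_microclimate,
    export_maps,
    filter_extraneous,
    read_survey_log,
    sampling_interval,
    spatialize_idw,
    write_survey_log,
)
from vitisense.synthetic_data import VirtualCanopy, simulate_survey


def make_record(t=0.0, lat=45.1, lon=9.6, side="left", ci=500.0, **kw):
    defaults = dict(
        timestamp=t, latitude=lat, longitude=lon, side=side,
        ci_sectors=(ci,) * 15, st_sectors=(18.0,) * 16,
        rh=55.0, at=24.0, us=120.0, n_satellites=10,
    )
    defaults.update(kw)
    return SensorRecord(**defaults)


@pytest.fixture
def small_track():
    records = [
        make_record(t=float(i), lon=9.6 + i * 1e-5, side=side)
        for i in range(10)
        for side in ("left", "right")
    ]
    return SurveyTrack(sorted(records, key=lambda r: r.timestamp))


class TestSurveyLogIO:
    def test_round_trip_identity(self, small_track, tmp_path):
        path = tmp_path / "survey.csv"
        write_survey_log(small_track, path)
        back = read_survey_log(path)
        assert len(back) == len(small_track)
        for a, b in zip(small_track.records, back.records):
            assert a == b

    def test_missing_columns_listed(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"timestamp": [0.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="latitude"):
            read_survey_log(path)

    def test_corrupt_row_skipped(self, small_track, tmp_path, caplog):
        path = tmp_path / "survey.csv"
        write_survey_log(small_track, path)
        df = pd.read_csv(path)
        df.loc[3, "side"] = "sideways"
        df.to_csv(path, index=False)
        back = read_survey_log(path)
        assert len(back) == len(small_track) - 1

    def test_generator_log_record_count(self):
        canopies = [VirtualCanopy(vigor=1.0, seed=i) for i in range(24)]
        track = simulate_survey(canopies, n_rows=2, seed=4)
        assert len(track) == 48  # 24 vines x 2 sides

    def test_invalid_record_fields(self):
        with pytest.raises(ValueError):
            make_record(lat=95.0)
        with pytest.raises(ValueError):
            make_record(rh=120.0)
        with pytest.raises(ValueError):
            make_record(side="up")


class TestDetrendMicroclimate:
    def test_linear_ramp_becomes_constant_at_mean(self):
        t = np.arange(50, dtype=float)
        v = 2.0 * t + 10.0
        out = detrend_microclimate(t, v)
        np.testing.assert_allclose(out, np.full(50, v.mean()), atol=1e-9)

    def test_constant_passthrough(self):
        t = np.arange(20, dtype=float)
        v = np.full(20, 55.0)
        np.testing.assert_allclose(detrend_microclimate(t, v), v)

    def test_residual_trend_near_zero(self, rng):
        t = np.arange(500, dtype=float)
        v = 0.01 * t + 20 + rng.normal(0, 0.3, 500)
        out = detrend_microclimate(t, v)
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 1e-6

    def test_mean_preserved(self, rng):
        t = np.arange(100, dtype=float)
        v = 0.05 * t + rng.normal(0, 0.1, 100) + 40
        out = detrend_microclimate(t, v)
        # mean of the smoothed series is preserved by construction
        assert out.mean() == pytest.approx(v.mean(), abs=0.1)

    def test_too_few_points_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            out = detrend_microclimate([0, 1, 2], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(out, [1.0, 2.0, 3.0])


class TestFilterExtraneous:
    def test_homogeneous_track_untouched(self, small_track):
        out = filter_extraneous(small_track)
        assert len(out) == len(small_track)

    def test_outlier_side_dropped_partner_kept(self):
        records = []
        for i in range(11):
            ci = 0.0 if i == 5 else 600.0
            records.append(make_record(t=float(2 * i), side="left", ci=ci))
            records.append(make_record(t=float(2 * i) + 0.5, side="right", ci=600.0))
        track = SurveyTrack(records)
        out = filter_extraneous(track)
        lefts = [r for r in out.records if r.side == "left"]
        rights = [r for r in out.records if r.side == "right"]
        assert len(lefts) == 10  # the CI=0 poll dropped
        assert len(rights) == 11

    def test_boundary_excludes_headland(self, small_track):
        # polygon covering only the first half of the track longitudes
        boundary = Polygon([
            (9.59999, 45.09), (9.60005, 45.09), (9.60005, 45.11), (9.59999, 45.11),
        ])
        out = filter_extraneous(small_track, boundary=boundary)
        inside = [r for r in small_track.records if r.longitude <= 9.60005]
        assert len(out) == len(inside)
        assert len(out) < len(small_track)

    def test_never_invents_records(self, small_track):
        out = filter_extraneous(small_track)
        original = {id(r) for r in small_track.records}
        assert all(id(r) in original for r in out.records)


class TestSpatializeIdw:
    def test_single_sample_fills_in_radius_cells(self):
        r = spatialize_idw([5.0], [5.0], [42.0], cell_size=1.0, radius=100.0)
        vals = r.values[~np.isnan(r.values)]
        assert len(vals) > 0
        np.testing.assert_allclose(vals, 42.0)

    def test_equidistant_symmetry(self):
        # cell centered exactly between two samples of 10 and 20
        r = spatialize_idw([0.0, 10.0], [0.0, 0.0], [10.0, 20.0], cell_size=10.0,
                           padding=0.0)
        # the single-row grid has its center cell equidistant -> 15
        assert np.nanmin(r.values) >= 10.0 and np.nanmax(r.values) <= 20.0

    def test_exact_hit_takes_sample_value(self):
        # sample at a cell center: padding 0.5 + cell 1 -> centers on integers
        r = spatialize_idw([1.0, 4.0], [1.0, 1.0], [7.0, 99.0], cell_size=1.0,
                           padding=0.5)
        assert 7.0 in r.values

    def test_brute_force_oracle(self, rng):
        x = rng.uniform(0, 20, 15)
        y = rng.uniform(0, 20, 15)
        v = rng.uniform(0, 100, 15)
        r = spatialize_idw(x, y, v, cell_size=2.0, power=2.0)
        nrows, ncols = r.values.shape
        for i in range(nrows):
            for j in range(ncols):
                cx = r.origin_x + (j + 0.5) * r.cell_size
                cy = r.origin_y + (nrows - 1 - i + 0.5) * r.cell_size
                d = np.hypot(x - cx, y - cy)
                if np.any(d == 0):
                    expected = v[np.argmin(d)]
                else:
                    w = 1.0 / d**2
                    expected = (w * v).sum() / w.sum()
                assert r.values[i, j] == pytest.approx(expected, rel=1e-9)

    def test_output_within_input_range(self, rng):
        x, y = rng.uniform(0, 50, 30), rng.uniform(0, 50, 30)
        v = rng.uniform(100, 900, 30)
        r = spatialize_idw(x, y, v)
        assert np.nanmin(r.values) >= v.min() - 1e-9
        assert np.nanmax(r.values) <= v.max() + 1e-9

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            spatialize_idw([], [], [])

    def test_ascii_grid_export(self, tmp_path, rng):
        r = spatialize_idw(rng.uniform(0, 9, 5), rng.uniform(0, 9, 5),
                           rng.uniform(0, 1, 5))
        path = tmp_path / "map.asc"
        r.write_ascii_grid(path)
        text = path.read_text()
        assert text.startswith("ncols")
        assert "NODATA_value" in text


class TestSamplingInterval:
    def test_upper_speed_within_band(self):
        assert sampling_interval(8, 3) == pytest.approx(0.7407, abs=1e-3)
        assert 0.3 <= sampling_interval(8, 3) <= 0.8

    def test_lower_speed_within_band(self):
        assert sampling_interval(4, 3) == pytest.approx(0.3704, abs=1e-3)
        assert 0.3 <= sampling_interval(4, 3) <= 0.8

    def test_one_meter_case(self):
        assert sampling_interval(3.6, 1) == pytest.approx(1.0)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            sampling_interval(0, 3)
        with pytest.raises(ValueError):
            sampling_interval(5, -1)


class TestExportMaps:
    def test_single_ci_map(self, small_track, tmp_path):
        products = export_maps(small_track, tmp_path, selection=["CI"])
        assert set(products) == {"CI"}
        assert products["CI"].exists()

    def test_full_catalog_about_50_products(self, small_track, tmp_path):
        products = export_maps(small_track, tmp_path)
        assert len(products) == len(MAP_CATALOG)
        assert 44 <= len(products) <= 55
        assert (tmp_path / "gps_track.geojson").exists()

    def test_3d_canopy_index_not_implemented(self, small_track, tmp_path):
        with pytest.raises(NotImplementedError):
            export_maps(small_track, tmp_path, selection=["3D_CI"])

    def test_unknown_key_lists_catalog(self, small_track, tmp_path):
        with pytest.raises(KeyError, match="CI"):
            export_maps(small_track, tmp_path, selection=["bogus"])

    def test_vigor_gradient_visible_in_raster(self):
        lo = [VirtualCanopy(vigor=0.3, seed=i) for i in range(6)]
        hi = [VirtualCanopy(vigor=2.8, seed=100 + i) for i in range(6)]
        track = simulate_survey(lo + hi, n_rows=2, seed=1)
        x = np.array([r.longitude for r in track.records])
        from vitisense.field_mapping import _local_xy

        lx, ly = _local_xy(track)
        v = np.array([r.vine_ci for r in track.records])
        raster = spatialize_idw(lx, ly, v, cell_size=1.0)
        # low-vigor row is row 0 (south), high-vigor row 1 (north = top rows)
        nrows = raster.values.shape[0]
        top = np.nanmean(raster.values[: nrows // 2])
        bottom = np.nanmean(raster.values[nrows // 2:])
        assert top > bottom
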
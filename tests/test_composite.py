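import datetime as dt

import numpy as np
import pytest

import wetstage as ws
from wetstage.composite import (QuarterKey, assign_quarter, build_feature_table,
                                composite_by_quarter, default_schema,
                                quarterly_composite, trailing_climate_means)
from wetstage.geoio import LinkageError
from wetstage.grid import GridSpec, RasterBand, SceneStack

GRID = GridSpec(0.0, 30.0, 10.0, 3, 3, "t")


def scene(date, value, name="B4", nodata_at=None, units="reflectance",
          sensor="S2"):
    vals = np.full(GRID.shape, float(value))
    mask = np.zeros(GRID.shape, dtype=bool)
    if nodata_at is not None:
        mask[nodata_at] = True
        vals[nodata_at] = np.nan
    band = RasterBand(grid=GRID, name=name, values=vals, nodata_mask=mask,
                      units=units)
    return SceneStack(date=date, bands={name: band}, sensor=sensor)


class TestQuarterAssignment:
    @pytest.mark.parametrize("date,expect", [
        (dt.date(2021, 1, 1), QuarterKey(2021, 1)),
        (dt.date(2021, 3, 31), QuarterKey(2021, 1)),
        (dt.date(2021, 4, 1), QuarterKey(2021, 2)),
        (dt.date(2024, 12, 31), QuarterKey(2024, 4)),
        (dt.date(2022, 7, 15), QuarterKey(2022, 3)),
    ])
    def test_calendar_quarter_boundaries(self, date, expect):
        assert assign_quarter(date) == expect

    def test_quarter_ranges_are_half_open_and_exhaustive(self):
        day = dt.date(2021, 1, 1)
        while day.year == 2021:
            q = assign_quarter(day)
            assert q.contains(day)
            day += dt.timedelta(days=1)


class TestQuarterlyComposite:
    def test_mean_of_two_scenes(self):
        scenes = [scene(dt.date(2021, 1, 10), 0.2),
                  scene(dt.date(2021, 2, 10), 0.4)]
        comp = quarterly_composite(scenes, QuarterKey(2021, 1))
        np.testing.assert_allclose(comp["B4"].values, 0.3)
        assert comp.n_scenes["S2"] == 2

    def test_single_scene_identity(self):
        s = scene(dt.date(2021, 5, 1), 0.7)
        comp = quarterly_composite([s], QuarterKey(2021, 2))
        np.testing.assert_array_equal(comp["B4"].values, s.bands["B4"].values)

    def test_nodata_aware_mean_uses_valid_value(self):
        scenes = [scene(dt.date(2021, 1, 10), 0.2, nodata_at=(0, 0)),
                  scene(dt.date(2021, 2, 10), 0.4)]
        comp = quarterly_composite(scenes, QuarterKey(2021, 1))
        assert comp["B4"].values[0, 0] == pytest.approx(0.4)
        assert comp["B4"].values[1, 1] == pytest.approx(0.3)

    def test_all_nodata_pixel_stays_nodata(self):
        scenes = [scene(dt.date(2021, 1, 10), 0.2, nodata_at=(0, 0)),
                  scene(dt.date(2021, 2, 10), 0.4, nodata_at=(0, 0))]
        comp = quarterly_composite(scenes, QuarterKey(2021, 1))
        assert comp["B4"].nodata_mask[0, 0]

    def test_empty_quarter_raises(self):
        with pytest.raises(ValueError, match="no scenes"):
            quarterly_composite([scene(dt.date(2021, 5, 1), 0.2)],
                                QuarterKey(2021, 1))

    def test_scenes_outside_quarter_excluded(self):
        scenes = [scene(dt.date(2021, 3, 31), 0.2),
                  scene(dt.date(2021, 4, 1), 0.8)]
        comp = quarterly_composite(scenes, QuarterKey(2021, 1))
        np.testing.assert_allclose(comp["B4"].values, 0.2)

    def test_masked_mean_matches_loop_oracle(self):
        """Composite equals a per-pixel loop over valid scene values."""
        rng = np.random.default_rng(7)
        scenes = []
        for day in (5, 12, 20):
            vals = rng.uniform(0, 1, GRID.shape)
            mask = rng.uniform(size=GRID.shape) < 0.3
            vals[mask] = np.nan
            band = RasterBand(grid=GRID, name="B4", values=vals,
                              nodata_mask=mask, units="reflectance")
            scenes.append(SceneStack(date=dt.date(2021, 1, day),
                                     bands={"B4": band}, sensor="S2"))
        comp = quarterly_composite(scenes, QuarterKey(2021, 1))
        for r in range(GRID.n_rows):
            for c in range(GRID.n_cols):
                vals = [s.bands["B4"].values[r, c] for s in scenes
                        if not s.bands["B4"].nodata_mask[r, c]]
                if vals:
                    assert comp["B4"].values[r, c] == sum(vals) / len(vals)
                else:
                    assert comp["B4"].nodata_mask[r, c]

    def test_compositing_commutes_with_band_selection(self):
        rng = np.random.default_rng(9)
        scenes = []
        for day in (3, 17):
            bands = {
                n: RasterBand(grid=GRID, name=n,
                              values=rng.uniform(0, 1, GRID.shape),
                              units="reflectance")
                for n in ("B2", "B4")
            }
            scenes.append(SceneStack(date=dt.date(2021, 2, day), bands=bands,
                                     sensor="S2"))
        full = quarterly_composite(scenes, QuarterKey(2021, 1))
        only_b4 = [SceneStack(date=s.date, bands={"B4": s.bands["B4"]},
                              sensor="S2") for s in scenes]
        sel = quarterly_composite(only_b4, QuarterKey(2021, 1))
        np.testing.assert_array_equal(full["B4"].values, sel["B4"].values)

    def test_indices_derived_from_composited_bands(self, default_study):
        scenes = ws.sar_to_linear(default_study.scenes)
        comps = composite_by_quarter(scenes)
        comp = next(iter(comps.values()))
        b8, b4 = comp["B8"].values, comp["B4"].values
        np.testing.assert_allclose(comp["NDVI"].values, (b8 - b4) / (b8 + b4),
                                   rtol=1e-12)
        vv, vh = comp["VV"].values, comp["VH"].values
        np.testing.assert_allclose(comp["SRVI"].values, 4 * vv / (vv + vh),
                                   rtol=1e-12)


class TestFeatureTable:
    def test_default_study_yields_324_rows(self, default_study):
        s = default_study
        comps = composite_by_quarter(ws.sar_to_linear(s.scenes))
        table, schema = build_feature_table(
            s.samples, comps, {w.wetland_id: w for w in s.wetlands},
            climate=s.climate)
        assert len(table) == 324
        assert not table["flagged"].any()
        assert list(table.columns[-1:]) == ["flagged"]
        for f in schema.all_features:
            assert f in table.columns

    def test_linkage_error_lists_offenders(self, default_study):
        s = default_study
        comps = composite_by_quarter(ws.sar_to_linear(s.scenes))
        with pytest.raises(LinkageError, match="W99"):
            bad = [s.samples[0].__class__(**{**s.samples[0].__dict__,
                                             "wetland_id": "W99"})]
            build_feature_table(bad, comps, {w.wetland_id: w for w in s.wetlands})

    def test_missing_quarter_composite_is_linkage_error(self, default_study):
        s = default_study
        comps = composite_by_quarter(ws.sar_to_linear(s.scenes))
        (k, _), = [next(iter(comps.items()))]
        partial = {kk: c for kk, c in comps.items() if kk != k}
        with pytest.raises(LinkageError, match=k.label):
            build_feature_table(s.samples, partial,
                                {w.wetland_id: w for w in s.wetlands})

    def test_same_pixel_same_quarter_identical_continuous(self, default_study):
        s = default_study
        comps = composite_by_quarter(ws.sar_to_linear(s.scenes))
        wets = {w.wetland_id: w for w in s.wetlands}
        two = [s.samples[0], s.samples[0]]
        table, schema = build_feature_table(two, comps, wets, climate=s.climate)
        a, b = table.iloc[0], table.iloc[1]
        for f in schema.continuous:
            assert a[f] == b[f]

    def test_nodata_pixel_flags_row(self, default_study):
        s = default_study
        comps = composite_by_quarter(ws.sar_to_linear(s.scenes))
        # punch a nodata hole at the first sample's pixel in every band
        first = s.samples[0]
        qk = assign_quarter(first.date)
        comp = comps[qk]
        r, c = comp.grid.cell_of(first.x, first.y)
        for band in comp.bands.values():
            band.nodata_mask[r, c] = True
        table, _ = build_feature_table(s.samples, comps,
                                       {w.wetland_id: w for w in s.wetlands},
                                       climate=s.climate)
        assert bool(table.iloc[0]["flagged"])
        assert len(table) == 324  # flagged, not dropped

    def test_trailing_climate_mean_is_seven_day_window(self, default_study):
        clim = default_study.climate
        date = dt.date(2021, 6, 15)
        rain, temp = trailing_climate_means(clim, "W01", date)
        end = np.datetime64(date)
        window = clim[(clim["wetland_id"] == "W01")
                      & (clim["date"] > np.datetime64(date) - np.timedelta64(7, "D"))
                      & (clim["date"] <= end)]
        assert len(window) == 7
        assert rain == pytest.approx(window["rain_mm"].mean())
        assert temp == pytest.approx(window["temp_F"].mean())
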
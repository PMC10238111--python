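"""Empirical-line calibration, DSM-differenced canopy height, zonal stats."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from ricepam.calibration import (
    DEFAULT_PANEL_LADDER,
    CalibrationPanelSet,
    EmpiricalLineCalibrator,
    PlotROI,
    Raster,
    apply_empirical_line,
    canopy_height,
    fit_empirical_line,
    load_rois,
    read_ascii_grid,
    write_ascii_grid,
    zonal_mean,
    zonal_table,
)
from ricepam.errors import (
    DegeneratePanelError,
    EmptyROIError,
    GridMismatchError,
    RicePamError,
)


def _ols_line(x, y):
    """Closed-form OLS slope/intercept oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return slope, y.mean() - slope * x.mean()


class TestEmpiricalLine:
    def test_exact_two_point_line(self):
        model = fit_empirical_line(
            CalibrationPanelSet(800, ((10.0, 0.10), (20.0, 0.20)))
        )
        assert model.gain_ == pytest.approx(0.01, abs=1e-12)
        assert model.offset_ == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generating_line_from_8_panels(self):
        # DN = 1000*R + 50 exactly, so R = 0.001*DN - 0.05
        records = tuple((1000.0 * r + 50.0, r) for r in DEFAULT_PANEL_LADDER)
        model = fit_empirical_line(CalibrationPanelSet(670, records))
        assert model.gain_ == pytest.approx(0.001, abs=1e-10)
        assert model.offset_ == pytest.approx(-0.05, abs=1e-10)

    def test_noisy_fit_matches_closed_form_ols(self, rng):
        dn = rng.uniform(100, 4000, 20)
        refl = 2e-4 * dn + 0.01 + rng.normal(0, 0.01, 20)
        model = EmpiricalLineCalibrator().fit(dn, refl)
        slope, intercept = _ols_line(dn, refl)
        assert model.gain_ == pytest.approx(slope, abs=1e-10)
        assert model.offset_ == pytest.approx(intercept, abs=1e-10)

    def test_degenerate_panels_rejected(self):
        with pytest.raises(DegeneratePanelError):
            fit_empirical_line(CalibrationPanelSet(670, ((50.0, 0.1), (50.0, 0.2))))
        with pytest.raises(RicePamError):
            CalibrationPanelSet(670, ((50.0, 0.1),))

    def test_negative_gain_warns(self):
        with pytest.warns(UserWarning, match="gain"):
            EmpiricalLineCalibrator().fit([10, 20, 30], [0.3, 0.2, 0.1])

    def test_apply_uniform_grid(self):
        model = EmpiricalLineCalibrator().fit([0, 1000], [0.0, 2.0])
        grid = Raster(np.full((3, 4), 100.0))
        out, n_clipped = apply_empirical_line(model, grid)
        assert np.allclose(out.data, 0.2)
        assert n_clipped == 0

    def test_apply_preserves_nodata_and_counts_clips(self):
        model = EmpiricalLineCalibrator().fit([0, 1000], [0.0, 2.0])
        grid = Raster(np.array([[100.0, -9999.0], [1e6, 200.0]]))
        out, n_clipped = apply_empirical_line(model, grid)
        assert out.data[0, 1] == -9999.0      # nodata in, nodata out
        assert out.data[1, 0] == 1.5          # clipped, not 2000
        assert n_clipped == 1

    @given(gain=st.floats(1e-5, 1e-2), offset=st.floats(-0.2, 0.2))
    def test_roundtrip_on_collinear_panels(self, gain, offset):
        """fit then transform on the panel DNs reproduces the reflectances."""
        refl = np.array(DEFAULT_PANEL_LADDER)
        dn = (refl - offset) / gain
        model = EmpiricalLineCalibrator().fit(dn, refl)
        assert np.allclose(model.transform(dn), refl, atol=1e-9)


class TestCanopyHeight:
    def test_basic_difference(self):
        dsm = Raster(np.array([[1.25, 0.45]]))
        soil = Raster(np.array([[0.45, 0.45]]))
        out, n_clamped = canopy_height(dsm, soil)
        assert out.data[0, 0] == pytest.approx(0.80)
        assert out.data[0, 1] == 0.0
        assert n_clamped == 0

    def test_negative_clamped_and_counted(self):
        out, n_clamped = canopy_height(
            Raster(np.array([[0.40]])), Raster(np.array([[0.45]]))
        )
        assert out.data[0, 0] == 0.0
        assert n_clamped == 1

    def test_nodata_propagates(self):
        dsm = Raster(np.array([[1.0, -9999.0]]))
        soil = Raster(np.array([[-9999.0, 0.5]]))
        out, _ = canopy_height(dsm, soil)
        assert (out.data == -9999.0).all()

    def test_antisymmetric_up_to_clamping(self, rng):
        a = Raster(rng.uniform(0, 2, (5, 5)))
        b = Raster(rng.uniform(0, 2, (5, 5)))
        ab, n_ab = canopy_height(a, b)
        ba, n_ba = canopy_height(b, a)
        diff = a.data - b.data
        assert np.allclose(ab.data, np.maximum(diff, 0))
        assert np.allclose(ba.data, np.maximum(-diff, 0))
        assert n_ab + n_ba == np.count_nonzero(diff != 0)

    def test_misaligned_grids_rejected(self):
        with pytest.raises(GridMismatchError, match="mismatch"):
            canopy_height(Raster(np.zeros((2, 2))), Raster(np.zeros((3, 2))))
        with pytest.raises(GridMismatchError):
            canopy_height(
                Raster(np.zeros((2, 2)), origin=(0, 0)),
                Raster(np.zeros((2, 2)), origin=(1, 0)),
            )


class TestZonal:
    def grid(self, data, **kw):
        return Raster(np.asarray(data, float), origin=(0.0, 2.0), cellsize=1.0, **kw)

    def test_uniform_grid_any_polygon(self):
        g = self.grid(np.full((2, 3), 7.5))
        mean, n = zonal_mean(g, PlotROI("A", box(0, 0, 3, 2)))
        assert mean == 7.5 and n == 6

    def test_mean_skips_nodata(self):
        g = self.grid([[1.0, 2.0], [3.0, -9999.0]])
        mean, n = zonal_mean(g, PlotROI("A", box(0, 0, 2, 2)))
        assert mean == pytest.approx(2.0)
        assert n == 3

    def test_polygon_outside_extent(self):
        g = self.grid(np.ones((2, 2)))
        with pytest.raises(EmptyROIError):
            zonal_mean(g, PlotROI("A", box(10, 10, 12, 12)))

    def test_cell_center_rule(self):
        # polygon covers only the left column's centers (x = 0.5)
        g = self.grid([[1.0, 5.0], [3.0, 5.0]])
        mean, n = zonal_mean(g, PlotROI("A", box(0, 0, 0.9, 2)))
        assert (mean, n) == (2.0, 2)

    def test_translation_invariance(self, rng):
        data = rng.uniform(0, 1, (4, 4))
        poly = Polygon([(0.2, 0.2), (3.1, 0.4), (2.5, 3.6)])
        base = zonal_mean(Raster(data, origin=(0, 4)), PlotROI("A", poly))
        shifted = zonal_mean(
            Raster(data, origin=(100, 54)),
            PlotROI("A", Polygon([(x + 100, y + 50) for x, y in poly.exterior.coords])),
        )
        assert base == shifted

    def test_zonal_table_and_roi_loading(self):
        g = self.grid([[1.0, 2.0], [3.0, 4.0]])
        geojson = {
            "type": "FeatureCollection",
            "features": [{
                "type": "Feature",
                "properties": {"plot_id": "P01"},
                "geometry": {"type": "Polygon",
                             "coordinates": [[[0, 0], [2, 0], [2, 2], [0, 2], [0, 0]]]},
            }],
        }
        table = zonal_table(g, load_rois(geojson), "mean_height_m")
        assert table.loc[0, "plot_id"] == "P01"
        assert table.loc[0, "mean_height_m"] == pytest.approx(2.5)
        assert table.loc[0, "n_valid"] == 4

    def test_roi_requires_plot_id(self):
        bad = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {},
             "geometry": {"type": "Point", "coordinates": [0, 0]}}]}
        with pytest.raises(RicePamError, match="plot_id"):
            load_rois(bad)


def test_ascii_grid_roundtrip(tmp_path, rng):
    grid = Raster(rng.uniform(0, 3, (4, 6)), origin=(500.0, 260.0),
                  cellsize=0.5, nodata=-1.0)
    grid.data[1, 2] = -1.0
    path = tmp_path / "g.asc"
    write_ascii_grid(grid, path)
    back = read_ascii_grid(path)
    assert np.array_equal(back.data, grid.data)
    assert back.origin == grid.origin
    assert back.cellsize == grid.cellsize
    assert back.nodata == grid.nodata
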
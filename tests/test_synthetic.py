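"""Ground-truth geometry, localization sampling, and rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from desmomap.errors import DataError, GeometryError
from desmomap.synthetic import (
    SimulationParams,
    make_junction,
    render,
    sample_localizations,
)


class TestMakeJunction:
    def test_axis_aligned_plaques_at_half_separation(self):
        j = make_junction(192, 400, 0.0, (0, 0), 15)
        lines = j.plaque_centers()
        assert sorted(lines[:, 1]) == [-96.0, 96.0]
        assert np.allclose(lines[:, 0], 0.0)

    def test_rotation_preserves_separation(self):
        j = make_junction(118, 400, 37.0, (0, 0), 15)
        lines = j.plaque_centers()
        # distance between the parallel lines measured along the normal
        d = abs(np.dot(lines[0] - lines[1], j.normal))
        assert d == pytest.approx(118.0)

    @pytest.mark.parametrize(
        "separation,length", [(0, 400), (-5, 400), (100, 0), (100, -1)]
    )
    def test_degenerate_geometry_rejected(self, separation, length):
        with pytest.raises(GeometryError):
            make_junction(separation, length)

    @given(
        separation=st.floats(10, 400),
        length=st.floats(50, 2000),
        orientation=st.floats(0, 360),
    )
    @settings(max_examples=50, deadline=None)
    def test_mirror_symmetric_construction(self, separation, length, orientation):
        j = make_junction(separation, length, orientation)
        lines = j.plaque_centers()
        mid = lines.mean(axis=0)
        assert np.allclose(mid, j.center, atol=1e-9)
        assert abs(np.dot(lines[0] - lines[1], j.normal)) == pytest.approx(separation)


class TestSampleLocalizations:
    def test_noise_free_points_lie_on_plaque_lines(self):
        j = make_junction(192, 400, 25.0, (500, 500), plaque_thickness=0)
        p = SimulationParams(localization_precision=0, background_density=0, seed=3)
        table = sample_localizations(j, p)
        xy = table[["x_nm", "y_nm"]].to_numpy() - np.asarray(j.center)
        transverse = xy @ j.normal
        assert np.allclose(np.abs(transverse), 96.0, atol=1e-9)

    def test_mirror_symmetry_of_noise_free_table(self):
        """Reflecting plaque-1 localizations across the midline lands them on
        the plaque-2 line."""
        j = make_junction(150, 400, 40.0, (0, 0), plaque_thickness=0)
        p = SimulationParams(localization_precision=0, background_density=0, seed=7)
        table = sample_localizations(j, p)
        xy = table[["x_nm", "y_nm"]].to_numpy()
        p1 = xy[table["source"] == 1]
        reflected = p1 - 2 * (p1 @ j.normal)[:, None] * j.normal[None, :]
        assert np.allclose(reflected @ j.normal, -75.0, atol=1e-9)

    def test_determinism_same_seed_identical_tables(self):
        j = make_junction(118, 400, 10.0)
        p = SimulationParams(seed=42)
        t1, t2 = sample_localizations(j, p), sample_localizations(j, p)
        pd.testing.assert_frame_equal(t1, t2)

    def test_rms_localization_displacement_matches_precision(self):
        """Isotropic N(0, 15²) noise per axis gives a radial RMS of 15·√2."""
        j = make_junction(192, 400, 0.0, plaque_thickness=0)
        p = SimulationParams(
            localization_precision=15, localizations_per_plaque=200,
            background_density=0, seed=11,
        )
        table, truth = sample_localizations(j, p, return_truth=True)
        disp = table[["x_nm", "y_nm"]].to_numpy() - truth
        rms = np.sqrt((disp**2).sum(axis=1).mean())
        assert rms == pytest.approx(15 * np.sqrt(2), rel=0.10)

    def test_background_count_is_poisson_with_expected_mean(self):
        """density 5/µm² over a 4 µm² field → counts ~ Poisson(20)."""
        j = make_junction(192, 400)
        counts = [
            (
                sample_localizations(
                    j,
                    SimulationParams(
                        localizations_per_plaque=0, background_density=5,
                        field_size=2000, seed=s,
                    ),
                )
            ).shape[0]
            for s in range(200)
        ]
        mean = np.mean(counts)
        se = np.sqrt(20 / 200)  # Poisson variance = mean
        assert abs(mean - 20) < 2 * se * 2  # 2 s.e. with slack for var estimate
        assert np.var(counts) == pytest.approx(20, rel=0.35)

    def test_zero_counts_give_empty_table(self):
        j = make_junction(100, 300)
        p = SimulationParams(localizations_per_plaque=0, background_density=0)
        assert len(sample_localizations(j, p)) == 0


class TestRender:
    def test_single_localization_single_pixel(self):
        t = pd.DataFrame({"x_nm": [0.0], "y_nm": [0.0], "precision_nm": [10.0]})
        img = render(t, 4.0, "histogram", origin=(-20, -20), shape=(10, 10))
        assert (img.data > 0).sum() == 1
        assert img.data.max() == 1.0

    def test_two_localizations_192nm_apart_are_48_rows_apart(self):
        t = pd.DataFrame({"x_nm": [50.0, 50.0], "y_nm": [10.0, 202.0], "precision_nm": [0, 0]})
        img = render(t, 4.0, "histogram", origin=(0, 0), shape=(60, 30))
        rows = np.flatnonzero(img.data.sum(axis=1))
        assert rows[1] - rows[0] == 48

    def test_empty_table_renders_zero_image(self):
        t = pd.DataFrame({"x_nm": [], "y_nm": [], "precision_nm": []})
        img = render(t, 4.0, "histogram", origin=(0, 0), shape=(5, 8))
        assert img.data.shape == (5, 8)
        assert img.data.sum() == 0

    @pytest.mark.parametrize("mode", ["histogram", "gaussian"])
    def test_interior_rendering_conserves_counts(self, mode):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(
            {
                "x_nm": rng.uniform(200, 800, 100),
                "y_nm": rng.uniform(200, 800, 100),
                "precision_nm": np.full(100, 12.0),
            }
        )
        img = render(t, 4.0, mode, origin=(0, 0), shape=(250, 250))
        assert img.data.sum() == pytest.approx(100, rel=1e-4)

    def test_invalid_pixel_size(self):
        with pytest.raises(DataError):
            render(pd.DataFrame({"x_nm": [0], "y_nm": [0], "precision_nm": [0]}), 0)
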
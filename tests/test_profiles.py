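import numpy as np
import pytest

from mpod.errors import ExtrapolationError, OutOfBoundsError, ProfileParseError
from mpod.models import eval_model
from mpod.profiles import (MPODMap, RadialProfile, default_radii,
                           extract_radial_profile, read_map, read_profile,
                           resample_profile, write_map, write_profile)
from mpod.simulate import render_map


class TestReadProfile:
    def test_plain_three_rows(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("0,0.6\n1,0.3\n2,0.1\n")
        prof = read_profile(path)
        assert len(prof) == 3
        np.testing.assert_allclose(prof.mpod, [0.6, 0.3, 0.1])

    def test_rows_sorted_ascending(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("2,0.1\n0,0.6\n1,0.3\n")
        prof = read_profile(path)
        np.testing.assert_allclose(prof.ecc, [0, 1, 2])
        np.testing.assert_allclose(prof.mpod, [0.6, 0.3, 0.1])

    def test_duplicate_eccentricities_averaged(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("0.5,0.2\n0.5,0.4\n1.0,0.1\n")
        prof = read_profile(path)
        assert len(prof) == 2
        assert prof.mpod[0] == pytest.approx(0.3)

    def test_header_detected(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("ecc_deg,mpod\n0,0.6\n1,0.3\n")
        assert len(read_profile(path)) == 2

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("0,0.6\n1,oops\n")
        with pytest.raises(ProfileParseError, match="row 2"):
            read_profile(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("")
        with pytest.raises(ProfileParseError, match="empty"):
            read_profile(path)


class TestWriteProfile:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        prof = RadialProfile(np.sort(rng.uniform(0, 5, 30)) + np.arange(30) * 1e-6,
                             rng.uniform(0, 1, 30), rng.uniform(0, 0.1, 30))
        path = tmp_path / "p.csv"
        write_profile(prof, path)
        back = read_profile(path)
        np.testing.assert_allclose(back.ecc, prof.ecc, rtol=1e-8)
        np.testing.assert_allclose(back.mpod, prof.mpod, rtol=1e-8)
        np.testing.assert_allclose(back.sd, prof.sd, rtol=1e-8)

    def test_sd_column_omitted_when_absent(self, tmp_path):
        prof = RadialProfile([0.0, 1.0], [0.5, 0.2])
        path = tmp_path / "p.csv"
        write_profile(prof, path)
        assert path.read_text().splitlines()[0] == "ecc_deg,mpod"
        assert read_profile(path).sd is None


class TestValidation:
    def test_non_increasing_ecc_rejected(self):
        with pytest.raises(ValueError):
            RadialProfile([0.0, 1.0, 1.0], [1, 2, 3])

    def test_negative_ecc_rejected(self):
        with pytest.raises(ValueError):
            RadialProfile([-0.5, 1.0], [1, 2])

    def test_map_scale_positive(self):
        with pytest.raises(ValueError):
            MPODMap(np.zeros((4, 4)), (1, 1), 0.0)

    def test_map_center_inside(self):
        with pytest.raises(OutOfBoundsError):
            MPODMap(np.zeros((4, 4)), (10, 1), 0.1)


class TestExtraction:
    def test_constant_map(self):
        mp = MPODMap(np.full((64, 64), 0.42), (31.5, 31.5), 0.05)
        prof = extract_radial_profile(mp, [0.2, 0.5, 1.0], n_angles=90)
        np.testing.assert_allclose(prof.mpod, 0.42, rtol=1e-12)
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-12)

    def test_rendered_model_recovered(self, grand_mean_curve):
        mp = render_map(grand_mean_curve.params, size_px=(512, 512), scale=0.02)
        radii = default_radii(0.1, 4.0, 0.1)
        prof = extract_radial_profile(mp, radii)
        np.testing.assert_allclose(prof.mpod, eval_model(grand_mean_curve, radii),
                                   atol=1e-3)
        assert np.all(prof.sd >= 0)
        assert np.all(prof.sd < 1e-3)

    def test_rotation_invariance_on_symmetric_map(self, grand_mean_curve):
        mp = render_map(grand_mean_curve.params, size_px=(201, 201), scale=0.05)
        rotated = MPODMap(np.rot90(mp.pixels).copy(), mp.center, mp.scale)
        radii = [0.5, 1.0, 2.0]
        a = extract_radial_profile(mp, radii)
        b = extract_radial_profile(rotated, radii)
        np.testing.assert_allclose(a.mpod, b.mpod, rtol=1e-10)

    def test_radius_zero_is_centre_value(self):
        mp = MPODMap(np.arange(16.0).reshape(4, 4), (1.0, 2.0), 0.1)
        prof = extract_radial_profile(mp, [0.0], n_angles=8)
        assert prof.mpod[0] == pytest.approx(6.0)
        assert prof.sd[0] == 0.0

    def test_out_of_bounds_radius_reported(self):
        mp = MPODMap(np.zeros((64, 64)), (31.5, 31.5), 0.05)
        with pytest.raises(OutOfBoundsError, match="radius 3"):
            extract_radial_profile(mp, [3.0])

    def test_map_write_read_round_trip(self, tmp_path, grand_mean_curve):
        mp = render_map(grand_mean_curve.params, size_px=(64, 64), scale=0.05)
        path = tmp_path / "map.tif"
        write_map(mp, path)
        back = read_map(path)
        np.testing.assert_allclose(back.pixels, mp.pixels, atol=1e-6)
        assert back.center == mp.center
        assert back.scale == mp.scale


class TestResample:
    def test_identity_on_own_grid(self):
        prof = RadialProfile([0.0, 0.5, 1.0], [0.6, 0.4, 0.2], [0.1, 0.1, 0.1])
        out = resample_profile(prof, prof.ecc)
        np.testing.assert_allclose(out.mpod, prof.mpod)
        np.testing.assert_allclose(out.sd, prof.sd)

    def test_midpoint_linear(self):
        prof = RadialProfile([0.0, 1.0], [0.4, 0.2])
        out = resample_profile(prof, [0.5])
        assert out.mpod[0] == pytest.approx(0.3)

    def test_dense_grid_recovers_linear_profile(self):
        ecc = np.array([0.0, 1.0, 2.0, 3.0])
        prof = RadialProfile(ecc, 1.0 - 0.2 * ecc)
        grid = np.linspace(0.0, 3.0, 61)
        out = resample_profile(prof, grid)
        np.testing.assert_allclose(out.mpod, 1.0 - 0.2 * grid, rtol=1e-12)

    def test_extrapolation_rejected(self):
        prof = RadialProfile([0.5, 1.0], [0.4, 0.2])
        with pytest.raises(ExtrapolationError):
            resample_profile(prof, [0.0, 0.7])
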
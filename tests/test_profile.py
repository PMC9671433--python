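import numpy as np
import pytest
from scipy import integrate

import vesselflow as vf
from vesselflow.exceptions import FitError


def make_profile(radii, speeds, n_valid=None):
    if n_valid is None:
        n_valid = np.full(len(radii), 10)
    return vf.VelocityProfile(np.asarray(radii, float), np.asarray(speeds, float),
                              np.asarray(n_valid))


def bluntness_model(r, v_max, radius, k):
    return v_max * (1.0 - (np.abs(r) / radius) ** k)


def disc_mean_velocity(v_max, radius, k):
    """Oracle: numerical integration of V over the circular cross-section."""
    num, _ = integrate.quad(
        lambda r: bluntness_model(r, v_max, radius, k) * 2 * np.pi * r, 0, radius
    )
    return num / (np.pi * radius**2)


class TestAverageProfiles:
    def make_field(self, speed, valid=None):
        speed = np.asarray(speed, float)
        if valid is None:
            valid = np.isfinite(speed)
        n_pairs, n_rows, n_cols = speed.shape
        mesh = vf.PIVMesh(
            row_centers=np.linspace(10, 10 + n_rows - 1, n_rows),
            col_centers=np.linspace(0, n_cols - 1, n_cols),
            window_size=4, overlap_fraction=0.0,
            centerline_row=10 + (n_rows - 1) / 2,
            lumen_height=float(n_rows), wall_top=10.0,
            wall_bottom=10.0 + n_rows - 1,
        )
        field = vf.VelocityField(
            frame_pairs=[(k, k + 1) for k in range(n_pairs)],
            displacement=np.zeros(speed.shape + (2,)),
            peak_correlation=np.ones_like(speed),
            speed=np.nan_to_num(speed),
            valid=np.asarray(valid, bool),
            reason=np.zeros(speed.shape, dtype=np.int8),
            mesh=mesh,
        )
        return field, mesh

    def test_row_proportional_speeds(self, calibration):
        speed = np.zeros((3, 4, 2))
        for i in range(4):
            speed[:, i, :] = 100.0 * i
        field, mesh = self.make_field(speed)
        prof = vf.average_profiles(field, mesh, calibration)
        np.testing.assert_allclose(prof.speeds, [0, 100, 200, 300])

    def test_shifted_column_moves_mean_by_fifth(self, calibration):
        speed = np.full((2, 3, 5), 100.0)
        speed[:, :, 2] += 10.0
        field, mesh = self.make_field(speed)
        prof = vf.average_profiles(field, mesh, calibration)
        np.testing.assert_allclose(prof.speeds, 102.0)

    def test_row_with_no_valid_vectors_flagged_missing(self, calibration):
        speed = np.full((2, 3, 2), 50.0)
        valid = np.ones_like(speed, bool)
        valid[:, 1, :] = False
        field, mesh = self.make_field(speed, valid)
        prof = vf.average_profiles(field, mesh, calibration)
        assert list(prof.missing) == [False, True, False]

    def test_radial_positions_signed_about_centerline(self, calibration):
        speed = np.full((1, 5, 1), 10.0)
        field, mesh = self.make_field(speed)
        prof = vf.average_profiles(field, mesh, calibration)
        np.testing.assert_allclose(
            prof.radial_positions,
            (mesh.row_centers - mesh.centerline_row) * calibration.pixel_size,
        )
        assert prof.radial_positions[0] == -prof.radial_positions[-1]


class TestFitProfile:
    def test_exact_parabola_recovered(self):
        r = np.linspace(-24, 24, 15)
        v = bluntness_model(r, 800.0, 25.0, 2.0)
        fit = vf.fit_profile(make_profile(r, v), radius_R=25.0)
        assert fit.v_max == pytest.approx(800.0, rel=1e-6)
        assert fit.bluntness_k == pytest.approx(2.0, abs=1e-5)

    def test_blunt_k4_recovered(self):
        r = np.linspace(-24, 24, 15)
        v = bluntness_model(r, 1200.0, 25.0, 4.0)
        fit = vf.fit_profile(make_profile(r, v), radius_R=25.0)
        assert fit.bluntness_k == pytest.approx(4.0, abs=0.01)

    @pytest.mark.parametrize("k_true", [0.8, 1.5, 3.0, 6.0])
    def test_recovery_across_k(self, k_true):
        r = np.linspace(-20, 20, 13)
        v = bluntness_model(r, 1000.0, 22.0, k_true)
        fit = vf.fit_profile(make_profile(r, v), radius_R=22.0)
        assert fit.bluntness_k == pytest.approx(k_true, abs=1e-4)

    def test_scale_equivariance(self):
        r = np.linspace(-20, 20, 13)
        v = bluntness_model(r, 1000.0, 22.0, 2.5)
        f1 = vf.fit_profile(make_profile(r, v), radius_R=22.0)
        f2 = vf.fit_profile(make_profile(r, 3.7 * v), radius_R=22.0)
        assert f2.bluntness_k == pytest.approx(f1.bluntness_k, abs=1e-6)
        assert f2.v_max == pytest.approx(3.7 * f1.v_max, rel=1e-6)

    def test_monotone_in_generative_k(self):
        r = np.linspace(-20, 20, 13)
        fitted = [
            vf.fit_profile(
                make_profile(r, bluntness_model(r, 900.0, 22.0, k)), 22.0
            ).bluntness_k
            for k in [1.0, 2.0, 3.0, 5.0]
        ]
        assert all(a < b for a, b in zip(fitted, fitted[1:]))

    def test_noise_replicates_median_within_tolerance(self):
        r = np.linspace(-22, 22, 15)
        clean = bluntness_model(r, 1000.0, 25.0, 2.0)
        rng = np.random.default_rng(42)
        ks = []
        for _ in range(100):
            noisy = clean * (1 + 0.05 * rng.normal(size=clean.shape))
            ks.append(vf.fit_profile(make_profile(r, noisy), 25.0).bluntness_k)
        assert abs(np.median(ks) - 2.0) <= 0.2

    def test_beyond_wall_rows_clamped_with_warning(self):
        r = np.linspace(-26, 26, 15)  # outermost beyond R=25
        v = bluntness_model(np.clip(r, -24.9, 24.9), 700.0, 25.0, 2.0)
        with pytest.warns(UserWarning, match="clamped"):
            fit = vf.fit_profile(make_profile(r, v), radius_R=25.0)
        assert fit.bluntness_k > 0

    def test_flat_zero_profile_raises(self):
        r = np.linspace(-20, 20, 13)
        with pytest.raises(FitError):
            vf.fit_profile(make_profile(r, np.zeros_like(r)), radius_R=22.0)

    def test_too_few_rows_raises(self):
        with pytest.raises(FitError):
            vf.fit_profile(make_profile([0, 1, 2], [5, 4, 3]), radius_R=10.0)


class TestMeanVelocityAndFlow:
    def make_fit(self, v_max, k, radius):
        mean_v = v_max * k / (k + 2)
        return vf.ProfileFit(v_max=v_max, radius_R=radius, bluntness_k=k,
                             rss=0.0, mean_velocity=mean_v,
                             flow=mean_v * np.pi * radius**2)

    def test_parabolic_closed_form(self):
        mean_v, _ = vf.mean_velocity_and_flow(self.make_fit(1000.0, 2.0, 12.5))
        assert mean_v == pytest.approx(500.0)

    def test_k4_against_disc_integration(self):
        mean_v, flow = vf.mean_velocity_and_flow(self.make_fit(1000.0, 4.0, 12.5))
        assert mean_v == pytest.approx(1000 * 4 / 6)
        oracle = disc_mean_velocity(1000.0, 12.5, 4.0)
        assert mean_v == pytest.approx(oracle, rel=1e-9)
        assert flow == pytest.approx(oracle * np.pi * 12.5**2, rel=1e-9)

    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_matches_numerical_integration(self, k):
        mean_v, _ = vf.mean_velocity_and_flow(self.make_fit(873.0, k, 14.0))
        assert mean_v == pytest.approx(disc_mean_velocity(873.0, 14.0, k),
                                       rel=1e-6)

    def test_plug_flow_limit(self):
        mean_v, _ = vf.mean_velocity_and_flow(self.make_fit(1000.0, 1e6, 10.0))
        assert mean_v == pytest.approx(1000.0, rel=1e-5)
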
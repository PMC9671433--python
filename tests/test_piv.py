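import numpy as np
import pytest

import vesselflow as vf
from vesselflow.exceptions import MatchError, MeshError

from conftest import band_mask


def naive_ncc(template, search):
    """Independent oracle: literal double-loop normalized cross-correlation."""
    th, tw = template.shape
    sh, sw = search.shape
    t = template.astype(np.float64)
    gamma = np.full((sh - th + 1, sw - tw + 1), np.nan)
    for u in range(sh - th + 1):
        for v in range(sw - tw + 1):
            win = search[u : u + th, v : v + tw].astype(np.float64)
            dt = t - t.mean()
            dw = win - win.mean()
            den = np.sqrt((dt * dt).sum() * (dw * dw).sum())
            if den > 0:
                gamma[u, v] = (dt * dw).sum() / den
    return gamma


def gamma_surface(template, search):
    """Package gamma surface via ncc_match internals (argmax checked apart)."""
    from numpy.lib.stride_tricks import sliding_window_view

    t = template.astype(np.float64)
    s = search.astype(np.float64)
    tc = t - t.mean()
    windows = sliding_window_view(s, t.shape)
    wc = windows - windows.mean(axis=(2, 3), keepdims=True)
    w_norm = np.sqrt((wc * wc).sum(axis=(2, 3)))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.einsum("ijkl,kl->ij", wc, tc) / (w_norm * np.sqrt((tc * tc).sum()))
    g[w_norm == 0] = np.nan
    return g


class TestBuildMesh:
    def test_degenerate_height_rows_coincide(self):
        mask = np.zeros((60, 80), dtype=bool)
        mask[20:40] = True  # height exactly 20
        mesh = vf.build_mesh(mask, window_size=20)
        assert np.allclose(mesh.row_centers, mesh.row_centers[0])
        assert mesh.overlap_fraction == 0.95  # clamped

    def test_row_spacing_formula(self):
        mask = np.zeros((120, 100), dtype=bool)
        mask[20:100] = True  # height 80
        mesh = vf.build_mesh(mask, n_rows=15, window_size=20)
        spacing = np.diff(mesh.row_centers)
        np.testing.assert_allclose(spacing, (80 - 20) / 14)
        # overlap derived from lumen height
        assert mesh.overlap_fraction == pytest.approx(1 - 60 / (14 * 20))

    def test_outermost_windows_touch_walls(self, calibration):
        diameter_px = 30.3 / calibration.pixel_size  # ~89 px
        mask = band_mask((160, 160), diameter_px)
        mesh = vf.build_mesh(mask)
        top_edge = mesh.row_centers[0] - (mesh.window_size - 1) / 2
        bottom_edge = mesh.row_centers[-1] + (mesh.window_size - 1) / 2
        assert abs(top_edge - mesh.wall_top) <= 1.0
        assert abs(bottom_edge - mesh.wall_bottom) <= 1.0

    def test_too_narrow_lumen(self):
        mask = np.zeros((40, 60), dtype=bool)
        mask[18:28] = True  # height 10 < 20
        with pytest.raises(MeshError):
            vf.build_mesh(mask)


class TestNccMatch:
    def test_zero_shift_identity(self, rng):
        template = rng.integers(0, 255, size=(8, 8)).astype(np.uint8)
        search = np.zeros((16, 16), dtype=np.uint8)
        search[4:12, 4:12] = template
        disp, g = vf.ncc_match(template, search)
        assert disp == (0.0, 0.0)
        assert g == pytest.approx(1.0)

    def test_integer_offset_recovered_exactly(self, rng):
        big = rng.integers(0, 255, size=(40, 40)).astype(np.uint8)
        template = big[10:22, 14:26]
        disp, g = vf.ncc_match(template, big, origin=(7, 13))
        assert disp == (3.0, 1.0)
        assert g == pytest.approx(1.0)

    def test_constant_search_region(self, rng):
        template = rng.integers(0, 255, size=(6, 6)).astype(np.uint8)
        with pytest.raises(MatchError):
            vf.ncc_match(template, np.full((12, 12), 9, dtype=np.uint8))

    def test_zero_variance_template(self):
        with pytest.raises(MatchError):
            vf.ncc_match(np.full((6, 6), 3), np.arange(144).reshape(12, 12))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle(self, seed):
        r = np.random.default_rng(seed)
        th = int(r.integers(3, 12))
        sh = int(r.integers(th + 1, 32))
        template = r.integers(0, 255, size=(th, th)).astype(np.uint8)
        search = r.integers(0, 255, size=(sh, sh)).astype(np.uint8)
        oracle = naive_ncc(template, search)
        ours = gamma_surface(template, search)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)
        origin = (0, 0)
        disp, g = vf.ncc_match(template, search, origin=origin)
        assert g == pytest.approx(np.nanmax(oracle), abs=1e-9)

    def test_affine_invariance(self, rng):
        template = rng.normal(size=(8, 8))
        search = rng.normal(size=(20, 20))
        d0, g0 = vf.ncc_match(template, search)
        d1, g1 = vf.ncc_match(3.0 * template + 11.0, search)
        d2, g2 = vf.ncc_match(template, 0.5 * search - 4.0)
        assert d0 == d1 == d2
        assert g0 == pytest.approx(g1) == pytest.approx(g2)

    def test_tie_breaks_to_smallest_displacement(self):
        # periodic search: equal peaks at shifts 0 and +4
        template = np.tile(np.array([[0, 50], [50, 0]]), (2, 2)).astype(float)
        search = np.tile(np.array([[0, 50], [50, 0]]), (5, 5)).astype(float)
        disp, g = vf.ncc_match(template, search, origin=(2, 2))
        assert g == pytest.approx(1.0)
        assert disp == (0.0, 0.0)


class TestTrackField:
    def make_video(self, frames, calibration):
        return vf.VideoSequence(np.asarray(frames), calibration)

    def full_mesh(self, shape, rows=3, cols=3, ws=12):
        mask = np.ones(shape, dtype=bool)
        return vf.build_mesh(mask, n_rows=rows, n_cols=cols, window_size=ws,
                             column_range=(ws, shape[1] - ws))

    def test_global_shift_gives_680(self, calibration, rng):
        base = rng.integers(0, 255, size=(96, 96)).astype(np.uint8)
        frames = [np.roll(base, k, axis=1) for k in range(5)]
        video = self.make_video(frames, calibration)
        mesh = self.full_mesh((96, 96))
        field = vf.track_field(video, mesh, [(k, k + 1) for k in range(4)],
                               search_radius=5)
        assert field.valid.all()
        np.testing.assert_allclose(field.speed[field.valid], 680.0)
        np.testing.assert_allclose(field.displacement[..., 1], 1.0)

    def test_static_video_zero_speeds(self, calibration, rng):
        base = rng.integers(0, 255, size=(64, 64)).astype(np.uint8)
        video = self.make_video([base] * 4, calibration)
        mesh = self.full_mesh((64, 64))
        field = vf.track_field(video, mesh, [(0, 1), (1, 2)], search_radius=4)
        assert field.valid.all()
        np.testing.assert_allclose(field.speed, 0.0)

    def test_speed_scales_with_calibration(self, rng):
        base = rng.integers(0, 255, size=(64, 64)).astype(np.uint8)
        frames = [base, np.roll(base, 2, axis=1)]
        mesh = self.full_mesh((64, 64))
        speeds = {}
        for px, fps in [(0.34, 2000.0), (0.68, 2000.0), (0.34, 1000.0)]:
            cal = vf.Calibration(px, fps)
            field = vf.track_field(self.make_video(frames, cal), mesh, [(0, 1)],
                                   search_radius=4)
            speeds[(px, fps)] = field.speed[field.valid].mean()
        assert speeds[(0.68, 2000.0)] == pytest.approx(2 * speeds[(0.34, 2000.0)])
        assert speeds[(0.34, 1000.0)] == pytest.approx(0.5 * speeds[(0.34, 2000.0)])

    def test_frame_gap_divides_speed(self, calibration, rng):
        base = rng.integers(0, 255, size=(64, 64)).astype(np.uint8)
        frames = [np.roll(base, k, axis=1) for k in range(3)]
        video = self.make_video(frames, calibration)
        mesh = self.full_mesh((64, 64))
        gap1 = vf.track_field(video, mesh, [(0, 1)], search_radius=5)
        gap2 = vf.track_field(video, mesh, [(0, 2)], search_radius=5)
        # 2 px over 2 frames is still 680 um/s
        assert gap2.speed[gap2.valid].mean() == pytest.approx(
            gap1.speed[gap1.valid].mean()
        )


class TestRemoveOutliers:
    def test_all_equal_none_removed(self):
        kept, mask = vf.remove_outliers(np.full(10, 5.0))
        assert mask.all()

    def test_textbook_outlier(self):
        kept, mask = vf.remove_outliers(np.array([10.0, 11, 12, 13, 200]))
        assert list(kept) == [10, 11, 12, 13]
        assert list(mask) == [True, True, True, True, False]

    def test_fewer_than_four_skipped(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, mask = vf.remove_outliers(np.array([1.0, 2.0, 3.0]))
        assert mask.all()

    def test_injected_spurious_vectors_flagged(self, rng):
        true = rng.normal(1000, 30, size=400)
        n_bad = 20
        speeds = true.copy()
        bad_idx = rng.choice(400, size=n_bad, replace=False)
        speeds[bad_idx] = 10000.0
        _, keep = vf.remove_outliers(speeds)
        flagged = ~keep
        assert flagged[bad_idx].mean() >= 0.90
        good = np.setdiff1d(np.arange(400), bad_idx)
        assert flagged[good].mean() <= 0.02
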
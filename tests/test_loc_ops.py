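import numpy as np
import pandas as pd
import pytest

from endonano import loc_ops, synthetic_data as sd, tables


def two_record_table(frames, positions, photons=(1000.0, 1000.0), precisions=(10.0, 10.0)):
    return tables.make_table(
        frame=list(frames),
        x_nm=[p[0] for p in positions],
        y_nm=[p[1] for p in positions],
        photons=list(photons),
        sigma_nm=[120.0] * len(frames),
        precision_nm=list(precisions),
    )


class TestGrouping:
    def test_gap_one_merges(self):
        t = two_record_table([1, 3], [(0.0, 0.0), (50.0, 0.0)])
        out = loc_ops.group_localizations(t)
        assert len(out) == 1
        assert out["frame"].iloc[0] == 1

    def test_gap_exceeded_not_merged(self):
        t = two_record_table([1, 4], [(0.0, 0.0), (50.0, 0.0)])
        assert len(loc_ops.group_localizations(t)) == 2

    def test_beyond_radius_not_merged(self):
        t = two_record_table([1, 2], [(0.0, 0.0), (80.0, 0.0)])
        assert len(loc_ops.group_localizations(t)) == 2

    def test_equal_photons_midpoint(self):
        t = two_record_table([1, 2], [(10.0, 20.0), (40.0, 60.0)])
        out = loc_ops.group_localizations(t)
        assert out["x_nm"].iloc[0] == pytest.approx(25.0)
        assert out["y_nm"].iloc[0] == pytest.approx(40.0)
        assert out["photons"].iloc[0] == pytest.approx(2000.0)

    def test_inverse_variance_precision(self):
        t = two_record_table([1, 2], [(0.0, 0.0), (10.0, 0.0)], precisions=(10.0, 20.0))
        out = loc_ops.group_localizations(t)
        expected = (1 / 100 + 1 / 400) ** -0.5
        assert out["precision_nm"].iloc[0] == pytest.approx(expected)

    def test_never_increases_count(self, ring_table):
        grouped = loc_ops.group_localizations(ring_table)
        assert len(grouped) <= len(ring_table)

    def test_idempotent_on_isolated_emitters(self):
        # idempotence holds when merged records stay > radius apart
        rng = np.random.default_rng(8)
        n = 40
        xs = np.arange(n) * 300.0
        frames, x, y, prec = [], [], [], []
        for i in range(n):
            start = rng.integers(0, 500)
            for k in range(rng.integers(1, 4)):
                frames.append(start + k)
                x.append(xs[i] + rng.normal(0, 10))
                y.append(rng.normal(0, 10))
                prec.append(10.0)
        t = tables.make_table(
            frame=frames, x_nm=x, y_nm=y, photons=[100.0] * len(frames),
            sigma_nm=[120.0] * len(frames), precision_nm=prec,
        )
        grouped = loc_ops.group_localizations(t)
        assert len(grouped) <= len(t)
        again = loc_ops.group_localizations(grouped)
        pd.testing.assert_frame_equal(again, grouped)

    def test_chain_across_multiple_frames(self):
        t = tables.make_table(
            frame=[1, 2, 3, 4],
            x_nm=[0.0, 5.0, 10.0, 15.0],
            y_nm=[0.0, 0.0, 0.0, 0.0],
            photons=[100.0] * 4,
            sigma_nm=[120.0] * 4,
            precision_nm=[10.0] * 4,
        )
        out = loc_ops.group_localizations(t)
        assert len(out) == 1
        assert out["photons"].iloc[0] == 400.0


class TestFiltering:
    def test_kept_and_removed(self):
        t = two_record_table([1, 2], [(0.0, 0.0), (500.0, 0.0)], precisions=(29.0, 31.0))
        out = loc_ops.filter_localizations(t)
        assert len(out) == 1
        assert out["precision_nm"].iloc[0] == 29.0

    def test_boundaries_kept(self):
        t = two_record_table([1, 2], [(0.0, 0.0), (500.0, 0.0)], precisions=(30.0, 30.0))
        t.loc[0, "sigma_nm"] = 175.0
        assert len(loc_ops.filter_localizations(t)) == 2

    def test_exact_survivor_count(self):
        rng = np.random.default_rng(3)
        n = 500
        t = tables.make_table(
            frame=np.arange(n),
            x_nm=rng.uniform(0, 1000, n),
            y_nm=rng.uniform(0, 1000, n),
            photons=np.full(n, 100.0),
            sigma_nm=rng.uniform(100, 250, n),
            precision_nm=rng.uniform(5, 50, n),
        )
        # brute-force count oracle
        expected = sum(
            1 for p, s in zip(t["precision_nm"], t["sigma_nm"]) if p <= 30 and s <= 175
        )
        assert len(loc_ops.filter_localizations(t)) == expected

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="precision_nm"):
            loc_ops.filter_localizations(pd.DataFrame({"x_nm": [1.0], "sigma_nm": [1.0]}))


class TestRenderImage:
    def test_min_sigma_rule(self):
        t = two_record_table([1], [(100.0, 100.0)], photons=[1.0], precisions=[3.0])
        settings = loc_ops.RenderSettings(pixel_size_nm=2.0, min_sigma_nm=6.0)
        img = loc_ops.render_image(t, settings, extent_nm=(50, 150, 50, 150))
        # sigma must be 6 nm, not 3: compare against analytic 6 nm rendering
        xc = 50 + (np.arange(50) + 0.5) * 2.0
        from scipy.special import erf

        edges = 50 + np.arange(51) * 2.0
        g = np.diff(0.5 * (1 + erf((edges - 100.0) / (np.sqrt(2) * 6.0))))
        expected = np.outer(g, g)
        # the renderer truncates at 6 sigma, so compare to ~1e-8
        np.testing.assert_allclose(img, expected, atol=1e-8)

    def test_normalization(self):
        rng = np.random.default_rng(0)
        n = 200
        t = tables.make_table(
            frame=np.arange(n),
            x_nm=rng.uniform(400, 600, n),
            y_nm=rng.uniform(400, 600, n),
            photons=np.full(n, 1.0),
            sigma_nm=np.full(n, 120.0),
            precision_nm=rng.uniform(5, 20, n),
        )
        settings = loc_ops.RenderSettings(pixel_size_nm=5.0)
        img = loc_ops.render_image(t, settings, extent_nm=(200, 800, 200, 800))
        assert img.sum() == pytest.approx(n, rel=1e-6)

    def test_argmax_contains_record(self):
        t = two_record_table([1], [(523.0, 687.0)], photons=[1.0], precisions=[8.0])
        settings = loc_ops.RenderSettings(pixel_size_nm=5.0)
        img = loc_ops.render_image(t, settings, extent_nm=(400, 700, 500, 800))
        r, c = np.unravel_index(np.argmax(img), img.shape)
        assert 400 + c * 5.0 <= 523.0 < 400 + (c + 1) * 5.0
        assert 500 + r * 5.0 <= 687.0 < 500 + (r + 1) * 5.0

    def test_saturation_only_affects_display(self):
        t = two_record_table([1, 2], [(100.0, 100.0), (102.0, 100.0)], precisions=(6.0, 6.0))
        settings = loc_ops.RenderSettings(pixel_size_nm=5.0)
        img = loc_ops.render_image(t, settings, extent_nm=(0, 200, 0, 200))
        disp = loc_ops.export_display(img, 0.9)
        assert disp.max() == 1.0
        assert img.sum() == pytest.approx(2.0, rel=1e-6)  # numeric array untouched


def dense_structure_table(rng, n=20_000, n_frames=10_000, n_clusters=60):
    """Clustered localizations (sharp autocorrelation) spread over the movie."""
    centers = rng.uniform(200, 2800, (n_clusters, 2))
    which = rng.integers(0, n_clusters, n)
    xy = centers[which] + rng.normal(0, 25.0, (n, 2))
    return tables.make_table(
        frame=rng.integers(0, n_frames, n),
        x_nm=xy[:, 0],
        y_nm=xy[:, 1],
        photons=np.full(n, 1000.0),
        sigma_nm=np.full(n, 120.0),
        precision_nm=np.full(n, 10.0),
    )


class TestDriftCorrect:
    def test_short_movie_skipped(self):
        rng = np.random.default_rng(1)
        t = dense_structure_table(rng, n_frames=3000)
        res = loc_ops.drift_correct(t)
        assert res.skipped
        pd.testing.assert_frame_equal(res.table, t)

    def test_zero_drift_skipped(self):
        rng = np.random.default_rng(2)
        t = dense_structure_table(rng)
        res = loc_ops.drift_correct(t)
        assert res.skipped
        assert res.reason == "estimated drift below min_drift"

    def test_linear_drift_recovered(self):
        rng = np.random.default_rng(3)
        t = dense_structure_table(rng)
        frames = t["frame"].to_numpy()
        true = sd.linear_drift(10_000, (50.0, -30.0))
        drifted = t.copy()
        drifted["x_nm"] += true[frames, 0]
        drifted["y_nm"] += true[frames, 1]
        res = loc_ops.drift_correct(drifted)
        assert not res.skipped
        n = len(res.trajectory)
        resid = res.trajectory - true[:n]
        resid -= resid.mean(axis=0)  # global offset is unobservable
        rms = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert rms < 5.0

    def test_exactly_invertible(self):
        rng = np.random.default_rng(4)
        t = dense_structure_table(rng, n=20000)
        frames = t["frame"].to_numpy()
        true = sd.linear_drift(10_000, (60.0, 40.0))
        drifted = t.copy()
        drifted["x_nm"] += true[frames, 0]
        drifted["y_nm"] += true[frames, 1]
        res = loc_ops.drift_correct(drifted)
        restored = res.table.copy()
        restored["x_nm"] += res.trajectory[frames, 0]
        restored["y_nm"] += res.trajectory[frames, 1]
        np.testing.assert_allclose(restored["x_nm"], drifted["x_nm"], atol=1e-9)
        np.testing.assert_allclose(restored["y_nm"], drifted["y_nm"], atol=1e-9)

    def test_single_frame_error(self):
        t = two_record_table([1, 1], [(0.0, 0.0), (10.0, 0.0)])
        with pytest.raises(ValueError):
            loc_ops.drift_correct(t)


class TestChannelTransform:
    def test_identity(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10_000, (50, 2))
        tf = loc_ops.estimate_channel_transform(pts, pts)
        np.testing.assert_allclose(tf.matrix / tf.matrix[2, 2], np.eye(3), atol=1e-9)
        assert tf.rms_error < 1e-6
        assert tf.n_control_points == 50

    def test_known_homography_recovered(self):
        # oracle: apply a known matrix, add 3 nm noise, check field-wide error
        H = np.array([
            [1.001, 0.002, 25.0],
            [-0.001, 0.999, -40.0],
            [1e-8, -2e-8, 1.0],
        ])
        rng = np.random.default_rng(6)
        mov = rng.uniform(0, 50_000, (1000, 2))
        h = np.column_stack([mov, np.ones(len(mov))]) @ H.T
        ref = h[:, :2] / h[:, 2:3] + rng.normal(0, 3.0, mov.shape)
        tf = loc_ops.estimate_channel_transform(ref, mov)
        grid = np.array([[x, y] for x in np.linspace(0, 50_000, 11)
                         for y in np.linspace(0, 50_000, 11)])
        gh = np.column_stack([grid, np.ones(len(grid))]) @ H.T
        expected = gh[:, :2] / gh[:, 2:3]
        err = np.hypot(*(tf.apply(grid) - expected).T)
        assert err.max() < 10.0
        assert tf.rms_error < 10.0

    def test_too_few_pairs(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        with pytest.raises(ValueError):
            loc_ops.estimate_channel_transform(pts, pts)

    def test_collinear_error(self):
        pts = np.column_stack([np.arange(6.0), np.arange(6.0) * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            loc_ops.estimate_channel_transform(pts, pts)

    def test_apply_to_table(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1000, (20, 2))
        tf = loc_ops.estimate_channel_transform(pts + [10.0, -5.0], pts)
        t = tables.make_table(
            frame=[0], x_nm=[100.0], y_nm=[200.0], photons=[1.0],
            sigma_nm=[120.0], precision_nm=[10.0],
        )
        out = loc_ops.apply_transform(t, tf)
        assert out["x_nm"].iloc[0] == pytest.approx(110.0, abs=1e-6)
        assert out["y_nm"].iloc[0] == pytest.approx(195.0, abs=1e-6)


class TestCommutation:
    def test_filter_group_commutes_on_clean_table(self):
        # merged precisions stay on the same side of the cutoff here
        t = tables.make_table(
            frame=[1, 2, 10, 11],
            x_nm=[0.0, 10.0, 500.0, 505.0],
            y_nm=[0.0, 0.0, 0.0, 0.0],
            photons=[100.0] * 4,
            sigma_nm=[120.0] * 4,
            precision_nm=[10.0, 12.0, 50.0, 60.0],
        )
        a = loc_ops.filter_localizations(loc_ops.group_localizations(t))
        b = loc_ops.group_localizations(loc_ops.filter_localizations(t))
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )
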
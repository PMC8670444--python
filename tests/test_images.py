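"""Contact-image pipeline: Otsu, areas, brightness, tracking, filtering."""

import numpy as np
import pytest
from scipy import signal

from frictouch.errors import (
    DataError,
    DegenerateHistogramError,
    ParameterError,
    UndefinedCorrelationError,
)
from frictouch.images import (
    ContactFrame,
    TrialRecord,
    correct_illumination,
    detect_features,
    displacement_brightness_correlation,
    filter_force,
    local_brightness,
    otsu_threshold,
    real_contact_area,
    track_features,
)


def brute_force_otsu(image, nbins=256):
    """Independent exhaustive between-class-variance maximiser."""
    flat = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(flat, bins=nbins)
    best_var, best_thr = -1.0, None
    for k in range(1, nbins):
        thr = edges[k]
        lo, hi = flat[flat <= edges[k - 1] + (edges[1] - edges[0]) * 0], None
        w0 = counts[:k].sum()
        w1 = counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        centers = 0.5 * (edges[:-1] + edges[1:])
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, thr
    return best_thr


class TestIlluminationCorrection:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.4)
        assert np.allclose(correct_illumination(img), img, atol=1e-9)

    def test_linear_shading_removed(self):
        rng = np.random.default_rng(0)
        base = 0.5 + 0.1 * rng.standard_normal((96, 96))
        base = np.clip(base, 0, 1)
        yy, xx = np.mgrid[0:96, 0:96] / 96.0
        shaded = base + 0.2 * (xx - 0.5)
        corrected = correct_illumination(shaded, sigma=24)
        # away from the borders the unshaded texture returns within 2%
        diff = (corrected - base)[16:-16, 16:-16]
        diff -= diff.mean()
        assert np.abs(diff).max() <= 0.02 * np.ptp(shaded)

    def test_impulse_noise_bounded_no_nan(self):
        img = np.zeros((32, 32))
        img[16, 16] = 1e6
        out = correct_illumination(img)
        assert np.all(np.isfinite(out))
        assert out.max() <= 1e6 and out.min() >= 0.0


class TestOtsu:
    def test_bimodal_separation(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((50, 50)) < 0.4, 50.0, 200.0)
        thr = otsu_threshold(img)
        assert 50.0 < thr < 200.0

    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            img = rng.integers(0, 256, size=(40, 40)).astype(float)
            assert otsu_threshold(img) == pytest.approx(brute_force_otsu(img))

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((10, 10), 7.0))


class TestRealContactArea:
    def test_synthetic_disk_area(self):
        n, r_px, res = 256, 50, 0.01
        yy, xx = np.mgrid[0:n, 0:n]
        img = ((xx - n / 2) ** 2 + (yy - n / 2) ** 2 <= r_px**2).astype(float)
        area = real_contact_area(img, res)
        assert area == pytest.approx(np.pi * (r_px * res) ** 2, rel=0.02)

    def test_two_disjoint_disks_add(self):
        n, res = 256, 0.01
        yy, xx = np.mgrid[0:n, 0:n]
        d1 = (xx - 60) ** 2 + (yy - 60) ** 2 <= 30**2
        d2 = (xx - 180) ** 2 + (yy - 180) ** 2 <= 40**2
        a1 = real_contact_area(d1.astype(float), res)
        a2 = real_contact_area(d2.astype(float), res)
        both = real_contact_area((d1 | d2).astype(float), res)
        assert both == pytest.approx(a1 + a2, rel=0.02)

    def test_forced_max_threshold_gives_zero(self):
        img = np.random.default_rng(3).random((32, 32))
        assert real_contact_area(img, 0.01, threshold=img.max()) == 0.0

    def test_area_invariant_to_shading_after_correction(self):
        n, res = 192, 0.01
        rng = np.random.default_rng(4)
        yy, xx = np.mgrid[0:n, 0:n]
        dots = (rng.random((n, n)) < 0.25) & (
            (xx - n / 2) ** 2 + (yy - n / 2) ** 2 <= 70**2
        )
        clean = np.where(dots, 0.9, 0.1)
        area_clean = real_contact_area(clean, res)
        shaded = clean + 0.15 * (xx / n - 0.5)
        area_corrected = real_contact_area(correct_illumination(shaded, sigma=48), res)
        assert area_corrected == pytest.approx(area_clean, rel=0.03)


class TestLocalBrightness:
    def test_uniform_image_returns_its_value(self):
        img = np.full((64, 64), 0.7)
        assert local_brightness(img, (30.0, 30.0)) == pytest.approx(0.7)

    def test_point_inside_large_bright_disk(self):
        n = 128
        yy, xx = np.mgrid[0:n, 0:n]
        img = (((xx - 64) ** 2 + (yy - 64) ** 2) <= 20**2).astype(float) * 0.9
        assert local_brightness(img, (64.0, 64.0)) == pytest.approx(0.9)

    def test_half_bright_boundary_matches_pixel_count(self):
        n = 64
        img = np.zeros((n, n))
        img[:, 32:] = 1.0  # right half bright
        got = local_brightness(img, (31.5, 32.0), radius_px=10)
        # oracle: count disk pixels falling in the bright half
        r = np.arange(-10, 11)
        dx, dy = np.meshgrid(r, r)
        disk = dx**2 + dy**2 <= 100
        cols = np.round(31.5 + dx[disk]).astype(int)
        expect = np.mean(cols >= 32)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_point_near_border_rejected(self):
        with pytest.raises(ParameterError):
            local_brightness(np.zeros((32, 32)), (2.0, 16.0), radius_px=10)


class TestFilterForce:
    def test_dc_gain_is_one(self):
        out = filter_force(np.full(500, 2.5), sample_rate=1000.0)
        assert np.allclose(out, 2.5, atol=1e-9)

    @pytest.mark.parametrize(
        "freq,tol_kind",
        [(5.0, "passband"), (200.0, "stopband")],
        ids=["passband-5Hz", "stopband-200Hz"],
    )
    def test_frequency_response_matches_analytic_butterworth(self, freq, tol_kind):
        fs = 1000.0
        t = np.arange(0, 4.0, 1 / fs)
        x = np.sin(2 * np.pi * freq * t)
        y = filter_force(x, fs)
        core = slice(len(t) // 4, -len(t) // 4)  # avoid edge transients
        gain = np.ptp(y[core]) / np.ptp(x[core])
        b, a = signal.butter(2, 50.0, fs=fs)
        _, h = signal.freqz(b, a, worN=[freq], fs=fs)
        expected = np.abs(h[0]) ** 2  # forward + backward
        if tol_kind == "passband":
            assert gain == pytest.approx(1.0, abs=0.01)
        assert gain == pytest.approx(expected, rel=0.05)

    def test_zero_phase_by_cross_correlation(self):
        fs = 1000.0
        t = np.arange(0, 2.0, 1 / fs)
        x = np.sin(2 * np.pi * 8 * t) + 0.3 * np.sin(2 * np.pi * 20 * t)
        y = filter_force(x, fs)
        xc = np.correlate(y - y.mean(), x - x.mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(x) - 1)
        assert lag == 0

    def test_double_filtering_stays_finite_and_tighter(self):
        fs = 1000.0
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        once = filter_force(x, fs)
        twice = filter_force(once, fs)
        assert np.all(np.isfinite(twice))
        assert twice.std() <= once.std()

    def test_short_series_rejected(self):
        with pytest.raises(DataError):
            filter_force(np.ones(5), sample_rate=1000.0)


def _static_trial(n_frames=4, n=160, seed=0):
    rng = np.random.default_rng(seed)
    ridge = np.clip(0.5 + 0.2 * rng.standard_normal((n, n)), 0, 1)
    from scipy.ndimage import gaussian_filter

    ridge = gaussian_filter(ridge, 1.0)
    contact = np.where(rng.random((n, n)) < 0.3, 0.8, 0.05)
    frames = [
        ContactFrame(
            ridge_image=ridge,
            contact_image=contact,
            timestamp=0.1 * i,
            normal_force=0.5 + i,
            pixel_resolution=0.02,
        )
        for i in range(n_frames)
    ]
    return TrialRecord(frames=frames)


class TestTracking:
    def test_static_sequence_has_near_zero_displacement(self):
        trial = _static_trial()
        tp = track_features(trial, max_features=150)
        drift_px = np.abs(tp.positions[-1] - tp.positions[0])
        assert np.median(drift_px) <= 0.3

    def test_rigid_translation_recovered(self, small_trial_pair):
        # translation via the generator's rigid-drift injection
        from frictouch.synth import GeneratorConfig, gen_press_trial

        cfg = GeneratorConfig(
            seed=9, alpha_um=1e-3, image_size=256, divergence_gain=0.0,
            global_drift_mm=(0.25, 0.0), frame_rate=12.0,
        )
        trial, truth = gen_press_trial(cfg)
        tp = track_features(trial, levels=3)
        final = tp.final_index
        shift_px = tp.positions[final] - tp.positions[0]
        res = trial.pixel_resolution
        f_frac = truth.force[final] / trial.meta["peak_force_N"]
        expect_x = 0.25 * f_frac / res
        assert np.median(shift_px[:, 0]) == pytest.approx(expect_x, abs=0.1 / res * 0.02)
        assert abs(np.median(shift_px[:, 1])) <= 1.0

    def test_single_frame_rejected(self):
        trial = _static_trial(n_frames=4)
        trial.frames = trial.frames[:1]
        with pytest.raises(ParameterError):
            track_features(trial)


class TestCorrelation:
    def test_monotone_relation_gives_rho_one(self):
        from frictouch.images import TrackedPoints

        rng = np.random.default_rng(6)
        # points on a coarse grid so their brightness disks never overlap
        gx, gy = np.meshgrid(np.arange(40, 180, 30), np.arange(40, 180, 30))
        pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        n = pts.shape[0]
        disp = rng.random((n, 2))
        mag = np.hypot(*disp.T)
        img = np.zeros((220, 220))
        yy, xx = np.mgrid[0:220, 0:220]
        # paint disks whose brightness increases monotonically with |disp|
        for (x, y), m in zip(pts, mag):
            img[(xx - x) ** 2 + (yy - y) ** 2 <= 100] = 0.1 + m
        tp = TrackedPoints(
            positions=pts[None, :, :],
            onset_index=np.zeros(n, dtype=int),
            displacement_mm=disp,
            brightness=np.zeros((1, n)),
            final_index=0,
            n_lost=0,
        )
        rho, _ = displacement_brightness_correlation(tp, img)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_five_point_table_matches_hand_computed_spearman(self):
        from scipy.stats import spearmanr

        # hand-ranked: x ranks 1..5, y ranks (2,1,4,3,5) -> rho = 1 - 6*4/120 = 0.8
        x = np.array([10, 20, 30, 40, 50.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        assert spearmanr(x, y).statistic == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        from frictouch.images import TrackedPoints

        n = 12
        tp = TrackedPoints(
            positions=np.full((1, n, 2), 50.0),
            onset_index=np.zeros(n, dtype=int),
            displacement_mm=np.ones((n, 2)),
            brightness=np.zeros((1, n)),
            final_index=0,
            n_lost=0,
        )
        with pytest.raises(UndefinedCorrelationError):
            displacement_brightness_correlation(tp, np.full((100, 100), 0.5))
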
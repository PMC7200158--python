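"""Spot-counting pipeline tests: background subtraction against a
brute-force rolling-ball oracle, detection accuracy on simulator ground
truth, linking against exhaustive assignment, mixture selection, and the
single-fluorophore calibration rules."""

import numpy as np
import pytest

from oligocount.tirf import (
    GmmModel,
    ImageStack,
    SpotDetection,
    Trajectory,
    calibrate,
    center_crop_bounds,
    detect_spots,
    fraction_within,
    link_trajectories,
    mean_gray_values,
    rolling_ball_subtract,
    select_gmm,
    select_trajectories,
    start_intensities,
    time_average,
)


def brute_force_rolling_ball(img, radius):
    """Apex height of the largest ball fitting under the surface, per pixel."""
    n = int(np.ceil(radius))
    offs = [
        (dy, dx)
        for dy in range(-n, n + 1)
        for dx in range(-n, n + 1)
        if dy * dy + dx * dx <= radius**2
    ]
    h, w = img.shape
    bg = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    z = radius - np.sqrt(radius**2 - (dy * dy + dx * dx))
                    vals.append(img[yy, xx] + z)
            bg[y, x] = min(vals)
    return bg


def det(frame, x, y, amplitude=100.0, background=0.0, sigma=1.0, p=1e-6):
    return SpotDetection(frame, x, y, amplitude, background, sigma, p)


class TestRollingBall:
    def test_constant_frame_becomes_zero(self):
        stack = ImageStack(np.full((2, 32, 32), 57.0))
        out = rolling_ball_subtract(stack)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_all_zero_frame_stays_zero(self):
        out = rolling_ball_subtract(ImageStack(np.zeros((1, 16, 16))))
        assert np.all(out.data == 0.0)

    def test_matches_brute_force_oracle(self, rng):
        img = rng.uniform(10, 30, (20, 20))
        stack = ImageStack(img[None])
        out = rolling_ball_subtract(stack, diameter_px=5)
        oracle = np.clip(img - brute_force_rolling_ball(img, 2.5), 0, None)
        assert np.allclose(out.data[0], oracle, atol=1e-6)

    def test_removes_ramp_and_preserves_spot(self, spot_renderer):
        # bright spot (volume 1200, peak ~190) on a gentle linear ramp
        shape = (40, 200)
        ramp = np.tile(np.linspace(0, 50, shape[1]), (shape[0], 1))
        img = ramp + 20 + spot_renderer(shape, [(20.0, 100.0, 1200.0, 1.0)])
        out = rolling_ball_subtract(ImageStack(img[None]), diameter_px=5).data[0]
        far_from_spot = out[:, :60]
        assert far_from_spot.mean() < 0.02 * 50  # ramp gone
        peak_before = img[20, 100] - ramp[20, 100] - 20
        # the ball climbs ~10% up a sigma=1 peak at this brightness (the
        # brute-force oracle reproduces the same shave exactly)
        assert out[20, 100] == pytest.approx(peak_before, rel=0.12)
        oracle = np.clip(img - brute_force_rolling_ball(img, 2.5), 0, None)
        assert out[20, 100] == pytest.approx(oracle[20, 100], abs=1e-6)

    def test_oversized_diameter_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(ImageStack(np.zeros((1, 8, 8))), diameter_px=20)


class TestTimeAverage:
    def test_window_one_is_identity(self, rng):
        stack = ImageStack(rng.uniform(0, 100, (6, 8, 8)))
        assert np.array_equal(time_average(stack, 1).data, stack.data)

    def test_constant_stack_unchanged(self):
        stack = ImageStack(np.full((7, 4, 4), 3.0))
        assert np.allclose(time_average(stack, 5).data, 3.0)

    def test_matches_direct_windowed_mean(self, rng):
        data = rng.uniform(0, 10, (9, 3, 3))
        out = time_average(ImageStack(data), 5).data
        for t in range(9):
            lo, hi = max(0, t - 2), min(9, t + 3)
            assert np.allclose(out[t], data[lo:hi].mean(axis=0))

    def test_alternating_series_interior_mean(self):
        # single pixel alternating 0/2: interior window-5 means are 0.8 or 1.2
        data = np.zeros((10, 1, 1))
        data[1::2] = 2.0
        out = time_average(ImageStack(data), 5).data[:, 0, 0]
        assert set(np.round(out[2:8], 6)) == {0.8, 1.2}

    def test_invalid_window_rejected(self):
        stack = ImageStack(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            time_average(stack, 0)
        with pytest.raises(ValueError):
            time_average(stack, 4)


class TestDetectSpots:
    def test_recovers_wellseparated_spots(self, spot_renderer, rng):
        truth = [
            (12.3, 15.7), (12.8, 40.2), (13.5, 70.9), (35.1, 20.4),
            (38.6, 55.5), (42.0, 80.8), (60.7, 12.1), (64.4, 44.6),
            (68.9, 77.3), (85.2, 52.9),
        ]
        vol = 600.0  # peak ~95 counts over noise sd 2: SNR ~ 10 per pixel
        img = spot_renderer(
            (100, 100),
            [(r, c, vol, 1.0) for r, c in truth],
            background=20.0,
            noise_sd=2.0,
            rng=rng,
        )
        dets = detect_spots(img, alpha=0.05, psf_sigma_px=1.0)
        assert len(dets) == 10
        for r, c in truth:
            best = min(dets, key=lambda d: (d.y - r) ** 2 + (d.x - c) ** 2)
            assert np.hypot(best.y - r, best.x - c) < 0.5
            assert best.integrated_intensity == pytest.approx(vol, rel=0.10)

    def test_pure_noise_yields_few_detections_scaling_with_alpha(self, rng):
        img = rng.normal(20, 2.0, (256, 256))
        loose = detect_spots(img, alpha=0.05)
        strict = detect_spots(img, alpha=1e-8)
        assert len(loose) <= 6  # prefilter keeps the null rate low
        assert len(strict) <= len(loose)

    def test_constant_frame_gives_empty_list(self):
        assert detect_spots(np.full((32, 32), 7.0)) == []

    def test_resolves_separated_pair_merges_overlapping_pair(self, spot_renderer, rng):
        far = spot_renderer(
            (40, 60), [(20.0, 20.0, 600.0, 1.0), (20.0, 30.0, 600.0, 1.0)],
            background=10.0, noise_sd=1.0, rng=rng,
        )
        assert len(detect_spots(far)) == 2
        near = spot_renderer(
            (40, 60), [(20.0, 29.75, 600.0, 1.0), (20.0, 30.25, 600.0, 1.0)],
            background=10.0, noise_sd=1.0, rng=rng,
        )
        assert len(detect_spots(near)) == 1  # 0.5 px apart: unresolvable

    def test_detection_is_deterministic(self, spot_renderer, rng):
        img = spot_renderer(
            (64, 64), [(30.0, 30.0, 400.0, 1.0)], background=15.0,
            noise_sd=2.0, rng=rng,
        )
        d1 = detect_spots(img)
        d2 = detect_spots(img)
        assert [(d.x, d.y, d.amplitude) for d in d1] == [
            (d.x, d.y, d.amplitude) for d in d2
        ]


class TestLinking:
    def test_static_spot_gives_one_full_trajectory(self):
        dets = [det(t, 10.0, 10.0) for t in range(20)]
        trajs = link_trajectories(dets)
        assert len(trajs) == 1
        assert trajs[0].length == 20
        assert trajs[0].gaps == []

    @pytest.mark.parametrize(
        "gap,expected_tracks", [(3, 1), (4, 1), (5, 2)]
    )
    def test_gap_closing_boundary(self, gap, expected_tracks):
        frames = list(range(10)) + list(range(10 + gap, 25 + gap))
        dets = [det(t, 5.0, 5.0) for t in frames]
        trajs = link_trajectories(dets, max_gap=4)
        assert len(trajs) == expected_tracks

    def test_crossing_spots_match_exhaustive_assignment(self):
        # two spots with constant velocity crossing mid-movie
        n = 21
        path_a = [(5.0 + 0.9 * t, 10.0) for t in range(n)]
        path_b = [(23.0 - 0.9 * t, 10.0) for t in range(n)]
        dets = []
        for t in range(n):
            dets.append(det(t, path_a[t][0], path_a[t][1]))
            dets.append(det(t, path_b[t][0], path_b[t][1]))
        trajs = link_trajectories(dets, max_disp_px=2.0)
        assert len(trajs) == 2

        # oracle: per frame-pair, pick the permutation minimizing total
        # squared displacement, then follow the chains
        chains = [[(path_a[0][0], path_a[0][1])], [(path_b[0][0], path_b[0][1])]]
        for t in range(1, n):
            cur = [path_a[t], path_b[t]]
            prev = [c[-1] for c in chains]
            straight = sum(
                (p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2
                for p, c in zip(prev, cur)
            )
            swapped = sum(
                (p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2
                for p, c in zip(prev, cur[::-1])
            )
            order = cur if straight <= swapped else cur[::-1]
            chains[0].append(order[0])
            chains[1].append(order[1])
        got = sorted(
            tuple((round(d.x, 6), round(d.y, 6)) for d in tr.detections)
            for tr in trajs
        )
        expected = sorted(
            tuple((round(x, 6), round(y, 6)) for x, y in chain)
            for chain in chains
        )
        assert got == expected

    def test_empty_input_gives_empty_output(self):
        assert link_trajectories([]) == []

    def test_gap_budget_scales_with_span(self):
        # same 3-frame gap, but the re-appearance is too far to bridge
        dets = [det(t, 5.0, 5.0) for t in range(10)]
        dets += [det(t, 50.0, 50.0) for t in range(13, 20)]
        trajs = link_trajectories(dets, max_gap=4, max_disp_px=2.0)
        assert len(trajs) == 2


class TestTrajectorySelection:
    def test_length_boundary_inclusive(self):
        trajs = [
            Trajectory([det(t, 1.0, 1.0) for t in range(n)]) for n in (9, 10, 40)
        ]
        kept = select_trajectories(trajs, min_length=10)
        assert [t.length for t in kept] == [10, 40]

    def test_empty_input(self):
        assert select_trajectories([], 10) == []

    def test_gaps_excluded_from_length(self):
        frames = [0, 1, 2, 5, 6]  # 5 detections, one 2-frame gap
        traj = Trajectory([det(t, 0.0, 0.0) for t in frames])
        assert traj.length == 5
        assert traj.gaps == [2]

    def test_start_intensity_is_integrated_gaussian_volume(self):
        traj = Trajectory([det(0, 1.0, 1.0, amplitude=50.0, sigma=1.0)])
        samples = start_intensities([traj])
        assert samples[0] == pytest.approx(2 * np.pi * 50.0)
        peak = start_intensities([traj], mode="peak")
        assert peak[0] == pytest.approx(50.0)

    def test_one_sample_per_trajectory(self):
        trajs = [
            Trajectory([det(0, 1.0, 1.0, amplitude=a)]) for a in (10.0, 20.0, 30.0)
        ]
        assert len(start_intensities(trajs)) == 3


class TestGmmSelection:
    def test_single_population_selects_one_component(self, rng):
        samples = rng.normal(150, 20, 2000)
        model = select_gmm(samples, k_max=5, criterion="bic", replicates=20, seed=9)
        assert model.k == 1

    def test_two_component_recovery(self, rng):
        samples = np.concatenate(
            [rng.normal(100, 15, 1200), rng.normal(200, 15, 800)]
        )
        rng.shuffle(samples)
        model = select_gmm(samples, k_max=5, criterion="bic", replicates=20, seed=9)
        assert model.k == 2
        mu = model.sorted_means
        assert mu[0] == pytest.approx(100, rel=0.05)
        assert mu[1] == pytest.approx(200, rel=0.05)

    def test_aic_never_chooses_fewer_components_than_bic(self, rng):
        samples = np.concatenate(
            [rng.normal(100, 15, 1200), rng.normal(200, 15, 800)]
        )
        bic = select_gmm(samples, k_max=6, criterion="bic", replicates=10, seed=9)
        aic = select_gmm(samples, k_max=6, criterion="aic", replicates=10, seed=9)
        assert aic.k >= bic.k

    def test_reproducible_under_seed(self, rng):
        samples = rng.normal(100, 10, 300)
        m1 = select_gmm(samples, k_max=3, replicates=10, seed=4)
        m2 = select_gmm(samples, k_max=3, replicates=10, seed=4)
        assert np.array_equal(m1.means, m2.means)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            select_gmm([1.0, 2.0, 3.0], k_max=5)


class TestCalibration:
    def make_gmm(self, means):
        means = np.asarray(means, float)
        k = len(means)
        return GmmModel(
            k=k,
            means=means,
            variances=np.ones(k),
            weights=np.full(k, 1.0 / k),
            bic=0.0,
            aic=0.0,
            replicates=1,
            max_iter=1,
        )

    def test_zero_offset_case(self):
        cal = calibrate(self.make_gmm([100.0, 200.0]))
        assert cal.single_fluor_intensity == 100.0
        assert cal.background_offset == 0.0

    def test_nonzero_offset_case(self):
        cal = calibrate(self.make_gmm([150.0, 250.0]), samples=[250.0])
        assert cal.single_fluor_intensity == 100.0
        assert cal.background_offset == 50.0
        assert cal.normalized[0] == pytest.approx(2.0)

    def test_single_component_rejected(self):
        with pytest.raises(ValueError):
            calibrate(self.make_gmm([100.0]))

    def test_fraction_within_counts(self):
        assert fraction_within(np.arange(1, 21), multiple=10) == 0.5
        assert fraction_within([0.5, 3.0, 9.9], multiple=10) == 1.0
        with pytest.raises(ValueError):
            fraction_within([])


class TestMeanGrayValues:
    def test_constant_and_split_fields(self):
        const = np.full((10, 10), 7.0)
        split = np.zeros((10, 10))
        split[:, 5:] = 2.0
        assert mean_gray_values([const, split]) == [7.0, 1.0]

    def test_matches_direct_mean_with_crop(self, rng):
        img = rng.uniform(0, 255, (50, 60))
        crop = center_crop_bounds(img.shape, 20, 20)
        r0, r1, c0, c1 = crop
        [mgv] = mean_gray_values([img], crop=crop)
        assert mgv == pytest.approx(img[r0:r1, c0:c1].mean())

    def test_invalid_crop_rejected(self):
        with pytest.raises(ValueError):
            mean_gray_values([np.zeros((10, 10))], crop=(0, 20, 0, 5))
        with pytest.raises(ValueError):
            mean_gray_values([])
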
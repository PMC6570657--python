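"""Spot detection, linking, lifetimes, kymographs and profiles."""

import numpy as np
import pytest

from discspt import (
    AcquisitionParams,
    ClusterTrack,
    DiscGeometry,
    cluster_msd,
    detect_spots,
    fit_lifetime,
    kymograph,
    link_spots,
    preset,
    radial_profile,
    simulate_cluster_movie,
    transverse_profile,
)
from discspt.clusters import Spot, detect_movie
from discspt.movie import MovieStack, _render_spot
from discspt.simulate import ClusterKinetics

PIX = 0.076
DT = 1.0 / 30.0


def frame_with_spots(shape, spots_px, photons=2000.0, sigma_px=2.0, noise_rng=None,
                     background=20.0):
    img = np.full(shape, background)
    for r, c in spots_px:
        _render_spot(img, r, c, photons, sigma_px)
    if noise_rng is not None:
        img = noise_rng.poisson(img).astype(float)
    return img


def spot_at(x_um, y_um, intensity=1.0):
    return Spot(row=0.0, col=0.0, x_um=x_um, y_um=y_um, intensity=intensity)


class TestDetect:
    def test_blank_frame_no_spots(self):
        assert detect_spots(np.full((64, 64), 10.0), psf_sigma=0.15) == []

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.empty((0, 0)), psf_sigma=0.15)

    def test_single_spot_subpixel_accuracy(self):
        rng = np.random.default_rng(1)
        truth = (31.4, 28.7)
        img = frame_with_spots((64, 64), [truth], noise_rng=rng)
        spots = detect_spots(img, psf_sigma=2.0 * PIX, snr_threshold=8, pixel_size=PIX)
        assert len(spots) == 1
        err = np.hypot(spots[0].row - truth[0], spots[0].col - truth[1])
        assert err < 0.5

    def test_two_separated_spots(self):
        rng = np.random.default_rng(2)
        img = frame_with_spots((64, 64), [(20.0, 20.0), (20.0, 30.0)], noise_rng=rng)
        spots = detect_spots(img, psf_sigma=2.0 * PIX, snr_threshold=8, pixel_size=PIX)
        assert len(spots) == 2


class TestLink:
    def test_stationary_spot_single_track(self):
        lists = [[spot_at(0.0, 0.0)] for _ in range(10)]
        tracks = link_spots(lists, max_displacement=0.5)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 10

    def test_distant_spots_never_swap(self):
        rng = np.random.default_rng(3)
        a = np.array([-2.0, 0.0])
        b = np.array([2.0, 0.0])
        lists = []
        pos_a, pos_b = [], []
        for _ in range(20):
            a = a + rng.normal(0, 0.05, 2)
            b = b + rng.normal(0, 0.05, 2)
            pos_a.append(a.copy())
            pos_b.append(b.copy())
            lists.append([spot_at(*a), spot_at(*b)])
        tracks = link_spots(lists, max_displacement=0.5)
        assert len(tracks) == 2
        for tr in tracks:
            start = tr.positions[0]
            ref = pos_a if np.allclose(start, pos_a[0]) else pos_b
            np.testing.assert_allclose(tr.positions, np.array(ref), atol=1e-9)

    def test_long_gap_splits_track(self):
        lists = [[spot_at(0, 0)]] * 3 + [[]] * 3 + [[spot_at(0, 0)]] * 3
        tracks = link_spots(lists, max_displacement=0.5, max_gap=1)
        assert len(tracks) == 2

    def test_short_gap_closed_and_interpolated(self):
        lists = [[spot_at(0, 0)], [spot_at(0.1, 0)], [], [spot_at(0.3, 0)]]
        tracks = link_spots(lists, max_displacement=0.5, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 4
        assert tracks[0].positions[2, 0] == pytest.approx(0.2)

    def test_no_splits_or_merges(self):
        """Every spot is used by at most one track per frame."""
        rng = np.random.default_rng(4)
        lists = [
            [spot_at(*rng.uniform(-3, 3, 2)) for _ in range(5)] for _ in range(15)
        ]
        tracks = link_spots(lists, max_displacement=1.0)
        used = {}
        for tr in tracks:
            for f, p in zip(tr.frames, tr.positions):
                key = (int(f), round(p[0], 6), round(p[1], 6))
                assert key not in used
                used[key] = tr.track_id


class TestLifetime:
    def test_degenerate_constant_durations(self):
        durations = np.full(20, 0.05 + 0.1)  # all exactly 0.1 s above minimum
        fit = fit_lifetime(durations, frame_interval=None, min_duration_s=0.05)
        assert fit.tau_star == pytest.approx(0.1)

    def test_exponential_sample_recovered(self):
        rng = np.random.default_rng(5)
        durations = rng.exponential(0.1, size=500)
        fit = fit_lifetime(durations, frame_interval=None)
        assert fit.tau_star == pytest.approx(0.1, rel=0.10)

    def test_frame_quantized_tracks_unbiased(self):
        """Discrete (geometric) MLE removes the quantization bias."""
        rng = np.random.default_rng(6)
        tau, n = 0.1, 4000
        births = rng.uniform(0, DT, n)
        lives = rng.exponential(tau, n)
        n_frames = np.ceil((births + lives) / DT) - np.ceil(births / DT)
        tracks = [
            ClusterTrack(i, np.arange(5, 5 + int(m)), np.zeros((int(m), 2)),
                         np.ones(int(m)))
            for i, m in enumerate(n_frames) if m >= 1
        ]
        fit = fit_lifetime(tracks, frame_interval=DT)
        assert fit.tau_star == pytest.approx(tau, rel=0.05)

    def test_censored_policy_at_least_discard(self):
        rng = np.random.default_rng(7)
        tracks = []
        for i, m in enumerate(rng.geometric(0.3, size=200) + 1):
            censored = i % 4 == 0
            tracks.append(
                ClusterTrack(i, np.arange(m), np.zeros((m, 2)), np.ones(m),
                             censored=censored)
            )
        tau_d = fit_lifetime(tracks, frame_interval=DT, policy="discard").tau_star
        tau_c = fit_lifetime(tracks, frame_interval=DT, policy="censored").tau_star
        assert tau_c >= tau_d * 0.99

    def test_too_few_tracks_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime([0.1, 0.2], frame_interval=None)


def small_movie(frames):
    return MovieStack(np.asarray(frames, dtype=float), pixel_size=PIX,
                      frame_interval=DT)


class TestKymograph:
    def test_constant_movie_identical_columns(self):
        rng = np.random.default_rng(8)
        frame = rng.uniform(50, 150, size=(32, 32))
        movie = small_movie([frame] * 6)
        k = kymograph(movie, ((-1.0, 0.0), (1.0, 0.0)))
        for col in range(1, k.shape[1]):
            np.testing.assert_allclose(k[:, col], k[:, 0])

    def test_moving_spot_tilted_streak(self):
        frames = []
        for f in range(8):
            img = np.zeros((40, 40))
            _render_spot(img, 20.0, 8.0 + 3 * f, 5000.0, 1.5)
            frames.append(img)
        movie = small_movie(frames)
        half = 19.5 * PIX
        k = kymograph(movie, ((-half, 0.0), (half, 0.0)))
        peaks = k.argmax(axis=0)
        assert np.all(np.diff(peaks) > 0)  # streak advances every frame

    def test_blank_movie_uniform(self):
        movie = small_movie(np.full((4, 32, 32), 7.0))
        k = kymograph(movie, ((-1.0, -1.0), (1.0, 1.0)))
        np.testing.assert_allclose(k, 7.0)

    def test_line_outside_image_rejected(self):
        movie = small_movie(np.zeros((3, 16, 16)))
        with pytest.raises(ValueError):
            kymograph(movie, ((-5.0, 0.0), (5.0, 0.0)))


class TestProfiles:
    def test_uniform_disc_confinement_index_one(self):
        img = np.full((80, 80), 100.0)
        _, profile, ci = radial_profile(img, disc_radius=2.5, pixel_size=PIX,
                                        centre=(39.5, 39.5))
        assert ci == pytest.approx(1.0, abs=0.01)

    def test_centre_weighted_gaussian_index_above_one(self):
        rr, cc = np.mgrid[0:80, 0:80]
        img = 100 * np.exp(-((rr - 40) ** 2 + (cc - 40) ** 2) / (2 * 15**2))
        _, _, ci = radial_profile(img, disc_radius=2.5, pixel_size=PIX, centre=(40, 40))
        assert ci > 1.5

    def test_rim_annulus_index_below_one(self):
        rr, cc = np.mgrid[0:80, 0:80]
        r = np.hypot(rr - 40, cc - 40) * PIX
        img = 10 + 100 * np.exp(-((r - 2.3) ** 2) / (2 * 0.2**2))
        _, _, ci = radial_profile(img, disc_radius=2.5, pixel_size=PIX, centre=(40, 40))
        assert ci < 0.5

    def test_centre_outside_image_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(np.ones((20, 20)), 1.0, PIX, centre=(50, 50))

    def test_transverse_uniform_flat(self):
        prof = transverse_profile(np.full((30, 30), 3.0), ((5, 5), (25, 25)))
        np.testing.assert_allclose(prof, 3.0)

    def test_transverse_step_profile(self):
        img = np.zeros((30, 30))
        img[:, 15:] = 10.0
        prof = transverse_profile(img, ((15, 2), (15, 27)))
        assert prof[0] == 0.0 and prof[-1] == 10.0
        assert np.all(np.diff(prof) >= 0)

    def test_transverse_matches_radial_on_rendered_disc(self):
        rr, cc = np.mgrid[0:80, 0:80]
        img = 100 * np.exp(-((rr - 40) ** 2 + (cc - 40) ** 2) / (2 * 12**2))
        prof = transverse_profile(img, ((40, 5), (40, 75)))
        # convex, centre-peaked: midpoint exceeds both ends
        assert prof[len(prof) // 2] > prof[0] and prof[len(prof) // 2] > prof[-1]


class TestClusterMSD:
    def test_stationary_tracks_d_near_zero(self):
        tracks = [
            ClusterTrack(i, np.arange(10), np.zeros((10, 2)), np.ones(10))
            for i in range(5)
        ]
        _, med, _ = cluster_msd(tracks)
        assert med == pytest.approx(0.0, abs=1e-12)

    def test_simulated_cluster_d_recovered(self):
        from discspt import DiffusiveStateModel, simulate_trajectories

        d_true = 0.078
        acq = AcquisitionParams()
        ts = simulate_trajectories(
            DiffusiveStateModel([d_true], [[1.0]], [1.0]),
            DiscGeometry(shape="unbounded"), acq,
            n_traj=18, lengths=[40] * 18, seed=9,
        )
        tracks = [
            ClusterTrack(t.track_id, t.frames, t.positions, np.ones(len(t)))
            for t in ts
        ]
        _, med, se = cluster_msd(tracks, acq)
        assert med == pytest.approx(d_true, rel=0.15)
        assert se > 0

    def test_median_robust_to_outlier(self):
        rng = np.random.default_rng(10)
        base = [
            ClusterTrack(i, np.arange(20),
                         0.01 * rng.standard_normal((20, 2)).cumsum(axis=0),
                         np.ones(20))
            for i in range(9)
        ]
        _, med0, _ = cluster_msd(base)
        outlier = ClusterTrack(99, np.arange(20),
                               5.0 * rng.standard_normal((20, 2)).cumsum(axis=0),
                               np.ones(20))
        _, med1, _ = cluster_msd(base + [outlier])
        assert med1 == pytest.approx(med0, rel=0.5)


class TestEndToEndMovie:
    def test_confinement_index_tracks_placement_bias(self):
        """Centre-biased nucleation yields a higher confinement index than
        near-uniform placement, seed by seed."""
        _, geom, acq, kin = preset("dark")
        from dataclasses import replace

        for seed in (20, 21):
            cis = {}
            for scale in (1.5, 50.0):
                k = replace(kin, radial_placement_scale=scale, nucleation_rate=40.0)
                movie, _ = simulate_cluster_movie(k, geom, acq, n_frames=40, seed=seed)
                mean_img = movie.data.mean(axis=0) - kin.camera_offset
                h = mean_img.shape[0]
                _, _, ci = radial_profile(
                    mean_img.clip(0), disc_radius=4.0, pixel_size=acq.pixel_size,
                    centre=((h - 1) / 2, (h - 1) / 2),
                )
                cis[scale] = ci
            assert cis[1.5] > cis[50.0]

    def test_empty_scene_only_noise(self):
        _, geom, acq, _ = preset("dark")
        kin = ClusterKinetics(nucleation_rate=0.0, monomer_count=0)
        movie, truth = simulate_cluster_movie(kin, geom, acq, n_frames=5, seed=22)
        assert truth.empty
        spread = movie.data.astype(float).std()
        assert spread < 3 * np.sqrt(kin.background_photons + kin.read_noise_std**2)

    def test_ground_truth_lifetime_mean(self):
        _, geom, acq, kin = preset("dark")
        movie, truth = simulate_cluster_movie(kin, geom, acq, n_frames=1500, seed=23)
        lifetimes = truth.attrs["events"]["lifetime"]
        assert len(lifetimes) >= 500
        assert lifetimes.mean() == pytest.approx(kin.mean_lifetime, rel=0.05)

    def test_birth_count_poisson(self):
        _, geom, acq, kin = preset("dark")
        n_frames = 600
        movie, truth = simulate_cluster_movie(kin, geom, acq, n_frames=n_frames, seed=24)
        expected = kin.nucleation_rate * n_frames * acq.frame_interval
        n_events = len(truth.attrs["events"])
        assert abs(n_events - expected) < 4 * np.sqrt(expected)

    def test_detection_linking_recovers_lifetime(self):
        """End-to-end: simulate -> detect -> link -> MLE within 20%."""
        _, geom, acq, kin = preset("dark")
        movie, truth = simulate_cluster_movie(kin, geom, acq, n_frames=700, seed=25)
        assert truth["cluster_id"].nunique() >= 250
        spots = detect_movie(movie, kin.psf_sigma, snr_threshold=10)
        tracks = link_spots(spots, max_displacement=0.5)
        fit = fit_lifetime(tracks, frame_interval=acq.frame_interval)
        assert fit.tau_star == pytest.approx(kin.mean_lifetime, rel=0.20)
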
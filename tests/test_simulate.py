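"""Counting-simulator behaviour: mechanism, conservation, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import countdet as cd
from countdet.simulate import make_edge_scene

from conftest import detected_rate_se


def brute_force_detected(a, x, n_pixels, duration, seed):
    """Independent event-by-event oracle.

    Enumerates every electron arrival time per pixel and merges arrivals
    sharing a counting window of length a (window index = floor(t/a)).
    Returns total detected events and total emitted electrons.
    """
    rng = np.random.default_rng(seed)
    detected = emitted = 0
    for _ in range(n_pixels):
        n = rng.poisson(x * duration)
        t = rng.uniform(0.0, duration, n)
        detected += len(np.unique(np.floor(t / a).astype(np.int64)))
        emitted += n
    return detected, emitted


class TestFlatMovie:
    def test_empty_beam_gives_zero_frames(self, quiet_spec):
        movie, gt = cd.simulate_flat_movie(
            quiet_spec, cd.Scene.uniform((32, 32), 0.0), 0.1, seed=1)
        assert movie.data.sum() == 0
        assert gt.emitted_electrons.sum() == 0

    @pytest.mark.parametrize("accumulate", [False, True])
    def test_electron_conservation_and_nonnegativity(self, spec, accumulate):
        _, gt = cd.simulate_flat_movie(
            spec, cd.Scene.uniform((48, 48), 40.0), 0.25, seed=9,
            accumulate=accumulate)
        gt.check()  # detected + merged == emitted, all counts >= 0
        assert gt.merged_events.sum() > 0  # loss actually happens at 40 eps

    def test_same_seed_bit_identical(self, spec):
        scene = cd.Scene.uniform((32, 32), 20.0)
        m1, g1 = cd.simulate_flat_movie(spec, scene, 0.2, seed=123)
        m2, g2 = cd.simulate_flat_movie(spec, scene, 0.2, seed=123)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(g1.emitted_electrons, g2.emitted_electrons)
        assert np.array_equal(g1.false_positives, g2.false_positives)

    def test_values_are_multiples_of_electron_value(self, spec):
        movie, _ = cd.simulate_flat_movie(
            spec, cd.Scene.uniform((32, 32), 30.0), 0.2, seed=4)
        nz = movie.data[movie.data > 0]
        assert nz.size > 0
        assert (nz % spec.electron_value == 0).all()

    def test_matches_brute_force_oracle(self, quiet_spec):
        """Vectorized simulator and event-by-event oracle agree with each
        other and with (1-exp(-a x))/a = 15.14 eps at a=0.007, x=16."""
        a, x, duration = 0.007, 16.0, 1.0
        n_px = 64 * 64
        movie, gt = cd.simulate_flat_movie(
            quiet_spec, cd.Scene.uniform((64, 64), x), duration, seed=77,
            accumulate=True)
        rate_sim = gt.detected_electrons.sum() / n_px / duration
        det_bf, _ = brute_force_detected(a, x, n_px, duration, seed=101)
        rate_bf = det_bf / n_px / duration
        expected = (1 - math.exp(-a * x)) / a
        se = detected_rate_se(a, x, n_px, duration)
        assert abs(rate_sim - expected) < 3 * se
        assert abs(rate_bf - expected) < 3 * se
        assert abs(rate_sim - rate_bf) < 3 * math.sqrt(2) * se

    @pytest.mark.parametrize("x", [5.0, 15.0, 30.0, 60.0, 78.0])
    def test_detected_rate_matches_closed_form(self, quiet_spec, x):
        a = quiet_spec.a
        duration = 200 * a  # whole number of counting windows
        n_px = 128 * 128
        movie, _ = cd.simulate_flat_movie(
            quiet_spec, cd.Scene.uniform((128, 128), x), duration,
            seed=int(x), accumulate=True, ground_truth=False)
        rate = cd.intensity_to_detected_eps(movie)
        expected = (1 - math.exp(-a * x)) / a
        assert abs(rate - expected) < 3 * detected_rate_se(a, x, n_px,
                                                          duration)

    def test_linearity_limit_and_monotonicity(self):
        # a -> 0: detected rate -> x
        tiny = cd.DetectorSpec(a=1e-4, false_positive_rate=0.0)
        movie, _ = cd.simulate_flat_movie(
            tiny, cd.Scene.uniform((128, 128), 50.0), 1.0, seed=2,
            accumulate=True, ground_truth=False)
        rate = cd.intensity_to_detected_eps(movie)
        assert rate == pytest.approx(50.0, rel=0.01)
        # detected rate monotone in x and bounded by 1/a
        spec = cd.DetectorSpec(a=0.007, false_positive_rate=0.0)
        rates = []
        for x in (5.0, 30.0, 78.0):
            m, _ = cd.simulate_flat_movie(
                spec, cd.Scene.uniform((128, 128), x), 1.0, seed=3,
                accumulate=True, ground_truth=False)
            rates.append(cd.intensity_to_detected_eps(m))
        assert rates == sorted(rates)
        assert rates[-1] < 1 / spec.a

    def test_saturation_and_duration_errors(self, spec):
        with pytest.raises(cd.SaturationError, match="saturat"):
            cd.simulate_flat_movie(spec, cd.Scene.uniform((16, 16), 90.0),
                                   0.1, seed=1)
        with pytest.raises(ValueError):
            cd.simulate_flat_movie(spec, cd.Scene.uniform((16, 16), 10.0),
                                   -1.0, seed=1)
        with pytest.raises(ValueError, match="frame period"):
            cd.simulate_flat_movie(spec, cd.Scene.uniform((16, 16), 10.0),
                                   0.001, seed=1)

    def test_frame_resolved_and_accumulated_paths_agree(self, quiet_spec):
        """Both sampling paths realize the same counting distribution."""
        scene = cd.Scene.uniform((96, 96), 40.0)
        duration = 0.5
        _, g1 = cd.simulate_flat_movie(quiet_spec, scene, duration, seed=11)
        _, g2 = cd.simulate_flat_movie(quiet_spec, scene, duration, seed=12,
                                       accumulate=True)
        n_px = 96 * 96
        se = detected_rate_se(quiet_spec.a, 40.0, n_px, duration)
        r1 = g1.detected_electrons.sum() / n_px / duration
        r2 = g2.detected_electrons.sum() / n_px / duration
        assert abs(r1 - r2) < 3 * math.sqrt(2) * se
        # emitted electrons are plain Poisson(x * duration) on both paths
        for g in (g1, g2):
            mean_emitted = g.emitted_electrons.mean()
            se_e = math.sqrt(40.0 * duration / n_px)
            assert abs(mean_emitted - 40.0 * duration) < 3 * se_e


class TestEdgeMovie:
    def test_dark_side_has_no_signal(self):
        spec = cd.DetectorSpec(psf_sigma=0.0, false_positive_rate=0.0)
        movie = cd.simulate_edge_movie(spec, 5.0, 0.0, 12.0, 1.0, seed=6,
                                       shape=(64, 64), accumulate=True)
        img = movie.physical_image()
        # edge at column 32 +- tilt: columns beyond 40 are fully dark
        assert img[:, 44:].sum() == 0
        assert img[:, :20].sum() > 0

    def test_angle_bounds_enforced(self, spec):
        for bad in (0.0, 0.5, 20.0, 90.0):
            with pytest.raises(cd.EdgeAngleError, match="steep|shallow"):
                cd.simulate_edge_movie(spec, bad, 0.0, 12.0, 1.0, seed=1)

    def test_scene_coverage_is_pixel_area_fraction(self):
        # no PSF: pixel value equals the bright-side area fraction, so the
        # column sums of a slanted edge drop linearly across the crossing
        scene = make_edge_scene((64, 64), 5.0, 0.0, 1.0, psf_sigma=0.0)
        col = scene.intensity_map[32]  # row center y=32.5
        edge_x = 32 + math.tan(math.radians(5.0)) * 0.5
        assert col[28] == pytest.approx(1.0, abs=1e-9)
        assert col[36] == pytest.approx(0.0, abs=1e-9)
        # pixel 32 spans [32, 33]: bright fraction = edge_x - 32
        assert col[32] == pytest.approx(edge_x - 32, abs=0.02)
        assert col.sum() == pytest.approx(edge_x, abs=0.05)

    def test_true_mtf_recorded(self):
        spec = cd.DetectorSpec(psf_sigma=0.5)
        movie = cd.simulate_edge_movie(spec, 5.0, 0.0, 12.0, 1.0, seed=1,
                                       shape=(64, 64), accumulate=True)
        f = movie.extra["true_mtf_freq"]
        m = movie.extra["true_mtf"]
        assert m[0] == pytest.approx(1.0)
        i = np.searchsorted(f, 1.0)
        assert m[i] == pytest.approx(
            math.exp(-2 * math.pi ** 2 * 0.25 * 0.25) * 2 / math.pi,
            rel=1e-6)


class TestBeamOff:
    def test_zero_rate_gives_zero_movie(self):
        spec = cd.DetectorSpec(false_positive_rate=0.0)
        movie = cd.simulate_beam_off(spec, (64, 64), 10.0, seed=5)
        assert movie.data.sum() == 0

    def test_event_count_at_published_rate(self):
        """2.86e-6 events/px/s over 4096^2 px for 10 s => ~479.9 events."""
        spec = cd.DetectorSpec(false_positive_rate=2.86e-6)
        movie = cd.simulate_beam_off(spec, (4096, 4096), 10.0, seed=8)
        total = movie.data.sum() / spec.electron_value
        expected = 2.86e-6 * 4096 ** 2 * 10
        assert expected == pytest.approx(479.9, abs=0.1)
        assert abs(total - expected) < 3 * math.sqrt(expected)

    def test_rate_estimate_round_trip(self):
        spec = cd.DetectorSpec(false_positive_rate=1e-3)
        movie = cd.simulate_beam_off(spec, (256, 256), 100.0, seed=13)
        est = cd.false_positive_rate_estimate(movie)
        expected_events = 1e-3 * 256 ** 2 * 100
        se = math.sqrt(expected_events) / (256 ** 2 * 100)
        assert abs(est - 1e-3) < 3 * se

    def test_frame_resolved_stack(self):
        spec = cd.DetectorSpec(false_positive_rate=0.1)
        movie = cd.simulate_beam_off(spec, (32, 32), 0.5, seed=2,
                                     accumulate=False)
        assert movie.n_frames == 30
        assert movie.data.sum() > 0


@given(st.floats(min_value=1.0, max_value=78.0),
       st.integers(min_value=0, max_value=2 ** 16))
def test_conservation_property(x, seed):
    """Electron conservation holds for any rate and seed."""
    spec = cd.DetectorSpec(a=0.007)
    _, gt = cd.simulate_flat_movie(spec, cd.Scene.uniform((16, 16), x),
                                   0.05, seed=seed)
    gt.check()


def test_scene_validation():
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        cd.Scene((2, 2), np.array([[0.0, 2.0], [0.0, 0.0]]), 10.0)
    with pytest.raises(ValueError, match="shape"):
        cd.Scene((2, 3), np.zeros((2, 2)), 10.0)


def test_detector_spec_validation():
    for kwargs in ({"a": 0.0}, {"a": -1.0}, {"false_positive_rate": -1e-6},
                   {"frame_period": 0.0}, {"subpixels_per_axis": 0},
                   {"electron_value": 0}):
        with pytest.raises(ValueError):
            cd.DetectorSpec(**kwargs)
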
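"""Slanted-edge MTF, noise-binning DQE(0), and DQE-curve composition."""

import math

import numpy as np
import pytest

import countdet as cd
from countdet.simulate import analytic_system_mtf, make_edge_scene
from countdet.transfer import PlateauError


def noiseless_edge_image(sigma, angle=5.0, offset=0.0, shape=(256, 192)):
    scene = make_edge_scene(shape, angle, offset, 1.0, psf_sigma=sigma)
    return scene.intensity_map * 1000.0


def counted_edge_movie(sigma, seed, angle=5.0, shape=(2048, 256)):
    """~1040 detected electrons per physical pixel, as in beamstop practice."""
    spec = cd.DetectorSpec(psf_sigma=sigma, false_positive_rate=0.0)
    return cd.simulate_edge_movie(spec, angle, 0.0, 12.0, 87.0, seed=seed,
                                  shape=shape, accumulate=True)


class TestFitEdge:
    def test_noiseless_angle_recovery(self):
        edge = cd.fit_edge(noiseless_edge_image(0.3))
        assert edge.angle == pytest.approx(5.0, abs=0.05)
        assert edge.rms_line_residual < 0.05

    def test_vertical_edge_rejected(self):
        img = np.zeros((128, 128))
        img[:, :64] = 1000.0
        with pytest.raises(cd.EdgeAngleError, match="steep|shallow"):
            cd.fit_edge(img)

    def test_no_edge_found(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="no edge"):
            cd.fit_edge(rng.poisson(100, (128, 128)).astype(float))

    def test_counted_angle_within_two_tenths(self):
        edge = cd.fit_edge(counted_edge_movie(0.5, seed=14,
                                              shape=(512, 160)))
        assert edge.angle == pytest.approx(5.0, abs=0.2)

    def test_offset_shift_recovered(self):
        """Moving the edge by +0.5 px moves the fit by +0.5 px."""
        e0 = cd.fit_edge(noiseless_edge_image(0.3, offset=0.0))
        e5 = cd.fit_edge(noiseless_edge_image(0.3, offset=0.5))
        mid_row = 128
        shift = e5.edge_x(np.array([mid_row])) - e0.edge_x(np.array([mid_row]))
        assert shift[0] == pytest.approx(0.5, abs=0.05)

    def test_horizontal_edge_transposed(self):
        img = noiseless_edge_image(0.3).T
        edge = cd.fit_edge(img)
        assert edge.transposed
        assert edge.angle == pytest.approx(5.0, abs=0.05)


class TestEdgeToMtf:
    def test_aperture_only_mtf_is_sinc(self):
        """No PSF: MTF = |sinc|, 2/pi = 0.637 at physical Nyquist."""
        img = noiseless_edge_image(0.0)
        curves = cd.edge_to_mtf(img, cd.fit_edge(img))
        assert curves.mtf[0] == 1.0
        assert curves.at(1.0) == pytest.approx(2 / math.pi, abs=0.02)

    @pytest.mark.parametrize("sigma", [0.3, 0.5, 1.0])
    def test_gaussian_psf_recovery_noiseless(self, sigma):
        img = noiseless_edge_image(sigma)
        curves = cd.edge_to_mtf(img, cd.fit_edge(img))
        sel = curves.freq <= 1.0
        true = analytic_system_mtf(curves.freq[sel], sigma)
        assert np.abs(curves.mtf[sel] - true).max() <= 0.02

    @pytest.mark.parametrize("sigma", [0.3, 0.5, 1.0])
    def test_gaussian_psf_recovery_counted(self, sigma):
        """Counted edge at ~1040 e-/px: recovery within 0.03 to Nyquist."""
        movie = counted_edge_movie(sigma, seed=int(sigma * 10))
        curves = cd.edge_to_mtf(movie, cd.fit_edge(movie))
        sel = curves.freq <= 1.0
        true = analytic_system_mtf(curves.freq[sel], sigma)
        assert np.abs(curves.mtf[sel] - true).max() <= 0.03

    def test_polarity_invariance(self):
        spec = cd.DetectorSpec(psf_sigma=0.5, false_positive_rate=0.0)
        grid = np.linspace(0.0, 1.0, 40)
        curves = []
        for side in ("left", "right"):
            movie = cd.simulate_edge_movie(spec, 5.0, 0.0, 12.0, 87.0,
                                           seed=23, shape=(1024, 256),
                                           accumulate=True, bright_side=side)
            c = cd.edge_to_mtf(movie, cd.fit_edge(movie))
            curves.append(np.interp(grid, c.freq, c.mtf))
        assert np.abs(curves[0] - curves[1]).max() < 0.03

    def test_rotation_invariance(self):
        movie = counted_edge_movie(0.5, seed=23, shape=(1024, 256))
        img = movie.physical_image().astype(float)
        grid = np.linspace(0.0, 1.0, 40)
        c1 = cd.edge_to_mtf(img, cd.fit_edge(img))
        rot = np.rot90(img)
        c2 = cd.edge_to_mtf(rot, cd.fit_edge(rot))
        m1 = np.interp(grid, c1.freq, c1.mtf)
        m2 = np.interp(grid, c2.freq, c2.mtf)
        assert np.abs(m1 - m2).max() < 0.01

    def test_mtf_bounded_for_ordinary_scenes(self):
        movie = counted_edge_movie(0.5, seed=31, shape=(1024, 256))
        curves = cd.edge_to_mtf(movie, cd.fit_edge(movie))
        sel = curves.freq <= 1.0
        assert (curves.mtf[sel] >= 0).all()
        assert (curves.mtf[sel] <= 1.02).all()


class TestDqe0:
    def test_ideal_poisson_is_unity(self):
        rng = np.random.default_rng(41)
        img = rng.poisson(20.0, (2048, 2048))
        res = cd.dqe0_noise_binning(img, incident_per_pixel=20.0)
        assert res.mode == "absolute"
        assert res.value == pytest.approx(1.0, abs=0.05)

    def test_binomial_thinning_gives_thinning_fraction(self):
        rng = np.random.default_rng(43)
        img = rng.binomial(rng.poisson(20.0, (2048, 2048)), 0.8)
        res = cd.dqe0_noise_binning(img, incident_per_pixel=20.0)
        assert res.value == pytest.approx(0.8, abs=0.05)

    def test_poisson_relative_mode_flagged(self):
        rng = np.random.default_rng(47)
        img = rng.poisson(15.0, (1024, 1024))
        res = cd.dqe0_noise_binning(img)
        assert res.mode == "poisson_relative"
        assert res.value == pytest.approx(1.0, abs=0.06)
        assert res.incident_per_pixel is None

    def test_window_counting_is_sub_poisson(self, quiet_spec,
                                            printed_model):
        """At-most-one-count-per-window merging makes the detected counts
        sub-Poisson: the zero-frequency variance ratio is ~exp(-a x), so
        the absolute DQE(0) of the simulated flood is (1-CL)/exp(-a x) =
        1/(1-CL), slightly above one."""
        x, duration = 12.5, 100 * quiet_spec.a
        movie, _ = cd.simulate_flat_movie(
            quiet_spec, cd.Scene.uniform((1024, 1024), x), duration,
            seed=53, accumulate=True, ground_truth=False)
        res = cd.dqe0_noise_binning(movie, incident_per_pixel=x * duration)
        lam = quiet_spec.a * x
        assert res.v_infinity == pytest.approx(math.exp(-lam), abs=0.05)
        cl = cd.coincidence_loss(cd.DoseResponseModel(a=quiet_spec.a), x)
        assert res.value == pytest.approx(1.0 / (1.0 - cl), abs=0.06)

    def test_nonuniform_illumination_fails_plateau(self):
        rng = np.random.default_rng(59)
        ramp = np.linspace(5.0, 50.0, 1024)[None, :] * np.ones((1024, 1))
        img = rng.poisson(ramp)
        with pytest.raises(PlateauError, match="uniform"):
            cd.dqe0_noise_binning(img, incident_per_pixel=27.0)

    def test_movie_input_uses_electron_units(self, quiet_spec):
        movie, _ = cd.simulate_flat_movie(
            quiet_spec, cd.Scene.uniform((512, 512), 10.0), 1.0, seed=61,
            accumulate=True, ground_truth=False)
        res = cd.dqe0_noise_binning(movie, incident_eps=10.0)
        assert res.incident_per_pixel == pytest.approx(10.0)
        assert 0.8 < res.value < 1.2


class TestDqeCurve:
    def test_published_worked_example(self):
        """DQE(0)=0.937 with MTF 0.84 / 0.5 gives DQE 0.66 / 0.23."""
        freq = np.array([0.0, 0.5, 1.0])
        mtf = cd.TransferCurves(freq=freq, mtf=np.array([1.0, 0.84, 0.5]))
        curves = cd.dqe_curve(0.937, mtf)
        assert round(curves.at(0.5, "dqe"), 2) == 0.66
        assert round(curves.at(1.0, "dqe"), 2) == 0.23

    def test_unity_everything(self):
        freq = np.linspace(0, 2, 21)
        mtf = cd.TransferCurves(freq=freq, mtf=np.ones_like(freq))
        curves = cd.dqe_curve(1.0, mtf)
        assert np.allclose(curves.dqe, 1.0)

    def test_multiplicative_in_dqe0(self):
        freq = np.linspace(0, 1, 11)
        mtf = cd.TransferCurves(freq=freq, mtf=np.exp(-freq))
        c1 = cd.dqe_curve(0.4, mtf)
        c2 = cd.dqe_curve(0.8, mtf)
        assert np.allclose(c2.dqe, 2 * c1.dqe)

    def test_measured_nnps_divides(self):
        freq = np.linspace(0.0, 2.0, 41)
        mtf = cd.TransferCurves(freq=freq, mtf=np.ones_like(freq))
        nnps = cd.RadialSpectrum(freq=np.linspace(0.0, 2.0, 81),
                                 power=np.full(81, 0.8),
                                 counts=np.full(81, 50), n_bins=81,
                                 norm_band=(1.5, 2.0))
        curves = cd.dqe_curve(0.8, mtf, nnps=nnps)
        assert curves.nnps_assumed == "measured"
        assert np.allclose(curves.dqe, 1.0)

    def test_axis_coverage_required(self):
        freq = np.linspace(0.0, 2.0, 41)
        mtf = cd.TransferCurves(freq=freq, mtf=np.ones_like(freq))
        short = cd.RadialSpectrum(freq=np.linspace(0.0, 1.0, 41),
                                  power=np.ones(41),
                                  counts=np.full(41, 50), n_bins=41,
                                  norm_band=(0.5, 1.0))
        with pytest.raises(ValueError, match="cover"):
            cd.dqe_curve(0.9, mtf, nnps=short)


def test_theoretical_square_pixel_dqe():
    assert cd.theoretical_square_pixel_dqe(0.0) == pytest.approx(1.0)
    assert cd.theoretical_square_pixel_dqe(1.0) == pytest.approx(0.405,
                                                                 abs=0.001)
    assert round(cd.theoretical_square_pixel_dqe(1.0), 1) == 0.4
    assert cd.theoretical_square_pixel_dqe(0.5) == pytest.approx(0.811,
                                                                 abs=0.001)
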
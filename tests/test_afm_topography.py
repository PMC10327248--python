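"""Pseudo-AFM synthesis, noise machinery and Fourier-ring resolution."""

import numpy as np
import pytest

from afmfit.afm_topography import (
    BENCHMARK_NOISE_LEVELS,
    TipModel,
    acv,
    add_gaussian_noise,
    estimate_background_noise,
    full_band_nm_inv,
    lowpass_ring,
    resolution_profile,
    synthesize_surface,
)
from afmfit.io_formats import AFMSurface

from .conftest import simple_model


def _single_bead_model(x, y, z):
    # one full residue; sugar carries the bead of interest, others colocated
    return simple_model(np.array([[x, y, z]] * 3))


class TestSynthesis:
    def test_single_bead_sharp_tip_cap(self):
        tip = TipModel(radius=0.0, bead_radius=4.0)
        m = _single_bead_model(0.0, 0.0, 0.0)
        s = synthesize_surface(m, pixel_size=1.0, tip=tip, margin=10.0)
        # dropped so the bead surface rests at 0 -> center z = 4
        assert s.heights.max() == pytest.approx(8.0, abs=1e-9)
        xs, ys = s.x_coords(), s.y_coords()
        X, Y = np.meshgrid(xs, ys)
        rho = np.hypot(X, Y)
        assert np.all(s.heights[rho > 4.0 + 1e-9] == 0.0)
        assert np.all(s.heights[rho < 4.0 - 1e-9] > 0.0)

    def test_tip_dilation_widens_footprint_not_peak(self):
        m = _single_bead_model(0.0, 0.0, 0.0)
        sharp = synthesize_surface(m, pixel_size=1.0,
                                   tip=TipModel(radius=0.0, bead_radius=4.0),
                                   margin=20.0)
        blunt = synthesize_surface(m, pixel_size=1.0,
                                   tip=TipModel(radius=10.0, bead_radius=4.0),
                                   margin=20.0)
        assert blunt.heights.max() == pytest.approx(sharp.heights.max(), abs=1e-9)
        xs, ys = blunt.x_coords(), blunt.y_coords()
        X, Y = np.meshgrid(xs, ys)
        rho = np.hypot(X, Y)
        # contact region (possibly zero-clipped) extends to rho = 14
        assert np.all(blunt.heights[rho > 14.0 + 1e-9] == 0.0)
        contact = (rho < 12.0) & (rho > 4.5)
        assert np.all(blunt.heights[contact] >= 0.0)
        assert blunt.heights[(rho > 4.5) & (rho < 10.0)].max() > 0.0

    def test_brute_force_dilation_oracle(self, hairpin, tip):
        # oracle: sample each bead sphere finely; image = max contact height
        model, _ = hairpin
        s = synthesize_surface(model, pixel_size=5.0, tip=tip, margin=10.0)
        coords = model.coords.copy()
        coords[:, 2] -= coords[:, 2].min() - tip.bead_radius
        R = tip.contact_radius
        xs, ys = s.x_coords(), s.y_coords()
        expect = np.zeros_like(s.heights)
        for iy, y in enumerate(ys):
            for ix, x in enumerate(xs):
                best = 0.0
                for b in coords:
                    rho2 = (x - b[0]) ** 2 + (y - b[1]) ** 2
                    if rho2 <= R * R:
                        h = b[2] - tip.radius + np.sqrt(R * R - rho2)
                        best = max(best, h)
                expect[iy, ix] = best
        np.testing.assert_allclose(s.heights, expect, atol=1e-9)

    def test_dilation_monotone_in_tip_radius(self, hairpin):
        model, _ = hairpin
        base = synthesize_surface(model, tip=TipModel(radius=0.0), margin=25.0)
        for r in (5.0, 10.0):
            s = synthesize_surface(model, tip=TipModel(radius=r), margin=25.0,
                                   grid_like=base)
            assert np.all(s.heights >= base.heights - 1e-9)

    def test_translation_equivariance(self, hairpin, tip):
        model, _ = hairpin
        base = synthesize_surface(model, tip=tip, margin=30.0)
        shifted_model = model.with_coords(model.coords + [10.0, 5.0, 0.0])
        shifted = synthesize_surface(shifted_model, tip=tip, grid_like=base)
        # 10 A = 2 px right, 5 A = 1 px up
        np.testing.assert_allclose(shifted.heights[1:, 2:],
                                   base.heights[:-1, :-2], atol=1e-9)

    def test_invalid_pixel_size(self, hairpin, tip):
        model, _ = hairpin
        with pytest.raises(ValueError):
            synthesize_surface(model, pixel_size=0.0, tip=tip)


class TestNoise:
    def test_level_zero_identity(self, hairpin, tip):
        model, _ = hairpin
        s = synthesize_surface(model, tip=tip)
        n = add_gaussian_noise(s, 0.0, seed=1)
        np.testing.assert_array_equal(n.heights, s.heights)

    def test_injected_sigma_recovered(self):
        base = AFMSurface(np.full((256, 256), 20.0), pixel_size=5.0)
        noisy = add_gaussian_noise(base, 0.10, seed=2)
        # plateau at 20 with sigma 2: clipping negligible
        assert noisy.heights.std() == pytest.approx(0.10 * 20.0, rel=0.05)

    def test_deterministic_per_seed(self, flat_surface):
        a = add_gaussian_noise(flat_surface, 0.3, seed=5)
        b = add_gaussian_noise(flat_surface, 0.3, seed=5)
        c = add_gaussian_noise(flat_surface, 0.3, seed=6)
        np.testing.assert_array_equal(a.heights, b.heights)
        assert not np.array_equal(a.heights, c.heights)

    def test_level_bounds(self, flat_surface):
        with pytest.raises(ValueError):
            add_gaussian_noise(flat_surface, -0.1, seed=0)
        with pytest.raises(ValueError):
            add_gaussian_noise(flat_surface, 1.1, seed=0)

    def test_benchmark_levels_as_published(self):
        assert BENCHMARK_NOISE_LEVELS == (0.05, 0.10, 0.15, 0.20, 0.30,
                                          0.40, 0.50)


class TestBackgroundNoise:
    def test_flat_background_zero_sigma(self):
        z = np.zeros((32, 32))
        z[12:20, 12:20] = 25.0
        est = estimate_background_noise(AFMSurface(z, 5.0))
        assert est.mean == 0.0
        assert est.sigma == 0.0

    def test_recovers_injected_sigma(self):
        rng = np.random.default_rng(3)
        z = np.abs(rng.normal(0.0, 0.5, (128, 128)))  # |N|: known sigma ratio
        z[40:60, 40:60] = 30.0
        mask = z > 20.0
        est = estimate_background_noise(AFMSurface(z, 5.0), particle_mask=mask)
        # folded normal of N(0, 0.5): sd = 0.5*sqrt(1-2/pi)... use direct
        background = z[~mask]
        assert est.sigma == pytest.approx(background.std(ddof=1), rel=1e-12)
        assert est.n_pixels == background.size

    def test_unfolded_gaussian_background_within_5pct(self):
        rng = np.random.default_rng(4)
        z = np.full((128, 128), 5.0) + rng.normal(0, 0.5, (128, 128))
        z[50:70, 50:70] = 40.0
        mask = z > 20.0
        est = estimate_background_noise(AFMSurface(z, 5.0), particle_mask=mask)
        assert est.sigma == pytest.approx(0.5, rel=0.05)
        assert est.n_pixels >= 10_000

    def test_all_particle_mask_errors(self, flat_surface):
        with pytest.raises(ValueError):
            estimate_background_noise(flat_surface,
                                      particle_mask=np.ones((8, 8), bool))


class TestResolution:
    def _textured(self, n=64, seed=0):
        rng = np.random.default_rng(seed)
        return AFMSurface(np.abs(rng.normal(5, 2, (n, n))), pixel_size=5.0)

    def test_lowpass_full_band_identity(self):
        s = self._textured()
        out = lowpass_ring(s, full_band_nm_inv(s))
        np.testing.assert_allclose(out.heights, s.heights, atol=1e-9)

    def test_lowpass_to_dc_plane(self):
        s = self._textured()
        out = lowpass_ring(s, 1e-6)
        np.testing.assert_allclose(out.heights, s.heights.mean(), atol=1e-9)

    def test_single_sinusoid_below_cutoff_unchanged(self):
        n = 64
        x = np.arange(n)
        # frequency 4 cycles / (n px * 5 A) = 0.0125 /A = 0.125 nm^-1
        grid = 3.0 + np.sin(2 * np.pi * 4 * x[None, :] / n) * np.ones((n, 1))
        s = AFMSurface(grid, pixel_size=5.0)
        out = lowpass_ring(s, 0.2)
        np.testing.assert_allclose(out.heights, s.heights, atol=1e-6)
        # and removed when the cutoff sits below it
        out2 = lowpass_ring(s, 0.05)
        np.testing.assert_allclose(out2.heights, 3.0, atol=1e-6)

    def test_acv_identity_and_reflection(self):
        s = self._textured(seed=1)
        assert acv(s, s) == pytest.approx(1.0, abs=1e-12)
        refl = AFMSurface(2 * s.heights.mean() - s.heights, s.pixel_size)
        assert acv(s, refl) == pytest.approx(-1.0, abs=1e-12)

    def test_acv_formula_oracle(self):
        r = AFMSurface(np.array([[0.0, 1.0], [2.0, 3.0]]), 5.0)
        rp = AFMSurface(np.array([[0.0, 1.0], [1.0, 2.0]]), 5.0)
        a, b = r.heights.ravel(), rp.heights.ravel()
        da, db = a - a.mean(), b - b.mean()
        expect = np.sum(da * db) / np.sqrt(np.sum(da**2) * np.sum(db**2))
        assert acv(r, rp) == pytest.approx(expect, abs=1e-9)

    def test_acv_zero_variance_error(self, flat_surface):
        with pytest.raises(ValueError):
            acv(flat_surface, flat_surface)

    def test_profile_endpoint_reaches_one(self):
        prof = resolution_profile(self._textured(seed=2), n_rings=16)
        assert prof.acv[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(prof.cutoffs) > 0)

    def test_band_limited_surface_saturates(self):
        # construct by truncating the spectrum of a textured surface
        s = self._textured(seed=3)
        f0 = 0.4 * full_band_nm_inv(s)
        band = lowpass_ring(s, f0)
        prof = resolution_profile(band, n_rings=24)
        above = prof.cutoffs >= f0 + 1e-9
        np.testing.assert_allclose(prof.acv[above], 1.0, atol=1e-9)

    def test_white_noise_acv_monotone(self):
        prof = resolution_profile(self._textured(seed=4), n_rings=20)
        assert np.all(np.diff(prof.acv) >= -1e-12)

    def test_degenerate_surface_error(self, flat_surface):
        with pytest.raises(ValueError):
            resolution_profile(flat_surface)
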
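import numpy as np
import pytest

from conftest import PIXEL_NM, params_from_truth, uniform_field
from simsir import (
    Domain,
    Field2D,
    FilterSettings,
    GroundTruth,
    RawStack,
    SimParams,
    apodize,
    forward_transform,
    hermitian_mirror,
    make_bead_surface,
    make_point_pair,
    place_bands,
    reconstruct,
    simulate_stack,
    support_radius,
    widefield_and_filtered,
    wiener_combine,
)
from simsir.bands import separate
from simsir.fourier import freq_radii_cyc_per_img, inverse_transform


def kc_cyc_img(otf, n, pix=PIXEL_NM):
    return otf.cutoff_cyc_per_um * n * pix * 1e-3


class TestWienerCombine:
    def test_single_flat_band_scalar_filter(self):
        n = 32
        rng = np.random.default_rng(0)
        spec = Field2D(rng.normal(size=(n, n)) + 0j, PIXEL_NM, Domain.FREQ)
        settings = FilterSettings(wiener_w=0.3)
        out = wiener_combine([(spec, np.ones((n, n)))], settings)
        np.testing.assert_allclose(out.values, spec.values / (1 + 0.3**2))

    def test_large_w_suppresses_output(self):
        n = 32
        spec = Field2D(np.ones((n, n)) + 0j, PIXEL_NM, Domain.FREQ)
        strong = wiener_combine([(spec, np.ones((n, n)))], FilterSettings(wiener_w=1.0))
        weak = wiener_combine([(spec, np.ones((n, n)))], FilterSettings(wiener_w=0.01))
        assert np.abs(strong.values).max() < np.abs(weak.values).max()

    def test_noiseless_error_decreases_with_w(self, bead_object, otf):
        # on noise-free data, less regularization means a closer object fit
        # inside the extended support
        n = bead_object.object_image.size_px
        stack, truth = simulate_stack(bead_object, otf, 3, 3, 2, modulation=0.8,
                                      photons=None, seed=1)
        params = params_from_truth(truth)
        obj_spec = forward_transform(bead_object.object_image).values
        ref = np.zeros((2 * n, 2 * n), complex)
        ref[n // 2 : n // 2 + n, n // 2 : n // 2 + n] = obj_spec
        kc = kc_cyc_img(otf, n)
        k1 = max(np.hypot(*t["k_vector"]) for t in truth)
        mask = freq_radii_cyc_per_img(2 * n) < 0.8 * (kc + k1)
        errs = []
        for w in (0.5, 0.2, 0.05, 0.01):
            res = reconstruct(stack, params, otf,
                              FilterSettings(wiener_w=w, fade_px=0,
                                             apodization="none"))
            sr, rf = res.sr_spectrum.values[mask], ref[mask]
            scale = np.vdot(rf, sr) / np.vdot(rf, rf)
            errs.append(float(np.linalg.norm(sr - scale * rf) / np.linalg.norm(rf)))
        assert all(a > b for a, b in zip(errs, errs[1:]))


class TestApodization:
    def test_none_is_identity(self):
        spec = Field2D(np.random.default_rng(1).normal(size=(32, 32)) + 0j,
                       PIXEL_NM, Domain.FREQ)
        out = apodize(spec, FilterSettings(apodization="none"), 10.0)
        np.testing.assert_array_equal(out.values, spec.values)

    def test_zero_at_extended_cutoff_and_monotone(self):
        n = 64
        spec = Field2D(np.ones((n, n)) + 0j, PIXEL_NM, Domain.FREQ)
        k_ext = 20.0
        out = apodize(spec, FilterSettings(), k_ext)
        r = freq_radii_cyc_per_img(n)
        assert np.abs(out.values[np.abs(r - k_ext) < 0.5]).max() < 0.05
        assert np.abs(out.values[r > k_ext]).max() == 0.0
        prof = np.abs(out.values[n // 2, n // 2 :])
        assert np.all(np.diff(prof) <= 1e-12)


class TestPlaceBands:
    def test_zero_order_band_is_unshifted(self, two_beam_stack, otf):
        stack, truth = two_beam_stack
        sep = separate(stack, 0)
        params = params_from_truth(truth)[0]
        placed = place_bands(sep, params, otf)
        band0, weight0 = placed[0]
        big = np.zeros_like(band0.values)
        n = stack.size_px
        big[n // 2 : n // 2 + n, n // 2 : n // 2 + n] = sep.components[0].values
        og = otf.grid(2 * n, stack.pixel_size_nm / 2)
        np.testing.assert_allclose(band0.values, big * og, atol=1e-9)
        np.testing.assert_allclose(weight0, og * og)

    def test_cross_band_consistency_on_tone(self, otf):
        # a pure-tone object must land at the same frequency through band 0
        # and band 1 once both are placed
        n = 128
        x = np.arange(n)
        tone = 1.0 + 0.9 * np.cos(2 * np.pi * 12 * x / n)[None, :] * np.ones((n, 1))
        gt = GroundTruth(Field2D(tone, PIXEL_NM, Domain.REAL), {"kind": "tone"})
        stack, truth = simulate_stack(gt, otf, 1, 3, 2, k_vectors=[(20.0, 0.0)],
                                      modulation=0.8, photons=None, seed=0)
        params = params_from_truth(truth)[0]
        sep = separate(stack, 0, fade_px=0)
        placed = place_bands(sep, params, otf)
        n2 = 2 * n
        idx = (n2 // 2, n2 // 2 + 12)  # the tone's +12 cyc/img sample
        v0 = placed[0][0].values[idx]
        v1 = placed[1][0].values[idx]
        # identical object content; each route carries its own OTF twice
        # (detection + the conjugate-OTF numerator factor)
        o_here = otf.grid(n2, PIXEL_NM / 2)[idx]
        o_shift = otf.grid(n2, PIXEL_NM / 2, (-20.0, 0.0))[idx]
        assert abs(v1 / o_shift**2 - v0 / o_here**2) / abs(v0 / o_here**2) < 1e-3

    def test_mirror_is_hermitian_reflection(self, two_beam_stack, otf):
        stack, truth = two_beam_stack
        sep = separate(stack, 0)
        placed = place_bands(sep, params_from_truth(truth)[0], otf)
        plus, _ = placed[1]
        minus, _ = placed[2]
        np.testing.assert_allclose(
            minus.values, hermitian_mirror(plus).values, atol=1e-9)

    def test_shift_beyond_nyquist_rejected(self, two_beam_stack, otf):
        stack, truth = two_beam_stack
        sep = separate(stack, 0)
        bad = SimParams((130.0, 0.0), (0.0,), (0.8,))
        with pytest.raises(ValueError, match="Nyquist"):
            place_bands(sep, bad, otf)


class TestReconstruct:
    def test_output_sizing_contract(self, two_beam_stack, otf):
        stack, truth = two_beam_stack
        res = reconstruct(stack, params_from_truth(truth), otf)
        assert res.sr_image.size_px == 2 * stack.size_px
        assert res.sr_image.pixel_size_nm == stack.pixel_size_nm / 2
        assert res.widefield.size_px == stack.size_px

    def test_three_beam_15_frames_double_size(self, three_beam_stack, otf):
        stack, truth = three_beam_stack
        assert len(stack.frames) == 15
        res = reconstruct(stack, params_from_truth(truth), otf)
        assert res.sr_image.size_px == 2 * stack.size_px

    def test_output_is_real_without_warning(self, two_beam_stack, otf):
        import warnings

        stack, truth = two_beam_stack
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = reconstruct(stack, params_from_truth(truth), otf)
        assert np.isrealobj(np.real(res.sr_image.values))

    def test_uniform_object_no_pattern_printthrough(self, otf):
        n = 128
        gt = GroundTruth(uniform_field(n), {"kind": "uniform"})
        stack, truth = simulate_stack(gt, otf, 3, 3, 2, modulation=0.8,
                                      photons=None, seed=0)
        res = reconstruct(stack, params_from_truth(truth), otf)
        v = np.real(res.sr_image.values)
        m = 3 * (2 * (n // 16))  # stay clear of the windowed border
        core = v[m:-m, m:-m]
        assert core.std() / core.mean() < 0.01

    def test_linearity_of_fixed_parameter_pipeline(self, otf):
        gt_a = make_bead_surface(30, 128, PIXEL_NM, seed=3)
        gt_b = make_bead_surface(30, 128, PIXEL_NM, seed=4)
        stack_a, truth = simulate_stack(gt_a, otf, 3, 3, 2, modulation=0.8,
                                        photons=None, seed=0)
        stack_b, _ = simulate_stack(gt_b, otf, 3, 3, 2, modulation=0.8,
                                    photons=None, seed=0)
        al, be = 1.7, -0.4
        mixed = RawStack(
            [Field2D(al * a.values + be * b.values, PIXEL_NM, Domain.REAL)
             for a, b in zip(stack_a.frames, stack_b.frames)],
            3, 3, 2, stack_a.ordering, PIXEL_NM)
        params = params_from_truth(truth)
        fs = FilterSettings()
        r_a = reconstruct(stack_a, params, otf, fs)
        r_b = reconstruct(stack_b, params, otf, fs)
        r_m = reconstruct(mixed, params, otf, fs)
        lhs = np.real(r_m.sr_image.values)
        rhs = al * np.real(r_a.sr_image.values) + be * np.real(r_b.sr_image.values)
        assert np.abs(lhs - rhs).max() / np.abs(rhs).max() < 1e-9

    def test_rotational_equivariance_periodic_grid(self, otf):
        # exact for integer-cycle patterns under the periodic quarter-turn
        # about the FFT centre (fractional patterns are not grid-periodic)
        n = 128

        def rot(a):
            idx = np.arange(a.shape[0])
            return a[(-idx) % a.shape[0], :].T

        gt = make_bead_surface(40, n, PIXEL_NM, seed=6)
        kv = [(30, 5), (10, 28), (-20, 22)]
        stack1, truth1 = simulate_stack(gt, otf, 3, 3, 2, k_vectors=kv,
                                        phase_offsets=[0.3, 1.2, -0.8],
                                        modulation=0.8, photons=None, seed=0)
        gt_r = GroundTruth(
            Field2D(rot(np.real(gt.object_image.values)), PIXEL_NM, Domain.REAL), {})
        stack2, truth2 = simulate_stack(gt_r, otf, 3, 3, 2,
                                        k_vectors=[(-ky, kx) for kx, ky in kv],
                                        phase_offsets=[0.3, 1.2, -0.8],
                                        modulation=0.8, photons=None, seed=0)
        fs = FilterSettings(fade_px=0)
        r1 = reconstruct(stack1, params_from_truth(truth1), otf, fs)
        r2 = reconstruct(stack2, params_from_truth(truth2), otf, fs)
        a = rot(np.real(r1.sr_image.values))
        b = np.real(r2.sr_image.values)
        assert np.abs(a - b).max() / np.abs(b).max() < 1e-9

    def test_support_doubling_at_cutoff_pattern(self, otf):
        # |k_pattern| = kc: azimuthal power support of the reconstruction is
        # twice the widefield support (the resolution-doubling claim)
        n = 256
        gt = make_bead_surface(50, n, PIXEL_NM, diameter_nm=40.0, seed=2)
        stack, truth = simulate_stack(gt, otf, 3, 3, 2, k_frac_of_cutoff=1.0,
                                      modulation=0.8, photons=None, seed=2)
        res = reconstruct(stack, params_from_truth(truth), otf)
        kc = kc_cyc_img(otf, n)
        inband = (0.1 * kc, 0.4 * kc)
        r_wf = support_radius(forward_transform(res.widefield), 1e-3, inband)
        r_sr = support_radius(res.sr_spectrum, 1e-3, inband)
        assert r_sr / r_wf == pytest.approx(2.0, abs=0.1)

    def test_detail_levels_emit_intermediates(self, two_beam_stack, otf):
        stack, truth = two_beam_stack
        params = params_from_truth(truth)
        assert reconstruct(stack, params, otf).intermediates == {}
        res = reconstruct(stack, params, otf, FilterSettings(detail="full"))
        keys = res.intermediates.keys()
        assert any("band" in k and "_spectrum" in k for k in keys)
        assert any("band" in k and "_spatial" in k for k in keys)
        assert any("combined_spatial" in k for k in keys)


class TestWidefield:
    def test_identical_frames_mean(self, otf):
        n = 64
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 100, size=(n, n))
        frames = [Field2D(frame.copy(), PIXEL_NM, Domain.REAL) for _ in range(9)]
        stack = RawStack(frames, 3, 3, 2, pixel_size_nm=PIXEL_NM)
        wf, _ = widefield_and_filtered(stack, otf)
        np.testing.assert_allclose(np.real(wf.values), frame)

    def test_filtered_point_source_radially_symmetric(self, otf):
        n = 64
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        frames = [Field2D(img.copy(), PIXEL_NM, Domain.REAL) for _ in range(9)]
        stack = RawStack(frames, 3, 3, 2, pixel_size_nm=PIXEL_NM)
        _, filt = widefield_and_filtered(stack, otf)
        v = np.real(filt.values)
        # periodic point reflection about the source pixel (n/2, n/2)
        idx = (n - np.arange(n)) % n
        np.testing.assert_allclose(v, v[np.ix_(idx, idx)], atol=1e-9 * np.abs(v).max())
        np.testing.assert_allclose(v, v.T, atol=1e-9 * np.abs(v).max())

    def test_bead_pair_resolved_only_in_sr(self, otf):
        # two emitters at 0.6x the Rayleigh distance: single blob in the
        # filtered widefield, two maxima with a clear dip in the SR image.
        # Pattern parameters are calibrated on a bead-field stack (the
        # instrument property), then applied to the pair acquisition.
        from simsir import estimate_parameters
        from simsir.metrics import two_point_dip

        n = 256
        sep_nm = 0.6 * 0.61 * otf.lambda_em_nm / otf.na
        beads = make_bead_surface(150, n, PIXEL_NM, diameter_nm=120.0, seed=21)
        cal_stack, _ = simulate_stack(beads, otf, 3, 3, 2, modulation=0.8,
                                      photons=2000.0, seed=11)
        params = estimate_parameters(cal_stack, otf)
        pair = make_point_pair(sep_nm, n, PIXEL_NM, orientation_deg=0.0)
        pair_stack, _ = simulate_stack(pair, otf, 3, 3, 2, modulation=0.8,
                                       photons=2000.0, seed=12)
        res = reconstruct(pair_stack, params, otf)
        assert two_point_dip(res.filtered_widefield, sep_nm) < 0.05
        assert two_point_dip(res.sr_image, sep_nm) >= 0.20
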
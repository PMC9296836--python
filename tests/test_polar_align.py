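"""Polar/FFT alignment kernels against direct (non-FFT) oracles."""

import numpy as np
import pytest

from isac2d.polar_align import (
    SearchGrid,
    align,
    align_assigned,
    align_multiref,
    average_class,
    ccf_rotational,
    normalize,
    to_polar_fft,
)
from isac2d.stack_io import make_synthetic_stack, motif
from isac2d.transforms import AlignmentParams, apply_transform, invert_params, mirror_image
from tests.conftest import circular_mask, masked_ncc


def direct_polar_rings(image, grid, shift=(0, 0)):
    """Independent bilinear resampling of the weighted polar rings."""
    b = image.shape[-1]
    c = b // 2
    radii = np.asarray(grid.ring_radii, dtype=float)
    phi = 2 * np.pi * np.arange(grid.n_angular) / grid.n_angular
    out = np.zeros((len(radii), grid.n_angular))
    for ri, r in enumerate(radii):
        for ai, p in enumerate(phi):
            col = c + shift[0] + r * np.cos(p)
            row = c - (shift[1] + r * np.sin(p))
            r0, c0 = int(np.floor(row)), int(np.floor(col))
            fr, fc = row - r0, col - c0
            r1, c1 = min(r0 + 1, b - 1), min(c0 + 1, b - 1)  # zero-weight at edge
            out[ri, ai] = (
                image[r0, c0] * (1 - fr) * (1 - fc)
                + image[r0, c1] * (1 - fr) * fc
                + image[r1, c0] * fr * (1 - fc)
                + image[r1, c1] * fr * fc
            )
        out[ri] *= np.sqrt(2 * np.pi * r)
    return out


class TestSearchGrid:
    def test_shifted_rings_must_fit_in_the_box(self):
        with pytest.raises(ValueError, match="leave the frame"):
            SearchGrid(ring_radii=tuple(range(1, 15)), s_max=3, n_angular=64).validate_box(32)

    def test_angular_increment(self, grid32):
        assert grid32.angular_increment == 360.0 / grid32.n_angular

    def test_default_rings_and_angular_sampling(self):
        g = SearchGrid.for_box(32, s_max=3)
        assert g.max_radius == 32 // 2 - 1 - 3
        assert g.n_angular >= 2 * np.pi * g.max_radius
        assert g.n_angular & (g.n_angular - 1) == 0  # power of two


class TestNormalize:
    def test_masked_mean_zero_variance_one(self, blob_image):
        out = normalize(blob_image * 3.7 + 2.2, mask_radius=14)
        mask = circular_mask(32, 14)
        assert out[mask].mean() == pytest.approx(0.0, abs=1e-9)
        assert out[mask].var() == pytest.approx(1.0, rel=1e-6)

    def test_constant_image_is_flagged_degenerate(self):
        out, flag = normalize(np.full((32, 32), 5.0), return_flag=True)
        assert flag
        np.testing.assert_array_equal(out, 0.0)

    def test_idempotent(self, blob_image):
        once = normalize(blob_image)
        np.testing.assert_allclose(normalize(once), once, atol=1e-9)


class TestPolarSpectrum:
    def test_rotationally_symmetric_image_has_no_angular_power(self, grid32):
        b = 32
        jj, ii = np.meshgrid(np.arange(b), np.arange(b))
        g = np.exp(-((jj - 16) ** 2 + (ii - 16) ** 2) / (2 * 5.0**2))
        spec = to_polar_fft(g, grid32, (0, 0), unit_norm=False)
        ratio = np.abs(spec.data[:, 1:]).max() / np.abs(spec.data[:, 0]).max()
        assert ratio < 1e-2  # only bilinear anisotropy remains

    def test_shift_covariance_for_integer_translation(self, blob_image, grid32):
        translated = np.roll(blob_image, (-2, 2), axis=(0, 1))  # +2 in x, +2 in y
        a = to_polar_fft(blob_image, grid32, (0, 0))
        b = to_polar_fft(translated, grid32, (2, 2))
        np.testing.assert_allclose(b.data, a.data, atol=1e-6)

    def test_rings_match_direct_resampling_oracle(self, grid32):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(32, 32))
        spec = to_polar_fft(img, grid32, (1, -2), unit_norm=False)
        oracle = direct_polar_rings(img, grid32, (1, -2))
        np.testing.assert_allclose(spec.rings(), oracle, atol=1e-10)

    def test_off_grid_shift_rejected(self, blob_image, grid32):
        with pytest.raises(ValueError, match="not on the search grid"):
            to_polar_fft(blob_image, grid32, (9, 0))


class TestCcfRotational:
    def test_autocorrelation_peaks_at_zero_rotation(self, blob_image, grid32):
        p = to_polar_fft(blob_image, grid32)
        ccf = ccf_rotational(p, p)
        assert np.argmax(ccf) == 0
        assert ccf[0] == pytest.approx(1.0, abs=1e-9)

    def test_quarter_turn_moves_the_argmax(self, blob_image, grid32):
        rotated = apply_transform(blob_image, AlignmentParams(0, 0, 90.0, 0))
        ccf = ccf_rotational(to_polar_fft(rotated, grid32), to_polar_fft(blob_image, grid32))
        # registering the rotated copy back needs a -90 degree turn
        expected = int(round((360.0 - 90.0) / grid32.angular_increment))
        assert abs(int(np.argmax(ccf)) - expected) <= 1

    def test_matches_direct_rotational_inner_product(self, grid32):
        rng = np.random.default_rng(4)
        x = normalize(rng.normal(size=(32, 32)))
        y = normalize(rng.normal(size=(32, 32)))
        p, r = to_polar_fft(x, grid32), to_polar_fft(y, grid32)
        ccf = ccf_rotational(p, r)
        pr, rr = p.rings(), r.rings()
        # entry a rotates the particle CCW by a * increment: p(phi - a)
        oracle = np.array(
            [np.sum(np.roll(pr, a, axis=1) * rr) for a in range(grid32.n_angular)]
        )
        np.testing.assert_allclose(ccf, oracle, atol=1e-8)

    def test_grid_mismatch_rejected(self, blob_image, grid32):
        other = SearchGrid.for_box(32, s_max=1)
        with pytest.raises(ValueError, match="different grids"):
            ccf_rotational(to_polar_fft(blob_image, grid32), to_polar_fft(blob_image, other))


class TestAlign:
    def test_self_alignment_is_identity_with_unit_peak(self, blob_image, grid32):
        p = align(blob_image, blob_image, grid32)
        assert (p.sx, p.sy, p.theta, p.mirror) == (0, 0, 0, 0)
        assert p.peak == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "true", [(2, -1, 40.0, 0), (-2, 2, 123.75, 1), (1, 2, 0.0, 1), (0, 0, 90.0, 0)]
    )
    def test_recovers_known_transform(self, blob_image, grid32, true):
        t = AlignmentParams(*true)
        particle = apply_transform(blob_image, invert_params(t))
        rec = align(particle, blob_image, grid32)
        assert rec.sx == t.sx and rec.sy == t.sy and rec.mirror == t.mirror
        dtheta = min((rec.theta - t.theta) % 360, (t.theta - rec.theta) % 360)
        assert dtheta <= grid32.angular_increment

    def test_mirror_detected_on_asymmetric_motif(self, motif32, grid32):
        assert align(mirror_image(motif32), motif32, grid32).mirror == 1

    def test_degenerate_particle_flagged_identity(self, motif32, grid32):
        p = align(np.zeros((32, 32)), motif32, grid32)
        assert p.degenerate
        assert p.peak == 0.0 and p.identity

    def test_score_monotonicity_self_beats_others(self, grid32):
        rng = np.random.default_rng(6)
        x = normalize(motif(0, 32))
        best = align(x, x, grid32).peak
        for k in range(1, 5):
            assert best >= align(normalize(motif(k, 32)), x, grid32).peak

    def test_peak_symmetry_under_symmetric_shift_search(self, grid32):
        x = normalize(motif(0, 32))
        y = normalize(motif(1, 32))
        assert align(x, y, grid32).peak == pytest.approx(
            align(y, x, grid32).peak, abs=0.02
        )


class TestBatchedAligners:
    def test_multiref_equals_pairwise_loop(self, grid24):
        rng = np.random.default_rng(7)
        parts = rng.normal(size=(8, 24, 24))
        refs = rng.normal(size=(3, 24, 24))
        table = align_multiref(parts, refs, grid24)
        assert table.shape == (8, 3)  # m x k parameter tuples
        for i in range(8):
            for j in range(3):
                single = align(parts[i], refs[j], grid24)
                rec = table[i, j]
                assert (rec["sx"], rec["sy"], rec["theta"], rec["mirror"]) == (
                    single.sx,
                    single.sy,
                    single.theta,
                    single.mirror,
                )
                assert rec["peak"] == pytest.approx(single.peak, rel=1e-6)

    def test_single_pair_reduces_to_align(self, blob_image, motif32, grid32):
        table = align_multiref(blob_image[None], motif32[None], grid32)
        single = align(blob_image, motif32, grid32)
        assert table[0, 0]["peak"] == pytest.approx(single.peak, rel=1e-9)
        assert table[0, 0]["theta"] == single.theta

    def test_chunked_equals_unchunked(self, grid24):
        rng = np.random.default_rng(8)
        parts = rng.normal(size=(10, 24, 24))
        refs = rng.normal(size=(2, 24, 24))
        full = align_multiref(parts, refs, grid24)
        chunked = align_multiref(parts, refs, grid24, chunk=3)
        np.testing.assert_array_equal(full, chunked)

    def test_assigned_matches_multiref_columns(self, grid24):
        rng = np.random.default_rng(9)
        parts = rng.normal(size=(12, 24, 24))
        refs = rng.normal(size=(3, 24, 24))
        assignment = rng.integers(0, 3, size=12)
        table = align_multiref(parts, refs, grid24)
        assigned = align_assigned(parts, assignment, refs, grid24)
        for i in range(12):
            want = table[i, assignment[i]]
            got = assigned[i]
            for f in ("sx", "sy", "theta", "mirror"):
                assert got[f] == want[f]
            assert got["peak"] == pytest.approx(want["peak"], rel=1e-9)

    def test_assigned_permutation_equivariance(self, grid24):
        rng = np.random.default_rng(10)
        parts = rng.normal(size=(9, 24, 24))
        refs = rng.normal(size=(2, 24, 24))
        assignment = rng.integers(0, 2, size=9)
        base = align_assigned(parts, assignment, refs, grid24)
        perm = rng.permutation(9)
        permuted = align_assigned(parts[perm], assignment[perm], refs, grid24)
        np.testing.assert_array_equal(permuted, base[perm])

    def test_assigned_rejects_bad_reference_index(self, grid24):
        parts = np.random.default_rng(0).normal(size=(3, 24, 24))
        with pytest.raises(ValueError, match="non-existent reference"):
            align_assigned(parts, [0, 1, 5], parts[:2], grid24)

    def test_mixed_box_sizes_rejected(self, grid24):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="box"):
            align_multiref(
                rng.normal(size=(2, 24, 24)), rng.normal(size=(1, 32, 32)), grid24
            )


class TestAverageClass:
    def test_single_member_identity_is_normalized_member(self, blob_image):
        avg, count = average_class(blob_image[None], [AlignmentParams()])
        assert count == 1
        np.testing.assert_allclose(avg, normalize(blob_image), atol=1e-9)

    def test_member_permutation_leaves_average_unchanged(self, grid32):
        stack, truth = make_synthetic_stack(1, 10, 32, snr=1.0, max_shift=2, seed=12)
        imgs = stack.images.astype(float)
        params = truth.true_transform
        a1, _ = average_class(imgs, params)
        perm = np.random.default_rng(0).permutation(10)
        a2, _ = average_class(imgs[perm], [params[i] for i in perm])
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_noise_averages_out_as_one_over_n(self):
        """Residual noise variance in the average shrinks like 1/N."""
        b = 32
        mask = circular_mask(b, 13)
        m0 = normalize(motif(0, b))

        def residual_var(n, snr, seed):
            stack, truth = make_synthetic_stack(1, n, b, snr=snr, max_shift=2, seed=seed)
            avg, _ = average_class(stack.images.astype(float), truth.true_transform)
            r = avg - m0
            return np.mean(r[mask] ** 2)

        bias = residual_var(64, np.inf, 1)  # interpolation/normalization floor
        v = {n: residual_var(n, 0.5, 40 + n) - bias for n in (4, 16, 64)}
        assert 2.0 < v[4] / v[16] < 8.0
        assert 2.0 < v[16] / v[64] < 8.0

    def test_empty_member_set_rejected(self, blob_image):
        with pytest.raises(ValueError, match="at least one member"):
            average_class(blob_image[None], [AlignmentParams()], member_ids=[])
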
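"""Stack I/O round trips and the synthetic generator's guarantees."""

import struct

import numpy as np
import pytest

from isac2d.stack_io import (
    GroundTruth,
    ParticleStack,
    StackFormatError,
    make_synthetic_stack,
    motif,
    n_motifs,
    read_ground_truth,
    read_stack,
    write_ground_truth,
    write_stack,
)
from isac2d.transforms import AlignmentParams, apply_transform, invert_params, mirror_image
from tests.conftest import circular_mask, masked_ncc


@pytest.fixture
def small_stack():
    stack, _ = make_synthetic_stack(2, 3, 32, snr=2.0, max_shift=2, seed=1)
    return stack


class TestRoundTrips:
    @pytest.mark.parametrize("suffix", ["mrcs", "h5"])
    def test_write_then_read_is_identity(self, small_stack, tmp_path, suffix):
        path = tmp_path / f"stack.{suffix}"
        write_stack(small_stack, path)
        back = read_stack(path)
        assert back.n == small_stack.n and back.box == small_stack.box
        np.testing.assert_allclose(
            back.images, small_stack.images.astype(np.float32), atol=1e-6
        )
        assert list(back.ids) == list(range(small_stack.n))

    def test_single_particle_stack_round_trips(self, tmp_path):
        stack = ParticleStack(np.random.default_rng(0).normal(size=(1, 32, 32)))
        path = tmp_path / "one.mrcs"
        write_stack(stack, path)
        assert read_stack(path).n == 1

    def test_missing_directories_are_created(self, small_stack, tmp_path):
        path = tmp_path / "a" / "b" / "stack.mrcs"
        write_stack(small_stack, path)
        assert path.exists()

    def test_fixture_dimensions_read_back(self, tmp_path):
        stack, _ = make_synthetic_stack(1, 3, 32, snr=np.inf, max_shift=0, seed=0)
        path = tmp_path / "s.mrcs"
        write_stack(stack, path)
        back = read_stack(path)
        assert back.n == 3 and back.box == 32

    def test_non_square_mrc_rejected(self, tmp_path):
        path = tmp_path / "bad.mrcs"
        header = bytearray(1024)
        struct.pack_into("<4i", header, 0, 32, 64, 1, 2)
        header[208:212] = b"MAP "
        header[212:216] = b"\x44\x44\x00\x00"
        path.write_bytes(bytes(header) + np.zeros(32 * 64, np.float32).tobytes())
        with pytest.raises(StackFormatError, match="square"):
            read_stack(path)

    def test_truncated_mrc_rejected(self, tmp_path):
        path = tmp_path / "short.mrcs"
        header = bytearray(1024)
        struct.pack_into("<4i", header, 0, 32, 32, 4, 2)
        path.write_bytes(bytes(header) + np.zeros(32 * 32, np.float32).tobytes())
        with pytest.raises(StackFormatError, match="shorter"):
            read_stack(path)


class TestParticleStackInvariants:
    def test_inconsistent_frame_sizes_rejected(self):
        with pytest.raises(StackFormatError, match="square"):
            ParticleStack(np.zeros((2, 32, 64)))

    def test_odd_or_tiny_box_rejected(self):
        with pytest.raises(StackFormatError, match="even"):
            ParticleStack(np.zeros((1, 17, 17)))
        with pytest.raises(StackFormatError, match="even"):
            ParticleStack(np.zeros((1, 8, 8)))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(StackFormatError, match="unique"):
            ParticleStack(np.zeros((2, 32, 32)), ids=np.array([1, 1]))


class TestGroundTruthTable:
    def test_tsv_round_trip(self, tmp_path):
        _, truth = make_synthetic_stack(2, 4, 32, snr=1.0, max_shift=3, seed=3)
        path = tmp_path / "truth.tsv"
        write_ground_truth(truth, path)
        back = read_ground_truth(path)
        np.testing.assert_array_equal(back.class_label, truth.class_label)
        for a, b in zip(back.true_transform, truth.true_transform):
            assert (a.sx, a.sy, a.mirror) == (b.sx, b.sy, b.mirror)
            assert a.theta == pytest.approx(b.theta, abs=1e-9)


class TestSyntheticGenerator:
    def test_noise_free_unshifted_unrotated_equals_motif(self):
        stack, truth = make_synthetic_stack(
            1, 5, 32, snr=np.inf, max_shift=0, mirror_allowed=False, seed=0,
            rotation=False,
        )
        ref = motif(0, 32)
        for i in range(5):
            np.testing.assert_allclose(stack.images[i], ref, atol=1e-6)
            assert truth.true_transform[i].identity

    def test_same_seed_gives_bit_identical_stacks(self):
        a, _ = make_synthetic_stack(3, 10, 32, snr=1.0, max_shift=3, seed=42)
        b, _ = make_synthetic_stack(3, 10, 32, snr=1.0, max_shift=3, seed=42)
        np.testing.assert_array_equal(a.images, b.images)

    def test_different_seed_changes_the_stack(self):
        a, _ = make_synthetic_stack(1, 5, 32, snr=1.0, max_shift=3, seed=1)
        b, _ = make_synthetic_stack(1, 5, 32, snr=1.0, max_shift=3, seed=2)
        assert not np.array_equal(a.images, b.images)

    def test_snr_calibration_within_ten_percent(self):
        stack, truth = make_synthetic_stack(1, 1000, 48, snr=1.0, max_shift=3, seed=7)
        mask = circular_mask(48, 48 // 2 - 2)
        m0 = motif(0, 48)
        ratios = np.empty(stack.n)
        for i in range(stack.n):
            clean = apply_transform(m0, invert_params(truth.true_transform[i]))
            noise = stack.images[i] - clean
            ratios[i] = clean[mask].var() / noise[mask].var()
        assert abs(ratios.mean() - 1.0) < 0.1

    def test_pure_noise_stack_has_no_signal(self):
        stack, truth = make_synthetic_stack(1, 20, 32, snr=0.0, max_shift=2, seed=5)
        assert truth.snr == 0.0
        # images are white noise: no correlation with the motif
        mask = circular_mask(32, 14)
        m0 = motif(0, 32)
        cc = [masked_ncc(stack.images[i].astype(float), m0, mask) for i in range(20)]
        assert np.abs(cc).max() < 0.5

    def test_negative_snr_rejected(self):
        with pytest.raises(ValueError, match="snr"):
            make_synthetic_stack(1, 2, 32, snr=-1.0)

    def test_odd_box_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_synthetic_stack(1, 2, 31, snr=1.0)

    def test_too_many_classes_rejected(self):
        with pytest.raises(ValueError, match="n_classes"):
            make_synthetic_stack(n_motifs() + 1, 2, 32, snr=1.0)


class TestMotifLibrary:
    def test_at_least_six_motifs(self):
        assert n_motifs() >= 6

    @pytest.mark.parametrize("index", range(8))
    def test_no_rotational_or_mirror_self_symmetry(self, index):
        """Self-correlation stays below 0.9 for distinct rotations/mirror.

        Rotations closer than 20 degrees are excluded: any smooth motif
        correlates with a slightly rotated copy of itself, and the
        alignment search resolves far finer than that.
        """
        b = 32
        m = motif(index, b)
        mask = circular_mask(b, 14)
        worst = 0.0
        for theta in np.arange(20.0, 341.0, 5.0):
            r = apply_transform(m, AlignmentParams(0, 0, theta, 0))
            worst = max(worst, masked_ncc(m, r, mask))
        mm = mirror_image(m)
        for theta in np.arange(0.0, 360.0, 5.0):
            r = apply_transform(mm, AlignmentParams(0, 0, theta, 0))
            worst = max(worst, masked_ncc(m, r, mask))
        assert worst < 0.9

    def test_motifs_are_mutually_distinguishable(self):
        b = 32
        mask = circular_mask(b, 14)
        ms = [motif(k, b) for k in range(n_motifs())]
        for a in range(len(ms)):
            for c in range(a + 1, len(ms)):
                worst = max(
                    masked_ncc(
                        ms[a],
                        apply_transform(ms[c], AlignmentParams(0, 0, th, 0)),
                        mask,
                    )
                    for th in np.arange(0.0, 360.0, 10.0)
                )
                assert worst < 0.9
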
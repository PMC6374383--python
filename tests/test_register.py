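"""Serial-section registration: pair recovery, chaining, re-probe fusion."""

import numpy as np
import pytest

from iftomo import RigidTransform2D, SectionImage
from iftomo.register import (
    RegistrationError,
    align_stack,
    fuse_reprobe,
    register_pair,
)
from iftomo.transforms import compose, warp_image


def _dapi(sections, i):
    return sections[i].data[0].astype(float)


class TestRegisterPair:
    def test_self_registration_is_identity(self, misaligned_phantom):
        _, sections, _ = misaligned_phantom
        img = _dapi(sections, 4)
        t, score = register_pair(img, img, max_rotation=5)
        assert score > 0.99
        assert np.hypot(t.tx, t.ty) < 0.2 and abs(t.theta) < 0.1

    def test_known_transform_recovered(self, misaligned_phantom):
        _, sections, _ = misaligned_phantom
        img = _dapi(sections, 4)
        applied = RigidTransform2D(5.0, -3.0, 2.0)
        moving = warp_image(img, applied)
        t, score = register_pair(img, moving, max_rotation=5)
        want = applied.inverse()
        assert np.hypot(t.tx - want.tx, t.ty - want.ty) <= 0.5
        assert abs(t.theta - want.theta) <= 0.25
        assert score > 0.9

    def test_independent_noise_flagged_as_identity(self, rng):
        a = rng.random((192, 192))
        b = rng.random((192, 192))
        with pytest.warns(UserWarning, match="confidence floor"):
            t, score = register_pair(a, b, max_rotation=3)
        assert t == RigidTransform2D(0, 0, 0)
        assert score == 0.0

    def test_zero_variance_rejected(self):
        flat = np.zeros((64, 64))
        with pytest.raises(ValueError, match="zero-variance"):
            register_pair(flat, flat)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            register_pair(rng.random((32, 32)), rng.random((40, 40)))

    def test_registration_symmetry(self, misaligned_phantom):
        """register(A, B) agrees with the inverse of register(B, A)."""
        _, sections, _ = misaligned_phantom
        a, b = _dapi(sections, 4), _dapi(sections, 5)
        fwd, _ = register_pair(a, b, max_rotation=8)
        bwd, _ = register_pair(b, a, max_rotation=8)
        inv = bwd.inverse()
        assert np.hypot(fwd.tx - inv.tx, fwd.ty - inv.ty) <= 0.5
        assert abs(fwd.theta - inv.theta) <= 0.25


class TestAlignStack:
    def test_identical_sections_align_to_identity(self, small_phantom):
        _, sections, _ = small_phantom
        stack = [sections[4]] * 4
        result, aligned = align_stack(stack, max_rotation=3)
        for t in result.absolute:
            assert np.hypot(t.tx, t.ty) < 0.3 and abs(t.theta) < 0.2
        assert result.flagged == []

    def test_two_sections_layout(self, misaligned_phantom):
        _, sections, _ = misaligned_phantom
        result, aligned = align_stack(sections[:2], max_rotation=8)
        assert len(result.pairwise) == 2  # identity placeholder + one pair
        assert result.pairwise[0] == RigidTransform2D(0, 0, 0)
        assert result.absolute[0] == RigidTransform2D(0, 0, 0)
        assert len(aligned) == 2

    def test_chaining_identity_holds_exactly(self, misaligned_phantom):
        _, sections, _ = misaligned_phantom
        result, _ = align_stack(sections[:6], max_rotation=8)
        for i in range(1, 6):
            chained = compose(result.absolute[i - 1], result.pairwise[i])
            got = result.absolute[i]
            assert np.allclose(
                (chained.tx, chained.ty, chained.theta),
                (got.tx, got.ty, got.theta),
                atol=1e-12,
            )

    def test_misalignment_recovery_against_truth(self, misaligned_phantom):
        """Recovered absolute transforms undo the generated misplacements."""
        _, sections, truth = misaligned_phantom
        result, _ = align_stack(sections, max_rotation=8)
        errs_px, errs_deg = [], []
        for i, (got, applied) in enumerate(
            zip(result.absolute, truth.section_transforms)
        ):
            want = applied.inverse()
            errs_px.append(np.hypot(got.tx - want.tx, got.ty - want.ty))
            errs_deg.append(abs(got.theta - want.theta))
        assert np.mean(errs_px) <= 0.5
        assert np.mean(errs_deg) <= 0.5

    def test_needs_at_least_two_sections(self, small_phantom):
        _, sections, _ = small_phantom
        with pytest.raises(ValueError):
            align_stack(sections[:1])


class TestFuseReprobe:
    @pytest.fixture()
    def rounds(self, small_phantom):
        _, sections, _ = small_phantom
        base = sections[4]
        r1 = SectionImage(
            np.stack([base.data[0], base.data[1], base.data[1] // 2]),
            ["DAPI", "K5", "PPARg"], pixel_size=0.44, thickness=2.0,
        )
        shifted = np.stack(
            [
                np.clip(np.floor(warp_image(p.astype(float), RigidTransform2D(4, 4, 0)) + 0.5), 0, 255)
                for p in r1.data
            ]
        ).astype(np.uint8)
        r2 = SectionImage(shifted, ["DAPI", "K6", "Ki67"], pixel_size=0.44, thickness=2.0)
        return r1, r2

    def test_two_rounds_sharing_dapi_give_five_channels(self, rounds):
        r1, r2 = rounds
        fused, _ = fuse_reprobe(r1, r2)
        assert fused.channel_names == ["DAPI", "K5", "PPARg", "K6", "Ki67"]
        assert fused.n_channels == 5

    def test_known_shift_realigned_within_half_pixel(self, rounds):
        r1, r2 = rounds
        _, t = fuse_reprobe(r1, r2)
        assert np.hypot(t.tx + 4, t.ty + 4) <= 0.5

    def test_self_fusion_suffixes_duplicates(self, rounds):
        r1, _ = rounds
        fused, t = fuse_reprobe(r1, r1)
        assert fused.channel_names == ["DAPI", "K5", "PPARg", "K5_r2", "PPARg_r2"]
        assert np.hypot(t.tx, t.ty) < 0.2

    def test_unregistrable_rounds_raise(self, rng):
        noise1 = SectionImage(
            (rng.random((2, 96, 96)) * 255).astype(np.uint8), ["DAPI", "K5"]
        )
        noise2 = SectionImage(
            (rng.random((2, 96, 96)) * 255).astype(np.uint8), ["DAPI", "K6"]
        )
        with pytest.warns(UserWarning):
            with pytest.raises(RegistrationError):
                fuse_reprobe(noise1, noise2, max_rotation=2)
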
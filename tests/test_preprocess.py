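"""I/O round-trips, z-score normalization, resampling and patch/augment
contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfseg import (
    ContractError,
    DimensionalityError,
    LabelMap,
    ValidationError,
    Volume,
    augment,
    extract_patch,
    read_labelmap,
    read_volume,
    resample,
    write_labelmap,
    write_volume,
    zscore_normalize,
)
from selfseg.preprocess import PatchPair, rotate_inplane


class TestIO:
    def test_volume_round_trip_bit_exact(self, tmp_path, phantom_case):
        vol, _ = phantom_case
        write_volume(vol, tmp_path / "v.nii.gz")
        back = read_volume(tmp_path / "v.nii.gz")
        assert np.array_equal(back.data, vol.data)
        assert np.allclose(back.spacing_mm, vol.spacing_mm, atol=1e-6)

    def test_labelmap_round_trip(self, tmp_path, phantom_case):
        _, lab = phantom_case
        write_labelmap(lab, tmp_path / "l.nii.gz")
        back = read_labelmap(tmp_path / "l.nii.gz")
        assert np.array_equal(back.data, lab.data)

    def test_reading_2d_image_raises(self, tmp_path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.zeros((4, 4), dtype=np.float32), np.eye(4)),
                 str(tmp_path / "flat.nii.gz"))
        with pytest.raises(DimensionalityError):
            read_volume(tmp_path / "flat.nii.gz")

    def test_label_value_out_of_range_raises(self, tmp_path):
        import nibabel as nib
        bad = np.full((4, 4, 4), 5, dtype=np.uint8)
        nib.save(nib.Nifti1Image(bad, np.eye(4)), str(tmp_path / "bad.nii.gz"))
        with pytest.raises(ValidationError):
            read_labelmap(tmp_path / "bad.nii.gz")


class TestZscore:
    def test_constant_volume_maps_to_zero(self):
        v = Volume(np.full((4, 5, 6), 42.0, np.float32), (1, 1, 1))
        assert np.all(zscore_normalize(v).data == 0)

    def test_mean_zero_sd_one(self, phantom_case):
        out = zscore_normalize(phantom_case[0]).data
        assert abs(out.mean()) < 1e-5
        assert abs(out.std() - 1.0) < 1e-5

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 6, 6)).astype(np.float32)
        v1 = zscore_normalize(Volume(x, (1, 1, 1)))
        v2 = zscore_normalize(Volume(a * x + b, (1, 1, 1)))
        assert np.allclose(v1.data, v2.data, atol=1e-4)

    def test_idempotent(self, phantom_case):
        v1 = zscore_normalize(phantom_case[0])
        v2 = zscore_normalize(v1)
        assert np.allclose(v1.data, v2.data, atol=1e-6)


class TestResample:
    def test_identity_spacing_is_identity(self, phantom_case):
        vol, _ = phantom_case
        out = resample(vol, vol.spacing_mm)
        assert np.array_equal(out.data, vol.data)

    def test_constant_stays_constant(self):
        v = Volume(np.full((6, 8, 8), 3.5, np.float32), (2.0, 1.0, 1.0))
        out = resample(v, (1.0, 2.0, 2.0))
        assert out.shape == (12, 4, 4)
        assert np.allclose(out.data, 3.5, atol=1e-6)

    def test_shape_rule_rounds_half_away(self):
        v = Volume(np.zeros((5, 5, 5), np.float32), (1.0, 1.0, 1.0))
        out = resample(v, (2.0, 2.0, 2.0))
        # 5 * 1 / 2 = 2.5 -> 3 under round-half-away-from-zero
        assert out.shape == (3, 3, 3)

    def test_labels_keep_codomain(self):
        data = np.zeros((6, 6, 6), np.uint8)
        data[2:4] = 2
        lab = LabelMap(data, (1, 1, 1))
        out = resample(lab, (0.7, 0.7, 0.7))
        assert set(np.unique(out.data)) <= {0, 2}

    def test_linear_mode_for_labels_rejected(self):
        lab = LabelMap(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        with pytest.raises(ContractError):
            resample(lab, (2, 2, 2), mode="linear")

    def test_smooth_round_trip_error_small(self):
        z, y, x = np.meshgrid(np.linspace(0, 1, 12), np.linspace(0, 1, 12),
                              np.linspace(0, 1, 12), indexing="ij")
        sig = np.sin(2 * np.pi * z) * np.cos(np.pi * y) + x
        v = Volume(sig.astype(np.float32), (1, 1, 1))
        up = resample(v, (0.5, 0.5, 0.5))
        back = resample(up, (1.0, 1.0, 1.0))
        core = (slice(1, -1),) * 3  # edge voxels extrapolate
        assert np.abs(back.data[core] - v.data[core]).max() < 0.05


class TestPatches:
    def test_full_volume_patch_is_identity(self, phantom_case, rng):
        vol, lab = phantom_case
        pair = extract_patch(vol, lab, vol.shape, rng)
        assert np.array_equal(pair.image_patch, vol.data)
        assert np.array_equal(pair.label_patch, lab.data)

    def test_small_volume_padded_centered(self, rng):
        v = Volume(np.ones((4, 4, 4), np.float32), (1, 1, 1))
        lab = LabelMap(np.ones((4, 4, 4), np.uint8), (1, 1, 1))
        pair = extract_patch(v, lab, (8, 8, 8), rng)
        assert pair.image_patch.shape == (8, 8, 8)
        assert pair.image_patch[2:6, 2:6, 2:6].all()
        assert pair.image_patch.sum() == 64  # only the original data
        assert pair.label_patch[2:6, 2:6, 2:6].all()

    def test_foreground_oversampling_rate(self, phantom_case):
        """Binomial check: with oversampling fraction f, about f of the
        draws are centered on a foreground voxel."""
        vol, lab = phantom_case
        rng = np.random.default_rng(7)
        n, hits = 2000, 0
        size = (4, 16, 16)
        for _ in range(n):
            pair = extract_patch(vol, lab, size, rng, foreground_fraction=0.5)
            center = tuple(s // 2 for s in size)
            hits += pair.label_patch[center] > 0
        # the uniform half also hits foreground sometimes, so the rate is
        # at least ~0.5 minus binomial noise; require the oversampled share
        base = (lab.data > 0).mean()
        lo = 0.5 * (1 - 3 / np.sqrt(n))
        assert hits / n > lo > base

    def test_reproducible_under_seed(self, phantom_case):
        vol, lab = phantom_case
        a = extract_patch(vol, lab, (4, 16, 16), np.random.default_rng(3),
                          foreground_fraction=0.3)
        b = extract_patch(vol, lab, (4, 16, 16), np.random.default_rng(3),
                          foreground_fraction=0.3)
        assert np.array_equal(a.image_patch, b.image_patch)
        assert a.provenance == b.provenance


class TestAugment:
    def _pair(self):
        img = np.zeros((1, 8, 8), np.float32)
        lab = np.zeros((1, 8, 8), np.uint8)
        lab[0, 3:5, 1:7] = 2  # axis-aligned bar
        img[0] = lab[0]
        return PatchPair(img, lab)

    def test_zero_augmentation_is_identity(self, rng):
        pair = self._pair()
        out = augment(pair, rng, rotation_deg=0.0, jitter_vox=0)
        assert np.array_equal(out.image_patch, pair.image_patch)
        assert np.array_equal(out.label_patch, pair.label_patch)

    def test_90_degree_rotation_is_lattice_exact(self):
        pair = self._pair()
        rot = rotate_inplane(pair.label_patch, 90.0, order=0)
        assert rot.sum() == pair.label_patch.sum()
        assert np.array_equal(rot, np.rot90(pair.label_patch, axes=(-2, -1)))

    def test_label_codomain_preserved(self, phantom_case, rng):
        vol, lab = phantom_case
        pair = extract_patch(vol, lab, (1, 32, 32), rng, foreground_fraction=1.0)
        for _ in range(10):
            out = augment(pair, rng, rotation_deg=15.0, jitter_vox=2)
            assert out.image_patch.shape == pair.image_patch.shape
            assert set(np.unique(out.label_patch)) <= {0, 1, 2, 3, 4}
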
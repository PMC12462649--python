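"""Preprocessing pipeline: resampling geometry, depth-window selection,
min-max scaling and the five-fold augmentation expansion."""

import numpy as np
import pytest

from petmri3d.phantoms import PhantomConfig, VolumeCase, generate_case
from petmri3d.preprocess import (
    PreprocessConfig,
    TrainingTensor,
    augment,
    harmonise_voxels,
    minmax_scale,
    preprocess_case,
    resize_inplane,
    select_depth_window,
)


def _case(shape=(20, 20, 12), voxel=(1.0, 1.0, 1.0), label=0, mask=None, cid="c0"):
    rng = np.random.default_rng(0)
    return VolumeCase(cid, rng.random(shape), rng.random(shape), voxel, label, mask)


# -- min-max scaling ---------------------------------------------------------

def test_minmax_linear_map():
    np.testing.assert_allclose(minmax_scale(np.array([[[2.0, 4.0, 6.0]]])),
                               [[[0.0, 0.5, 1.0]]])


def test_minmax_constant_volume_maps_to_zeros():
    with pytest.warns(UserWarning, match="constant"):
        out = minmax_scale(np.full((4, 4, 4), 7.0))
    assert not out.any()


def test_minmax_hits_exact_bounds():
    out = minmax_scale(np.random.default_rng(1).random((6, 6, 6)))
    assert out.min() == 0.0 and out.max() == 1.0


# -- voxel harmonisation -----------------------------------------------------

def test_harmonise_identity_at_target_pitch():
    case = _case(voxel=(0.5, 0.5, 3.0))
    cfg = PreprocessConfig(target_voxel=(0.5, 0.5, 3.0))
    out = harmonise_voxels(case, cfg)
    assert out.shape == case.shape
    np.testing.assert_array_equal(out.pet, case.pet)


def test_harmonise_doubles_extent_for_halved_pitch():
    case = _case(shape=(16, 16, 8), voxel=(0.8, 0.8, 2.0))
    out = harmonise_voxels(case, PreprocessConfig(target_voxel=(0.4, 0.4, 2.0)))
    assert out.shape == (32, 32, 8)
    assert out.voxel_size == (0.4, 0.4, 2.0)


def test_harmonise_keeps_mask_binary():
    mask = np.zeros((16, 16, 8), dtype=np.uint8)
    mask[6:9, 6:9, 3:5] = 1
    case = _case(shape=(16, 16, 8), voxel=(0.8, 0.8, 2.0), label=1, mask=mask)
    out = harmonise_voxels(case, PreprocessConfig(target_voxel=(0.4, 0.4, 2.0)))
    assert set(np.unique(out.tumour_mask)) <= {0, 1}
    assert out.tumour_mask.any()


# -- in-plane resize ---------------------------------------------------------

def test_resize_downscales_slicewise():
    case = _case(shape=(64, 64, 5))
    out = resize_inplane(case, PreprocessConfig(inplane_size=16))
    assert out.shape == (16, 16, 5)


def test_resize_identity_at_target_size():
    case = _case(shape=(16, 16, 5))
    out = resize_inplane(case, PreprocessConfig(inplane_size=16))
    np.testing.assert_array_equal(out.pet, case.pet)


def test_resize_preserves_constant_slices():
    pet = np.ones((32, 32, 4)) * np.arange(1, 5)[None, None, :]
    case = VolumeCase("c", pet, pet.copy(), (1, 1, 1), 0, None)
    out = resize_inplane(case, PreprocessConfig(inplane_size=8))
    for z in range(4):
        np.testing.assert_allclose(out.pet[:, :, z], z + 1.0, rtol=1e-6)


def test_resize_upscaling_warns_but_proceeds():
    case = _case(shape=(12, 12, 4))
    with pytest.warns(UserWarning, match="upscal"):
        out = resize_inplane(case, PreprocessConfig(inplane_size=16))
    assert out.shape == (16, 16, 4)


# -- depth-window selection --------------------------------------------------

def _masked_case(nz, mask_slices, cid="p0"):
    shape = (10, 10, nz)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[4:6, 4:6, mask_slices] = 1
    return _case(shape=shape, label=1, mask=mask, cid=cid)


def test_window_equals_volume_when_depth_matches():
    cfg = PreprocessConfig(depth_window=12)
    case = _case(shape=(10, 10, 12))
    out = select_depth_window(case, cfg)
    assert out.shape[2] == 12
    np.testing.assert_array_equal(out.pet, case.pet)


def test_window_clamps_at_superior_boundary():
    # centremost mask slice 5 of 64: symmetric extension would start at
    # -11, clamped to [0, 32)
    cfg = PreprocessConfig(depth_window=32)
    case = _masked_case(64, slice(4, 7))
    out = select_depth_window(case, cfg)
    assert out.shape[2] == 32
    assert np.flatnonzero(out.tumour_mask.any(axis=(0, 1))).tolist() == [4, 5, 6]


def test_window_contains_tumour_and_centres_when_possible():
    cfg = PreprocessConfig(depth_window=8)
    case = _masked_case(24, slice(11, 14))  # centremost slice 12
    out = select_depth_window(case, cfg)
    assert out.shape[2] == 8
    assert out.tumour_mask.any()
    # window [8, 16) holds all three mask slices
    assert np.flatnonzero(out.tumour_mask.any(axis=(0, 1))).tolist() == [3, 4, 5]


def test_negative_window_reproducible_per_case_seed():
    cfg = PreprocessConfig(depth_window=8, seed=42)
    case = _case(shape=(10, 10, 24), cid="neg1")
    a = select_depth_window(case, cfg)
    b = select_depth_window(case, cfg)
    np.testing.assert_array_equal(a.pet, b.pet)


def test_window_errors():
    cfg = PreprocessConfig(depth_window=16)
    with pytest.raises(ValueError, match="depth"):
        select_depth_window(_case(shape=(10, 10, 8)), cfg)
    bad = _case(shape=(10, 10, 24), label=0,
                mask=np.zeros((10, 10, 24), dtype=np.uint8))
    bad.label = 1  # mutate past validation: positive with empty mask
    with pytest.raises(ValueError, match="empty"):
        select_depth_window(bad, cfg)


# -- augmentation ------------------------------------------------------------

def _tiny_tensors(n, rng):
    return [TrainingTensor(rng.random((4, 4, 2, 1)), int(i % 2), [f"t{i}"])
            for i in range(n)]


@pytest.mark.parametrize("n,expected", [(161, 805), (162, 810), (1, 5)])
def test_augment_quintuples_sample_count(n, expected, rng):
    out = augment(_tiny_tensors(n, rng), rng)
    assert len(out) == expected


def test_augment_preserves_labels_and_value_multisets(rng):
    originals = _tiny_tensors(3, rng)
    out = augment(originals, rng)
    assert all(a is b for a, b in zip(out[:3], originals))  # originals retained
    for i, t in enumerate(out[3:]):
        src = originals[i // 4]
        assert t.label == src.label
        np.testing.assert_array_equal(np.sort(t.data, axis=None),
                                      np.sort(src.data, axis=None))


def test_augment_variants_are_distinct_transforms(rng):
    originals = _tiny_tensors(1, rng)
    out = augment(originals, rng)
    variants = [t.data.tobytes() for t in out[1:]]
    assert len(set(variants)) == 4


# -- full pipeline -----------------------------------------------------------

def test_pipeline_produces_scaled_depth_window_tensor():
    cfg = PhantomConfig(shape=(16, 16, 12), tumour_radius_range=(1.5, 2.5), seed=3)
    case = generate_case(cfg, positive=True, rng=np.random.default_rng(3))
    pcfg = PreprocessConfig(inplane_size=16, depth_window=8)
    t = preprocess_case(case, pcfg, modality="petmri")
    assert t.data.shape == (16, 16, 8, 2)
    assert t.data.min() >= 0.0 and t.data.max() <= 1.0
    assert t.label == 1
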
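"""Image preparation: resampling, ADC, high-b selection, tensor assembly,
augmentation."""

import numpy as np
import pytest

from rsipipe.errors import ConfigurationError
from rsipipe.prep import (
    AugmentPolicy,
    BPMRI_CHANNELS,
    BPMRI_RSI_CHANNELS,
    ImagingStudy,
    ModelInputTensor,
    assemble_input,
    augment,
    compute_adc,
    resample_to_t2w,
    select_high_b,
)


def make_study(t2w, t2w_aff, dwi, dwi_aff, mask=None, mask_aff=None):
    if mask is None:
        mask = np.ones(t2w.shape, dtype=np.uint8)
    return ImagingStudy(
        patient_id="p0",
        t2w=t2w,
        t2w_affine=t2w_aff,
        dwi=dwi,
        dwi_affine=dwi_aff,
        prostate_mask=mask,
        mask_affine=t2w_aff if mask_aff is None else mask_aff,
    )


def test_identity_resample_unchanged(rng):
    aff = np.eye(4)
    vol = rng.random((8, 8, 6)).astype(np.float32)
    study = make_study(rng.random((8, 8, 6)), aff, {0.0: vol, 1000.0: vol * 2}, aff.copy())
    out = resample_to_t2w(study)
    assert np.allclose(out.dwi[0.0], vol, atol=1e-6)
    assert np.allclose(out.dwi[1000.0], 2 * vol, atol=1e-6)


def test_constant_volume_stays_constant():
    t2w_aff = np.eye(4)
    dwi_aff = np.eye(4)
    dwi_aff[:3, 3] = [0.25, 0.0, 0.0]  # slightly shifted grid
    study = make_study(
        np.zeros((8, 8, 6)), t2w_aff, {0.0: np.full((8, 8, 6), 3.0)}, dwi_aff
    )
    out = resample_to_t2w(study)
    interior = out.dwi[0.0][1:-1, 1:-1, 1:-1]
    assert np.allclose(interior, 3.0, atol=1e-6)


def test_linear_ramp_reproduced_at_half_voxel_offset():
    """Trilinear interpolation is exact on a linear field."""
    ramp = np.arange(10, dtype=float)[:, None, None] * np.ones((10, 8, 6))
    src_aff = np.eye(4)
    t2w_aff = np.eye(4)
    t2w_aff[0, 3] = 0.5  # T2W grid shifted half a voxel along x
    study = make_study(np.zeros((9, 8, 6)), t2w_aff, {0.0: ramp}, src_aff)
    out = resample_to_t2w(study)
    expected = np.broadcast_to(np.arange(9, dtype=float)[:, None, None] + 0.5, (9, 8, 6))
    assert np.allclose(out.dwi[0.0][:, 1:-1, 1:-1], expected[:, 1:-1, 1:-1], atol=1e-5)


def test_mask_resampled_binary():
    src_aff = np.eye(4)
    t2w_aff = np.eye(4)
    t2w_aff[0, 3] = 0.4
    mask = np.zeros((10, 8, 6), dtype=np.uint8)
    mask[3:7, 2:6, 1:5] = 1
    study = make_study(np.zeros((10, 8, 6)), t2w_aff, {0.0: np.zeros((10, 8, 6))},
                       src_aff, mask=mask, mask_aff=src_aff)
    out = resample_to_t2w(study)
    assert set(np.unique(out.prostate_mask)) <= {0, 1}


def test_non_overlapping_fov_errors():
    aff_far = np.eye(4)
    aff_far[:3, 3] = [1000.0, 1000.0, 1000.0]
    study = make_study(np.zeros((6, 6, 4)), np.eye(4), {0.0: np.ones((6, 6, 4))}, aff_far)
    with pytest.raises(ConfigurationError, match="overlap"):
        resample_to_t2w(study)


def test_adc_closed_form_and_invariances(rng):
    d_true = 1.5e-3
    b = (0.0, 500.0, 1000.0)
    s0 = 200.0
    stack = {bb: s0 * np.exp(-bb * d_true) * np.ones((4, 4, 2)) for bb in b}
    adc = compute_adc(stack)
    assert np.allclose(adc, d_true, atol=1e-9)
    # overall scaling does not change the log-slope
    adc2 = compute_adc({bb: 3.0 * v for bb, v in stack.items()})
    assert np.allclose(adc2, adc, atol=1e-9)
    # zero-signal voxel is clamped and finite
    stack[0.0][0, 0, 0] = 0.0
    assert np.all(np.isfinite(compute_adc(stack)))
    # high b-values excluded by the default clinical subset
    stack[3000.0] = np.zeros((4, 4, 2))
    assert np.allclose(compute_adc(stack)[1:, 1:, :], d_true, atol=1e-9)
    with pytest.raises(ConfigurationError):
        compute_adc({0.0: np.ones((2, 2, 2))})


def test_high_b_selection(rng):
    vols = {0.0: rng.random((3, 3, 2)), 1000.0: rng.random((3, 3, 2)),
            2000.0: rng.random((3, 3, 2))}
    # enumeration oracle: volume of argmax over the listed b-values
    best_b = max(vols.keys())
    assert np.array_equal(select_high_b(vols), vols[best_b])
    only = {500.0: rng.random((3, 3, 2))}
    assert np.array_equal(select_high_b(only), only[500.0])
    with pytest.raises(ConfigurationError):
        select_high_b({})


def _prepared_study(rng, shape=(12, 12, 8)):
    aff = np.eye(4)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[3:9, 3:9, 2:6] = 1  # bounding-box center coincides with the grid center
    study = make_study(rng.random(shape) * 50, aff, {0.0: rng.random(shape)}, aff, mask=mask)
    study.adc = rng.random(shape) * 3e-3
    study.high_b = rng.random(shape)
    return study


def test_assemble_channel_order_and_count(rng):
    study = _prepared_study(rng)
    t = assemble_input(study, None, BPMRI_CHANNELS, crop_shape=(8, 8, 6))
    assert t.channels == ("t2w", "adc", "high_b")
    assert t.array.shape == (3, 8, 8, 6)
    rsi_maps = {"rsi_c1": rng.random((12, 12, 8)), "rsi_c2": rng.random((12, 12, 8))}
    t5 = assemble_input(study, rsi_maps, BPMRI_RSI_CHANNELS, crop_shape=(8, 8, 6), rsirs_max=1.2)
    assert t5.array.shape == (5, 8, 8, 6)
    assert t5.rsirs_max == 1.2
    with pytest.raises(ConfigurationError, match="rsi_c1"):
        assemble_input(study, None, BPMRI_RSI_CHANNELS, crop_shape=(8, 8, 6))


def test_assemble_constant_channel_zeroes(rng):
    study = _prepared_study(rng)
    study.adc = np.full((12, 12, 8), 2.0)
    t = assemble_input(study, None, BPMRI_CHANNELS, crop_shape=(8, 8, 6))
    assert np.allclose(t.array[1], 0.0)


def test_crop_center_equals_bruteforce_bbox_center(rng):
    study = _prepared_study(rng)
    # mark the brute-force bounding-box center voxel and check it lands at the
    # crop center
    vox = np.argwhere(study.prostate_mask > 0)
    center = np.round((vox.min(axis=0) + vox.max(axis=0)) / 2.0).astype(int)
    study.t2w = np.zeros_like(study.t2w)
    study.t2w[tuple(center)] = 100.0
    t = assemble_input(study, None, BPMRI_CHANNELS, crop_shape=(9, 9, 7))
    peak = np.unravel_index(np.argmax(t.array[0]), t.array[0].shape)
    crop_center = (np.asarray(t.array[0].shape) - 1) // 2
    assert np.all(np.abs(np.asarray(peak) - crop_center) <= 1)


def test_normalization_idempotent(rng):
    study = _prepared_study(rng)
    t1 = assemble_input(study, None, BPMRI_CHANNELS, crop_shape=(12, 12, 8))
    study2 = _prepared_study(rng)
    study2.t2w, study2.adc, study2.high_b = t1.array[0], t1.array[1], t1.array[2]
    study2.prostate_mask = study.prostate_mask
    t2 = assemble_input(study2, None, BPMRI_CHANNELS, crop_shape=(12, 12, 8))
    assert np.allclose(t2.array, t1.array, atol=1e-5)


def test_augment_identity_and_replay(rng):
    t = ModelInputTensor(("a", "b"), rng.random((2, 6, 6, 4)).astype(np.float32), rsirs_max=2.5)
    out = augment(t, np.random.default_rng(0), AugmentPolicy.identity())
    assert np.array_equal(out.array, t.array)
    policy = AugmentPolicy()
    a1 = augment(t, np.random.default_rng(9), policy)
    a2 = augment(t, np.random.default_rng(9), policy)
    assert np.array_equal(a1.array, a2.array)
    assert a1.rsirs_max == 2.5  # scalar biomarker untouched


def test_double_flip_is_identity(rng):
    t = ModelInputTensor(("a",), rng.random((1, 6, 6, 4)).astype(np.float32))
    policy = AugmentPolicy(flip_lr=True, max_translation=0, intensity_jitter=0.0)
    # seed 2 draws < 0.5 on its first uniform, so the flip fires both times
    assert np.random.default_rng(2).random() < 0.5
    flipped = augment(t, np.random.default_rng(2), policy)
    restored = augment(flipped, np.random.default_rng(2), policy)
    assert np.array_equal(restored.array, t.array)
    assert not np.array_equal(flipped.array, t.array)
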
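"""Preprocessing chain: resampling, registration, skull stripping, slices."""

import numpy as np
import pytest

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from adslice.phantom import (
    aligned_phantom_image,
    brain_mask_ground_truth,
    build_template,
    generate_volume,
)
from adslice.volumes import RigidTransform, Volume3D
from adslice.preprocess import (
    FAST_STEP1,
    FAST_STEP2,
    RegistrationSettings,
    extract_brain,
    extract_coronal_slices,
    minmax_normalize,
    register_rigid,
    resample_isotropic,
    two_step_align,
)



def _clean_volume(spec):
    return Volume3D(aligned_phantom_image(spec), (spec.voxel_spacing_mm,) * 3)


def _clean_template(spec):
    vol = _clean_volume(spec)
    return build_template([vol], geometry=spec.geometry)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_identity(default_spec):
    vol = _clean_volume(default_spec)
    out = resample_isotropic(vol, grid=96, spacing_mm=2.0)
    assert np.allclose(out.data, vol.data, atol=1e-6)


def test_resample_default_targets_full_scale_grid():
    vol = Volume3D(np.zeros((8, 8, 8), dtype=np.float32), (4.0,) * 3)
    out = resample_isotropic(vol)
    assert out.shape == (256, 256, 256)
    assert out.spacing_mm == (1.0, 1.0, 1.0)


def test_resample_constant_field():
    vol = Volume3D(np.full((32, 32, 32), 0.7, dtype=np.float32), (2.0,) * 3)
    out = resample_isotropic(vol, grid=16, spacing_mm=3.0)
    # interior voxels keep the constant value (edges may hit zero padding)
    assert np.allclose(out.data[4:-4, 4:-4, 4:-4], 0.7, atol=1e-5)


def test_resample_rejects_bad_arguments(default_spec):
    with pytest.raises(ValueError):
        resample_isotropic(_clean_volume(default_spec), grid=0)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def test_register_identity_recovers_near_zero(default_spec):
    vol = _clean_volume(default_spec)
    res = register_rigid(vol, vol)
    assert res.transform.rotation_angle_deg() <= 0.1
    assert res.transform.translation_norm_mm() <= 0.1


def test_register_recovers_pure_translation(default_spec):
    import SimpleITK as sitk

    vol = _clean_volume(default_spec)
    true = RigidTransform(translations_mm=(5.0, 0.0, 0.0))
    moved = sitk.Resample(vol.to_sitk(), vol.to_sitk(), true.to_sitk(), sitk.sitkLinear, 0.0)
    res = register_rigid(Volume3D.from_sitk(moved), vol)
    resid = res.transform.compose(true)
    assert resid.translation_norm_mm() <= 0.5


def test_register_recovers_known_misalignment(default_spec, rng):
    for _ in range(2):
        vol, subj = generate_volume(
            default_spec,
            dict(subject_id="S", age_years=75, sex=0, diagnosis="CN"),
            rng,
        )
        res = register_rigid(vol, _clean_volume(default_spec))
        resid = res.transform.compose(subj.true_transform)
        assert resid.rotation_angle_deg() <= 1.0
        assert resid.translation_norm_mm() <= 1.0


def test_registration_transform_is_rigid(default_spec, rng):
    vol, _ = generate_volume(
        default_spec, dict(subject_id="S", age_years=70, sex=1, diagnosis="AD"), rng
    )
    res = register_rigid(vol, _clean_volume(default_spec), FAST_STEP1)
    det = np.linalg.det(res.transform.matrix()[:3, :3])
    assert abs(det - 1.0) < 1e-6


# ---------------------------------------------------------------------------
# brain extraction
# ---------------------------------------------------------------------------

def test_extract_brain_recovers_parenchyma(default_spec):
    mask, masked = extract_brain(_clean_volume(default_spec))
    gt = brain_mask_ground_truth(default_spec)
    dice = 2.0 * np.sum(mask & gt) / (mask.sum() + gt.sum())
    assert dice >= 0.95
    assert np.all(masked.data[~mask] == 0.0)


def test_extract_brain_empty_volume_errors():
    with pytest.raises(ValueError):
        extract_brain(Volume3D(np.zeros((48, 48, 48), dtype=np.float32), (4.0,) * 3))


# ---------------------------------------------------------------------------
# two-step alignment
# ---------------------------------------------------------------------------

def test_two_step_fixed_point(default_spec):
    """An already-aligned skull-stripped input stays put.

    The rotation tolerance reflects the flat rotational basin of the
    similarity metric at 2 mm voxels: sub-half-degree rotations displace the
    boundary of a near-axisymmetric brain by far less than a voxel.
    """
    template = _clean_template(default_spec)
    already = Volume3D(
        template.volume.data * template.brain_mask, template.volume.spacing_mm
    )
    res = two_step_align(already, template)
    for t in (res.transform_step1, res.transform_step2):
        assert t.rotation_angle_deg() <= 0.5
        assert t.translation_norm_mm() <= 0.2
    assert res.aligned.shape == template.volume.shape


def test_two_step_refines_step_one(default_spec):
    """Second (brain-only) registration reduces the mean alignment error."""
    template = _clean_template(default_spec)
    rng = np.random.default_rng(21)
    e1, e2 = [], []
    for i in range(20):
        vol, subj = generate_volume(
            default_spec,
            dict(subject_id=f"S{i}", age_years=75, sex=0, diagnosis="CN"),
            rng,
        )
        res = two_step_align(vol, template, FAST_STEP1, FAST_STEP2)
        r1 = res.transform_step1.compose(subj.true_transform)
        r12 = res.overall_transform.compose(subj.true_transform)
        e1.append(r1.rotation_angle_deg() + r1.translation_norm_mm())
        e2.append(r12.rotation_angle_deg() + r12.translation_norm_mm())
    assert np.mean(e2) < np.mean(e1)


# ---------------------------------------------------------------------------
# normalization and slices
# ---------------------------------------------------------------------------

def test_minmax_examples():
    out = minmax_normalize(np.array([[0.0, 5.0, 10.0]]))
    assert np.allclose(out, [[0.0, 0.5, 1.0]])
    assert np.all(minmax_normalize(np.full((4, 4), 3.3)) == 0.0)
    with pytest.raises(ValueError):
        minmax_normalize(np.array([[np.inf, 1.0]]))


@given(
    arrays(
        np.float32,
        (6, 7),
        elements=st.floats(-50, 50, width=32, allow_nan=False),
    )
)
@settings(max_examples=50, deadline=None)
def test_minmax_idempotent_and_bounded(slc):
    once = minmax_normalize(slc)
    assert once.min() >= 0.0 and once.max() <= 1.0
    if not np.all(slc == slc.flat[0]):
        assert once.min() == 0.0 and once.max() == 1.0
    assert np.array_equal(minmax_normalize(once), once)


def test_extract_slices_contract(default_spec):
    template = _clean_template(default_spec)
    aligned = template.masked_volume()
    stack = extract_coronal_slices(aligned, template, n_slices=30, subject_ref="s1")
    assert stack.n_slices == 30
    anchor = template.anchor_coronal_index
    assert stack.slice_indices == list(range(anchor, anchor + 30))
    shapes = {s.shape for s in stack.slices}
    assert shapes == {(96, 96)}
    again = extract_coronal_slices(aligned, template, n_slices=30, subject_ref="s1")
    for a, b in zip(stack.slices, again.slices):
        assert np.array_equal(a, b)


def test_extract_slices_default_count_is_thirty(default_spec):
    template = _clean_template(default_spec)
    stack = extract_coronal_slices(template.masked_volume(), template)
    assert stack.n_slices == 30


def test_extract_slices_range_error(default_spec):
    template = _clean_template(default_spec)
    with pytest.raises(ValueError):
        extract_coronal_slices(template.masked_volume(), template, n_slices=100)


def test_registration_settings_validation():
    with pytest.raises(ValueError):
        RegistrationSettings(metric="ncc")
    with pytest.raises(ValueError):
        RegistrationSettings(shrink_factors=(4, 2), smoothing_sigmas_mm=(1.0,))
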
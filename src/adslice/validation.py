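"""Ground-truth validation studies for the pipeline's building blocks.

These helpers quantify, against the phantom generator's recorded truth,
how well rigid registration recovers known misalignments, the DeLong
test's type-I error under the null, and the coverage of the DeLong-based
AUC confidence interval.  They back the package's quality checks and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .metrics import auc_confidence_interval, delong_compare, roc_auc
from .phantom import BRAIN_INTENSITY, PhantomSpec, aligned_phantom_image, _draw_transform
from .preprocess import RegistrationSettings, register_rigid
from .volumes import Volume3D

__all__ = [
    "registration_recovery",
    "delong_null_rejection_rate",
    "auc_ci_coverage",
]


def registration_recovery(
    spec: PhantomSpec,
    n_cases: int,
    seed: int,
    settings: RegistrationSettings | None = None,
) -> list[dict]:
    """Register misaligned noisy phantoms back to the aligned reference.

    Each case draws a random rigid misalignment within the configured
    ranges, resamples a phantom through it, adds noise, and registers the
    result to the noise-free aligned phantom.  The residual transform
    ``recovered ∘ true`` measures the error (identity = perfect recovery).
    """
    import SimpleITK as sitk

    rng = np.random.default_rng(seed)
    reference = Volume3D(aligned_phantom_image(spec), (spec.voxel_spacing_mm,) * 3)
    ref_img = reference.to_sitk()
    noise_sd = spec.intensity_noise_sd * BRAIN_INTENSITY

    results = []
    for _ in range(n_cases):
        true = _draw_transform(spec, rng)
        moved = sitk.Resample(ref_img, ref_img, true.to_sitk(), sitk.sitkLinear, 0.0)
        data = Volume3D.from_sitk(moved).data
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, data.shape).astype(np.float32)
        moving = Volume3D(data, reference.spacing_mm)
        res = register_rigid(moving, reference, settings)
        residual = res.transform.compose(true)
        results.append(
            {
                "rotation_error_deg": residual.rotation_angle_deg(),
                "translation_error_mm": residual.translation_norm_mm(),
                "converged": res.converged,
            }
        )
    return results


def delong_null_rejection_rate(
    n_sims: int = 200, n_per_class: int = 50, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of the unpaired DeLong test on null data.

    Two independent score sets with labels unrelated to the scores (true
    AUC 0.5 in both); the fraction of two-sided p-values below alpha
    estimates the test's size.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        rocs = []
        for _ in range(2):
            scores = rng.normal(size=2 * n_per_class)
            labels = np.array([1] * n_per_class + [0] * n_per_class)
            rocs.append(roc_auc(scores, labels))
        if delong_compare(rocs[0], rocs[1], paired=False).p_value < alpha:
            rejections += 1
    return rejections / n_sims


def auc_ci_coverage(
    n_sims: int = 200,
    n_per_class: int = 40,
    true_auc: float = 0.8,
    level: float = 0.95,
    seed: int = 0,
) -> float:
    """Coverage of the DeLong normal-approximation AUC confidence interval.

    Scores follow the binormal model with unit variances; the positive-class
    mean shift is chosen so the population AUC equals ``true_auc``.
    """
    rng = np.random.default_rng(seed)
    delta = np.sqrt(2.0) * stats.norm.ppf(true_auc)
    covered = 0
    for _ in range(n_sims):
        pos = rng.normal(delta, 1.0, n_per_class)
        neg = rng.normal(0.0, 1.0, n_per_class)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * n_per_class + [0] * n_per_class)
        lo, hi = auc_confidence_interval(roc_auc(scores, labels), level)
        if lo <= true_auc <= hi:
            covered += 1
    return covered / n_sims
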
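"""Real-time stochastic augmentation of normalized 2D slices.

Each draw applies, in a fixed order, rotation -> isotropic scaling ->
translation (one bilinear resampling with zero fill), then the intensity
perturbations contrast ``c (v - 0.5) + 0.5`` and gamma ``v ** g``, with every
parameter sampled uniformly from its configured range.  The result is
clipped back into [0, 1].  Given the drawn parameters the operation is a
pure function, so a seeded generator reproduces identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "augment_slice", "apply_augmentation"]


def _check_interval(name: str, interval, identity: float) -> tuple[float, float]:
    lo, hi = float(interval[0]), float(interval[1])
    if not (lo <= identity <= hi):
        raise ValueError(f"{name} range {interval} must contain its identity value {identity}")
    return lo, hi


@dataclass
class AugmentConfig:
    """Uniform sampling ranges; each must contain its identity value.

    Default ranges are mild perturbations appropriate for rigidly aligned
    anatomy; translations are in pixels of the slice being augmented.
    """

    rotation_deg_range: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_px_range: tuple[float, float] = (-8.0, 8.0)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        self.rotation_deg_range = _check_interval("rotation", self.rotation_deg_range, 0.0)
        self.scale_range = _check_interval("scale", self.scale_range, 1.0)
        self.translation_px_range = _check_interval(
            "translation", self.translation_px_range, 0.0
        )
        self.contrast_range = _check_interval("contrast", self.contrast_range, 1.0)
        self.gamma_range = _check_interval("gamma", self.gamma_range, 1.0)

    def draw(self, rng: np.random.Generator) -> dict:
        return {
            "rotation_deg": rng.uniform(*self.rotation_deg_range),
            "scale": rng.uniform(*self.scale_range),
            "translation_px": (
                rng.uniform(*self.translation_px_range),
                rng.uniform(*self.translation_px_range),
            ),
            "contrast": rng.uniform(*self.contrast_range),
            "gamma": rng.uniform(*self.gamma_range),
        }


def apply_augmentation(slc: np.ndarray, params: dict) -> np.ndarray:
    """Deterministically apply one drawn parameter set to a [0, 1] slice."""
    slc = np.asarray(slc, dtype=np.float32)
    if float(slc.min()) < -1e-6 or float(slc.max()) > 1.0 + 1e-6:
        raise ValueError("augment_slice expects a min-max normalized slice in [0, 1]")

    rot = float(params["rotation_deg"])
    scale = float(params["scale"])
    t0, t1 = (float(v) for v in params["translation_px"])

    geometric_identity = rot == 0.0 and scale == 1.0 and t0 == 0.0 and t1 == 0.0
    if not geometric_identity:
        # single combined affine about the slice center: rotate, scale, shift
        theta = np.deg2rad(rot)
        rot_m = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        m = rot_m * scale
        center = (np.asarray(slc.shape, dtype=float) - 1.0) / 2.0
        # output coord y maps to input coord  m^-1 (y - center - t) + center
        m_inv = np.linalg.inv(m)
        offset = center - m_inv @ (center + np.array([t0, t1]))
        slc = ndimage.affine_transform(
            slc, m_inv, offset=offset, order=1, mode="constant", cval=0.0
        )

    contrast = float(params["contrast"])
    gamma = float(params["gamma"])
    if contrast != 1.0:
        slc = contrast * (slc - 0.5) + 0.5
    slc = np.clip(slc, 0.0, 1.0)
    if gamma != 1.0:
        slc = slc**gamma
    return np.clip(slc, 0.0, 1.0).astype(np.float32)


def augment_slice(
    slc: np.ndarray, config: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one parameter set from ``config`` and apply it to ``slc``."""
    return apply_augmentation(slc, config.draw(rng))
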
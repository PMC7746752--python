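"""Synthetic head phantoms with class-dependent medial-temporal atrophy.

The generator emulates the structure the classification pipeline assumes: a
head-like object (bright outer shell standing in for scalp/skull, interior
brain ellipsoid) containing two bilateral medial-temporal ellipsoids whose
volume is reduced in the AD class.  Each subject is corrupted by a random
rigid misalignment and additive Gaussian noise, with the ground-truth
transform and structure volume recorded so registration and classification
can be validated against known answers.

Intensity convention (before noise): background 0, shell 1.0, brain tissue
0.6, medial-temporal structure 0.8 — ordered like a T1-weighted image so
thresholding and min-max normalization behave as they would on real scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import RigidTransform, Template, Volume3D

__all__ = [
    "PhantomGeometry",
    "PhantomSpec",
    "PhantomSubject",
    "generate_volume",
    "generate_cohort",
    "iter_cohort",
    "cohort_metadata",
    "build_template",
    "DEFAULT_GEOMETRY",
]

BACKGROUND_INTENSITY = 0.0
SHELL_INTENSITY = 1.0
BRAIN_INTENSITY = 0.6
MTL_INTENSITY = 0.8


@dataclass(frozen=True)
class PhantomGeometry:
    """Ellipsoid layout of the phantom head, in millimetres (RAS axes).

    The medial-temporal structures are a bilateral pair of ellipsoids
    elongated along the anterior-posterior axis, placed infero-medially in
    the brain like the hippocampal/parahippocampal complex.
    """

    shell_outer_mm: tuple[float, float, float] = (66.0, 80.0, 62.0)
    shell_thickness_mm: float = 4.0
    brain_mm: tuple[float, float, float] = (56.0, 70.0, 52.0)
    mtl_semiaxes_mm: tuple[float, float, float] = (12.0, 18.0, 10.0)
    mtl_center_mm: tuple[float, float, float] = (28.0, -10.0, -15.0)  # right side; left mirrored

    def mtl_volume_mm3(self, scale: float = 1.0) -> float:
        """Total (both sides) ellipsoid volume for a linear scale factor."""
        a, b, c = (s * scale for s in self.mtl_semiaxes_mm)
        return 2.0 * 4.0 / 3.0 * np.pi * a * b * c

    def posterior_mtl_extent_mm(self) -> float:
        """Anterior-posterior coordinate of the structure's posterior edge."""
        return self.mtl_center_mm[1] - self.mtl_semiaxes_mm[1]

    def anchor_coronal_index(self, grid_size: int, spacing_mm: float) -> int:
        """Coronal voxel index of the posterior-most extent of the structure."""
        y = self.posterior_mtl_extent_mm()
        return int(np.floor(y / spacing_mm + (grid_size - 1) / 2.0))


DEFAULT_GEOMETRY = PhantomGeometry()


@dataclass
class PhantomSpec:
    """Study conditions for a phantom cohort."""

    grid_size: int = 96
    voxel_spacing_mm: float = 2.0
    atrophy_effect: float = 0.3
    mtl_jitter_sd: float = 0.05
    intensity_noise_sd: float = 0.05  # fraction of brain-tissue intensity
    misalign_rot_deg_max: float = 10.0
    misalign_trans_mm_max: float = 10.0
    age_mean_years: float = 74.6
    age_sd_years: float = 7.0
    age_range_years: tuple[float, float] = (55.0, 95.0)
    female_fraction: float = 0.467
    age_class_shift_years: float = 0.0  # optional AD age shift for confounding studies
    seed: int = 0
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)

    def __post_init__(self) -> None:
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if not 0.0 <= self.atrophy_effect < 1.0:
            raise ValueError("atrophy_effect must be in [0, 1)")
        for name in ("mtl_jitter_sd", "intensity_noise_sd",
                     "misalign_rot_deg_max", "misalign_trans_mm_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        half_fov = self.grid_size * self.voxel_spacing_mm / 2.0
        reach = max(self.geometry.shell_outer_mm) + self.misalign_trans_mm_max
        if reach > half_fov:
            raise ValueError(
                f"phantom does not fit in grid: extent {reach:.0f} mm exceeds "
                f"half field-of-view {half_fov:.0f} mm"
            )


@dataclass
class PhantomSubject:
    """Ground truth and metadata for one generated subject."""

    subject_id: str
    age_years: float
    sex: int  # 1 = female, 0 = male
    diagnosis: str  # "AD" or "CN"
    true_transform: RigidTransform
    true_mtl_volume_mm3: float

    def __post_init__(self) -> None:
        if self.diagnosis not in ("AD", "CN"):
            raise ValueError(f"diagnosis must be 'AD' or 'CN', got {self.diagnosis!r}")

    @property
    def label(self) -> int:
        return 1 if self.diagnosis == "AD" else 0


def _ellipsoid(coords, center_mm, semiaxes_mm) -> np.ndarray:
    x, y, z = coords
    q = (
        ((x - center_mm[0]) / semiaxes_mm[0]) ** 2
        + ((y - center_mm[1]) / semiaxes_mm[1]) ** 2
        + ((z - center_mm[2]) / semiaxes_mm[2]) ** 2
    )
    return q <= 1.0


def _grid_coords(spec: PhantomSpec):
    n, s = spec.grid_size, spec.voxel_spacing_mm
    ax = (np.arange(n) - (n - 1) / 2.0) * s
    return ax[:, None, None], ax[None, :, None], ax[None, None, :]


def aligned_phantom_image(spec: PhantomSpec, mtl_scale: float = 1.0) -> np.ndarray:
    """Noise-free, perfectly aligned phantom with a given MTL linear scale."""
    geom = spec.geometry
    coords = _grid_coords(spec)
    img = np.zeros((spec.grid_size,) * 3, dtype=np.float32)

    outer = _ellipsoid(coords, (0, 0, 0), geom.shell_outer_mm)
    inner_semi = tuple(a - geom.shell_thickness_mm for a in geom.shell_outer_mm)
    inner = _ellipsoid(coords, (0, 0, 0), inner_semi)
    img[outer & ~inner] = SHELL_INTENSITY

    brain = _ellipsoid(coords, (0, 0, 0), geom.brain_mm)
    img[brain] = BRAIN_INTENSITY

    semi = tuple(a * mtl_scale for a in geom.mtl_semiaxes_mm)
    cx, cy, cz = geom.mtl_center_mm
    for side in (+1, -1):
        img[_ellipsoid(coords, (side * cx, cy, cz), semi)] = MTL_INTENSITY

    # mild band-limiting so trilinear resampling behaves like on real images
    return ndimage.gaussian_filter(img, sigma=0.5).astype(np.float32)


def brain_mask_ground_truth(spec: PhantomSpec) -> np.ndarray:
    """True (aligned-space) brain parenchyma mask of the phantom."""
    return _ellipsoid(_grid_coords(spec), (0, 0, 0), spec.geometry.brain_mm)


def _draw_transform(spec: PhantomSpec, rng: np.random.Generator) -> RigidTransform:
    rot = rng.uniform(-spec.misalign_rot_deg_max, spec.misalign_rot_deg_max, 3)
    tra = rng.uniform(-spec.misalign_trans_mm_max, spec.misalign_trans_mm_max, 3)
    return RigidTransform(rotations_deg=tuple(rot), translations_mm=tuple(tra))


def generate_volume(
    spec: PhantomSpec,
    subject_params: dict,
    rng: np.random.Generator,
) -> tuple[Volume3D, PhantomSubject]:
    """Generate one misaligned, noisy phantom plus its ground truth.

    ``subject_params`` carries ``subject_id``, ``age_years``, ``sex`` and
    ``diagnosis``.  The medial-temporal linear scale is
    ``((1 - atrophy_effect) * jitter) ** (1/3)`` for AD subjects (jitter
    lognormal with log-SD ``mtl_jitter_sd``), so the *volume* ratio between
    the classes is exactly ``1 - atrophy_effect`` in law.
    """
    import SimpleITK as sitk  # local import keeps module import light

    diagnosis = subject_params["diagnosis"]
    volume_factor = float(rng.lognormal(mean=0.0, sigma=spec.mtl_jitter_sd))
    if diagnosis == "AD":
        volume_factor *= 1.0 - spec.atrophy_effect
    mtl_scale = volume_factor ** (1.0 / 3.0)

    aligned = aligned_phantom_image(spec, mtl_scale=mtl_scale)
    true_transform = _draw_transform(spec, rng)

    vol = Volume3D(aligned, spacing_mm=(spec.voxel_spacing_mm,) * 3)
    img = vol.to_sitk()
    moved = sitk.Resample(img, img, true_transform.to_sitk(), sitk.sitkLinear, 0.0)
    data = Volume3D.from_sitk(moved).data

    noise_sd = spec.intensity_noise_sd * BRAIN_INTENSITY
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape).astype(np.float32)

    subject = PhantomSubject(
        subject_id=str(subject_params["subject_id"]),
        age_years=float(subject_params["age_years"]),
        sex=int(subject_params["sex"]),
        diagnosis=diagnosis,
        true_transform=true_transform,
        true_mtl_volume_mm3=spec.geometry.mtl_volume_mm3(scale=mtl_scale),
    )
    return Volume3D(data, spacing_mm=(spec.voxel_spacing_mm,) * 3), subject


def _draw_demographics(spec: PhantomSpec, diagnosis: str, rng: np.random.Generator):
    lo, hi = spec.age_range_years
    age = float(np.clip(rng.normal(spec.age_mean_years, spec.age_sd_years), lo, hi))
    if diagnosis == "AD":
        age = float(np.clip(age + spec.age_class_shift_years, lo, hi))
    sex = int(rng.random() < spec.female_fraction)
    return age, sex


def _subject_plan(spec: PhantomSpec, n_ad: int, n_cn: int, seed: int):
    if n_ad < 1 or n_cn < 1:
        raise ValueError("n_ad and n_cn must each be >= 1")
    rng = np.random.default_rng(seed)
    plan = []
    for diagnosis, n in (("AD", n_ad), ("CN", n_cn)):
        for i in range(n):
            age, sex = _draw_demographics(spec, diagnosis, rng)
            plan.append(
                dict(
                    subject_id=f"{diagnosis}{i + 1:03d}",
                    age_years=age,
                    sex=sex,
                    diagnosis=diagnosis,
                )
            )
    return plan, rng


def iter_cohort(
    spec: PhantomSpec, n_ad: int, n_cn: int, seed: int | None = None
) -> Iterator[tuple[Volume3D, PhantomSubject]]:
    """Stream (volume, subject) pairs; memory-friendly form of generate_cohort."""
    seed = spec.seed if seed is None else seed
    plan, rng = _subject_plan(spec, n_ad, n_cn, seed)
    for params in plan:
        yield generate_volume(spec, params, rng)


def generate_cohort(
    spec: PhantomSpec, n_ad: int, n_cn: int, seed: int | None = None
) -> list[tuple[Volume3D, PhantomSubject]]:
    """Generate a full cohort; a pure function of (spec, seed)."""
    return list(iter_cohort(spec, n_ad, n_cn, seed))


def cohort_metadata(subjects: list[PhantomSubject]) -> pd.DataFrame:
    """Subject table in the on-disk CSV schema."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age_years": [s.age_years for s in subjects],
            "sex": [s.sex for s in subjects],
            "diagnosis": [s.diagnosis for s in subjects],
        }
    )


def build_template(
    cn_volumes: list[Volume3D],
    geometry: PhantomGeometry = DEFAULT_GEOMETRY,
) -> Template:
    """Build the reference template from cognitively normal volumes.

    Each input is rigidly aligned to the first, the aligned volumes are
    averaged voxelwise, and a brain mask is extracted from the mean.  The
    anchor coronal index (start of the medial-temporal slice range) comes
    from the known phantom geometry and is stored as template metadata.
    """
    from .preprocess import extract_brain, register_rigid

    if len(cn_volumes) < 1:
        raise ValueError("need at least one CN volume")
    first = cn_volumes[0]
    for v in cn_volumes[1:]:
        if v.shape != first.shape or v.spacing_mm != first.spacing_mm:
            raise ValueError("all template volumes must share grid and spacing")

    acc = first.data.astype(np.float64).copy()
    for v in cn_volumes[1:]:
        _, resampled = register_rigid(v, first)
        acc += resampled.data
    mean = Volume3D((acc / len(cn_volumes)).astype(np.float32), first.spacing_mm)

    mask, _ = extract_brain(mean)
    anchor = geometry.anchor_coronal_index(mean.shape[1], mean.spacing_mm[1])
    return Template(
        volume=mean,
        brain_mask=mask,
        anchor_coronal_index=anchor,
        meta={"n_subjects": len(cn_volumes)},
    )
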
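"""Core spatial types: 3D volumes and 6-parameter rigid transforms.

Conventions
-----------
Arrays are indexed ``data[x, y, z]`` with axes canonically oriented RAS
(+x right, +y anterior, +z superior).  The world origin sits at the grid
center, so voxel ``i`` on an axis of length ``n`` with spacing ``s`` lies at
``(i - (n - 1)/2) * s`` millimetres.  Coronal planes are constant-``y``
planes; a coronal slice is the 2D array ``data[:, iy, :]``.

Rigid transforms follow the ITK Euler3D convention: rotation matrix
``R = Rz * Rx * Ry`` built from three Euler angles, applied about
``center_mm``, followed by a translation.  Composition and inversion are
closed (the result is again a 6-parameter rigid map).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume3D",
    "RigidTransform",
    "Template",
    "load_volume",
    "save_volume",
    "load_template",
    "save_template",
]


@dataclass
class Volume3D:
    """A 3D scalar image with isotropic-per-axis voxel spacing, RAS axes."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.orientation != "RAS":
            raise ValueError("only RAS-canonicalized volumes are supported")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_coords(self, axis: int) -> np.ndarray:
        """World coordinate (mm) of each voxel center along ``axis``."""
        n = self.shape[axis]
        s = self.spacing_mm[axis]
        return (np.arange(n) - (n - 1) / 2.0) * s

    def origin_mm(self) -> tuple[float, float, float]:
        """World coordinate of voxel (0, 0, 0)."""
        return tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing_mm)
        )

    def to_sitk(self) -> sitk.Image:
        # SimpleITK expects array order (z, y, x)
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing(self.spacing_mm)
        img.SetOrigin(self.origin_mm())
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume3D":
        data = sitk.GetArrayFromImage(img).T
        return cls(data=data, spacing_mm=tuple(img.GetSpacing()))


def _euler_matrix(rotations_deg, center_mm, translations_mm) -> np.ndarray:
    """4x4 homogeneous matrix of the ITK Euler3D map."""
    t = sitk.Euler3DTransform()
    t.SetCenter([float(c) for c in center_mm])
    rx, ry, rz = np.deg2rad(np.asarray(rotations_deg, dtype=float))
    t.SetRotation(rx, ry, rz)
    t.SetTranslation([float(v) for v in translations_mm])
    m = np.eye(4)
    m[:3, :3] = np.asarray(t.GetMatrix()).reshape(3, 3)
    # full affine offset: t + c - R c
    c = np.asarray(center_mm, dtype=float)
    m[:3, 3] = np.asarray(translations_mm, dtype=float) + c - m[:3, :3] @ c
    return m


@dataclass
class RigidTransform:
    """6-DOF rigid map: 3 Euler rotations (deg) + 3 translations (mm).

    ``apply`` maps a world point x to ``R (x - c) + c + t``.  The linear part
    is a pure rotation (det = 1); composition and inversion stay rigid.
    """

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.rotations_deg = tuple(float(v) for v in self.rotations_deg)
        self.translations_mm = tuple(float(v) for v in self.translations_mm)
        self.center_mm = tuple(float(v) for v in self.center_mm)

    # -- conversions ------------------------------------------------------
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous affine of this transform."""
        return _euler_matrix(self.rotations_deg, self.center_mm, self.translations_mm)

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(self.center_mm)
        rx, ry, rz = np.deg2rad(np.asarray(self.rotations_deg))
        t.SetRotation(float(rx), float(ry), float(rz))
        t.SetTranslation(self.translations_mm)
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        return cls(
            rotations_deg=tuple(np.rad2deg([t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()])),
            translations_mm=tuple(t.GetTranslation()),
            center_mm=tuple(t.GetCenter()),
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        """Recover Euler parameters (center 0) from a 4x4 rigid matrix."""
        r = np.asarray(m)[:3, :3]
        if abs(np.linalg.det(r) - 1.0) > 1e-5:
            raise ValueError("matrix linear part is not a rotation")
        t = sitk.Euler3DTransform()
        t.SetMatrix(tuple(r.ravel()), 1e-6)
        t.SetTranslation(tuple(np.asarray(m)[:3, 3]))
        return cls.from_sitk(t)

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points (N, 3) or (3,) through the transform."""
        m = self.matrix()
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ m[:3, :3].T + m[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix())

    def inverse(self) -> "RigidTransform":
        m = self.matrix()
        inv = np.eye(4)
        inv[:3, :3] = m[:3, :3].T
        inv[:3, 3] = -m[:3, :3].T @ m[:3, 3]
        return RigidTransform.from_matrix(inv)

    # -- magnitudes (used for registration error reporting) ---------------
    def rotation_angle_deg(self) -> float:
        """Total geodesic rotation angle of the linear part."""
        r = self.matrix()[:3, :3]
        c = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.rad2deg(np.arccos(c)))

    def translation_norm_mm(self) -> float:
        """Norm of the affine offset (displacement of the world origin)."""
        return float(np.linalg.norm(self.matrix()[:3, 3]))

    def to_dict(self) -> dict:
        return {
            "rotations_deg": list(self.rotations_deg),
            "translations_mm": list(self.translations_mm),
            "center_mm": list(self.center_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotations_deg=tuple(d["rotations_deg"]),
            translations_mm=tuple(d["translations_mm"]),
            center_mm=tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
        )


@dataclass
class Template:
    """Population reference: mean volume, brain mask, and the anchor coronal
    index where the medial-temporal slice range starts."""

    volume: Volume3D
    brain_mask: np.ndarray
    anchor_coronal_index: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != self.volume.shape:
            raise ValueError("brain mask shape must equal volume shape")
        if not 0 <= self.anchor_coronal_index < self.volume.shape[1]:
            raise ValueError("anchor coronal index outside grid")

    def masked_volume(self) -> Volume3D:
        return Volume3D(
            data=self.volume.data * self.brain_mask,
            spacing_mm=self.volume.spacing_mm,
        )


# ---------------------------------------------------------------------------
# NIfTI round-trips.  The affine encodes RAS orientation with the world origin
# at the grid center, matching the in-memory convention above.
# ---------------------------------------------------------------------------

def save_volume(volume: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm()
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))
    return path


def load_volume(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # enforce RAS
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data=np.asarray(img.dataobj, dtype=np.float32), spacing_mm=zooms)


def save_template(template: Template, path_prefix: str | Path) -> dict:
    """Write template as <prefix>.nii.gz + <prefix>_mask.nii.gz + JSON sidecar."""
    prefix = Path(path_prefix)
    vol_path = prefix.with_suffix(".nii.gz")
    mask_path = prefix.parent / (prefix.name + "_mask.nii.gz")
    json_path = prefix.with_suffix(".json")
    save_volume(template.volume, vol_path)
    save_volume(
        Volume3D(template.brain_mask.astype(np.float32), template.volume.spacing_mm),
        mask_path,
    )
    sidecar = {
        "anchor_coronal_index": int(template.anchor_coronal_index),
        "mask_path": mask_path.name,
        "meta": template.meta,
    }
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"volume": vol_path, "mask": mask_path, "sidecar": json_path}


def load_template(path_prefix: str | Path) -> Template:
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    volume = load_volume(prefix.with_suffix(".nii.gz"))
    mask = load_volume(prefix.parent / sidecar["mask_path"])
    return Template(
        volume=volume,
        brain_mask=mask.data > 0.5,
        anchor_coronal_index=sidecar["anchor_coronal_index"],
        meta=sidecar.get("meta", {}),
    )
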
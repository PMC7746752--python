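"""On-disk dataset formats.

Cohorts live in a directory of NIfTI-1 volumes (``<subject_id>.nii.gz``)
plus a ``subjects.csv`` table with columns
``subject_id,age_years,sex,diagnosis``.  Slice stacks persist as 3D NIfTI
(n_slices x H x W) with a JSON sidecar recording the coronal indices.
Reports are JSON with sorted keys so identical runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model import SubjectSlices
from .preprocess import SliceStack
from .volumes import load_volume, save_volume

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_stack",
    "load_stack",
    "load_dataset",
    "write_report",
]


def save_cohort(items, out_dir: str | Path) -> Path:
    """Write (volume, subject) pairs as NIfTI files plus subjects.csv."""
    from .phantom import cohort_metadata

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for volume, subject in items:
        save_volume(volume, out_dir / f"{subject.subject_id}.nii.gz")
        subjects.append(subject)
    cohort_metadata(subjects).to_csv(out_dir / "subjects.csv", index=False)
    return out_dir


def load_cohort(cohort_dir: str | Path):
    """Yield (Volume3D, metadata row) pairs from a cohort directory."""
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "subjects.csv")
    for row in table.itertuples(index=False):
        volume = load_volume(cohort_dir / f"{row.subject_id}.nii.gz")
        yield volume, row


def save_stack(stack: SliceStack, path: str | Path) -> Path:
    path = Path(path)
    arr = stack.to_array().astype(np.float32)
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
    sidecar = {
        "slice_indices": [int(i) for i in stack.slice_indices],
        "subject_ref": stack.subject_ref,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
    return path


def load_stack(path: str | Path) -> SliceStack:
    path = Path(path)
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return SliceStack(
        slices=[arr[i] for i in range(arr.shape[0])],
        slice_indices=sidecar["slice_indices"],
        subject_ref=sidecar["subject_ref"],
    )


def load_dataset(stack_dir: str | Path, input_px: int) -> list[SubjectSlices]:
    """Read preprocessed stacks + subjects.csv into classifier-ready records."""
    from .model import prepare_subject

    stack_dir = Path(stack_dir)
    table = pd.read_csv(stack_dir / "subjects.csv")
    records = []
    for row in table.itertuples(index=False):
        stack = load_stack(stack_dir / f"{row.subject_id}.nii.gz")

        class _Subject:
            subject_id = row.subject_id
            age_years = row.age_years
            sex = row.sex
            label = 1 if row.diagnosis == "AD" else 0

        records.append(prepare_subject(stack, _Subject, input_px))
    return records


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path
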
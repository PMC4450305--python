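"""NIfTI I/O, ROI handling, intensity normalization and subject-level folds.

Conventions: coordinates are 0-based with axis order (x, y, z) equal to array
index order; masks are binarized as value > 0; cross-validation folds always
partition *subjects*, never voxels, so that a voxel and its neighbours can
never straddle a train/validation boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "SubjectVolume",
    "FoldSplit",
    "load_subject",
    "save_subject",
    "extract_roi",
    "normalize_intensity",
    "make_folds",
]


@dataclass
class SubjectVolume:
    """One subject's (ROI of a) volume, optional mask, and its offset.

    ``roi_origin`` is the 0-based offset of this array within the original
    volume it was cropped from ((0, 0, 0) for an uncropped volume).
    """

    subject_id: str
    intensities: np.ndarray
    mask: np.ndarray | None = None
    roi_origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"non-3D image: got {self.intensities.ndim} dimensions for "
                f"subject {self.subject_id!r}"
            )
        if self.mask is not None:
            self.mask = (np.asarray(self.mask) > 0).astype(np.uint8)
            if self.mask.shape != self.intensities.shape:
                raise ValueError(
                    f"shape mismatch for subject {self.subject_id!r}: volume "
                    f"{self.intensities.shape} vs mask {self.mask.shape}"
                )
        if any(o < 0 for o in self.roi_origin):
            raise ValueError(f"roi_origin must be non-negative, got {self.roi_origin}")


def load_subject(volume_path, mask_path=None, subject_id: str | None = None) -> SubjectVolume:
    """Load a NIfTI volume (and optionally its mask) as a SubjectVolume.

    Intensities are converted to float; the mask is binarized (> 0 -> 1).
    """
    volume_path = Path(volume_path)
    try:
        img = nib.load(volume_path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise OSError(f"unreadable NIfTI file {volume_path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {volume_path} has {data.ndim} dimensions")
    mask = None
    if mask_path is not None:
        mask_img = nib.load(Path(mask_path))
        mask = np.asanyarray(mask_img.dataobj)
        if mask.ndim != 3:
            raise ValueError(f"non-3D image: {mask_path} has {mask.ndim} dimensions")
        if mask.shape != data.shape:
            raise ValueError(
                f"shape mismatch: volume {data.shape} vs mask {mask.shape}"
            )
    sid = subject_id if subject_id is not None else volume_path.name.split(".")[0]
    return SubjectVolume(subject_id=sid, intensities=data.astype(float), mask=mask)


def save_subject(sv: SubjectVolume, volume_path, mask_path=None) -> None:
    """Write the volume (and mask, if requested and present) with identity affine."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(sv.intensities.astype(np.float32), affine), str(volume_path))
    if mask_path is not None:
        if sv.mask is None:
            raise ValueError(f"subject {sv.subject_id!r} has no mask to save")
        nib.save(nib.Nifti1Image(sv.mask.astype(np.uint8), affine), str(mask_path))


def extract_roi(sv: SubjectVolume, margin: int = 0) -> SubjectVolume:
    """Crop to the mask bounding box expanded by ``margin``, clamped at borders."""
    if sv.mask is None:
        raise ValueError("extract_roi requires a mask")
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    nz = np.nonzero(sv.mask)
    if nz[0].size == 0:
        raise ValueError(f"empty mask for subject {sv.subject_id!r}")
    lo = [max(0, int(idx.min()) - margin) for idx in nz]
    hi = [min(n, int(idx.max()) + 1 + margin) for idx, n in zip(nz, sv.mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return SubjectVolume(
        subject_id=sv.subject_id,
        intensities=sv.intensities[sl].copy(),
        mask=sv.mask[sl].copy(),
        roi_origin=tuple(o + a for o, a in zip(sv.roi_origin, lo)),
    )


def normalize_intensity(sv: SubjectVolume) -> SubjectVolume:
    """Min-max map of the intensities onto [0, 1] (order-preserving, affine)."""
    lo = float(sv.intensities.min())
    hi = float(sv.intensities.max())
    if hi == lo:
        raise ValueError(
            f"constant volume for subject {sv.subject_id!r}: normalization is degenerate"
        )
    return replace(sv, intensities=(sv.intensities - lo) / (hi - lo))


@dataclass
class FoldSplit:
    """Subject-level k-fold partition: subject id -> fold index in [0, k)."""

    k: int
    assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if folds and (min(folds) < 0 or max(folds) >= self.k):
            raise ValueError("fold indices must lie in [0, k)")
        sizes = self.fold_sizes()
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes must differ by at most 1, got {sizes}")

    def fold_sizes(self) -> list[int]:
        return [sum(1 for f in self.assignment.values() if f == i) for i in range(self.k)]

    def subjects_in_fold(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"k": self.k, "assignment": self.assignment}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "FoldSplit":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(k=d["k"], assignment=d["assignment"])


def make_folds(subject_ids, k: int, seed: int = 0) -> FoldSplit:
    """Randomly partition subjects into k folds of near-equal size."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: int(pos % k) for pos, j in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment)
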
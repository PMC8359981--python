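"""Reading, writing and cropping of 3D image stacks and landmark files.

Conventions owned by this module:

* Voxel arrays are indexed ``(x, y, z)`` = (image width K, image height M,
  slice count N); ``stack.voxels[..., k]`` is the k-th slice.
* Voxel indices are 0-based; crop boxes are half-open.
* Physical coordinates are millimetres at voxel centers:
  ``p = origin + index * spacing``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "LandmarkSet",
    "ReferenceAxis",
    "read_stack",
    "write_stack",
    "crop",
    "read_amira_landmarks",
    "axis_from_landmarks",
]


@dataclass
class ImageStack:
    """A 3D scalar volume with physical voxel geometry.

    Parameters
    ----------
    voxels
        Array of shape ``(K, M, N)`` — width, height, slice count.
    spacing
        Physical voxel size per axis in mm, all > 0.
    origin
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    is_binary
        If True the volume contains exactly the values {0, 1}.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"all dims must be >= 1, got {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.is_binary:
            vals = np.unique(self.voxels)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("is_binary stack contains values other than {0, 1}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_to_physical(self, index: Sequence[float]) -> np.ndarray:
        """Physical mm coordinate of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def binarized_like(self, voxels: np.ndarray) -> "ImageStack":
        """New binary stack sharing this stack's geometry."""
        return ImageStack(
            voxels=voxels.astype(np.uint8),
            spacing=self.spacing,
            origin=self.origin,
            is_binary=True,
        )


@dataclass
class LandmarkSet:
    """Ordered 3D landmarks in physical mm."""

    points: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or self.points.shape[0] < 1:
            raise ValueError("points must be an (n >= 1, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ReferenceAxis:
    """A directed reference axis between two physical points (mm)."""

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.start.shape != (3,) or self.end.shape != (3,):
            raise ValueError("axis endpoints must be 3-vectors")
        if np.allclose(self.start, self.end):
            raise ValueError("zero-length axis: start and end coincide")

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


def read_stack(
    path: str | Path,
    format: str | None = None,
    spacing_override: Sequence[float] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF stack or a NIfTI-1 volume.

    ``format`` is ``"tiff_stack"`` or ``"nifti"``; inferred from the file
    suffix when omitted. NIfTI spacing comes from the header ``pixdim``
    (overridable); TIFF stacks carry no reliable spacing so
    ``spacing_override`` is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if format is None:
        suffixes = "".join(path.suffixes).lower()
        if suffixes.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif suffixes.endswith((".tif", ".tiff")):
            format = "tiff_stack"
        else:
            raise ValueError(f"cannot infer format from suffix of {path.name}")

    if format == "tiff_stack":
        pages = tifffile.imread(str(path))
        if pages.ndim == 2:
            pages = pages[None, ...]
        if pages.ndim != 3:
            raise ValueError(f"TIFF stack must be 2D pages, got shape {pages.shape}")
        # tifffile returns (page=N, row=M, col=K); reorder to (K, M, N)
        voxels = np.ascontiguousarray(pages.transpose(2, 1, 0))
        if spacing_override is None:
            raise ValueError("spacing unknown: TIFF stacks need spacing_override")
        spacing = tuple(float(s) for s in spacing_override)
    elif format == "nifti":
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj)
        if voxels.ndim == 4 and voxels.shape[3] == 1:
            voxels = voxels[..., 0]
        if voxels.ndim != 3:
            raise ValueError(f"NIfTI volume must be 3D, got shape {voxels.shape}")
        if spacing_override is not None:
            spacing = tuple(float(s) for s in spacing_override)
        else:
            zooms = img.header.get_zooms()[:3]
            spacing = tuple(float(z) for z in zooms)
            if any(s <= 0 for s in spacing):
                raise ValueError("spacing unknown: NIfTI header has non-positive pixdim")
    else:
        raise ValueError(f"unknown format {format!r}")

    vals = np.unique(voxels)
    is_binary = vals.size <= 2 and np.isin(vals, (0, 1)).all()
    if is_binary:
        voxels = voxels.astype(np.uint8)
    return ImageStack(voxels=voxels, spacing=spacing, is_binary=is_binary)


def write_stack(stack: ImageStack, path: str | Path, format: str | None = None) -> None:
    """Write a stack as multi-page TIFF or NIfTI-1; round-trips with read_stack."""
    path = Path(path)
    if format is None:
        suffixes = "".join(path.suffixes).lower()
        if suffixes.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif suffixes.endswith((".tif", ".tiff")):
            format = "tiff_stack"
        else:
            raise ValueError(f"cannot infer format from suffix of {path.name}")

    if format == "tiff_stack":
        pages = np.ascontiguousarray(stack.voxels.transpose(2, 1, 0))
        if pages.dtype == bool:
            pages = pages.astype(np.uint8)
        tifffile.imwrite(str(path), pages)
    elif format == "nifti":
        affine = np.diag(list(stack.spacing) + [1.0])
        affine[:3, 3] = stack.origin
        data = stack.voxels
        if data.dtype == bool:
            data = data.astype(np.uint8)
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def crop(stack: ImageStack, lo: Sequence[int], hi: Sequence[int]) -> ImageStack:
    """Extract the half-open sub-volume ``[lo, hi)``; origin shifts by lo*spacing."""
    lo = tuple(int(v) for v in lo)
    hi = tuple(int(v) for v in hi)
    dims = stack.dims
    for axis in range(3):
        if not (0 <= lo[axis] < hi[axis] <= dims[axis]):
            raise ValueError(
                f"crop box [{lo}, {hi}) invalid for dims {dims} on axis {axis}"
            )
    sub = stack.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    origin = tuple(
        stack.origin[a] + lo[a] * stack.spacing[a] for a in range(3)
    )
    return ImageStack(voxels=sub, spacing=stack.spacing, origin=origin, is_binary=stack.is_binary)


_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"


def read_amira_landmarks(path: str | Path, voxel_units: bool = False,
                         spacing: Sequence[float] | None = None) -> LandmarkSet:
    """Parse an Amira LandmarkSet ASCII file.

    Coordinates are taken as physical mm. Some exports store voxel indices
    instead; pass ``voxel_units=True`` with a ``spacing`` to convert.
    """
    text = Path(path).read_text()
    m = re.search(r"define\s+Markers\s+(\d+)", text)
    if m is None:
        raise ValueError("malformed Amira landmark file: no 'define Markers' header")
    n = int(m.group(1))
    data = _read_data_section(text, "@1")
    if len(data) == 0:
        raise ValueError("empty landmark data section")
    if len(data) % 3 != 0 or len(data) // 3 != n:
        raise ValueError(
            f"landmark data has {len(data)} numbers, expected {3 * n} for {n} markers"
        )
    points = np.asarray(data, dtype=float).reshape(n, 3)
    if voxel_units:
        if spacing is None:
            raise ValueError("voxel_units=True requires a spacing to convert to mm")
        points = points * np.asarray(spacing, dtype=float)
    return LandmarkSet(points=points)


def _read_data_section(text: str, marker: str) -> list[float]:
    """Collect the numbers following a line that is exactly the @N marker."""
    lines = text.splitlines()
    out: list[float] = []
    active = False
    for line in lines:
        stripped = line.strip()
        if stripped == marker:
            active = True
            continue
        if active:
            if re.fullmatch(r"@\d+", stripped):
                break
            if not stripped or stripped.startswith("#"):
                continue
            for tok in stripped.split():
                try:
                    out.append(float(tok))
                except ValueError as exc:
                    raise ValueError(f"non-numeric value {tok!r} in section {marker}") from exc
    if not active:
        raise ValueError(f"data section {marker} not found")
    return out


def axis_from_landmarks(lm: LandmarkSet, i: int, j: int) -> ReferenceAxis:
    """Reference axis from landmark ``i`` to landmark ``j`` (0-based)."""
    n = len(lm)
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"landmark indices ({i}, {j}) out of range for {n} points")
    if i == j:
        raise ValueError("axis endpoints must be two different landmarks")
    return ReferenceAxis(start=lm.points[i], end=lm.points[j])
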
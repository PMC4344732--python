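"""Binary intracranial masks and slice-wise area profiles.

A :class:`VoxelMask` is a 3D boolean grid on an isotropic lattice whose
axes are labelled with the three anatomical slicing orientations
(sagittal, coronal, transversal).  Collapsing the mask along one axis
yields an :class:`AreaProfile` — the ordered sequence of cross-sectional
intracranial areas (ICAs) that all sparse-sampling volume estimators
consume.  The voxel-count volume of the mask is the reference standard
("ground truth") every estimate is compared against.

Axis direction conventions (fixed so that offset indices are anatomically
meaningful): sagittal profiles run left→right, coronal anterior→posterior,
transversal superior→inferior.  NIfTI orientation codes are honoured on
load and axes are flipped into this canonical order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

ORIENTATIONS = ("sagittal", "coronal", "transversal")

#: RAS axis-code letter -> orientation name
_AXCODE_TO_ORIENTATION = {
    "R": "sagittal", "L": "sagittal",
    "A": "coronal", "P": "coronal",
    "S": "transversal", "I": "transversal",
}

#: canonical direction per orientation: profile index increases towards this code
_CANONICAL_CODE = {"sagittal": "R", "coronal": "P", "transversal": "I"}


def _check_orientation(orientation: str) -> str:
    if orientation not in ORIENTATIONS:
        raise ValueError(
            f"unknown orientation {orientation!r}; valid labels are {ORIENTATIONS}"
        )
    return orientation


@dataclass
class VoxelMask:
    """3D binary intracranial segmentation on an isotropic voxel grid.

    Parameters
    ----------
    data : ndarray of bool, 3D
        True marks intracranial voxels.  At least one voxel must be set.
    voxel_size : float
        Edge length of the (isotropic) voxels in mm.
    axis_labels : tuple of str
        Orientation name of each grid axis; must be a permutation of
        ``("sagittal", "coronal", "transversal")``.
    subject_id : str
        Opaque identifier carried through to profiles and estimates.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    axis_labels: tuple[str, str, str] = ORIENTATIONS
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {self.data.shape}")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        if not self.data.any():
            raise ValueError("mask contains no true voxels")
        if not (np.isscalar(self.voxel_size) or np.ndim(self.voxel_size) == 0):
            raise ValueError(
                "VoxelMask requires a single isotropic voxel size; resample "
                "anisotropic data first (preprocess.resample_isotropic)"
            )
        self.voxel_size = float(self.voxel_size)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.axis_labels = tuple(self.axis_labels)
        if sorted(self.axis_labels) != sorted(ORIENTATIONS):
            raise ValueError(
                f"axis_labels must be a permutation of {ORIENTATIONS}, "
                f"got {self.axis_labels}"
            )

    def axis_of(self, orientation: str) -> int:
        """Grid axis index carrying the given orientation label."""
        return self.axis_labels.index(_check_orientation(orientation))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class AreaProfile:
    """Ordered (position, area) samples of one slicing orientation.

    ``positions`` are slice-centre coordinates in mm on a uniform grid
    with step ``voxel_size``; ``areas`` are the matching cross-sectional
    areas in mm².  The nonzero support must be one contiguous run —
    a real intracranial vault produces no interior empty slices.
    """

    orientation: str
    positions: np.ndarray
    areas: np.ndarray
    subject_id: str = ""
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        _check_orientation(self.orientation)
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.areas.shape:
            raise ValueError("positions and areas must be 1D arrays of equal length")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        steps = np.diff(self.positions)
        if len(steps) and not np.allclose(steps, self.voxel_size, rtol=0, atol=1e-9):
            raise ValueError(
                "positions must increase with constant step equal to voxel_size"
            )
        if (self.areas < 0).any():
            raise ValueError("areas must be nonnegative")
        support = np.flatnonzero(self.areas > 0)
        if support.size == 0:
            raise ValueError("profile has no positive areas")
        if support[-1] - support[0] + 1 != support.size:
            raise ValueError(
                "profile support is not contiguous (interior zero-area slices); "
                "such degenerate profiles are rejected"
            )
        self._support = (int(support[0]), int(support[-1]))

    @property
    def support(self) -> tuple[int, int]:
        """First and last index with positive area (inclusive)."""
        return self._support

    @property
    def support_length(self) -> int:
        lo, hi = self._support
        return hi - lo + 1

    @property
    def total_volume(self) -> float:
        """Slice-sum volume in mm³ (areas × slice thickness)."""
        return float(self.areas.sum() * self.voxel_size)

    def reversed(self) -> "AreaProfile":
        """Profile traversed from the other end (used for symmetry checks)."""
        return AreaProfile(
            orientation=self.orientation,
            positions=self.positions,
            areas=self.areas[::-1].copy(),
            subject_id=self.subject_id,
            voxel_size=self.voxel_size,
        )


def area_profile(mask: VoxelMask, orientation: str) -> AreaProfile:
    """Extract the cross-sectional area profile along one orientation.

    Slice ``i`` of the chosen axis contributes area
    ``(true voxels in slice i) × voxel_size²`` at position ``i × voxel_size``.
    """
    axis = mask.axis_of(orientation)
    other = tuple(a for a in range(3) if a != axis)
    counts = mask.data.sum(axis=other)
    areas = counts.astype(float) * mask.voxel_size**2
    positions = np.arange(counts.size, dtype=float) * mask.voxel_size
    return AreaProfile(
        orientation=orientation,
        positions=positions,
        areas=areas,
        subject_id=mask.subject_id,
        voxel_size=mask.voxel_size,
    )


def total_volume(mask: VoxelMask) -> float:
    """Reference intracranial volume in mm³: voxel count × voxel_size³."""
    return mask.n_voxels * mask.voxel_size**3


# ---------------------------------------------------------------------------
# NIfTI / CSV round-trips


def save_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as binary-valued NIfTI with canonical direction codes."""
    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    sign = {"R": 1.0, "P": -1.0, "I": -1.0}
    world_axis = {"sagittal": 0, "coronal": 1, "transversal": 2}
    for i, label in enumerate(mask.axis_labels):
        j = world_axis[label]
        affine[j, i] = sign[_CANONICAL_CODE[label]] * mask.voxel_size
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms((mask.voxel_size,) * 3)
    nib.save(img, str(path))


def load_mask(path: str | Path, subject_id: str | None = None) -> VoxelMask:
    """Read a binary NIfTI mask, honouring its orientation codes.

    Axes are flipped so profiles run left→right / anterior→posterior /
    superior→inferior.  Anisotropic images are rejected: resample first.
    """
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        raise ValueError(
            f"mask at {path} has anisotropic voxels {tuple(zooms)}; "
            "resample to an isotropic grid first (preprocess.resample_isotropic)"
        )
    data = np.asarray(img.dataobj) > 0.5
    axcodes = nib.aff2axcodes(img.affine)
    labels = []
    for axis, code in enumerate(axcodes):
        label = _AXCODE_TO_ORIENTATION[code]
        labels.append(label)
        if code != _CANONICAL_CODE[label]:
            data = np.flip(data, axis=axis)
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return VoxelMask(
        data=np.ascontiguousarray(data),
        voxel_size=float(zooms[0]),
        axis_labels=tuple(labels),
        subject_id=subject_id,
    )


def _sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def save_profile(profile: AreaProfile, csv_path: str | Path) -> None:
    """Write an area profile as CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    lines = ["position_mm,area_mm2"]
    lines += [f"{p:.6g},{a:.10g}" for p, a in zip(profile.positions, profile.areas)]
    csv_path.write_text("\n".join(lines) + "\n")
    meta = {
        "orientation": profile.orientation,
        "subject_id": profile.subject_id,
        "voxel_size": profile.voxel_size,
    }
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=2) + "\n")


def load_profile(
    csv_path: str | Path,
    orientation: str | None = None,
    subject_id: str | None = None,
) -> AreaProfile:
    """Read a profile CSV (header ``position_mm,area_mm2``) and its sidecar."""
    import pandas as pd

    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    if list(table.columns) != ["position_mm", "area_mm2"]:
        raise ValueError(
            f"{csv_path} must have header 'position_mm,area_mm2', got {list(table.columns)}"
        )
    meta: dict = {}
    sidecar = _sidecar_path(csv_path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    orientation = orientation or meta.get("orientation")
    if orientation is None:
        raise ValueError(
            f"no orientation given and no sidecar {sidecar.name}; pass orientation="
        )
    positions = table["position_mm"].to_numpy(dtype=float)
    step = float(np.diff(positions).mean()) if positions.size > 1 else meta.get("voxel_size", 1.0)
    return AreaProfile(
        orientation=orientation,
        positions=positions,
        areas=table["area_mm2"].to_numpy(dtype=float),
        subject_id=subject_id or meta.get("subject_id", csv_path.stem),
        voxel_size=float(meta.get("voxel_size", step)),
    )
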
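"""Intensity conditioning and isotropic resampling for raw MRI volumes.

These steps prepare scalar images for manual tracing of the intracranial
vault: each scan's brightness is matched to a cohort-wide robust mean
(computed over the central 80 % of the tonal range, so large background
regions do not bias it), the tonal range is then expanded by clipping the
darkest and brightest tails, and finally a gamma curve brightens the data
to improve dura visibility.  None of these operations touch the area
profiles themselves; they condition the images areas are traced on.

The robust mean's band is taken over the representable range ``[0, B−1]``
(not the per-image min–max) so the same band means the same thing across
scans.  Brightness matching is an additive shift: because shifting moves
voxels in and out of the central band, the shift is iterated to a fixed
point instead of applied once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .mask_model import VoxelMask

logger = logging.getLogger(__name__)

#: default intensity ceiling: 12-bit data
DEFAULT_B = 4096


@dataclass
class IntensityImage:
    """3D scalar image with values in ``[0, B−1]``.

    ``B`` is the intensity scale ceiling derived from bit depth (4096 for
    12-bit data); ``voxel_size`` is per-axis in mm and may be anisotropic
    until :func:`resample_isotropic` is applied.
    """

    data: np.ndarray
    B: int = DEFAULT_B
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"image data must be 3D, got shape {self.data.shape}")
        if self.B <= 1:
            raise ValueError("intensity ceiling B must exceed 1")
        if self.data.min() < 0 or self.data.max() > self.B - 1:
            raise ValueError(f"intensities must lie in [0, {self.B - 1}]")
        self.voxel_size = tuple(float(v) for v in np.atleast_1d(self.voxel_size).repeat(
            3 if np.ndim(self.voxel_size) == 0 else 1
        ))[:3]
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


def robust_mean(image: IntensityImage) -> float:
    """Mean intensity over the central 80 % of the tonal range.

    Only voxels with values in ``[0.1·(B−1), 0.9·(B−1)]`` contribute, which
    discounts background (dark) and hyperintense voxels so that scans with
    different head sizes are compared on equal footing.
    """
    lo = 0.1 * (image.B - 1)
    hi = 0.9 * (image.B - 1)
    band = (image.data >= lo) & (image.data <= hi)
    if not band.any():
        raise ValueError(
            "no voxel lies within the central 80% of the tonal range; "
            "degenerate image"
        )
    return float(image.data[band].mean())


def match_brightness(
    image: IntensityImage,
    target_mean: float,
    tol: float = 0.5,
    max_iter: int = 20,
) -> IntensityImage:
    """Shift the image so its robust mean matches ``target_mean``.

    The shift is additive and iterated because clipping to ``[0, B−1]``
    and band-membership changes make a single shift inexact.  Converges
    when the re-measured robust mean is within ``tol`` intensity units.
    """
    if not 0 < target_mean < image.B - 1:
        raise ValueError(f"target_mean must lie in (0, {image.B - 1})")
    shift = 0.0
    for _ in range(max_iter):
        shifted = np.clip(image.data + shift, 0, image.B - 1)
        current = robust_mean(replace(image, data=shifted))
        err = target_mean - current
        if abs(err) <= tol:
            return replace(image, data=shifted)
        shift += err
    raise RuntimeError(
        f"brightness matching did not converge to within {tol} units "
        f"after {max_iter} iterations"
    )


def contrast_stretch(image: IntensityImage, tail_fraction: float = 0.10) -> IntensityImage:
    """Expand the tonal range by compressing both intensity tails.

    The darkest ``tail_fraction`` of voxels map to 0, the brightest to
    ``B−1``, and the interior rescales linearly — improving the visible
    contrast of faint structures such as the dura.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must lie in (0, 0.5)")
    lo = float(np.quantile(image.data, tail_fraction))
    hi = float(np.quantile(image.data, 1 - tail_fraction))
    if hi <= lo:
        raise ValueError("degenerate image: tail quantiles coincide")
    scaled = (image.data - lo) / (hi - lo) * (image.B - 1)
    return replace(image, data=np.clip(scaled, 0, image.B - 1))


def gamma_map(x: np.ndarray | float, B: float, gamma: float) -> np.ndarray | float:
    """The raw gamma curve ``y = B·(x/B)^γ`` (endpoints 0 and B are fixed)."""
    return B * (np.asarray(x, dtype=float) / B) ** gamma


def gamma_correct(image: IntensityImage, gamma: float = 0.8) -> IntensityImage:
    """Apply the gamma curve ``y = B·(x/B)^γ`` voxel-wise.

    ``γ < 1`` brightens midtones.  The curve maps ``[0, B]`` onto ``[0, B]``;
    for γ < 1 values just below the ceiling can exceed ``B−1`` by under one
    unit and are clipped back to preserve the representable range.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if (image.data < 0).any():
        raise ValueError("negative intensities are not gamma-correctable")
    mapped = gamma_map(image.data, image.B, gamma)
    return replace(image, data=np.minimum(mapped, image.B - 1))


def resample_isotropic(
    obj: IntensityImage | VoxelMask, target_mm: float = 1.0
) -> IntensityImage | VoxelMask:
    """Resample an image or mask onto an isotropic grid of ``target_mm``.

    Trilinear interpolation; masks are interpolated as scalars and
    re-thresholded at 0.5.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    if isinstance(obj, VoxelMask):
        zoomed = _zoom((obj.data.astype(float)), (obj.voxel_size,) * 3, target_mm)
        return VoxelMask(
            data=zoomed > 0.5,
            voxel_size=target_mm,
            axis_labels=obj.axis_labels,
            subject_id=obj.subject_id,
        )
    if isinstance(obj, IntensityImage):
        zoomed = _zoom(obj.data, obj.voxel_size, target_mm)
        return replace(
            obj,
            data=np.clip(zoomed, 0, obj.B - 1),
            voxel_size=(target_mm,) * 3,
        )
    raise TypeError(f"cannot resample object of type {type(obj).__name__}")


def resample_mask_array(
    data: np.ndarray,
    voxel_size: tuple[float, float, float],
    target_mm: float = 1.0,
    axis_labels=("sagittal", "coronal", "transversal"),
    subject_id: str = "",
) -> VoxelMask:
    """Resample a raw (possibly anisotropic) boolean array into a VoxelMask."""
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    zoomed = _zoom(np.asarray(data, dtype=float), voxel_size, target_mm)
    return VoxelMask(
        data=zoomed > 0.5,
        voxel_size=target_mm,
        axis_labels=axis_labels,
        subject_id=subject_id,
    )


def _zoom(data: np.ndarray, voxel_size, target_mm: float) -> np.ndarray:
    factors = [float(v) / target_mm for v in voxel_size]
    if np.allclose(factors, 1.0):
        return data.copy()
    return ndimage.zoom(data, factors, order=1, mode="nearest", grid_mode=True)


def preprocess_cohort(
    images: list[IntensityImage],
    tail_fraction: float = 0.10,
    gamma: float = 0.8,
    target_mm: float | None = 1.0,
) -> list[IntensityImage]:
    """Condition a cohort of scans to a common intensity level.

    Order of operations: per-scan robust means → brightness matching to
    the cohort grand mean → contrast stretch → gamma correction, with an
    optional final isotropic resampling.  Every step is logged.
    """
    if not images:
        return []
    grand_mean = float(np.mean([robust_mean(im) for im in images]))
    logger.info("cohort grand robust mean: %.2f", grand_mean)
    out = []
    for i, im in enumerate(images):
        matched = match_brightness(im, grand_mean)
        stretched = contrast_stretch(matched, tail_fraction)
        corrected = gamma_correct(stretched, gamma)
        if target_mm is not None:
            corrected = resample_isotropic(corrected, target_mm)
        logger.info("scan %d: matched→stretched→gamma(%.2f) done", i, gamma)
        out.append(corrected)
    return out
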
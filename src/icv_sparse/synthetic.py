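"""Synthetic intracranial-vault phantom cohorts.

Real validation of sparse-sampling ICV estimators needs segmented MRI
volumes; this module generates stand-in phantoms with the population
structure of a memory-clinic cohort: 62 subjects (39 female / 23 male)
with gender-specific ICV distributions (female 1 416 955 ± 91 678 mm³,
male 1 658 268 ± 115 535 mm³) and a sagittal extent of about 136 ± 5
one-millimetre slices.

Each subject gets one area profile per orientation.  The base shape is a
smooth unimodal dome

    A(u) ∝ (1 − |u|^p)^(1/q),   u ∈ [−1, 1],

(the default p = 2, q = 1 is the cross-sectional area law of an
ellipsoidal vault; p = q = 2 gives the elliptical law), modulated by a
low-frequency
random perturbation whose relative amplitude is the per-orientation
``irregularity`` — transversal profiles are made noticeably less smooth
than sagittal/coronal ones, reflecting how axial cross-sections of the
skull base behave.  Profiles are rescaled multiplicatively so their
slice sum × 1 mm equals the subject's target volume exactly; all three
orientations therefore share one total volume, which doubles as the
ground truth for validity metrics.

Phantoms are primarily 1D profiles (the estimators' native input);
:func:`profile_to_mask` builds a 3D voxel mask from a sagittal profile
when a full mask fixture is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mask_model import ORIENTATIONS, AreaProfile, VoxelMask

#: per-orientation extent as a multiple of the sagittal extent
DEFAULT_EXTENT_RATIOS = {"sagittal": 1.0, "coronal": 1.25, "transversal": 0.95}

#: per-orientation relative perturbation amplitude; the transversal value
#: is set well above the others so axial profiles degrade spline estimates
#: at coarse spacings the way irregular real axial profiles do.
DEFAULT_IRREGULARITY = {"sagittal": 0.03, "coronal": 0.03, "transversal": 0.25}


@dataclass
class PopulationSpec:
    """Target population parameters for a phantom cohort.

    Volumes are mm³; ``extent_mean``/``extent_sd`` describe the sagittal
    support in 1 mm slices.  ``shape_power`` (p) controls how steeply the
    dome falls off at the ends and ``shape_root`` (q) its overall
    flatness; the default p = 2, q = 1 matches an ellipsoidal vault,
    while p = q = 2 gives the elliptical law.  ``irregularity`` maps
    each orientation to the relative amplitude of its low-frequency
    perturbation.
    """

    n_female: int = 39
    n_male: int = 23
    female_mean: float = 1416955.0
    female_sd: float = 91678.0
    male_mean: float = 1658268.0
    male_sd: float = 115535.0
    extent_mean: float = 136.0
    extent_sd: float = 5.0
    shape_power: float = 2.0
    shape_root: float = 1.0
    irregularity: dict = field(default_factory=lambda: dict(DEFAULT_IRREGULARITY))
    extent_ratios: dict = field(default_factory=lambda: dict(DEFAULT_EXTENT_RATIOS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0 or self.n_female + self.n_male < 2:
            raise ValueError("cohort must contain at least 2 subjects")
        if min(self.female_sd, self.male_sd) <= 0:
            raise ValueError("volume standard deviations must be positive")
        if self.extent_mean < 20:
            raise ValueError("extent must be at least 20 slices")
        if any(v < 0 for v in self.irregularity.values()):
            raise ValueError("irregularity must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return self.n_female + self.n_male


@dataclass
class Subject:
    """One phantom subject: profiles per orientation plus ground truth."""

    subject_id: str
    sex: str
    true_volume: float
    profiles: dict
    mask: VoxelMask | None = None


def generate_profile(
    target_volume: float,
    extent: int,
    shape_power: float = 2.0,
    shape_root: float = 1.0,
    irregularity: float = 0.0,
    rng: np.random.Generator | None = None,
    orientation: str = "sagittal",
    subject_id: str = "",
    max_harmonics: int = 3,
) -> AreaProfile:
    """Generate one unimodal phantom area profile at 1 mm slices.

    The dome ``(1 − |u|^p)^(1/q)`` is sampled at slice centres, modulated
    by 1–``max_harmonics`` low-frequency sinusoids of total relative
    amplitude ``irregularity`` (random frequencies and phases), floored
    at zero, and rescaled so the slice sum equals ``target_volume``.
    """
    if target_volume <= 0:
        raise ValueError("target_volume must be positive")
    if extent < 20:
        raise ValueError("extent must be at least 20 slices")
    rng = rng if rng is not None else np.random.default_rng()
    i = np.arange(extent)
    u = 2.0 * (i + 0.5) / extent - 1.0  # slice centres, ends excluded
    base = (1.0 - np.abs(u) ** shape_power) ** (1.0 / shape_root)
    if irregularity > 0:
        m = int(rng.integers(1, max_harmonics + 1))
        freqs = rng.uniform(0.5, 2.5, size=m)  # cycles across the support
        phases = rng.uniform(0, 2 * np.pi, size=m)
        weights = rng.uniform(0.2, 1.0, size=m)
        weights *= irregularity / weights.sum()
        t = (i + 0.5) / extent
        wobble = sum(
            w * np.sin(2 * np.pi * f * t + ph)
            for w, f, ph in zip(weights, freqs, phases)
        )
        base = base * (1.0 + wobble)
    areas = np.maximum(base, 0.0)
    total = areas.sum()
    if total <= 0:
        raise ValueError("parameters yield a profile with no positive area")
    areas = areas * (target_volume / total)  # slice thickness is 1 mm
    return AreaProfile(
        orientation=orientation,
        positions=i.astype(float),
        areas=areas,
        subject_id=subject_id,
        voxel_size=1.0,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n_sigma: float = 4.0
) -> float:
    """Normal draw truncated at ±n_sigma·sd (rules out nonphysical volumes)."""
    while True:
        v = rng.normal(mean, sd)
        if abs(v - mean) <= n_sigma * sd:
            return float(v)


def generate_cohort(spec: PopulationSpec, with_masks: bool = False) -> list[Subject]:
    """Generate a phantom cohort following a :class:`PopulationSpec`.

    The roster is fixed (females first, then males); each subject draws
    its target ICV from its gender's truncated normal and its sagittal
    extent from the extent distribution, with coronal/transversal extents
    derived by fixed anatomical aspect ratios.  Every subject uses an
    integer-indexed RNG substream ``(seed, index)`` so cohorts are
    reproducible element-wise across platforms.
    """
    roster = [("F", i) for i in range(spec.n_female)] + [
        ("M", i) for i in range(spec.n_male)
    ]
    subjects = []
    for index, (sex, within) in enumerate(roster):
        rng = np.random.default_rng([int(spec.seed), index])
        mean, sd = (
            (spec.female_mean, spec.female_sd)
            if sex == "F"
            else (spec.male_mean, spec.male_sd)
        )
        target = _truncated_normal(rng, mean, sd)
        sag_extent = max(20, int(round(rng.normal(spec.extent_mean, spec.extent_sd))))
        subject_id = f"{sex.lower()}{within + 1:03d}"
        profiles = {}
        for orient in ORIENTATIONS:
            extent = max(20, int(round(sag_extent * spec.extent_ratios[orient])))
            profiles[orient] = generate_profile(
                target_volume=target,
                extent=extent,
                shape_power=spec.shape_power,
                shape_root=spec.shape_root,
                irregularity=spec.irregularity.get(orient, 0.0),
                rng=rng,
                orientation=orient,
                subject_id=subject_id,
            )
        mask = profile_to_mask(profiles["sagittal"]) if with_masks else None
        subjects.append(
            Subject(
                subject_id=subject_id,
                sex=sex,
                true_volume=target,
                profiles=profiles,
                mask=mask,
            )
        )
    return subjects


def profile_to_mask(
    profile: AreaProfile, aspect_ratio: float = 1.3, margin: int = 2
) -> VoxelMask:
    """Voxelize a sagittal profile into a 3D mask of stacked ellipses.

    Slice ``i`` becomes an axis-aligned filled ellipse whose area matches
    ``areas[i]``; ``aspect_ratio`` is the anterior–posterior over
    superior–inferior semi-axis ratio.  Voxels are ranked by elliptical
    radius from the slice centre and exactly ``round(area / voxel²)`` of
    them are kept, so per-slice areas match to half a voxel.  Interior
    slices with areas below 1 mm² cannot be voxelized and raise.
    """
    if profile.orientation != "sagittal":
        raise ValueError("profile_to_mask expects a sagittal profile")
    v = profile.voxel_size
    areas = profile.areas
    lo, hi = profile.support
    interior = areas[lo + 1 : hi]
    if interior.size and (interior < 1.0).any():
        raise ValueError("interior slice area below 1 mm^2 cannot be voxelized")
    # semi-axes: pi * b * c = A with c = aspect_ratio * b
    b_max = np.sqrt(areas.max() / (np.pi * aspect_ratio))
    c_max = aspect_ratio * b_max
    ny = 2 * int(np.ceil(c_max / v)) + 1 + 2 * margin
    nz = 2 * int(np.ceil(b_max / v)) + 1 + 2 * margin
    cy, cz = ny // 2, nz // 2
    yy, zz = np.meshgrid(
        (np.arange(ny) - cy) * v, (np.arange(nz) - cz) * v, indexing="ij"
    )
    # squared elliptical radius; ranking by it fills the ellipse from the
    # centre outwards, so keeping the first round(area/v^2) voxels yields
    # a convex, ellipse-shaped slice with the exact target voxel count
    radius2 = (yy / aspect_ratio) ** 2 + zz**2
    order = np.argsort(radius2, axis=None, kind="stable")
    data = np.zeros((areas.size, ny, nz), dtype=bool)
    for i, area in enumerate(areas):
        if area <= 0:
            continue
        n_vox = max(1, int(round(area / v**2)))
        sl = np.zeros(ny * nz, dtype=bool)
        sl[order[:n_vox]] = True
        data[i] = sl.reshape(ny, nz)
    return VoxelMask(
        data=data,
        voxel_size=v,
        axis_labels=("sagittal", "coronal", "transversal"),
        subject_id=profile.subject_id,
    )
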
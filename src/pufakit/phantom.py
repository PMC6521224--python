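"""Synthetic FLAIR phantoms with known tissue labels and planted lesions.

The phantom is a nested-box "brain": a background shell, a peripheral CSF
shell, a GM rim, a WM interior, and a central ventricle slab (CSF-valued
voxels carrying their own label so periventricular adjacency is well
defined).  WM voxels are drawn i.i.d. normal(wm_mean, wm_sd); GM, CSF and
ventricle voxels sit at fixed offsets from the WM mean; lesion voxels are
*set* (not added) to ``wm_mean + z * wm_sd``, giving exact, analyzable
contrast against the WM reference statistics.

This deliberately omits realistic anatomy: no cortical folding, bias
fields, or partial-volume effects.  What it does provide is a ground-truth
lesion mask, so recovery of planted lesions (Dice overlap, volume error)
can be measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import (
    BACKGROUND,
    CSF,
    GM,
    VENTRICLE,
    WM,
    TissueLabelVolume,
    VoxelGrid,
    save_grid,
    save_labels,
    volume_cm3,
)

DEEP = "deep"
PERIVENTRICULAR = "periventricular"


class LesionPlacementError(ValueError):
    """A planted lesion violates the phantom geometry (outside the grid,
    outside WM+GM, or inconsistent with its intended class)."""


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal lesion: center voxel, semi-axes in voxels, contrast as
    a z offset above the WM mean in units of the WM SD, and intended class."""

    center: tuple[int, int, int]
    semi_axes: tuple[float, float, float]
    z: float = 4.0
    intended_class: str = DEEP

    def __post_init__(self) -> None:
        if any(a < 1 for a in self.semi_axes):
            raise ValueError(f"lesion semi-axes must be >= 1 voxel, got {self.semi_axes}")
        if self.intended_class not in (DEEP, PERIVENTRICULAR):
            raise ValueError(f"intended_class must be '{DEEP}' or '{PERIVENTRICULAR}'")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    wm_mean: float = 100.0
    wm_sd: float = 10.0
    gm_offset: float = 10.0   # GM mildly hyperintense to WM on FLAIR
    csf_offset: float = -60.0  # CSF attenuated (dark) on FLAIR
    lesions: tuple = ()
    noise_seed: int = 0
    shell: int = 2             # thickness of background/CSF/GM shells, voxels
    ventricle_half_thickness: int = 2
    ventricle_margin: int = 8  # in-plane inset of the slab from the WM border

    def __post_init__(self) -> None:
        if self.wm_sd <= 0:
            raise ValueError(f"wm_sd must be > 0, got {self.wm_sd}")
        if any(s < 8 * self.shell for s in self.grid_shape):
            raise ValueError("grid too small for the shell geometry")
        object.__setattr__(self, "lesions", tuple(self.lesions))


@dataclass(frozen=True)
class LesionTruth:
    """Ground truth for planted lesions: per-lesion voxel masks with intended
    class labels, the combined mask, and exact volumes in cm^3."""

    lesion_masks: tuple          # boolean arrays, one per lesion
    intended_classes: tuple      # "deep" | "periventricular", one per lesion
    mask: np.ndarray             # union of lesion masks
    voxel_dims: tuple[float, float, float]

    @property
    def total_cm3(self) -> float:
        return volume_cm3(int(self.mask.sum()), self.voxel_dims)

    def class_cm3(self, cls: str) -> float:
        count = sum(
            int(m.sum()) for m, c in zip(self.lesion_masks, self.intended_classes) if c == cls
        )
        return volume_cm3(count, self.voxel_dims)

    def manifest(self) -> dict:
        return {
            "n_lesions": len(self.lesion_masks),
            "voxel_dims_mm": list(self.voxel_dims),
            "total_cm3": self.total_cm3,
            "lesions": [
                {"intended_class": c, "voxels": int(m.sum()),
                 "volume_cm3": volume_cm3(int(m.sum()), self.voxel_dims)}
                for m, c in zip(self.lesion_masks, self.intended_classes)
            ],
        }


def build_tissue_labels(spec: PhantomSpec) -> TissueLabelVolume:
    """Nested-box geometry: background / CSF / GM shells, WM interior,
    central ventricle slab along axis 0."""
    shape = spec.grid_shape
    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    s = spec.shell
    idx = np.indices(shape)
    # distance (in voxels) to the nearest volume face, per voxel
    depth = np.minimum.reduce(
        [np.minimum(idx[a], shape[a] - 1 - idx[a]) for a in range(3)]
    )
    labels[depth >= s] = CSF
    labels[depth >= 2 * s] = GM
    labels[depth >= 3 * s] = WM

    c0 = shape[0] // 2
    ht = spec.ventricle_half_thickness
    wm_lo = 3 * s
    m = spec.ventricle_margin
    slab = (
        (np.abs(idx[0] - c0) <= ht)
        & (idx[1] >= wm_lo + m) & (idx[1] <= shape[1] - 1 - wm_lo - m)
        & (idx[2] >= wm_lo + m) & (idx[2] <= shape[2] - 1 - wm_lo - m)
        & (labels == WM)
    )
    labels[slab] = VENTRICLE
    return TissueLabelVolume(labels)


def _ellipsoid_mask(shape, lesion: LesionSpec) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    c = lesion.center
    a = lesion.semi_axes
    if any(ci < 0 or ci >= si for ci, si in zip(c, shape)):
        raise LesionPlacementError(f"lesion center {c} outside grid {shape}")
    r2 = sum(((idx[k] - c[k]) / a[k]) ** 2 for k in range(3))
    mask = r2 <= 1.0
    # clip check: ellipsoid must not poke outside the grid
    for k in range(3):
        if c[k] - a[k] < 0 or c[k] + a[k] > shape[k] - 1:
            raise LesionPlacementError(f"lesion at {c} with semi-axes {a} exceeds the grid")
    return mask


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, TissueLabelVolume, LesionTruth]:
    """Build a FLAIR-like phantom; fully reproducible from ``noise_seed``."""
    tissue = build_tissue_labels(spec)
    labels = tissue.labels
    shape = spec.grid_shape
    rng = np.random.default_rng(spec.noise_seed)

    data = np.zeros(shape, dtype=np.float64)
    wm = labels == WM
    data[wm] = rng.normal(spec.wm_mean, spec.wm_sd, size=int(wm.sum()))
    data[labels == GM] = spec.wm_mean + spec.gm_offset
    data[(labels == CSF) | (labels == VENTRICLE)] = spec.wm_mean + spec.csf_offset

    vent_halo = ndimage.binary_dilation(
        labels == VENTRICLE, structure=ndimage.generate_binary_structure(3, 3)
    )
    lesion_masks, classes = [], []
    for lesion in spec.lesions:
        m = _ellipsoid_mask(shape, lesion)
        inside = (labels == WM) | (labels == GM)
        if not np.all(inside[m]):
            raise LesionPlacementError(
                f"lesion at {lesion.center} extends outside the WM+GM region"
            )
        touches = bool((m & vent_halo).any())
        if lesion.intended_class == PERIVENTRICULAR and not touches:
            raise LesionPlacementError(
                f"lesion at {lesion.center} intended periventricular but does not "
                "touch the ventricle slab"
            )
        if lesion.intended_class == DEEP and touches:
            raise LesionPlacementError(
                f"lesion at {lesion.center} intended deep but touches the ventricle slab"
            )
        data[m] = spec.wm_mean + lesion.z * spec.wm_sd
        lesion_masks.append(m)
        classes.append(lesion.intended_class)

    union = np.zeros(shape, dtype=bool)
    for m in lesion_masks:
        union |= m
    truth = LesionTruth(tuple(lesion_masks), tuple(classes), union, spec.voxel_dims)
    grid = VoxelGrid(data, spec.voxel_dims)
    return grid, tissue, truth


def save_phantom(
    grid: VoxelGrid, tissue: TissueLabelVolume, truth: LesionTruth, outdir: str
) -> dict:
    """Write FLAIR (float32 NIfTI), labels (uint8 NIfTI), truth mask and a
    JSON manifest; returns the file map."""
    import os

    paths = {
        "flair": os.path.join(outdir, "flair.nii"),
        "labels": os.path.join(outdir, "labels.nii"),
        "truth_mask": os.path.join(outdir, "lesion_truth.nii"),
        "manifest": os.path.join(outdir, "lesion_truth.json"),
    }
    save_grid(grid, paths["flair"])
    save_labels(tissue, paths["labels"], affine=grid.affine)
    import nibabel as nib

    nib.save(nib.Nifti1Image(truth.mask.astype(np.uint8), grid.affine), paths["truth_mask"])
    with open(paths["manifest"], "w") as fh:
        json.dump(truth.manifest(), fh, indent=2)
    return paths
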
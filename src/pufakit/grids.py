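"""Core voxel containers and unit conversions.

A FLAIR acquisition is represented as a :class:`VoxelGrid` (3-D scalar
intensity field with physical voxel dimensions) paired with a
:class:`TissueLabelVolume` of the same shape carrying the upstream tissue
segmentation.  Both are assumed already co-registered; registration is out
of scope for this package.

Label codebook (uint8):

====  ===========
code  tissue
====  ===========
0     background
1     white matter
2     grey matter
3     CSF (peripheral)
4     ventricle
====  ===========

Ventricular CSF carries its own code so that periventricular adjacency is
well defined and distinct from sulcal/peripheral CSF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

BACKGROUND = 0
WM = 1
GM = 2
CSF = 3
VENTRICLE = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    WM: "white_matter",
    GM: "grey_matter",
    CSF: "csf",
    VENTRICLE: "ventricle",
}


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate for the operation (e.g. a
    constant-intensity white-matter mask, for which z-score thresholds are
    undefined)."""


def _default_affine(voxel_dims: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims
    return aff


@dataclass(frozen=True)
class VoxelGrid:
    """3-D scalar intensity field with physical voxel dimensions in mm."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("intensity volume contains non-finite values")
        dims = tuple(float(d) for d in self.voxel_dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"voxel_dims must be 3 positive lengths, got {self.voxel_dims}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_dims", dims)
        aff = self.affine if self.affine is not None else _default_affine(dims)
        object.__setattr__(self, "affine", np.asarray(aff, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclass(frozen=True)
class TissueLabelVolume:
    """Integer tissue-label field paired with a :class:`VoxelGrid`."""

    labels: np.ndarray
    codebook: dict = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected a 3-D label volume, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        unknown = set(np.unique(labels)) - set(self.codebook)
        if unknown:
            raise ValueError(f"labels outside the codebook: {sorted(unknown)}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


def check_paired(flair: VoxelGrid, tissue: TissueLabelVolume) -> None:
    if flair.shape != tissue.shape:
        raise ValueError(
            f"intensity volume {flair.shape} and label volume {tissue.shape} differ in shape"
        )


def volume_cm3(voxel_count: int, voxel_dims: tuple[float, float, float]) -> float:
    """Convert a voxel count to a volume in cm^3 (count x voxel volume / 1000)."""
    if voxel_count < 0:
        raise ValueError(f"voxel_count must be >= 0, got {voxel_count}")
    dims = tuple(float(d) for d in voxel_dims)
    if len(dims) != 3 or any(d <= 0 for d in dims):
        raise ValueError(f"voxel_dims must be 3 positive lengths, got {voxel_dims}")
    return voxel_count * dims[0] * dims[1] * dims[2] / 1000.0


# --- NIfTI I/O -------------------------------------------------------------

def save_grid(grid: VoxelGrid, path: str) -> None:
    img = nib.Nifti1Image(grid.data.astype(np.float32), grid.affine)
    img.header.set_zooms(grid.voxel_dims)
    nib.save(img, path)


def save_labels(tissue: TissueLabelVolume, path: str, affine: np.ndarray | None = None) -> None:
    aff = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(tissue.labels.astype(np.uint8), aff), path)


def load_grid(path: str) -> VoxelGrid:
    img = nib.load(path)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(np.asarray(img.dataobj, dtype=np.float64), zooms, img.affine)


def load_labels(path: str) -> TissueLabelVolume:
    img = nib.load(path)
    return TissueLabelVolume(np.asarray(img.dataobj).astype(np.int64))
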
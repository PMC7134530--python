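"""Volume I/O, normalization, resampling and orthogonal-view decomposition.

All grids are indexed ``(z, y, x)``: axial slices are planes of constant ``z``
(the acquisition direction of a transverse 3D LGE-CMR scan), sagittal slices
planes of constant ``x`` and coronal slices planes of constant ``y``.
Spacing is stored per axis in millimetres, in the same ``(z, y, x)`` order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Finite real intensities.
    spacing : tuple of float
        Voxel edge lengths in mm, ``(dz, dy, dx)``; strictly positive.
    origin : tuple of float
        Position of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.voxels.ndim}D")
        if min(self.voxels.shape) < 1:
            raise ValueError("all grid dimensions must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive lengths")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def is_cubic(self) -> bool:
        nz, ny, nx = self.shape
        return nz == ny == nx


@dataclass
class LabelVolume:
    """A binary label grid aligned voxel-for-voxel with a :class:`Volume`.

    Values are 0 (background) and 1 (foreground — anatomy or scar,
    depending on which channel the mask represents).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("label values must be in {0, 1}")
        self.labels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


@dataclass
class ViewDecomposition:
    """Ordered 2D slice stacks of a cubic volume along the three orthogonal axes.

    ``axial[k] = v[k, :, :]`` (a (y, x) plane), ``sagittal[k] = v[:, :, k]``
    (a (z, y) plane), ``coronal[k] = v[:, k, :]`` (a (z, x) plane).
    """

    axial: np.ndarray      # (nz, ny, nx)
    sagittal: np.ndarray   # (nx, nz, ny)
    coronal: np.ndarray    # (ny, nz, nx)
    source_shape: tuple[int, int, int] = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D NIfTI (.nii/.nii.gz) or NRRD (.nrrd) image.

    Spacing is taken from the file header; the array is re-ordered so that
    axis 0 is the slice (z) direction. Raises on non-3D images rather than
    guessing an orientation.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
        zooms = img.header.get_zooms()[:3]
        # nibabel arrays are (x, y, z); flip to (z, y, x)
        voxels = np.transpose(np.asarray(data, dtype=np.float64), (2, 1, 0))
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
        return Volume(voxels, spacing, origin)
    if lower.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        if img.GetDimension() != 3:
            raise ValueError(f"expected a 3D image, got {img.GetDimension()}D: {path}")
        voxels = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
        spacing = tuple(reversed(img.GetSpacing()))
        origin = tuple(reversed(img.GetOrigin()))
        return Volume(voxels, spacing, origin)
    raise IOError(f"unrecognized image format (expected .nii/.nii.gz/.nrrd): {path}")


def save_volume(volume: Volume, path: str | os.PathLike, dtype=None) -> None:
    """Write a volume as NIfTI-1 or NRRD, preserving spacing metadata."""
    path = os.fspath(path)
    lower = path.lower()
    data = volume.voxels if dtype is None else volume.voxels.astype(dtype)
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        # stored (x, y, z) with spacing on the diagonal affine
        arr = np.transpose(data, (2, 1, 0))
        sx, sy, sz = volume.spacing[2], volume.spacing[1], volume.spacing[0]
        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = list(volume.origin[::-1])
        nib.save(nib.Nifti1Image(arr, affine), path)
        return
    if lower.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        img.SetSpacing(tuple(reversed(volume.spacing)))
        img.SetOrigin(tuple(reversed(volume.origin)))
        sitk.WriteImage(img, path)
        return
    raise IOError(f"unrecognized output format: {path}")


def load_mask(path: str | os.PathLike) -> LabelVolume:
    """Read a binary mask stored as an unsigned-integer NIfTI/NRRD image."""
    vol = load_volume(path)
    return LabelVolume((vol.voxels > 0.5).astype(np.uint8), vol.spacing)


def save_mask(mask: LabelVolume, path: str | os.PathLike) -> None:
    save_volume(Volume(mask.labels.astype(np.float64), mask.spacing), path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Normalization and resampling
# ---------------------------------------------------------------------------

def normalize_slicewise(volume: Volume) -> Volume:
    """Mean-range normalization applied independently to each axial slice.

    Each slice is mapped ``I' = (I - mean(I)) / (max(I) - min(I))``, so the
    output slice mean is 0 and the output range is contained in [-1, 1].
    A constant slice (max = min) maps to zeros: its numerator is identically
    zero, and zeros are the unique continuous completion of the formula.
    """
    out = np.empty_like(volume.voxels)
    for k in range(volume.shape[0]):
        sl = volume.voxels[k]
        rng = sl.max() - sl.min()
        if rng == 0:
            out[k] = 0.0
        else:
            out[k] = (sl - sl.mean()) / rng
    return Volume(out, volume.spacing, volume.origin)


def resample_to_cube(volume: Volume, edge: int) -> Volume:
    """Trilinearly resample a volume onto an ``edge**3`` grid.

    Sampling uses corner-aligned index coordinates, so resampling a grid onto
    its own shape is the identity and a constant volume stays constant.
    Spacing is rescaled so the physical extent is preserved.
    """
    edge = int(edge)
    if edge < 8:
        raise ValueError(f"cube edge must be >= 8, got {edge}")
    src = volume.voxels
    if src.shape == (edge, edge, edge):
        return Volume(src.copy(), volume.spacing, volume.origin)
    coords = np.meshgrid(
        *[
            np.linspace(0.0, n - 1, edge) if n > 1 else np.zeros(edge)
            for n in src.shape
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(src, np.stack(coords), order=1, mode="nearest")
    new_spacing = tuple(
        s * (n - 1) / (edge - 1) if n > 1 else s
        for s, n in zip(volume.spacing, src.shape)
    )
    return Volume(out.reshape(edge, edge, edge), new_spacing, volume.origin)


# ---------------------------------------------------------------------------
# View decomposition and the transposition operator
# ---------------------------------------------------------------------------

def decompose_views(volume: Volume | np.ndarray) -> ViewDecomposition:
    """Slice a cubic volume into ordered axial, sagittal and coronal 2D stacks.

    Pure re-indexing — no interpolation. Requires a cubic grid so that the
    sagittal/coronal stacks can later be transposed back into axial order
    for feature fusion.
    """
    v = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
    nz, ny, nx = v.shape
    if not (nz == ny == nx):
        raise ValueError(f"decompose_views requires a cubic volume, got {v.shape}")
    return ViewDecomposition(
        axial=v.copy(),
        sagittal=np.transpose(v, (2, 0, 1)).copy(),   # stack[k] = v[:, :, k]
        coronal=np.transpose(v, (1, 0, 2)).copy(),    # stack[k] = v[:, k, :]
        source_shape=v.shape,
    )


def recompose_views(decomp: ViewDecomposition) -> np.ndarray:
    """Reassemble the source grid from the axial stack (exact inverse)."""
    return decomp.axial.copy()


# Axis permutations mapping a per-view slice stack back to axial ordering.
# A sagittal stack is indexed (x, z, y); a coronal stack (y, z, x). Both
# permute to the axial ordering (z, y, x).
_VIEW_TO_AXIAL_3D = {"sagittal": (1, 2, 0), "coronal": (1, 0, 2)}
# Same permutations with a channel axis at position 1: stacks (n, C, h, w).
_VIEW_TO_AXIAL_4D = {"sagittal": (2, 1, 3, 0), "coronal": (2, 1, 0, 3)}


def transpose_to_axial(stack: np.ndarray, view: str) -> np.ndarray:
    """Transposition operator T: re-order a sagittal/coronal stack to axial.

    Accepts a 3D stack ``(n_slices, h, w)`` or a 4D feature stack
    ``(n_slices, channels, h, w)`` built over a cubic grid. The operation is
    an axis permutation only, hence voxel-exact and self-inverse with the
    matching permutation.
    """
    stack = np.asarray(stack)
    if view not in ("sagittal", "coronal"):
        raise ValueError(f"view must be 'sagittal' or 'coronal', got {view!r}")
    if stack.ndim == 3:
        n, h, w = stack.shape
        if not (n == h == w):
            raise ValueError(f"stack must be built over a cubic grid, got {stack.shape}")
        return np.transpose(stack, _VIEW_TO_AXIAL_3D[view]).copy()
    if stack.ndim == 4:
        n, _, h, w = stack.shape
        if not (n == h == w):
            raise ValueError(f"stack must be built over a cubic grid, got {stack.shape}")
        return np.transpose(stack, _VIEW_TO_AXIAL_4D[view]).copy()
    raise ValueError(f"expected a 3D or 4D stack, got {stack.ndim}D")
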
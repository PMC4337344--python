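"""Volume containers, NIfTI I/O, Gaussian smoothing and gray-matter masking.

The pipeline operates on spatially normalized images: a 4D BOLD series
(typically 3 mm isotropic after normalization), a gray-matter probability
map derived from a T1-weighted segmentation, and assorted derived 3D maps
(eigenvector centrality, t statistics, ...).  Everything downstream works
on the flat vector of in-mask voxels, so the mask carries a fixed linear
ordering that makes every matrix row traceable to a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "Volume4D",
    "GrayMatterMask",
    "read_volume",
    "write_volume",
    "gaussian_smooth",
    "make_gm_mask",
    "extract_timeseries",
    "scatter_to_volume",
]

# FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _voxel_size_from_affine(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths in mm: Euclidean norms of the affine's spatial columns."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass
class Volume3D:
    """A 3D scalar grid with a voxel-to-world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D data must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return _voxel_size_from_affine(self.affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) 0-based voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ homog.T).T[:, :3]


@dataclass
class Volume4D:
    """A BOLD-like 4D series: 3 spatial axes plus time, sampled every tr_seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("Volume4D needs at least 2 time points")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return _voxel_size_from_affine(self.affine)

    def frame(self, t: int) -> Volume3D:
        return Volume3D(self.data[..., t], self.affine)


@dataclass
class GrayMatterMask:
    """Boolean voxel set with a fixed linear ordering of the included voxels.

    ``ordering`` holds the flat indices of included voxels in ascending
    order, with the first spatial axis varying fastest (Fortran order);
    row *i* of any extracted matrix corresponds to voxel
    ``np.unravel_index(ordering[i], shape, order="F")``.
    """

    include: np.ndarray
    affine: np.ndarray
    ordering: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.include.ndim != 3:
            raise ValueError("mask must be 3D")
        self.ordering = np.flatnonzero(self.include.ravel(order="F"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.include.shape

    @property
    def n_voxels(self) -> int:
        return int(self.ordering.size)

    def voxel_indices(self) -> np.ndarray:
        """(n_voxels, 3) array of 0-based (i, j, k) indices in mask order."""
        return np.column_stack(np.unravel_index(self.ordering, self.shape, order="F"))

    def world_coordinates(self) -> np.ndarray:
        """(n_voxels, 3) world mm coordinates of the voxel centers, in mask order."""
        ijk = self.voxel_indices()
        homog = np.c_[ijk, np.ones(self.n_voxels)]
        return (self.affine @ homog.T).T[:, :3]

    def to_volume(self) -> Volume3D:
        return Volume3D(self.include.astype(np.float64), self.affine)


def read_volume(path) -> Volume3D | Volume4D:
    """Read a NIfTI-1 file into a Volume3D or Volume4D depending on its header.

    Raises
    ------
    FileNotFoundError, nibabel.ImageFileError, ValueError
        For a missing path, non-NIfTI content, or dimensionality other
        than 3 or 4.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    affine = np.asarray(img.affine, dtype=np.float64)
    if data.ndim == 3:
        return Volume3D(data, affine)
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        return Volume4D(data, affine, tr_seconds=tr)
    raise ValueError(f"unsupported image dimensionality {data.ndim} for {path}")


def write_volume(vol: Volume3D | Volume4D, path, dtype=np.float64) -> None:
    """Write a volume as NIfTI-1; sets the TR pixdim for 4D series."""
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    if isinstance(vol, Volume4D):
        zooms = list(img.header.get_zooms())
        zooms[3] = vol.tr_seconds
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def gaussian_smooth(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Separable Gaussian smoothing with an isotropic FWHM given in mm.

    The per-axis sigma in voxel units is ``fwhm / (voxel_size_axis *
    2*sqrt(2*ln 2))`` so anisotropic voxels are handled correctly.  The
    kernel is truncated at 4 sigma and the volume is zero-padded at the
    boundary (background outside the field of view is treated as zero,
    as common neuroimaging smoothers do).  ``fwhm_mm == 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return Volume3D(vol.data.copy(), vol.affine)
    sigmas = fwhm_mm / (_FWHM_PER_SIGMA * vol.voxel_size)
    smoothed = ndimage.gaussian_filter(
        vol.data, sigma=sigmas, mode="constant", cval=0.0, truncate=4.0
    )
    return Volume3D(smoothed, vol.affine)


def smooth_series(vol4d: Volume4D, fwhm_mm: float) -> Volume4D:
    """Smooth a 4D series frame-by-frame with :func:`gaussian_smooth`."""
    if fwhm_mm == 0:
        return Volume4D(vol4d.data.copy(), vol4d.affine, vol4d.tr_seconds)
    out = np.empty_like(vol4d.data)
    for t in range(vol4d.n_frames):
        out[..., t] = gaussian_smooth(vol4d.frame(t), fwhm_mm).data
    return Volume4D(out, vol4d.affine, vol4d.tr_seconds)


def make_gm_mask(
    gm_prob: Volume3D, smooth_fwhm_mm: float = 4.0, threshold: float = 0.12
) -> GrayMatterMask:
    """Build the analysis mask from a gray-matter probability map.

    The probability map is smoothed (default 4 mm FWHM) and voxels whose
    smoothed probability reaches ``threshold`` (default 0.12) are
    included.  An empty mask is an error, not a silent result.
    """
    if np.any(gm_prob.data < 0) or np.any(gm_prob.data > 1):
        raise ValueError("gray-matter probabilities must lie in [0, 1]")
    smoothed = gaussian_smooth(gm_prob, smooth_fwhm_mm)
    include = smoothed.data >= threshold
    if not include.any():
        raise ValueError(
            f"gray-matter mask is empty at threshold {threshold} "
            f"after {smooth_fwhm_mm} mm smoothing"
        )
    return GrayMatterMask(include, gm_prob.affine)


def extract_timeseries(vol4d: Volume4D, mask: GrayMatterMask) -> np.ndarray:
    """Extract the (n_voxels, n_frames) matrix of in-mask time courses.

    Row order follows ``mask.ordering``.
    """
    if vol4d.spatial_shape != mask.shape:
        raise ValueError(
            f"spatial shape {vol4d.spatial_shape} does not match mask {mask.shape}"
        )
    flat = vol4d.data.reshape(-1, vol4d.n_frames, order="F")
    return flat[mask.ordering]


def scatter_to_volume(values: np.ndarray, mask: GrayMatterMask, fill: float = 0.0) -> Volume3D:
    """Scatter a per-in-mask-voxel vector back into a 3D volume (background = fill)."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mask.n_voxels,):
        raise ValueError(f"expected {mask.n_voxels} values, got {values.shape}")
    flat = np.full(int(np.prod(mask.shape)), fill, dtype=np.float64)
    flat[mask.ordering] = values
    return Volume3D(flat.reshape(mask.shape, order="F"), mask.affine)
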
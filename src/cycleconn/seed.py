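"""Seed-based functional connectivity and its hormone-covariate second level.

A seed is a small sphere of in-mask voxels (default 6 mm radius) placed at
a world-mm coordinate — typically a peak from the whole-brain EC analysis.
For each scan, the seed's mean time course is correlated with every
in-mask voxel and the correlation map is Fisher-z transformed
(z = atanh(r), variance-stabilizing).  The per-scan maps then enter the
same voxel-wise GLM as the EC maps, with a hormone covariate of interest
(progesterone in the motivating study) and a positive one-sided contrast,
thresholded uncorrected at p < 0.005 or p < 0.001 with an extent
threshold of k > 20 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import center_and_normalize_rows
from .glm import VoxelGLM, form_clusters
from .hormones import HormonePanel
from .volumes import GrayMatterMask, Volume4D, extract_timeseries

__all__ = [
    "SeedSpec",
    "make_sphere_seed",
    "seed_timecourse",
    "connectivity_map",
    "seed_second_level",
]

_R_CLAMP = 1.0 - 1e-7


@dataclass
class SeedSpec:
    """A spherical seed: world-mm center, radius, and its in-mask voxel rows."""

    label: str
    center_mm: np.ndarray
    radius_mm: float
    voxel_rows: np.ndarray  # indices into the mask's voxel ordering

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_rows.size)


def make_sphere_seed(
    center_mm,
    radius_mm: float,
    mask: GrayMatterMask,
    label: str = "seed",
) -> SeedSpec:
    """All in-mask voxels whose centers lie within radius_mm of center_mm.

    Distances are Euclidean in world space (via the mask affine), so the
    sphere is a true sphere regardless of voxel anisotropy.  An empty
    voxel set (center outside the mask, radius too small) is an error.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    center = np.asarray(center_mm, dtype=float).reshape(3)
    world = mask.world_coordinates()
    dist = np.linalg.norm(world - center, axis=1)
    rows = np.flatnonzero(dist <= radius_mm + 1e-9)
    if rows.size == 0:
        raise ValueError(
            f"seed '{label}' at {center.tolist()} mm (r={radius_mm} mm) "
            "contains no in-mask voxel"
        )
    return SeedSpec(label=label, center_mm=center, radius_mm=radius_mm, voxel_rows=rows)


def seed_timecourse(vol4d: Volume4D, seed: SeedSpec, mask: GrayMatterMask) -> np.ndarray:
    """Unweighted mean time course over the seed's voxels (length T)."""
    ts = extract_timeseries(vol4d, mask)
    return ts[seed.voxel_rows].mean(axis=0)


def connectivity_map(
    vol4d: Volume4D,
    seed: SeedSpec,
    mask: GrayMatterMask,
    fisher: bool = True,
) -> np.ndarray:
    """Per-in-mask-voxel correlation with the seed time course, for one scan.

    Returns Fisher z = atanh(r) by default (raw r with ``fisher=False``),
    with |r| clamped to 1 - 1e-7 so the transform stays finite at seed
    voxels that correlate perfectly with their own mean.  Seed voxels are
    retained in the map; their rows are available via ``seed.voxel_rows``.
    """
    ts = extract_timeseries(vol4d, mask)
    sc = seed_timecourse(vol4d, seed, mask)
    sc = sc - sc.mean()
    norm = np.linalg.norm(sc)
    if norm == 0:
        raise ValueError(f"seed '{seed.label}' time course is constant")
    z_rows = center_and_normalize_rows(ts)
    r = z_rows @ (sc / norm)
    r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    return np.arctanh(r) if fisher else r


def seed_second_level(
    maps: np.ndarray,
    panel: HormonePanel,
    covariate: str,
    mask: GrayMatterMask,
    voxel_p: float = 0.005,
    extent: int = 20,
    connectivity: int = 18,
    direction: float = 1.0,
) -> pd.DataFrame:
    """GLM over per-scan connectivity maps with one hormone covariate.

    ``maps`` is (n_scans, n_voxels) in panel order.  Delegates to the
    voxel-wise GLM (session indicators + covariate), tests the signed
    one-sided contrast on the covariate and forms clusters at the given
    uncorrected voxel threshold and extent threshold.
    """
    model = VoxelGLM.from_panel(maps, panel, interest=[covariate], mask=mask)
    results = model.fit()
    stat = results.t_contrast(model.design.contrast_vector(covariate, sign=direction))
    return form_clusters(
        stat,
        voxel_p_threshold=voxel_p,
        extent_threshold=extent,
        connectivity=connectivity,
    )
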
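"""Second-level voxel-wise general linear model with hormone covariates.

The 32 per-scan EC (or seed-connectivity) maps form a scan-by-voxel matrix
Y.  A design matrix X codes the two scanning periods as 0/1 indicator
columns (no global intercept) plus mean-centered hormone covariates of
interest (e.g. progesterone) and nuisance covariates (e.g. cortisol).
Per voxel, ordinary least squares gives

    beta_v = (X'X)^-1 X' y_v,   sigma2_v = RSS_v / (n - rank(X))

and a contrast c yields the t statistic

    t_v = c' beta_v / sqrt(sigma2_v * c' (X'X)^-1 c)

with a one-sided p value from the t distribution (two-sided by flag) and
the equivalent standard-normal Z.  Family-wise error correction is
Bonferroni or Sidak over a resel count supplied by the user (the effective
number of independent spatial units after smoothing); supra-threshold
voxels are grouped into connected clusters and reported peak-first.

The model/results split follows the convention of statistical modelling
packages: :class:`VoxelGLM` is built from data and ``fit()`` returns a
:class:`VoxelGLMResults` that carries estimates, contrasts and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .hormones import HormonePanel
from .volumes import GrayMatterMask, scatter_to_volume

__all__ = [
    "DesignMatrix",
    "build_design",
    "VoxelGLM",
    "VoxelGLMResults",
    "StatMap",
    "fwe_adjust",
    "naive_resel_count",
    "form_clusters",
    "CLUSTER_TABLE_COLUMNS",
]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Named design matrix: session indicators + covariates, full column rank."""

    matrix: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    @property
    def df_residual(self) -> int:
        return self.n_scans - self.rank

    def contrast_vector(self, column: str, sign: float = 1.0) -> np.ndarray:
        """Unit contrast on one named column, signed."""
        if column not in self.columns:
            raise KeyError(f"no design column '{column}'")
        c = np.zeros(len(self.columns))
        c[self.columns.index(column)] = sign
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)


def build_design(
    panel: HormonePanel,
    interest: list[str],
    nuisance: list[str] = (),
    center: bool = True,
    interaction: bool = False,
) -> DesignMatrix:
    """Build the factorial design: per-session indicators plus covariates.

    One 0/1 indicator column per scanning session replaces the global
    intercept.  Covariates (interest first, then nuisance) are taken from
    the panel by column name and mean-centered when ``center`` is set.
    ``interaction`` adds session x covariate-of-interest product columns
    (off by default; the additive design is the standard one here).

    Raises a rank-deficiency error naming the collinear columns.
    """
    df = panel.df
    sessions = panel.sessions
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for s in sessions:
        blocks.append((df["session_id"] == s).to_numpy(dtype=float))
        cols.append(f"session_{s}")
    for name in list(interest) + list(nuisance):
        vals = panel.column(name)
        if center:
            vals = vals - vals.mean()
        blocks.append(vals)
        cols.append(name)
    if interaction:
        for s in sessions[1:]:
            ind = (df["session_id"] == s).to_numpy(dtype=float)
            for name in interest:
                vals = panel.column(name)
                if center:
                    vals = vals - vals.mean()
                blocks.append(ind * vals)
                cols.append(f"session_{s}:{name}")
    x = np.column_stack(blocks)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns that do not increase rank when added in order
        collinear = []
        r = 0
        for j in range(x.shape[1]):
            rj = np.linalg.matrix_rank(x[:, : j + 1])
            if rj == r:
                collinear.append(cols[j])
            r = rj
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {collinear}")
    dm = DesignMatrix(x, cols)
    if dm.df_residual < 1:
        raise ValueError("no residual degrees of freedom")
    return dm


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------

_TINY_P = np.finfo(np.float64).tiny


@dataclass
class StatMap:
    """Per-voxel t, Z, uncorrected p and FWE-adjusted p for one contrast."""

    t: np.ndarray
    z: np.ndarray
    p: np.ndarray
    p_fwe: np.ndarray | None
    df: int
    contrast: np.ndarray
    two_sided: bool = False
    mask: GrayMatterMask | None = field(default=None, repr=False)

    @property
    def n_voxels(self) -> int:
        return int(self.t.size)


class VoxelGLM:
    """Mass-univariate OLS: one regression per voxel, shared design matrix.

    Parameters
    ----------
    maps : (n_scans, n_voxels) array
        One row per scan, in panel/design order.
    design : DesignMatrix
    mask : GrayMatterMask, optional
        Links voxel columns to spatial locations; required for cluster
        tables with world mm coordinates.
    """

    def __init__(self, maps: np.ndarray, design: DesignMatrix, mask: GrayMatterMask | None = None):
        maps = np.asarray(maps, dtype=np.float64)
        if maps.ndim != 2:
            raise ValueError("maps must be 2D (scans x voxels)")
        if maps.shape[0] != design.n_scans:
            raise ValueError(
                f"{maps.shape[0]} map rows but design has {design.n_scans} scans"
            )
        if design.df_residual < 1:
            raise ValueError("df_residual must be >= 1")
        if mask is not None and mask.n_voxels != maps.shape[1]:
            raise ValueError("mask voxel count does not match map columns")
        self.maps = maps
        self.design = design
        self.mask = mask

    @classmethod
    def from_panel(
        cls,
        maps: np.ndarray,
        panel: HormonePanel,
        interest: list[str],
        nuisance: list[str] = (),
        mask: GrayMatterMask | None = None,
        center: bool = True,
    ) -> "VoxelGLM":
        """Build design from a hormone panel and wrap the maps."""
        design = build_design(panel, interest=interest, nuisance=nuisance, center=center)
        return cls(maps, design, mask=mask)

    def fit(self) -> "VoxelGLMResults":
        x = self.design.matrix
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ self.maps  # (k, n_voxels)
        resid = self.maps - x @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        # an exact fit leaves only rounding residue; snap it to zero so the
        # degenerate-case contract (t = +/-inf) is reachable
        sst = np.einsum("ij,ij->j", self.maps, self.maps)
        rss[rss <= 1e-24 * sst] = 0.0
        sigma2 = rss / self.design.df_residual
        return VoxelGLMResults(self, beta, sigma2, xtx_inv)


class VoxelGLMResults:
    """OLS estimates per voxel plus contrast machinery and summaries."""

    def __init__(self, model: VoxelGLM, beta: np.ndarray, sigma2: np.ndarray, xtx_inv: np.ndarray):
        self.model = model
        self.params = beta
        self.sigma2 = sigma2
        self._xtx_inv = xtx_inv

    @property
    def design(self) -> DesignMatrix:
        return self.model.design

    @property
    def df_residual(self) -> int:
        return self.design.df_residual

    def t_contrast(self, c, two_sided: bool = False) -> StatMap:
        """t / Z / p maps for a contrast vector or named design column.

        One-sided by default: p is the upper-tail probability of t, so a
        negative effect is tested by negating the contrast.  Voxels with
        zero residual variance and a nonzero effect report t = +/-inf and
        the smallest representable positive p.
        """
        if isinstance(c, str):
            c = self.design.contrast_vector(c)
        c = np.asarray(c, dtype=np.float64)
        if c.shape != (len(self.design.columns),):
            raise ValueError("contrast length does not match design columns")
        if not np.any(c):
            raise ValueError("contrast must have at least one nonzero weight")
        var_c = float(c @ self._xtx_inv @ c)
        if var_c <= 0:
            raise ValueError("zero contrast variance")
        effect = c @ self.params
        se = np.sqrt(self.sigma2 * var_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / se
        # exact fits: zero residual variance
        zero_se = se == 0
        t[zero_se & (effect > 0)] = np.inf
        t[zero_se & (effect < 0)] = -np.inf
        t[zero_se & (effect == 0)] = 0.0
        df = self.df_residual
        if two_sided:
            p = 2.0 * stats.t.sf(np.abs(t), df)
        else:
            p = stats.t.sf(t, df)
        p = np.clip(p, _TINY_P, 1.0)
        z = stats.norm.isf(p) if not two_sided else stats.norm.isf(p / 2.0) * np.sign(t)
        z = np.where(np.isfinite(t), z, np.where(t > 0, np.inf, -np.inf))
        return StatMap(
            t=t, z=z, p=p, p_fwe=None, df=df, contrast=c,
            two_sided=two_sided, mask=self.model.mask,
        )

    def summary(self) -> str:
        """Human-readable fit summary (design, df, residual variance range)."""
        d = self.design
        lines = [
            "Voxel-wise GLM (ordinary least squares)",
            "=" * 46,
            f"scans:            {d.n_scans}",
            f"voxels:           {self.params.shape[1]}",
            f"design columns:   {', '.join(d.columns)}",
            f"rank:             {d.rank}",
            f"df residual:      {d.df_residual}",
            f"residual var:     min {self.sigma2.min():.4g}, "
            f"median {np.median(self.sigma2):.4g}, max {self.sigma2.max():.4g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Multiple-comparison correction
# ---------------------------------------------------------------------------

def fwe_adjust(p, n_comparisons: int, method: str = "bonferroni"):
    """Family-wise-error-adjusted p values over ``n_comparisons`` units.

    ``bonferroni``: min(1, n*p).  ``sidak``: 1 - (1-p)^n.  The comparison
    count is typically a resel (resolution element) count — the effective
    number of independent spatial units after smoothing — supplied by the
    user.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if method == "bonferroni":
        adj = np.minimum(1.0, n_comparisons * p)
    elif method == "sidak":
        adj = 1.0 - np.power(1.0 - p, n_comparisons)
    else:
        raise ValueError(f"unknown FWE method '{method}'")
    return adj if adj.ndim else float(adj)


def naive_resel_count(mask: GrayMatterMask, fwhm_mm: float) -> float:
    """Crude resel estimate: mask volume divided by FWHM^3.

    This is NOT a random-field smoothness estimate — it ignores the
    data's actual spatial autocorrelation and counts pure geometry.  Use
    a study-specific resel count where one is available.
    """
    voxel_vol = float(np.prod(_voxel_size(mask)))
    return mask.n_voxels * voxel_vol / fwhm_mm**3


def _voxel_size(mask: GrayMatterMask) -> np.ndarray:
    return np.linalg.norm(mask.affine[:3, :3], axis=0)


# ---------------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------------

CLUSTER_TABLE_COLUMNS = [
    "cluster_id",
    "k_E",
    "cluster_p_fwe",
    "peak_t",
    "peak_z",
    "peak_p_uncorr",
    "peak_p_fwe",
    "x_mm",
    "y_mm",
    "z_mm",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def form_clusters(
    stat: StatMap,
    voxel_p_threshold: float = 0.001,
    extent_threshold: int = 0,
    connectivity: int = 18,
    fwe_n: int | None = None,
    fwe_method: str = "bonferroni",
) -> pd.DataFrame:
    """Group supra-threshold voxels into connected clusters and report peaks.

    Voxels with uncorrected ``p < voxel_p_threshold`` are labeled into
    connected components under 6-, 18- or 26-connectivity; components
    smaller than ``extent_threshold`` voxels are dropped.  The returned
    table (one row per cluster, sorted by descending peak t) mirrors the
    conventional neuroimaging cluster report: extent k_E, peak t, peak Z,
    peak uncorrected p, peak FWE-adjusted p (when ``fwe_n`` is given) and
    the peak's world mm coordinates.  Cluster-level corrected p values
    require random-field theory and are left empty.

    No supra-threshold voxels is not an error: an empty table is returned.
    """
    if stat.mask is None:
        raise ValueError("StatMap carries no mask; cluster tables need voxel geometry")
    if not (0 < voxel_p_threshold <= 1):
        raise ValueError("voxel_p_threshold must lie in (0, 1]")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = stat.mask
    supra = stat.p < voxel_p_threshold
    supra_vol = scatter_to_volume(supra.astype(float), mask).data > 0
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_labels = ndimage.label(supra_vol, structure=structure)

    # map in-mask voxels to their cluster label
    flat_labels = labels.ravel(order="F")[mask.ordering]
    world = mask.world_coordinates()
    rows = []
    for lab in range(1, n_labels + 1):
        members = np.flatnonzero(flat_labels == lab)
        extent = int(members.size)
        if extent < extent_threshold:
            continue
        peak_local = members[np.argmax(stat.t[members])]
        peak_p = float(stat.p[peak_local])
        rows.append(
            {
                "k_E": extent,
                "cluster_p_fwe": np.nan,
                "peak_t": float(stat.t[peak_local]),
                "peak_z": float(stat.z[peak_local]),
                "peak_p_uncorr": peak_p,
                "peak_p_fwe": (
                    float(fwe_adjust(peak_p, fwe_n, fwe_method)) if fwe_n else np.nan
                ),
                "x_mm": float(world[peak_local, 0]),
                "y_mm": float(world[peak_local, 1]),
                "z_mm": float(world[peak_local, 2]),
                "_peak_index": int(peak_local),
                "_voxel_rows": members,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=CLUSTER_TABLE_COLUMNS + ["_peak_index", "_voxel_rows"])
    table = table.sort_values("peak_t", ascending=False).reset_index(drop=True)
    table.insert(0, "cluster_id", np.arange(1, len(table) + 1))
    return table[CLUSTER_TABLE_COLUMNS + ["_peak_index", "_voxel_rows"]]


def write_cluster_table(table: pd.DataFrame, path) -> None:
    """Write a cluster table as TSV (drops the internal peak-index column)."""
    out = table.drop(columns=[c for c in table.columns if c.startswith("_")])
    out.to_csv(path, sep="\t", index=False)
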
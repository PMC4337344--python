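"""Simulation-based validation experiments for the whole pipeline.

Each function runs one self-contained experiment against an independent
oracle or a known ground truth and returns plain numbers, so the same
machinery drives both the test suite and reproducibility scripts:

* exact-math checks (fast EC vs dense eigendecomposition, FWE arithmetic,
  connected components vs flood fill);
* calibration checks (voxel-wise false-positive rate of the GLM under a
  simulated null);
* end-to-end parameter recovery (does the pipeline find the
  progesterone-coupled ROI pair, and only that?) and null control (does a
  study with no hormone coupling stay silent after FWE correction?);
* the hormone-curve contract (cycle dynamics of the generated panels).
"""

from __future__ import annotations

import numpy as np

from .centrality import ec_dense, ec_fast
from .glm import VoxelGLM, build_design, form_clusters, fwe_adjust
from .hormones import HormonePanel, label_phase
from .pipeline import RunConfig, StudyData, run_ecm_study
from .simulate import CycleParams, GroundTruth, StudyDesign, simulate_study
from .volumes import GrayMatterMask

__all__ = [
    "ec_oracle_deviation",
    "glm_null_fpr",
    "fwe_grid_max_error",
    "cluster_oracle_mismatches",
    "recovery_experiment",
    "null_control_experiment",
    "hormone_contract_sweep",
]


def ec_oracle_deviation(seed: int, n_instances: int = 50) -> float:
    """Max abs difference between ec_fast and ec_dense over random instances.

    Instances cycle through N in {10, 50, 200} and T in {10, 100}.
    """
    rng = np.random.default_rng(seed)
    sizes = [(n, t) for n in (10, 50, 200) for t in (10, 100)]
    worst = 0.0
    for i in range(n_instances):
        n, t = sizes[i % len(sizes)]
        ts = rng.standard_normal((n, t))
        dev = float(np.max(np.abs(ec_fast(ts).values - ec_dense(ts).values)))
        worst = max(worst, dev)
    return worst


def _null_panel(rng: np.random.Generator, n: int = 32) -> HormonePanel:
    import pandas as pd

    return HormonePanel(
        pd.DataFrame(
            {
                "scan_id": np.arange(1, n + 1),
                "session_id": np.repeat([1, 2], n // 2),
                "cycle_day": np.tile(np.arange(1, n // 2 + 1), 2),
                "estradiol": rng.uniform(0.5, 3, n),
                "progesterone": rng.uniform(0.3, 3, n),
                "lh": rng.uniform(0.2, 5, n),
                "cortisol": rng.uniform(0.8, 1.2, n),
            }
        )
    )


def glm_null_fpr(seed: int, n_runs: int = 10, n_voxels: int = 5000,
                 alpha: float = 0.001) -> dict:
    """One-sided voxel-wise false-positive rate on pure-noise maps.

    Returns the pooled empirical rate, the nominal level and the
    Monte-Carlo standard error of the estimate.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for _ in range(n_runs):
        panel = _null_panel(rng)
        design = build_design(panel, ["progesterone"], ["cortisol"])
        maps = rng.standard_normal((panel.n_scans, n_voxels))
        stat = VoxelGLM(maps, design).fit().t_contrast("progesterone")
        hits += int(np.sum(stat.p < alpha))
        total += n_voxels
    rate = hits / total
    se = float(np.sqrt(alpha * (1 - alpha) / total))
    return {"rate": rate, "nominal": alpha, "mc_se": se}


def fwe_grid_max_error(reference_n: int = 575) -> float:
    """Max abs deviation of fwe_adjust from direct evaluation on a (p, n) grid."""
    ps = np.array([1e-6, 1e-4, 0.001, 0.005, 0.01, 0.05, 0.5, 1.0])
    ns = [1, 10, reference_n, 61940]
    worst = 0.0
    for n in ns:
        bon = fwe_adjust(ps, n)
        sid = fwe_adjust(ps, n, "sidak")
        worst = max(worst, float(np.max(np.abs(bon - np.minimum(1.0, n * ps)))))
        worst = max(worst, float(np.max(np.abs(sid - (1 - (1 - ps) ** n)))))
    return worst


_NEIGHBORS = {
    6: [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if abs(i) + abs(j) + abs(k) == 1],
    18: [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if 1 <= abs(i) + abs(j) + abs(k) <= 2],
    26: [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)],
}


def _flood_fill_sizes(binary: np.ndarray, connectivity: int) -> list[int]:
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    offsets = _NEIGHBORS[connectivity]
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        count = 0
        while stack:
            v = stack.pop()
            count += 1
            for di, dj, dk in offsets:
                w = (v[0] + di, v[1] + dj, v[2] + dk)
                if (
                    all(0 <= w[a] < binary.shape[a] for a in range(3))
                    and binary[w]
                    and not seen[w]
                ):
                    seen[w] = True
                    stack.append(w)
        sizes.append(count)
    return sizes


def cluster_oracle_mismatches(seed: int, n_volumes: int = 25,
                              extent_threshold: int = 0) -> int:
    """Count volumes where form_clusters disagrees with a BFS flood-fill oracle.

    Each random thresholded volume is checked under 6-, 18- and
    26-connectivity; agreement means identical multisets of cluster sizes
    (after the extent filter).
    """
    from .glm import StatMap

    rng = np.random.default_rng(seed)
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    mismatches = 0
    for _ in range(n_volumes):
        binary = rng.uniform(size=(10, 10, 8)) < rng.uniform(0.15, 0.4)
        mask = GrayMatterMask(np.ones(binary.shape, dtype=bool), aff)
        flat = binary.ravel(order="F")[mask.ordering]
        stat = StatMap(
            t=np.where(flat, 5.0, 0.0), z=np.where(flat, 5.0, 0.0),
            p=np.where(flat, 1e-5, 0.5), p_fwe=None, df=28,
            contrast=np.array([1.0]), mask=mask,
        )
        for conn in (6, 18, 26):
            table = form_clusters(stat, extent_threshold=extent_threshold,
                                  connectivity=conn)
            oracle = sorted(
                s for s in _flood_fill_sizes(binary, conn) if s >= extent_threshold
            )
            if sorted(table.k_E.tolist()) != oracle:
                mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# End-to-end experiments
# ---------------------------------------------------------------------------

def _roi_rows(bundle, mask):
    return {
        name: np.flatnonzero(grid.ravel(order="F")[mask.ordering])
        for name, grid in bundle.rois.items()
    }


def _roi_center_mm(bundle, name):
    ijk = np.array(np.nonzero(bundle.rois[name])).mean(axis=1)
    return (bundle.design.affine @ np.r_[ijk, 1.0])[:3]


def recovery_experiment(seed: int, n_studies: int = 20, voxel_p: float = 0.001,
                        seed_voxel_p: float = 0.005) -> dict:
    """Parameter recovery over seeded coupled studies.

    For each study: does the progesterone-positive EC contrast reach
    p < ``voxel_p`` inside the coupled ROI pair; does the seed-based
    second level (seed at ROI A center, p < ``seed_voxel_p``, k > 20)
    yield a cluster overlapping the partner ROI; does the estradiol
    contrast (which should stay silent) reach threshold in the pair.
    """
    ec_hits = seed_hits = estradiol_hits = 0
    for i in range(n_studies):
        bundle = simulate_study(rng_seed=seed + i)
        roi_a, roi_b = bundle.truth.coupled_pairs[0]
        ctr = _roi_center_mm(bundle, roi_a)
        cfg = RunConfig(
            seeds=(("roiA", float(ctr[0]), float(ctr[1]), float(ctr[2])),),
            seed_voxel_ps=(seed_voxel_p,),
        )
        res = run_ecm_study(StudyData.from_bundle(bundle), cfg)
        rows = _roi_rows(bundle, res.mask)
        pair_rows = np.r_[rows[roi_a], rows[roi_b]]
        ec_hits += bool(np.any(res.glm["z_progesterone"]["pos"].p[pair_rows] < voxel_p))
        estradiol_hits += bool(
            np.any(res.glm["z_estradiol"]["pos"].p[pair_rows] < voxel_p)
        )
        partner = set(rows[roi_b].tolist())
        table = res.seed_results["roiA"][seed_voxel_p]
        seed_hits += any(
            bool(partner & set(np.asarray(r).tolist())) for r in table["_voxel_rows"]
        )
    return {
        "n_studies": n_studies,
        "ec_recovered": ec_hits,
        "seed_recovered": seed_hits,
        "estradiol_recovered": estradiol_hits,
    }


def null_control_experiment(seed: int, n_studies: int = 20,
                            fwe_alpha: float = 0.05) -> dict:
    """Count null studies (beta = 0) with any FWE-significant EC peak.

    Both one-sided progesterone contrasts are screened at the pipeline's
    default Bonferroni family (two contrasts x in-mask voxels).
    """
    dirty = 0
    cfg = RunConfig(interest=("z_progesterone",), seed_analysis=False)
    for i in range(n_studies):
        bundle = simulate_study(truth=GroundTruth(beta=0.0), rng_seed=seed + i)
        res = run_ecm_study(StudyData.from_bundle(bundle), cfg)
        found = False
        for direction in ("pos_table", "neg_table"):
            table = res.glm["z_progesterone"][direction]
            if len(table) and np.any(table["peak_p_fwe"].to_numpy() < fwe_alpha):
                found = True
        dirty += found
    return {"n_studies": n_studies, "clean": n_studies - dirty, "dirty": dirty}


def hormone_contract_sweep(seed: int, n_seeds: int = 50) -> dict:
    """Check the cycle-dynamics contract of generated panels over many seeds.

    Contract per panel: luteal mean progesterone > follicular mean; the
    estradiol curve has >= 2 local maxima per cycle; the LH argmax scan
    lies at/after the estradiol peak scan and not after ovulation day.
    """
    params = CycleParams()
    design = StudyDesign()
    grid = np.linspace(1, params.cycle_length, 512)
    e2 = params.estradiol_curve(grid)
    curve_maxima = int(np.sum((e2[1:-1] > e2[:-2]) & (e2[1:-1] > e2[2:])))
    prog_ok = lh_ok = 0
    for i in range(n_seeds):
        bundle = simulate_study(params, design, rng_seed=seed + i)
        panel = bundle.panel
        labeled = label_phase(panel)
        means = labeled.df.groupby("phase")["progesterone"].mean()
        prog_ok += bool(means.get("luteal", -np.inf) > means.get("follicular", np.inf))
        df = panel.df
        lh_day = float(df.loc[df["lh"].idxmax(), "cycle_day"])
        e2_day = float(df.loc[df["estradiol"].idxmax(), "cycle_day"])
        lh_ok += bool(e2_day <= lh_day <= params.ovulation_day)
    return {
        "n_seeds": n_seeds,
        "progesterone_ok": prog_ok,
        "lh_ordering_ok": lh_ok,
        "estradiol_curve_local_maxima": curve_maxima,
    }
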
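"""End-to-end study analysis: smoothing -> masking -> EC -> GLM -> seeds.

Mirrors the motivating study's workflow: every scan is smoothed (8 mm
FWHM), an analysis mask is built from the gray-matter probability map
(4 mm smoothing, 0.12 threshold), per-scan EC maps are computed, a
voxel-wise GLM with session indicators, one hormone of interest and
cortisol as nuisance tests positive and negative hormone-EC correlations
(voxel p < 0.001, FWE-corrected peak p over a configured comparison
count), and seed-based connectivity maps from spheres at the EC peaks are
fed through the same GLM at uncorrected p < 0.005 / p < 0.001 with an
extent threshold of k > 20 voxels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .centrality import ec_map_volume
from .glm import VoxelGLM, build_design, form_clusters, write_cluster_table
from .hormones import HormonePanel, load_hormone_table, zstandardize
from .seed import connectivity_map, make_sphere_seed, seed_second_level
from .volumes import (
    GrayMatterMask,
    Volume3D,
    Volume4D,
    make_gm_mask,
    read_volume,
    scatter_to_volume,
    smooth_series,
    write_volume,
)

logger = logging.getLogger("cycleconn")

__all__ = ["RunConfig", "StudyData", "StudyResults", "run_ecm_study"]


@dataclass
class RunConfig:
    """All analysis settings; defaults reproduce the reference workflow."""

    # preprocessing
    smooth_fwhm_mm: float = 8.0
    mask_fwhm_mm: float = 4.0
    mask_threshold: float = 0.12
    # hormones / GLM
    standardization_scope: str = "all_scans"
    interest: tuple = ("z_progesterone", "z_estradiol")  # separate models
    nuisance: tuple = ("z_cortisol",)
    # thresholds
    voxel_p: float = 0.001
    fwe_alpha: float = 0.05
    fwe_method: str = "bonferroni"
    n_comparisons: int | None = None  # None -> contrasts x in-mask voxels (conservative)
    connectivity: int = 18
    # seed analysis
    seed_analysis: bool = True
    seed_radius_mm: float = 6.0
    seeds: tuple = ()  # (label, x, y, z) mm; empty -> EC peak of first hormone
    seed_voxel_ps: tuple = (0.005, 0.001)
    seed_extent: int = 20
    seed_covariate: str = "z_progesterone"
    # I/O (only used by the path-based entry point)
    volume_paths: tuple = ()
    gm_prob_path: str | None = None
    hormone_csv_path: str | None = None
    output_dir: str | None = None

    def validate(self) -> None:
        if not (0 < self.voxel_p <= 1 and 0 < self.fwe_alpha <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        for p in self.seed_voxel_ps:
            if not 0 < p <= 1:
                raise ValueError("seed voxel p thresholds must lie in (0, 1]")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.smooth_fwhm_mm < 0 or self.mask_fwhm_mm < 0:
            raise ValueError("FWHM values must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("interest", "nuisance", "seeds", "seed_voxel_ps", "volume_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class StudyData:
    """In-memory study inputs: scans (or a lazy provider), gm map, hormone panel."""

    gm_prob: Volume3D
    panel: HormonePanel
    scans: object  # sequence of Volume4D, or callable index -> Volume4D
    n_scans: int

    def scan(self, i: int) -> Volume4D:
        return self.scans(i) if callable(self.scans) else self.scans[i]

    @classmethod
    def from_bundle(cls, bundle) -> "StudyData":
        return cls(
            gm_prob=bundle.gm_prob,
            panel=bundle.panel,
            scans=bundle.scan,
            n_scans=bundle.n_scans,
        )

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "StudyData":
        if not cfg.volume_paths or cfg.gm_prob_path is None or cfg.hormone_csv_path is None:
            raise ValueError("config must name volume_paths, gm_prob_path and hormone_csv_path")
        gm = read_volume(cfg.gm_prob_path)
        panel = load_hormone_table(cfg.hormone_csv_path)
        paths = list(cfg.volume_paths)
        if len(paths) != panel.n_scans:
            raise ValueError(
                f"{len(paths)} volumes but hormone table has {panel.n_scans} scans"
            )
        return cls(
            gm_prob=gm,
            panel=panel,
            scans=lambda i: read_volume(paths[i]),
            n_scans=len(paths),
        )


@dataclass
class StudyResults:
    """Everything the pipeline produced, plus a JSON-ready summary."""

    config: RunConfig
    mask: GrayMatterMask
    panel: HormonePanel
    ec_maps: np.ndarray  # (n_scans, n_voxels)
    glm: dict  # hormone -> {"results", "pos", "neg", "pos_table", "neg_table"}
    seed_results: dict  # seed label -> {voxel_p -> ClusterTable}
    seed_specs: dict
    summary: dict

    def report_markdown(self) -> str:
        lines = ["# Study analysis report", ""]
        lines.append(f"- scans: {self.summary['n_scans']}")
        lines.append(f"- in-mask voxels: {self.summary['n_mask_voxels']}")
        lines.append(f"- FWE comparisons (n): {self.summary['n_comparisons']}")
        for hormone, tabs in self.summary["ec_glm"].items():
            lines.append(f"\n## EC ~ {hormone}")
            for direction in ("positive", "negative"):
                t = tabs[direction]
                lines.append(f"\n### {direction} contrast ({len(t)} cluster(s))")
                if t:
                    lines.append(pd.DataFrame(t).to_string(index=False))
        for label, per_p in self.summary["seed"].items():
            lines.append(f"\n## Seed '{label}' ~ {self.config.seed_covariate}")
            for p_key, t in per_p.items():
                lines.append(f"\n### voxel p < {p_key}, k > {self.config.seed_extent} "
                             f"({len(t)} cluster(s))")
                if t:
                    lines.append(pd.DataFrame(t).to_string(index=False))
        return "\n".join(lines) + "\n"


def _table_records(table: pd.DataFrame) -> list[dict]:
    out = table.drop(columns=[c for c in table.columns if c.startswith("_")])
    return json.loads(out.to_json(orient="records"))


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def compute_ec_maps(data: StudyData, cfg: RunConfig, mask: GrayMatterMask) -> np.ndarray:
    """Per-scan smoothed EC maps stacked into a (n_scans, n_voxels) matrix."""
    rows = []
    for i in range(data.n_scans):
        vol = data.scan(i)
        if cfg.smooth_fwhm_mm > 0:
            vol = smooth_series(vol, cfg.smooth_fwhm_mm)
        ecmap, _ = ec_map_volume(vol, mask)
        logger.info(
            "scan %d: EC converged in %d iterations (lambda=%.3f)",
            i + 1, ecmap.iterations, ecmap.eigenvalue,
        )
        rows.append(ecmap.values)
    return np.vstack(rows)


def run_ecm_study(
    data: StudyData,
    cfg: RunConfig | None = None,
    out_dir=None,
) -> StudyResults:
    """Run the full analysis on in-memory (or lazily loaded) study data.

    Stages: gray-matter mask -> per-scan smoothing + EC -> per-hormone GLM
    (positive and negative one-sided contrasts, cluster report with
    FWE-adjusted peak p) -> seed placement at the first hormone's peak (or
    configured seeds) -> seed-connectivity second level at both
    uncorrected thresholds.  Any stage error aborts with the stage name.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    stage = "mask"
    try:
        mask = make_gm_mask(data.gm_prob, cfg.mask_fwhm_mm, cfg.mask_threshold)
        logger.info("mask: %d voxels (gm hash %s)", mask.n_voxels, _hash_array(data.gm_prob.data))

        stage = "hormones"
        panel = zstandardize(data.panel, scope=cfg.standardization_scope)
        if panel.n_scans != data.n_scans:
            raise ValueError("hormone panel and scan count disagree")

        stage = "ecm"
        ec = compute_ec_maps(data, cfg, mask)

        stage = "glm"
        # Bonferroni family defaults to every comparison made per hormone model:
        # two one-sided contrasts at each in-mask voxel.  Supply a resel count
        # (e.g. from the acquisition software) via n_comparisons to override.
        n_comp = cfg.n_comparisons if cfg.n_comparisons else 2 * mask.n_voxels
        glm_out: dict = {}
        for hormone in cfg.interest:
            design = build_design(panel, interest=[hormone], nuisance=list(cfg.nuisance))
            results = VoxelGLM(ec, design, mask=mask).fit()
            pos = results.t_contrast(design.contrast_vector(hormone, +1.0))
            neg = results.t_contrast(design.contrast_vector(hormone, -1.0))
            tables = {}
            for name, stat in (("pos", pos), ("neg", neg)):
                tables[name] = form_clusters(
                    stat,
                    voxel_p_threshold=cfg.voxel_p,
                    extent_threshold=0,
                    connectivity=cfg.connectivity,
                    fwe_n=n_comp,
                    fwe_method=cfg.fwe_method,
                )
            glm_out[hormone] = {
                "results": results, "pos": pos, "neg": neg,
                "pos_table": tables["pos"], "neg_table": tables["neg"],
            }

        stage = "seed"
        seed_specs = {}
        if not cfg.seed_analysis:
            pass
        elif cfg.seeds:
            for label, x, y, z in cfg.seeds:
                seed_specs[label] = make_sphere_seed(
                    (x, y, z), cfg.seed_radius_mm, mask, label=label
                )
        else:
            # place one seed at the top positive-contrast EC peak of the first hormone
            first = cfg.interest[0]
            table = glm_out[first]["pos_table"]
            if len(table):
                peak = table.iloc[0]
                seed_specs["ec_peak"] = make_sphere_seed(
                    (peak.x_mm, peak.y_mm, peak.z_mm),
                    cfg.seed_radius_mm, mask, label="ec_peak",
                )
        seed_out: dict = {}
        for label, seed in seed_specs.items():
            conn = np.vstack(
                [
                    connectivity_map(
                        smooth_series(data.scan(i), cfg.smooth_fwhm_mm)
                        if cfg.smooth_fwhm_mm > 0 else data.scan(i),
                        seed, mask,
                    )
                    for i in range(data.n_scans)
                ]
            )
            seed_out[label] = {
                p: seed_second_level(
                    conn, panel, cfg.seed_covariate, mask,
                    voxel_p=p, extent=cfg.seed_extent, connectivity=cfg.connectivity,
                )
                for p in cfg.seed_voxel_ps
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    summary = {
        "n_scans": data.n_scans,
        "n_mask_voxels": mask.n_voxels,
        "n_comparisons": n_comp,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "ec_glm": {
            h: {
                "positive": _table_records(d["pos_table"]),
                "negative": _table_records(d["neg_table"]),
            }
            for h, d in glm_out.items()
        },
        "seed": {
            label: {str(p): _table_records(t) for p, t in per_p.items()}
            for label, per_p in seed_out.items()
        },
    }
    results = StudyResults(
        config=cfg, mask=mask, panel=panel, ec_maps=ec,
        glm=glm_out, seed_results=seed_out, seed_specs=seed_specs, summary=summary,
    )
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def _write_outputs(res: StudyResults, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    import nibabel as nib  # noqa: F401  (via write_volume)

    write_volume(res.mask.to_volume(), out / "mask.nii", dtype=np.uint8)
    for i in range(res.ec_maps.shape[0]):
        write_volume(
            scatter_to_volume(res.ec_maps[i], res.mask), out / f"ec_{i + 1:02d}.nii",
            dtype=np.float32,
        )
    for hormone, d in res.glm.items():
        d["results"].design.to_frame().to_csv(out / f"design_{hormone}.csv", index=False)
        for name in ("pos", "neg"):
            write_cluster_table(d[f"{name}_table"], out / f"clusters_{hormone}_{name}.tsv")
            write_volume(
                scatter_to_volume(d[name].t, res.mask),
                out / f"tmap_{hormone}_{name}.nii", dtype=np.float32,
            )
    for label, per_p in res.seed_results.items():
        for p, table in per_p.items():
            write_cluster_table(table, out / f"seed_{label}_p{p}.tsv")
    (out / "summary.json").write_text(json.dumps(res.summary, indent=2))
    (out / "report.md").write_text(res.report_markdown())
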
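"""Synthetic longitudinal study generator with known hormone-coupled connectivity.

No scan data accompanies the motivating single-subject study, so this
module emulates its design: 32 resting-state scans in 2 sessions of 16,
acquired every second or third day so that each session covers one full
menstrual cycle, each session starting on a different cycle day.  Three
pieces are generated:

* a hormone panel whose estradiol / progesterone / LH curves follow the
  canonical cycle dynamics (periovulatory estradiol peak followed by a
  smaller late-luteal peak; LH surge just after the estradiol peak and
  just before ovulation; progesterone low follicular, high luteal) plus
  multiplicative measurement noise and uncoupled cortisol;

* per-scan 4D BOLD-like volumes in which designated ROI pairs share a
  latent signal whose per-scan weight is ``w = alpha + beta * z_prog``,
  on top of voxel-wise AR(1) noise — so higher progesterone means
  stronger inter-ROI coupling, the qualitative finding the pipeline must
  recover.  ``beta = 0`` defines the null study;

* a matching gray-matter probability volume (1 on a brain-like block
  containing all ROIs, 0 outside).

Everything is reproducible from (params, design, truth, seed).  Hormone
units are arbitrary; the pipeline consumes z-standardized values, so
units are immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .hormones import HormonePanel, zstandardize
from .volumes import Volume3D, Volume4D, write_volume

__all__ = [
    "CycleParams",
    "StudyDesign",
    "GroundTruth",
    "StudyBundle",
    "default_rois",
    "gm_probability",
    "simulate_hormone_cycle",
    "simulate_scan",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleParams:
    """Parametric menstrual-cycle hormone curves (arbitrary concentration units).

    Estradiol is a baseline plus two Gaussian bumps: a prominent
    periovulatory peak (default day 12 for ovulation on day 14) and a
    broader, smaller mid/late-luteal peak (default day 21).  Progesterone
    is a smoothed rectangle: low until ovulation, rising to a luteal
    plateau and falling before menses.  LH is a narrow surge centered one
    day after the estradiol periovulatory peak, i.e. one day before
    ovulation.  Cortisol is uncoupled noise.  Measurement noise is
    multiplicative log-normal with coefficient of variation ``noise_cv``.
    """

    cycle_length: float = 28.0
    ovulation_day: float = 14.0
    # estradiol
    estradiol_baseline: float = 0.5
    e2_periov_amp: float = 3.0
    e2_periov_offset: float = -2.0  # peak day relative to ovulation
    e2_periov_width: float = 1.5
    e2_luteal_amp: float = 1.5
    e2_luteal_offset: float = 7.0
    e2_luteal_width: float = 3.0
    # progesterone
    p4_baseline: float = 0.3
    p4_amp: float = 3.0
    p4_rise_offset: float = 2.0  # plateau rise midpoint after ovulation
    p4_rise_width: float = 1.5
    p4_fall_offset: float = 12.0  # plateau fall midpoint after ovulation
    p4_fall_width: float = 1.5
    # LH
    lh_baseline: float = 0.3
    lh_surge_amp: float = 5.0
    lh_surge_width: float = 1.2
    # uncoupled cortisol and measurement noise
    cortisol_mean: float = 1.0
    cortisol_sd: float = 0.2
    noise_cv: float = 0.08

    def __post_init__(self) -> None:
        if not 0 < self.ovulation_day < self.cycle_length:
            raise ValueError("ovulation_day must lie strictly inside the cycle")
        for name in ("e2_periov_amp", "e2_luteal_amp", "p4_amp", "lh_surge_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def e2_periov_day(self) -> float:
        return self.ovulation_day + self.e2_periov_offset

    @property
    def lh_surge_day(self) -> float:
        """LH surges one day after the estradiol peak, just before ovulation."""
        return min(self.e2_periov_day + 1.0, self.ovulation_day)

    # -- noiseless curves over cycle days (scalar or array input) -----------

    def estradiol_curve(self, day):
        day = np.asarray(day, dtype=float)
        return (
            self.estradiol_baseline
            + self.e2_periov_amp
            * np.exp(-0.5 * ((day - self.e2_periov_day) / self.e2_periov_width) ** 2)
            + self.e2_luteal_amp
            * np.exp(
                -0.5
                * ((day - (self.ovulation_day + self.e2_luteal_offset)) / self.e2_luteal_width) ** 2
            )
        )

    def progesterone_curve(self, day):
        day = np.asarray(day, dtype=float)
        rise = self.ovulation_day + self.p4_rise_offset
        fall = self.ovulation_day + self.p4_fall_offset
        sig = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
        return self.p4_baseline + self.p4_amp * sig((day - rise) / self.p4_rise_width) * sig(
            (fall - day) / self.p4_fall_width
        )

    def lh_curve(self, day):
        day = np.asarray(day, dtype=float)
        return self.lh_baseline + self.lh_surge_amp * np.exp(
            -0.5 * ((day - self.lh_surge_day) / self.lh_surge_width) ** 2
        )


@dataclass(frozen=True)
class StudyDesign:
    """Scan schedule and image geometry of the emulated study.

    Scans are acquired every second or third day (gaps alternate through
    ``scan_gap_pattern``); each session starts at a different cycle day
    and its 16 scans wrap around the cycle, covering one full cycle
    across two calendar cycles.  The default grid (24 x 24 x 12 voxels at
    3 mm, 120 frames, TR 2 s) is a desk-scale stand-in for the original
    whole-brain 3 mm / 300-frame acquisition; ``paper_scale()`` gives the
    full-size geometry for performance checks.
    """

    n_scans: int = 32
    n_sessions: int = 2
    session_start_days: tuple = (1.0, 7.0)
    scan_gap_pattern: tuple = (2.0, 3.0)
    grid_shape: tuple = (24, 24, 12)
    voxel_size_mm: float = 3.0
    n_frames: int = 120
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.n_scans % self.n_sessions:
            raise ValueError("n_scans must be divisible by n_sessions")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")
        if len(self.session_start_days) != self.n_sessions:
            raise ValueError("one start day per session required")

    @property
    def scans_per_session(self) -> int:
        return self.n_scans // self.n_sessions

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size_mm] * 3 + [1.0])
        center = (np.array(self.grid_shape) - 1) / 2.0
        a[:3, 3] = -center * self.voxel_size_mm
        return a

    def schedule(self, cycle_length: float) -> pd.DataFrame:
        """Scan table: scan_id, session_id, day within session, cycle_day."""
        rows = []
        scan_id = 1
        for s in range(self.n_sessions):
            start = self.session_start_days[s]
            elapsed = 0.0
            for k in range(self.scans_per_session):
                day = (start - 1 + elapsed) % cycle_length + 1
                rows.append(
                    {
                        "scan_id": scan_id,
                        "session_id": s + 1,
                        "session_day": elapsed,
                        "cycle_day": day,
                    }
                )
                elapsed += self.scan_gap_pattern[k % len(self.scan_gap_pattern)]
                scan_id += 1
        return pd.DataFrame(rows)

    @classmethod
    def paper_scale(cls) -> "StudyDesign":
        """Full-size geometry (~6e4 in-mask voxels, 300 frames); perf checks only."""
        return cls(grid_shape=(48, 56, 40), n_frames=300)


def default_rois(design: StudyDesign) -> dict[str, np.ndarray]:
    """Six 3x3x3 ROIs (bilateral DLPFC, sensorimotor, hippocampus analogues).

    Placed inside the brain block with >= 2 voxel gaps so 8 mm smoothing
    does not merge them.  Returned as boolean grids.
    """
    nx, ny, nz = design.grid_shape
    if nx < 22 or ny < 22 or nz < 10:
        raise ValueError("grid too small for the default ROI layout")

    def box(x0, y0, z0):
        m = np.zeros(design.grid_shape, dtype=bool)
        m[x0 : x0 + 3, y0 : y0 + 3, z0 : z0 + 3] = True
        return m

    return {
        "dlpfc_L": box(5, 15, 6),
        "dlpfc_R": box(16, 15, 6),
        "sensorimotor_L": box(5, 9, 6),
        "sensorimotor_R": box(16, 9, 6),
        "hippocampus_L": box(6, 4, 3),
        "hippocampus_R": box(15, 4, 3),
    }


def gm_probability(design: StudyDesign) -> Volume3D:
    """Gray-matter probability: 1 on the brain block containing every ROI, 0 outside."""
    nx, ny, nz = design.grid_shape
    prob = np.zeros(design.grid_shape)
    prob[3 : nx - 3, 3 : ny - 3, 2 : nz - 2] = 1.0
    return Volume3D(prob, design.affine)


@dataclass
class GroundTruth:
    """Coupling model: which ROI pairs share a latent signal, and how strongly.

    Per scan, every voxel in both members of a coupled pair receives
    ``w_scan * s(t)`` with a shared standard-normal latent ``s`` and
    ``w_scan = alpha + beta * z_progesterone``; all voxels additionally
    carry AR(1) noise (coefficient ``ar1_coef``, stationary sd
    ``noise_sd``).  ``beta = 0`` is the null study.  ``w_per_scan`` is
    filled by :func:`simulate_study` and recorded in the manifest.
    """

    coupled_pairs: tuple = (("dlpfc_L", "hippocampus_L"),)
    alpha: float = 0.8
    beta: float = 0.4
    ar1_coef: float = 0.3
    noise_sd: float = 1.0
    session_common_weight: float = 0.0
    w_per_scan: np.ndarray | None = field(default=None)

    def weights(self, z_progesterone: np.ndarray) -> np.ndarray:
        w = self.alpha + self.beta * np.asarray(z_progesterone, dtype=float)
        return np.clip(w, 0.0, None)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_hormone_cycle(
    params: CycleParams, design: StudyDesign, rng_seed: int
) -> HormonePanel:
    """Generate the per-scan hormone panel (z-standardized over all scans).

    Curve values at each scan's cycle day receive multiplicative
    log-normal measurement noise; cortisol is independent Gaussian noise
    truncated at zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 17]))
    sched = design.schedule(params.cycle_length)
    days = sched["cycle_day"].to_numpy()
    n = len(sched)
    sigma = np.sqrt(np.log1p(params.noise_cv**2))
    noise = lambda: np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))  # noqa: E731
    df = sched.copy()
    df["estradiol"] = params.estradiol_curve(days) * noise()
    df["progesterone"] = params.progesterone_curve(days) * noise()
    df["lh"] = params.lh_curve(days) * noise()
    df["cortisol"] = np.maximum(
        rng.normal(params.cortisol_mean, params.cortisol_sd, size=n), 1e-6
    )
    return zstandardize(HormonePanel(df), scope="all_scans")


def _ar1_noise(rng: np.random.Generator, shape_spatial, t: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series per voxel, shape (*spatial, t)."""
    burn = 50
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(shape_spatial + (t + burn,)) * innov_sd
    series = lfilter([1.0], [1.0, -phi], eps, axis=-1)
    return series[..., burn:]


def simulate_scan(
    design: StudyDesign,
    truth: GroundTruth,
    scan_index: int,
    rng_seed: int,
    rois: dict[str, np.ndarray] | None = None,
    session_index: int | None = None,
) -> Volume4D:
    """One 4D BOLD-like scan: AR(1) noise everywhere + coupled-ROI latent signal.

    Deterministic in (design, truth, scan_index, rng_seed).  ``scan_index``
    is 0-based.
    """
    if not 0 <= scan_index < design.n_scans:
        raise ValueError(f"scan_index {scan_index} outside study of {design.n_scans} scans")
    if truth.w_per_scan is None:
        raise ValueError("GroundTruth.w_per_scan is unset; use simulate_study or fill it")
    rois = default_rois(design) if rois is None else rois
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 101, int(scan_index)]))
    t = design.n_frames
    data = _ar1_noise(rng, design.grid_shape, t, truth.ar1_coef, truth.noise_sd)
    w = float(truth.w_per_scan[scan_index])
    for a, b in truth.coupled_pairs:
        latent = rng.standard_normal(t)
        pair_mask = rois[a] | rois[b]
        data[pair_mask] += w * latent
    if truth.session_common_weight:
        if session_index is None:
            session_index = scan_index // design.scans_per_session
        common = rng.standard_normal(t)
        brain = gm_probability(design).data > 0.5
        data[brain] += truth.session_common_weight * (1 + session_index) * common
    data += 100.0  # BOLD-like positive baseline; correlations are unaffected
    return Volume4D(data, design.affine, tr_seconds=design.tr_seconds)


@dataclass
class StudyBundle:
    """A complete simulated study; scans are generated lazily and reproducibly."""

    params: CycleParams
    design: StudyDesign
    truth: GroundTruth
    panel: HormonePanel
    gm_prob: Volume3D
    rois: dict[str, np.ndarray]
    rng_seed: int

    @property
    def n_scans(self) -> int:
        return self.design.n_scans

    def scan(self, index: int) -> Volume4D:
        return simulate_scan(
            self.design, self.truth, index, self.rng_seed, rois=self.rois
        )

    def scans(self):
        for i in range(self.n_scans):
            yield self.scan(i)

    def manifest(self) -> dict:
        sched = self.panel.df
        return {
            "rng_seed": int(self.rng_seed),
            "n_scans": self.n_scans,
            "coupling": {
                "pairs": [list(p) for p in self.truth.coupled_pairs],
                "alpha": self.truth.alpha,
                "beta": self.truth.beta,
                "ar1_coef": self.truth.ar1_coef,
                "noise_sd": self.truth.noise_sd,
            },
            "scans": [
                {
                    "scan_id": int(row.scan_id),
                    "session_id": int(row.session_id),
                    "cycle_day": float(row.cycle_day),
                    "file": f"scan_{int(row.scan_id):02d}.nii",
                    "w_scan": float(self.truth.w_per_scan[i]),
                }
                for i, row in enumerate(sched.itertuples())
            ],
        }

    def write(self, out_dir) -> None:
        """Write NIfTI volumes, gray-matter map, hormone CSV and JSON manifest."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(self.gm_prob, out / "gm_probability.nii")
        self.panel.to_csv(out / "hormones.csv")
        for i in range(self.n_scans):
            write_volume(self.scan(i), out / f"scan_{i + 1:02d}.nii", dtype=np.float32)
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def simulate_study(
    params: CycleParams | None = None,
    design: StudyDesign | None = None,
    truth: GroundTruth | None = None,
    rng_seed: int = 0,
) -> StudyBundle:
    """Assemble a reproducible study: panel, ground truth weights, lazy scans."""
    params = params or CycleParams()
    design = design or StudyDesign()
    truth = truth or GroundTruth()
    panel = simulate_hormone_cycle(params, design, rng_seed)
    w = truth.weights(panel.column("z_progesterone"))
    truth = replace(truth, w_per_scan=w)
    return StudyBundle(
        params=params,
        design=design,
        truth=truth,
        panel=panel,
        gm_prob=gm_probability(design),
        rois=default_rois(design),
        rng_seed=int(rng_seed),
    )
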
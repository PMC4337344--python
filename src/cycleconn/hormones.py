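"""Hormone-panel handling: CSV I/O, z-standardization, cycle-phase labeling.

A hormone panel holds one row per resting-state scan: session membership,
cycle day (days since menses onset, 1-based), and the serum concentrations
of estradiol, progesterone, luteinizing hormone (LH) and cortisol drawn at
scan time.  The GLM consumes z-standardized hormone values; phase labels
(follicular / periovulatory / luteal) are derived from the LH surge.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "HORMONE_COLUMNS",
    "REQUIRED_COLUMNS",
    "HormonePanel",
    "load_hormone_table",
    "zstandardize",
    "label_phase",
]

HORMONE_COLUMNS = ("estradiol", "progesterone", "lh", "cortisol")
REQUIRED_COLUMNS = ("scan_id", "session_id", "cycle_day") + HORMONE_COLUMNS

PHASES = ("follicular", "periovulatory", "luteal")


class HormonePanel:
    """Per-scan hormone measurements plus session/cycle metadata.

    Thin wrapper around a pandas DataFrame with a validated schema; the
    frame is accessible as ``panel.df``.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"hormone table missing required column(s): {missing}")
        if df["scan_id"].duplicated().any():
            dupes = df.loc[df["scan_id"].duplicated(), "scan_id"].tolist()
            raise ValueError(f"duplicate scan_id values: {dupes}")
        for col in ("cycle_day",) + HORMONE_COLUMNS:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric entry in column '{col}'") from exc
        if (df["cycle_day"].dropna() < 1).any():
            raise ValueError("cycle_day must be >= 1 (days since menses onset)")
        n_missing = int(df[list(HORMONE_COLUMNS)].isna().sum().sum())
        if n_missing:
            warnings.warn(
                f"hormone panel contains {n_missing} missing hormone value(s)",
                stacklevel=3,
            )
        if "phase" not in df.columns:
            df["phase"] = pd.NA
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_scans(self) -> int:
        return len(self.df)

    @property
    def sessions(self) -> list:
        return sorted(self.df["session_id"].unique().tolist())

    def column(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise KeyError(f"unknown panel column '{name}'")
        return self.df[name].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def copy(self) -> "HormonePanel":
        return HormonePanel(self.df)


def load_hormone_table(path) -> HormonePanel:
    """Load a hormone panel from CSV (one row per scan, documented columns)."""
    df = pd.read_csv(path)
    return HormonePanel(df)


def zstandardize(panel: HormonePanel, scope: str = "all_scans") -> HormonePanel:
    """Fill ``z_<hormone>`` columns with standardized values.

    scope
        ``"all_scans"`` pools both sessions into a single standardization
        group; ``"per_session"`` standardizes within each session.  Sample
        (n-1) standard deviation throughout.  Raw columns are untouched.
    """
    if scope not in ("all_scans", "per_session"):
        raise ValueError(f"unknown scope '{scope}'")
    df = panel.df.copy()
    groups = [df.index] if scope == "all_scans" else [
        g.index for _, g in df.groupby("session_id")
    ]
    for idx in groups:
        if len(idx) < 2:
            raise ValueError("need at least 2 scans per standardization group")
    for col in HORMONE_COLUMNS:
        z = np.full(len(df), np.nan)
        for idx in groups:
            vals = df.loc[idx, col].to_numpy(dtype=float)
            sd = np.std(vals, ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero variance in column '{col}' within a group")
            z[idx] = (vals - vals.mean()) / sd
        df[f"z_{col}"] = z
    return HormonePanel(df)


def detect_lh_surge(panel: HormonePanel) -> int | None:
    """Cycle day of the LH surge, or None if no surge stands out.

    The surge day is the cycle day of maximal LH, accepted only when that
    maximum exceeds the panel's LH median by at least 2 panel standard
    deviations (sample SD).
    """
    lh = panel.column("lh")
    days = panel.column("cycle_day")
    sd = np.std(lh, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return None
    imax = int(np.argmax(lh))
    if lh[imax] - np.median(lh) < 2.0 * sd:
        return None
    return int(days[imax])


def label_phase(panel: HormonePanel) -> HormonePanel:
    """Label each scan follicular / periovulatory / luteal from the LH surge.

    The ovulation day is estimated as the LH-surge day + 1.  Scans more
    than one day before the surge are follicular, scans within surge day
    +/- 1 periovulatory, and scans after ovulation luteal.  If no surge is
    detectable every scan stays unlabeled and a warning is issued.
    """
    df = panel.df.copy()
    surge_day = detect_lh_surge(panel)
    if surge_day is None:
        warnings.warn("no LH surge detectable; phases left unlabeled", stacklevel=2)
        df["phase"] = pd.NA
        return HormonePanel(df)
    days = df["cycle_day"].to_numpy(dtype=float)
    phase = np.where(
        days < surge_day - 1,
        "follicular",
        np.where(days <= surge_day + 1, "periovulatory", "luteal"),
    )
    df["phase"] = phase
    return HormonePanel(df)
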
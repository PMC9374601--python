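"""Session-level aggregation and manual-vs-automated agreement.

Per-frame sector scores are summed over valid frames into eye-use totals,
durations (totals / fps) and proportions, plus a laterality index
(R - L) / (R + L) over the four seeing fields (+1 = fully right-field use,
-1 = fully left).  Head activity (path length of the eye midpoint and
frame-to-frame heading change) and zone occupancy (time the eye midpoint
spends inside configured rectangles) are computed from the raw tracks,
restricted to QC-valid frames.

Agreement between automated and manual scoring is measured per sector with
Pearson or Spearman correlations over paired valid frames (pooled, and per
subject when a ``subject`` column is present), and with a tracking accuracy:
the fraction of frames whose full six-sector score vectors agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ConsistencyError, InsufficientDataError, ValidationError
from .fieldscore import SCORE_COLUMNS
from .headgeom import SECTOR_LABELS, compute_head_frame, wrap_angle

__all__ = [
    "Zone",
    "SessionSummary",
    "AgreementResult",
    "aggregate_scores",
    "head_activity",
    "zone_occupancy",
    "compare_with_manual",
    "tracking_accuracy",
]

_SECTOR_COLS = [SCORE_COLUMNS[l] for l in SECTOR_LABELS]
_AGREE_TOL = 1e-9


@dataclass(frozen=True)
class Zone:
    """Axis-aligned rectangular arena zone in pixel coordinates."""

    id: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(f"zone {self.id!r}: min edges must be below max edges")

    def contains(self, x, y):
        """Min edges inclusive, max edges exclusive, so adjacent zones
        sharing an edge never double-count a point."""
        return (self.x_min <= x) & (x < self.x_max) & (self.y_min <= y) & (y < self.y_max)


@dataclass
class SessionSummary:
    """Aggregated eye-use measures for one video and one stimulus."""

    video_id: str
    stimulus_id: str
    fps: float
    n_frames: int
    n_valid: int
    totals: dict[str, float]
    durations: dict[str, float]
    proportions: Optional[dict[str, float]]
    laterality_index: Optional[float]
    head_path_length: Optional[float] = None
    mean_heading_change: Optional[float] = None
    zone_durations: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class AgreementResult:
    """Correlation between automated and manual scores for one sector."""

    sector: str
    scope: str  # "pooled" | "per-subject"
    subject: Optional[str]
    method: str  # "pearson" | "spearman"
    n: int
    r: float  # NaN when either series has zero variance
    p: float


def aggregate_scores(scores: pd.DataFrame, fps: float, stimulus_id: Optional[str] = None,
                     video_id: str = "") -> SessionSummary:
    """Aggregate a per-frame score table into a :class:`SessionSummary`.

    The table must contain a single stimulus (or ``stimulus_id`` selects
    one).  Totals are sums over valid frames; durations are totals / fps;
    proportions are totals / n_valid (they sum to 1 because every valid row
    does); the laterality index is (R - L)/(R + L) over the seeing fields
    (frontal + lateral totals per side).
    """
    if fps <= 0:
        raise ValidationError(f"fps must be > 0, got {fps}")
    df = scores
    ids = df["stimulus_id"].unique()
    if stimulus_id is not None:
        df = df[df["stimulus_id"] == stimulus_id]
        if df.empty:
            raise ValidationError(f"no rows for stimulus {stimulus_id!r}")
    elif len(ids) > 1:
        raise ValidationError(
            f"table contains {len(ids)} stimuli; pass stimulus_id to select one"
        )
    else:
        stimulus_id = str(ids[0]) if len(ids) else ""

    n_frames = int(df["frame"].nunique())
    valid = df[df["valid_flag"].astype(bool)]
    n_valid = int(len(valid))

    totals = {c: float(valid[c].sum()) for c in _SECTOR_COLS}
    durations = {c: totals[c] / fps for c in _SECTOR_COLS}

    if n_valid == 0:
        warnings.warn("no valid frames; proportions and laterality undefined")
        proportions = None
        laterality = None
    else:
        proportions = {c: totals[c] / n_valid for c in _SECTOR_COLS}
        left = totals["frontal_left"] + totals["lateral_left"]
        right = totals["frontal_right"] + totals["lateral_right"]
        laterality = (right - left) / (right + left) if (right + left) > 0 else None

    return SessionSummary(
        video_id=video_id,
        stimulus_id=stimulus_id,
        fps=fps,
        n_frames=n_frames,
        n_valid=n_valid,
        totals=totals,
        durations=durations,
        proportions=proportions,
        laterality_index=laterality,
    )


def head_activity(tracks, report=None) -> tuple[pd.DataFrame, dict]:
    """Per-frame head motion over consecutive valid frame pairs.

    For each pair of *adjacent* frames that are both QC-valid: the Euclidean
    displacement of the eye midpoint (pixels) and the absolute heading
    change (degrees, minimal wrapped difference).  Pairs spanning an invalid
    frame are skipped, never interpolated.

    Returns ``(per_pair, summary)`` where ``per_pair`` has columns
    ``frame`` (the later frame of the pair), ``displacement`` and
    ``heading_change``, and ``summary`` holds totals and means.
    """
    n = len(tracks)
    valid = report.frame_validity() if report is not None else np.ones(n, dtype=bool)
    if report is not None and not np.array_equal(np.asarray(report.frame_index),
                                                 tracks.frame_index):
        raise ConsistencyError("filter report does not describe the same frames as tracks")

    if int(valid.sum()) < 2:
        warnings.warn("fewer than 2 valid frames; head activity undefined")
        empty = pd.DataFrame(columns=["frame", "displacement", "heading_change"])
        return empty, {"path_length": 0.0, "mean_heading_change": np.nan, "n_pairs": 0}

    rows = []
    prev_hf = None
    prev_pos = None  # position in the frame sequence of the previous pose
    for i, pose in enumerate(tracks.iter_poses()):
        if not valid[i]:
            prev_hf = None
            continue
        hf = compute_head_frame(pose)
        if prev_hf is not None and prev_pos == i - 1:
            disp = float(np.hypot(*(hf.origin - prev_hf.origin)))
            ang = np.degrees(
                np.arctan2(prev_hf.heading[0] * hf.heading[1]
                           - prev_hf.heading[1] * hf.heading[0],
                           prev_hf.heading @ hf.heading)
            )
            rows.append((pose.frame_index, disp, abs(wrap_angle(float(ang)))))
        prev_hf, prev_pos = hf, i

    per_pair = pd.DataFrame(rows, columns=["frame", "displacement", "heading_change"])
    summary = {
        "path_length": float(per_pair["displacement"].sum()) if len(per_pair) else 0.0,
        "mean_heading_change": float(per_pair["heading_change"].mean())
        if len(per_pair) else np.nan,
        "n_pairs": int(len(per_pair)),
    }
    return per_pair, summary


def zone_occupancy(tracks, report, zones: Sequence[Zone], fps: float) -> dict[str, float]:
    """Seconds each zone's rectangle contains the eye midpoint, over valid
    frames.  A frame on a shared edge of adjacent zones counts once (min
    edges inclusive, max edges exclusive)."""
    if fps <= 0:
        raise ValidationError(f"fps must be > 0, got {fps}")
    n = len(tracks)
    valid = report.frame_validity() if report is not None else np.ones(n, dtype=bool)
    mid = tracks.eye_midpoints()
    out: dict[str, float] = {}
    for z in zones:
        inside = z.contains(mid[:, 0], mid[:, 1]) & valid
        out[z.id] = float(inside.sum()) / fps
    return out


def _paired(auto: pd.DataFrame, manual: pd.DataFrame) -> pd.DataFrame:
    key = ["frame", "stimulus_id"]
    a = auto.sort_values(key).reset_index(drop=True)
    m = manual.sort_values(key).reset_index(drop=True)
    if len(a) != len(m) or not (a[key].values == m[key].values).all():
        raise ConsistencyError("automated and manual tables must cover identical frames")
    return a.merge(m, on=key, suffixes=("_auto", "_manual"))


def compare_with_manual(auto: pd.DataFrame, manual: pd.DataFrame,
                        method: str = "pearson") -> list[AgreementResult]:
    """Per-sector correlation between automated and manual score tables.

    Rows are paired on (frame, stimulus_id); only frames valid in both
    tables enter the correlation.  Requires at least 3 paired frames.  A
    sector with zero variance in either series yields ``r = NaN`` (never
    coerced to 0).  Results are pooled, plus per subject when both tables
    carry a ``subject`` column.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"method must be pearson or spearman, got {method!r}")
    merged = _paired(auto, manual)
    both = merged["valid_flag_auto"].astype(bool) & merged["valid_flag_manual"].astype(bool)
    merged = merged[both]
    if len(merged) < 3:
        raise InsufficientDataError("need at least 3 paired valid frames")

    groups: list[tuple[str, Optional[str], pd.DataFrame]] = [("pooled", None, merged)]
    if "subject_auto" in merged.columns:
        for subj, g in merged.groupby("subject_auto"):
            groups.append(("per-subject", str(subj), g))

    out: list[AgreementResult] = []
    corr = _stats.pearsonr if method == "pearson" else _stats.spearmanr
    for scope, subj, g in groups:
        for label in SECTOR_LABELS:
            col = SCORE_COLUMNS[label]
            x = g[f"{col}_auto"].to_numpy(dtype=float)
            y = g[f"{col}_manual"].to_numpy(dtype=float)
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                res = corr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            out.append(AgreementResult(sector=label, scope=scope, subject=subj,
                                       method=method, n=len(x), r=r, p=p))
    return out


def tracking_accuracy(auto: pd.DataFrame, manual: pd.DataFrame) -> float:
    """Fraction of frames whose six-sector score vectors agree.

    A frame agrees when both rows are valid and every sector score matches
    within 1e-9, or when both rows are invalid.  This is the analogue of
    counting frames not relabelled by a human coder over frames verified.
    """
    merged = _paired(auto, manual)
    if merged.empty:
        raise InsufficientDataError("no frames to compare")
    va = merged["valid_flag_auto"].astype(bool).to_numpy()
    vm = merged["valid_flag_manual"].astype(bool).to_numpy()
    a = merged[[f"{c}_auto" for c in _SECTOR_COLS]].to_numpy(dtype=float)
    m = merged[[f"{c}_manual" for c in _SECTOR_COLS]].to_numpy(dtype=float)
    close = np.all(np.abs(a - m) <= _AGREE_TOL, axis=1)
    agree = (va & vm & close) | (~va & ~vm)
    return float(agree.mean())
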
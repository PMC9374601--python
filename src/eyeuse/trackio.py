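"""Input/output: pose tracks in the DeepLabCut CSV dialect, YAML session
configuration, and all result tables.

The track dialect has a three-row header (scorer, bodyparts, coords) over an
x / y / likelihood triplet per body part and a leading integer frame-index
column.  Only the CSV variant is read, and only the three head landmarks
``leftHead``, ``topHead`` and ``rightHead`` are required.  Image coordinates
have the origin at the top-left with y increasing downward; nothing in the
pipeline depends on that convention.

The experimenter-supplied session information (visual-field angles, stimulus
geometry, arena zones, frame rate, QC thresholds) lives in a YAML file with
an explicit, validated schema; omitted QC fields take the defaults
``likelihood_cutoff = 0.95`` and ``distance_threshold_k = 3``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParseError, ValidationError
from .fieldscore import FRAME_SCORE_COLUMNS, Stimulus
from .headgeom import VisualFieldConfig
from .summarize import SessionSummary, Zone

__all__ = [
    "LANDMARK_NAMES",
    "Landmark",
    "FramePose",
    "TrackTable",
    "SessionConfig",
    "read_dlc_tracks",
    "read_config",
    "write_frame_scores",
    "read_frame_scores",
    "write_summary",
    "read_summary",
    "write_filter_report",
    "read_review_decisions",
]

#: required body parts, in canonical storage order
LANDMARK_NAMES = ("leftHead", "topHead", "rightHead")

DEFAULT_LIKELIHOOD_CUTOFF = 0.95
DEFAULT_DISTANCE_THRESHOLD_K = 3.0


@dataclass(frozen=True)
class Landmark:
    """One tracked point: pixel position plus tracker confidence."""

    name: str
    x: float
    y: float
    likelihood: float

    def __post_init__(self) -> None:
        if self.name not in LANDMARK_NAMES:
            raise ValidationError(f"unknown landmark name {self.name!r}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"{self.name}: coordinates must be finite")
        if not (0.0 <= self.likelihood <= 1.0):
            raise ValidationError(
                f"{self.name}: likelihood {self.likelihood} outside [0, 1]"
            )

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class FramePose:
    """The three head landmarks of one frame."""

    frame_index: int
    landmarks: dict[str, Landmark]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        if set(self.landmarks) != set(LANDMARK_NAMES):
            raise ValidationError(
                f"frame {self.frame_index}: need exactly the landmarks {LANDMARK_NAMES}"
            )


@dataclass
class TrackTable:
    """Ordered per-frame landmark coordinates and likelihoods for one video.

    Stored columnar for speed: ``xy`` has shape (n, 3, 2) and ``likelihood``
    (n, 3), landmark axis ordered as :data:`LANDMARK_NAMES`.
    """

    video_id: str
    fps: float
    frame_index: np.ndarray
    xy: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 3, 2)
        self.likelihood = np.asarray(self.likelihood, dtype=float).reshape(-1, 3)
        n = len(self.frame_index)
        if self.xy.shape != (n, 3, 2) or self.likelihood.shape != (n, 3):
            raise ValidationError("frame_index, xy and likelihood lengths disagree")
        if not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if n and np.any(np.diff(self.frame_index) <= 0):
            raise ValidationError("frame_index must be strictly increasing")
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError("landmark coordinates must be finite")
        if np.any((self.likelihood < 0) | (self.likelihood > 1)):
            raise ValidationError("likelihoods must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame_index)

    def pose(self, i: int) -> FramePose:
        """FramePose at sequence position ``i`` (not frame index)."""
        lms = {
            name: Landmark(name, self.xy[i, j, 0], self.xy[i, j, 1],
                           self.likelihood[i, j])
            for j, name in enumerate(LANDMARK_NAMES)
        }
        return FramePose(int(self.frame_index[i]), lms)

    def iter_poses(self) -> Iterator[FramePose]:
        for i in range(len(self)):
            yield self.pose(i)

    def eye_midpoints(self) -> np.ndarray:
        """(n, 2) midpoint of leftHead and rightHead per frame."""
        left = self.xy[:, LANDMARK_NAMES.index("leftHead"), :]
        right = self.xy[:, LANDMARK_NAMES.index("rightHead"), :]
        return 0.5 * (left + right)


@dataclass
class SessionConfig:
    """Validated session parameters (the experimenter-entered information)."""

    field_angles: VisualFieldConfig
    stimuli: list[Stimulus]
    fps: float
    zones: list[Zone] = field(default_factory=list)
    likelihood_cutoff: float = DEFAULT_LIKELIHOOD_CUTOFF
    distance_threshold_k: float = DEFAULT_DISTANCE_THRESHOLD_K

    def __post_init__(self) -> None:
        if not self.stimuli:
            raise ValidationError("config must define at least one stimulus")
        if not (0.0 <= self.likelihood_cutoff <= 1.0):
            raise ValidationError(
                f"likelihood_cutoff {self.likelihood_cutoff} outside [0, 1]"
            )
        if not self.distance_threshold_k > 0:
            raise ValidationError("distance_threshold_k must be > 0")
        if not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")


def read_dlc_tracks(path, fps: float, video_id: Optional[str] = None) -> TrackTable:
    """Read a tracking CSV (three-row header dialect) into a TrackTable.

    Every data row of the file becomes exactly one frame; nothing is
    silently dropped.  A missing landmark column raises :class:`FormatError`
    naming the landmark; a non-numeric cell raises :class:`ParseError` with
    its row; a likelihood outside [0, 1] raises :class:`ValidationError`.
    """
    if video_id is None:
        video_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                         float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as e:  # malformed header / csv structure
        raise FormatError(f"{path}: not a valid tracking CSV ({e})") from e

    if df.columns.nlevels != 3:
        raise FormatError(f"{path}: expected a three-row header (scorer/bodyparts/coords)")
    bodyparts = set(df.columns.get_level_values(1))
    for name in LANDMARK_NAMES:
        if name not in bodyparts:
            raise FormatError(f"{path}: missing landmark column {name!r}")

    n = len(df)
    frame_index = _numeric_index(df, path)
    xy = np.empty((n, 3, 2), dtype=float)
    lik = np.empty((n, 3), dtype=float)
    for j, name in enumerate(LANDMARK_NAMES):
        for coord, dest in (("x", 0), ("y", 1), ("likelihood", None)):
            matches = [c for c in df.columns if c[1] == name and c[2] == coord]
            if not matches:
                raise FormatError(f"{path}: missing {coord!r} column for landmark {name!r}")
            vals = _numeric_column(df[matches[0]], frame_index, name, coord, path)
            if dest is None:
                lik[:, j] = vals
            else:
                xy[:, j, dest] = vals

    if np.any((lik < 0) | (lik > 1)):
        bad = frame_index[np.any((lik < 0) | (lik > 1), axis=1)][0]
        raise ValidationError(f"{path}: likelihood outside [0, 1] at frame {bad}")
    return TrackTable(video_id=video_id, fps=fps, frame_index=frame_index,
                      xy=xy, likelihood=lik)


def _numeric_index(df: pd.DataFrame, path) -> np.ndarray:
    idx = pd.to_numeric(pd.Series(df.index), errors="coerce")
    if idx.isna().any():
        row = df.index[int(idx.isna().to_numpy().argmax())]
        raise ParseError(f"{path}: non-numeric frame index {row!r}")
    return idx.to_numpy(dtype=int)


def _numeric_column(col: pd.Series, frame_index, name: str, coord: str, path) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce")
    bad = vals.isna().to_numpy()
    if bad.any():
        row = frame_index[int(bad.argmax())]
        raise ParseError(f"{path}: non-numeric {coord} for {name} at frame {row}")
    return vals.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# session configuration

def read_config(path) -> SessionConfig:
    """Read and validate a YAML session configuration.

    Schema (angles in degrees, coordinates in pixels)::

        fps: 25
        field_angles: {frontal_halfwidth: 15, lateral_width: 135, blind_halfwidth: 30}
        stimuli:
          - {id: cylinder, type: circle, center: [640, 70], radius: 29}
          - {id: dot, type: point, center: [100, 200]}
          - {id: bar, type: segment, border_a: [0, 0], border_b: [10, 0]}
        zones:
          - {id: left_half, rect: [0, 0, 640, 720]}
        qc: {likelihood_cutoff: 0.95, distance_threshold_k: 3}

    ``zones`` and ``qc`` may be omitted; QC fields default to a 0.95
    likelihood cut-off and k = 3.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise FormatError(f"{path}: invalid YAML ({e})") from e
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")

    try:
        fa = raw.get("field_angles") or {}
        field_angles = VisualFieldConfig(
            frontal_halfwidth=float(fa.get("frontal_halfwidth", 15.0)),
            lateral_width=float(fa.get("lateral_width", 135.0)),
            blind_halfwidth=float(fa.get("blind_halfwidth", 30.0)),
        )
        stimuli = [_parse_stimulus(s, i) for i, s in enumerate(raw.get("stimuli") or [])]
        zones = [_parse_zone(z, i) for i, z in enumerate(raw.get("zones") or [])]
        qc = raw.get("qc") or {}
        return SessionConfig(
            field_angles=field_angles,
            stimuli=stimuli,
            zones=zones,
            fps=float(raw.get("fps", 0.0)),
            likelihood_cutoff=float(qc.get("likelihood_cutoff", DEFAULT_LIKELIHOOD_CUTOFF)),
            distance_threshold_k=float(qc.get("distance_threshold_k",
                                              DEFAULT_DISTANCE_THRESHOLD_K)),
        )
    except (TypeError, KeyError) as e:
        raise FormatError(f"{path}: malformed config ({e})") from e


def _parse_stimulus(s: dict, i: int) -> Stimulus:
    sid = str(s.get("id", f"stimulus_{i}"))
    kind = s.get("type") or s.get("kind")
    if kind == "point":
        return Stimulus.point(sid, s["center"])
    if kind == "circle":
        return Stimulus.circle(sid, s["center"], s["radius"])
    if kind == "segment":
        return Stimulus.segment(sid, s["border_a"], s["border_b"])
    raise ValidationError(f"stimulus {sid!r}: unknown type {kind!r}")


def _parse_zone(z: dict, i: int) -> Zone:
    zid = str(z.get("id", f"zone_{i}"))
    rect = z["rect"]
    if len(rect) != 4:
        raise ValidationError(f"zone {zid!r}: rect must be [x_min, y_min, x_max, y_max]")
    return Zone(zid, *(float(v) for v in rect))


# ---------------------------------------------------------------------------
# result tables

_FLOAT_FMT = "%.12g"


def write_frame_scores(scores: pd.DataFrame, path) -> None:
    """Write a per-frame score table (one row per frame per stimulus).

    Excluded frames keep empty score cells and ``valid_flag=False`` — never
    zeros, which would bias aggregated eye-use proportions.
    """
    if scores.empty:
        raise ValidationError("refusing to write an empty score table")
    cols = [c for c in FRAME_SCORE_COLUMNS if c in scores.columns]
    missing = set(FRAME_SCORE_COLUMNS) - set(cols)
    if missing:
        raise ValidationError(f"score table missing columns {sorted(missing)}")
    extra = [c for c in scores.columns if c not in FRAME_SCORE_COLUMNS]
    scores[list(FRAME_SCORE_COLUMNS) + extra].to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_frame_scores(path) -> pd.DataFrame:
    """Read a table written by :func:`write_frame_scores` (also the accepted
    format for digitized manual scoring)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FRAME_SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: score table missing columns {sorted(missing)}")
    df["frame"] = df["frame"].astype(int)
    df["stimulus_id"] = df["stimulus_id"].astype(str)
    df["valid_flag"] = df["valid_flag"].astype(bool)
    return df


def write_summary(summary: SessionSummary, path) -> None:
    """Write a session summary as a two-column key,value CSV."""
    rows: list[tuple[str, object]] = [
        ("video_id", summary.video_id),
        ("stimulus_id", summary.stimulus_id),
        ("fps", summary.fps),
        ("n_frames", summary.n_frames),
        ("n_valid", summary.n_valid),
    ]
    for col, v in summary.totals.items():
        rows.append((f"total_{col}", v))
    for col, v in summary.durations.items():
        rows.append((f"duration_{col}_s", v))
    if summary.proportions is not None:
        for col, v in summary.proportions.items():
            rows.append((f"proportion_{col}", v))
    rows.append(("laterality_index",
                 "" if summary.laterality_index is None else summary.laterality_index))
    if summary.head_path_length is not None:
        rows.append(("head_path_length_px", summary.head_path_length))
    if summary.mean_heading_change is not None:
        rows.append(("mean_heading_change_deg", summary.mean_heading_change))
    for zid, v in summary.zone_durations.items():
        rows.append((f"zone_{zid}_s", v))
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_summary(path) -> dict[str, object]:
    """Read a summary CSV back into a key -> value mapping (numeric values
    parsed as floats)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, object] = {}
    for _, row in df.iterrows():
        key, val = row["key"], row["value"]
        try:
            out[key] = float(val)
        except ValueError:
            out[key] = val if val != "" else None
    return out


def write_filter_report(report, path) -> None:
    """Export a QC report as CSV (frame, low_likelihood, distance_outlier,
    overridden, valid) followed by a commented stats block."""
    valid = report.frame_validity()
    df = pd.DataFrame({
        "frame": report.frame_index,
        "low_likelihood": report.low_likelihood,
        "distance_outlier": report.distance_outlier,
        "overridden": [report.overrides.get(int(f), "") for f in report.frame_index],
        "valid": valid,
    })
    with open(path, "w") as fh:
        fh.write(f"# likelihood_cutoff={report.likelihood_cutoff}\n")
        fh.write(f"# distance_threshold_k={report.k}\n")
        if report.stats is not None:
            for s in report.stats:
                fh.write(f"# pair={s.pair} mean={s.mean:.6f} sd={s.sd:.6f} n={s.n}\n")
        df.to_csv(fh, index=False)


def read_review_decisions(path) -> list[tuple[int, str]]:
    """Read manual review decisions from a two-column CSV (frame, decision)
    with decision in {keep, drop}."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: review file needs columns frame,decision")
    frames = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if frames.isna().any():
        raise ParseError(f"{path}: non-numeric frame in review file")
    decisions = df.iloc[:, 1].astype(str).str.strip().str.lower()
    bad = ~decisions.isin(["keep", "drop"])
    if bad.any():
        raise ValidationError(f"{path}: decisions must be keep or drop")
    return [(int(f), d) for f, d in zip(frames, decisions)]
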
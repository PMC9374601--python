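"""Stimulus geometry and per-frame visual-field score attribution.

A stimulus fixed in the image (a point, a circle, or a segment joining its
two borders) subtends, as seen from the head origin, an angular interval.
Each frame's score for a sector is the fraction of that subtended *arc*
falling inside the sector: a stimulus entirely inside one visual field
contributes 1 to that field; a stimulus straddling a boundary contributes
the arc fraction on each side (e.g. 0.75 / 0.25).  Valid scores always sum
to 1 across the six sectors; frames excluded by quality control carry
missing values instead of zeros, so that downstream eye-use proportions are
not biased toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, GeometryError, ValidationError
from .headgeom import (
    SECTOR_LABELS,
    HeadFrame,
    Sector,
    VisualFieldConfig,
    build_sectors,
    classify_angle,
    compute_head_frame,
    signed_angle_to,
    wrap_angle,
)

__all__ = [
    "Stimulus",
    "AngularInterval",
    "FieldScores",
    "SCORE_COLUMNS",
    "FRAME_SCORE_COLUMNS",
    "stimulus_interval",
    "attribute_interval",
    "score_frame",
    "score_video",
]

#: sector label -> score-table column name
SCORE_COLUMNS = {
    "FL": "frontal_left",
    "FR": "frontal_right",
    "LL": "lateral_left",
    "LR": "lateral_right",
    "BL": "blind_left",
    "BR": "blind_right",
}

#: full column order of a per-frame score table
FRAME_SCORE_COLUMNS = (
    "frame",
    "stimulus_id",
    "frontal_left",
    "frontal_right",
    "lateral_left",
    "lateral_right",
    "blind_left",
    "blind_right",
    "valid_flag",
)


@dataclass(frozen=True)
class Stimulus:
    """A stimulus fixed in image coordinates.

    kind
        ``"point"`` (center only), ``"circle"`` (center + radius in pixels)
        or ``"segment"`` (the stimulus extent defined by its two borders).
    """

    id: str
    kind: str
    center: Optional[tuple[float, float]] = None
    radius: Optional[float] = None
    border_a: Optional[tuple[float, float]] = None
    border_b: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "circle", "segment"):
            raise ValidationError(f"unknown stimulus kind {self.kind!r}")
        if self.kind in ("point", "circle") and self.center is None:
            raise ValidationError(f"stimulus {self.id!r}: {self.kind} needs a center")
        if self.kind == "circle":
            if self.radius is None or not self.radius > 0:
                raise ValidationError(f"stimulus {self.id!r}: circle radius must be > 0")
        if self.kind == "segment":
            if self.border_a is None or self.border_b is None:
                raise ValidationError(f"stimulus {self.id!r}: segment needs two borders")
            if tuple(self.border_a) == tuple(self.border_b):
                raise ValidationError(f"stimulus {self.id!r}: segment borders coincide")

    @classmethod
    def point(cls, id: str, center) -> "Stimulus":
        return cls(id=id, kind="point", center=tuple(center))

    @classmethod
    def circle(cls, id: str, center, radius: float) -> "Stimulus":
        return cls(id=id, kind="circle", center=tuple(center), radius=float(radius))

    @classmethod
    def segment(cls, id: str, border_a, border_b) -> "Stimulus":
        return cls(id=id, kind="segment", border_a=tuple(border_a), border_b=tuple(border_b))


@dataclass(frozen=True)
class AngularInterval:
    """An arc on the signed-angle circle: ``start`` in ``(-180, 180]`` and a
    non-negative ``width`` in ``[0, 360)`` degrees; may wrap across 180."""

    start: float
    width: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.width < 360.0):
            raise ValidationError(f"interval width must be in [0, 360), got {self.width}")
        object.__setattr__(self, "start", wrap_angle(self.start))


@dataclass(frozen=True)
class FieldScores:
    """Per-frame attribution of one stimulus to the six sectors.

    When ``valid``, ``values`` maps each sector label to a score in [0, 1]
    and the scores sum to 1; when not valid (frame excluded by QC) there
    are no values.
    """

    valid: bool
    values: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.valid:
            if self.values is None or set(self.values) != set(SECTOR_LABELS):
                raise ValidationError("valid FieldScores need one value per sector")
        elif self.values is not None:
            raise ValidationError("invalid FieldScores must carry no values")

    def as_array(self) -> np.ndarray:
        """Scores in canonical label order; NaN for an invalid frame."""
        if not self.valid:
            return np.full(len(SECTOR_LABELS), np.nan)
        return np.array([self.values[l] for l in SECTOR_LABELS], dtype=float)


def stimulus_interval(frame: HeadFrame, stim: Stimulus) -> AngularInterval:
    """Angular interval subtended by a stimulus as seen from the head origin.

    point   -> zero-width interval at its signed angle
    circle  -> center angle +/- arcsin(radius / distance)
    segment -> the (< 180 deg) arc spanned by the two border angles

    Raises :class:`GeometryError` when the head origin lies inside or on the
    stimulus (the subtended interval is then undefined).
    """
    if stim.kind == "point":
        return AngularInterval(signed_angle_to(frame, stim.center), 0.0)

    if stim.kind == "circle":
        c = np.asarray(stim.center, dtype=float)
        d = math.hypot(*(c - frame.origin))
        if d <= stim.radius:
            raise GeometryError(
                f"head origin inside/on circle stimulus {stim.id!r} "
                f"(distance {d:.3g} <= radius {stim.radius:.3g})"
            )
        half = math.degrees(math.asin(stim.radius / d))
        center_angle = signed_angle_to(frame, c)
        return AngularInterval(center_angle - half, 2.0 * half)

    # segment
    a = np.asarray(stim.border_a, dtype=float)
    b = np.asarray(stim.border_b, dtype=float)
    if _point_on_segment(frame.origin, a, b):
        raise GeometryError(f"head origin lies on segment stimulus {stim.id!r}")
    ang_a = signed_angle_to(frame, a)
    ang_b = signed_angle_to(frame, b)
    diff = wrap_angle(ang_b - ang_a)
    if abs(diff) == 180.0:
        raise GeometryError(
            f"segment stimulus {stim.id!r} subtends exactly 180 deg; orientation undefined"
        )
    if diff >= 0:
        return AngularInterval(ang_a, diff)
    return AngularInterval(ang_b, -diff)


def _point_on_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> bool:
    ab = b - a
    ap = p - a
    cross = ab[0] * ap[1] - ab[1] * ap[0]
    if cross != 0.0:
        return False
    t = np.dot(ap, ab) / np.dot(ab, ab)
    return 0.0 <= t <= 1.0


def attribute_interval(interval: AngularInterval, sectors: Sequence[Sector]) -> FieldScores:
    """Distribute one unit of score across sectors by fractional arc overlap.

    A zero-width interval is an indicator of its containing sector.  For a
    positive-width interval, each sector receives
    ``arc_length(interval & sector) / arc_length(interval)``.
    """
    if interval.width == 0.0:
        label = classify_angle(interval.start, sectors)
        return FieldScores(True, {s.label: 1.0 if s.label == label else 0.0 for s in sectors})

    a, w = interval.start, interval.width
    values: dict[str, float] = {}
    for s in sectors:
        ov = 0.0
        # unwrap the sector onto the covering line; a in (-180,180], a+w < 540
        for k in (0.0, 360.0):
            lo, hi = s.lo + k, s.hi + k
            ov += max(0.0, min(a + w, hi) - max(a, lo))
        values[s.label] = ov / w
    return FieldScores(True, values)


def score_frame(
    pose, stimuli: Sequence[Stimulus], cfg: VisualFieldConfig
) -> dict[str, FieldScores]:
    """Score one frame for every stimulus: head frame -> subtended interval
    -> sector attribution, independently per stimulus."""
    hf = compute_head_frame(pose)
    sectors = build_sectors(cfg)
    out: dict[str, FieldScores] = {}
    for st in stimuli:
        try:
            iv = stimulus_interval(hf, st)
        except GeometryError as e:
            raise GeometryError(f"frame {pose.frame_index}: {e}") from e
        out[st.id] = attribute_interval(iv, sectors)
    return out


def score_video(tracks, cfg, report=None) -> pd.DataFrame:
    """Score every frame of a video for every configured stimulus.

    Parameters
    ----------
    tracks : TrackTable
    cfg : SessionConfig
    report : FilterReport, optional
        Frames invalid per the report are emitted with ``valid_flag=False``
        and missing score cells.  The report must describe the same frames
        as ``tracks``.  With ``report=None`` every frame is scored.

    Returns
    -------
    DataFrame with one row per frame per stimulus, columns
    :data:`FRAME_SCORE_COLUMNS`.
    """
    if report is not None:
        if not np.array_equal(np.asarray(report.frame_index), tracks.frame_index):
            raise ConsistencyError("filter report does not describe the same frames as tracks")
        valid = report.frame_validity()
    else:
        valid = np.ones(len(tracks), dtype=bool)

    records: list[tuple] = []
    for i, pose in enumerate(tracks.iter_poses()):
        if valid[i]:
            per_stim = score_frame(pose, cfg.stimuli, cfg.field_angles)
        for st in cfg.stimuli:
            if valid[i]:
                fs = per_stim[st.id]
                records.append(
                    (pose.frame_index, st.id, *(fs.values[l] for l in SECTOR_LABELS), True)
                )
            else:
                records.append((pose.frame_index, st.id, *([np.nan] * 6), False))

    df = pd.DataFrame(records, columns=list(FRAME_SCORE_COLUMNS))
    df["frame"] = df["frame"].astype(int)
    df["valid_flag"] = df["valid_flag"].astype(bool)
    return df
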
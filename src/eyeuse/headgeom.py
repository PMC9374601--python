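"""Head-centred geometry: per-frame head frame and the angular visual-field
partition.

The animal is filmed from above and three landmarks are tracked on its head:
``leftHead`` (near the left eye), ``rightHead`` (near the right eye) and
``topHead``.  From these we reconstruct, per frame, a *head frame*: an origin
(the midpoint of the two eye landmarks), a heading (unit vector from the
origin toward ``topHead``) and a left/right sign convention.  Angles of
points in the arena are measured relative to the heading, with positive
angles on the animal's left, in degrees in ``(-180, 180]``.

The visual field of a laterally-eyed bird is partitioned into six sectors
per side of the midline: frontal left/right (``FL``/``FR``), lateral
left/right (``LL``/``LR``) and blind left/right (``BL``/``BR``).  For the
domestic chick the defaults are 15 deg frontal half-width, 135 deg lateral
width and 30 deg blind half-width per side, which tile the full circle.

The left/right sign is determined per frame from which side the ``leftHead``
landmark actually lies on, so the construction is independent of the camera
orientation and of the image y-down pixel convention, and is equivariant
under rigid motions of the scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = [
    "SECTOR_LABELS",
    "VisualFieldConfig",
    "Sector",
    "HeadFrame",
    "wrap_angle",
    "build_sectors",
    "compute_head_frame",
    "signed_angle_to",
    "classify_angle",
    "classify_angles",
]

#: Sector labels in canonical order.
SECTOR_LABELS = ("FL", "FR", "LL", "LR", "BL", "BR")

_ANGLE_SUM_TOL = 1e-9


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees to the interval ``(-180, 180]``."""
    a = math.remainder(angle, 360.0)
    # math.remainder maps to [-180, 180]; move -180 to +180
    if a <= -180.0:
        a = 180.0
    return a


@dataclass(frozen=True)
class VisualFieldConfig:
    """Per-side angular widths of the visual-field partition, in degrees.

    ``frontal_halfwidth + lateral_width + blind_halfwidth`` must equal 180
    so that the six sectors tile the full 360-degree circle.  Defaults are
    the chick values: frontal fields 15 deg wide from the midline and
    lateral fields 135 deg wide on each side, leaving a 30 deg blind
    half-sector per side behind the head.
    """

    frontal_halfwidth: float = 15.0
    lateral_width: float = 135.0
    blind_halfwidth: float = 30.0

    def __post_init__(self) -> None:
        for name in ("frontal_halfwidth", "lateral_width", "blind_halfwidth"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        total = self.frontal_halfwidth + self.lateral_width + self.blind_halfwidth
        if abs(total - 180.0) > _ANGLE_SUM_TOL:
            raise ValidationError(
                "per-side visual-field widths must sum to 180 deg "
                f"(frontal + lateral + blind = {total})"
            )


@dataclass(frozen=True)
class Sector:
    """One angular sector, a half-open interval ``[lo, hi)`` of signed
    angles in degrees (positive = animal's left).  The sole exception is
    ``BL``, which is closed at +180 so that the six sectors exactly tile
    ``(-180, 180]``."""

    label: str
    lo: float
    hi: float

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, angle: float) -> bool:
        if self.label == "BL" and angle == 180.0:
            return True
        return self.lo <= angle < self.hi


def build_sectors(cfg: VisualFieldConfig) -> tuple[Sector, ...]:
    """Build the six sectors (FL, FR, LL, LR, BL, BR) from per-side widths.

    With f = frontal half-width and l = lateral width:
    FL=[0,f), FR=[-f,0), LL=[f,f+l), LR=[-f-l,-f), BL=[f+l,180], BR=(-180,-f-l).
    """
    f = cfg.frontal_halfwidth
    l = cfg.lateral_width
    return (
        Sector("FL", 0.0, f),
        Sector("FR", -f, 0.0),
        Sector("LL", f, f + l),
        Sector("LR", -f - l, -f),
        Sector("BL", f + l, 180.0),
        Sector("BR", -180.0, -f - l),
    )


@dataclass(frozen=True)
class HeadFrame:
    """Per-frame head coordinate frame.

    origin
        Midpoint of the two eye landmarks, pixels.
    heading
        Unit vector from the origin toward the ``topHead`` landmark.
    left_sign
        +1 or -1, chosen so that the ``leftHead`` landmark has a positive
        signed angle; this absorbs the image y-down convention.
    """

    origin: np.ndarray
    heading: np.ndarray
    left_sign: int


def compute_head_frame(pose) -> HeadFrame:
    """Reconstruct the head frame of a :class:`~eyeuse.trackio.FramePose`.

    Raises :class:`GeometryError` (naming the frame) when the landmarks are
    degenerate: coincident points, ``topHead`` on the eye midpoint, or
    ``topHead`` collinear with the eye axis (left/right undefined).
    """
    left = np.asarray(pose.landmarks["leftHead"].xy, dtype=float)
    right = np.asarray(pose.landmarks["rightHead"].xy, dtype=float)
    top = np.asarray(pose.landmarks["topHead"].xy, dtype=float)
    fi = pose.frame_index

    if np.array_equal(left, right) or np.array_equal(left, top) or np.array_equal(right, top):
        raise GeometryError(f"frame {fi}: landmarks are not pairwise distinct")

    origin = 0.5 * (left + right)
    v = top - origin
    norm = math.hypot(v[0], v[1])
    if norm == 0.0:
        raise GeometryError(f"frame {fi}: topHead coincides with the eye midpoint")
    heading = v / norm

    le = left - origin
    cross = heading[0] * le[1] - heading[1] * le[0]
    if cross == 0.0:
        raise GeometryError(
            f"frame {fi}: leftHead is collinear with the heading; left/right undefined"
        )
    return HeadFrame(origin=origin, heading=heading, left_sign=1 if cross > 0 else -1)


def signed_angle_to(frame: HeadFrame, point) -> float:
    """Signed angle (degrees, in ``(-180, 180]``) from the heading to
    ``origin -> point``, positive on the animal's left.

    Raises :class:`GeometryError` if ``point`` coincides with the origin.
    """
    p = np.asarray(point, dtype=float)
    v = p - frame.origin
    if v[0] == 0.0 and v[1] == 0.0:
        raise GeometryError("point coincides with the head origin; angle undefined")
    h = frame.heading
    cross = h[0] * v[1] - h[1] * v[0]
    dot = h[0] * v[0] + h[1] * v[1]
    return wrap_angle(frame.left_sign * math.degrees(math.atan2(cross, dot)))


def _boundaries(sectors) -> tuple[np.ndarray, list[str]]:
    ordered = sorted(sectors, key=lambda s: s.lo)
    bounds = np.array([s.lo for s in ordered] + [180.0])
    labels = [s.label for s in ordered]
    return bounds, labels


def classify_angle(angle: float, sectors) -> str:
    """Label of the sector containing a signed angle in ``(-180, 180]``."""
    for s in sectors:
        if s.contains(angle):
            return s.label
    raise ValidationError(f"angle {angle} not covered by the sector partition")


def classify_angles(angles: np.ndarray, sectors) -> np.ndarray:
    """Vectorised :func:`classify_angle`: integer index into the sector
    sequence *sorted by lower bound* for each angle.  Returns indices and
    the corresponding label list as ``(idx, labels)``."""
    bounds, labels = _boundaries(sectors)
    a = np.asarray(angles, dtype=float)
    idx = np.searchsorted(bounds, a, side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)  # +180 falls into the last sector (BL)
    return idx, labels
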
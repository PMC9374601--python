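"""Two-stage frame exclusion plus the manual-review workflow.

Mistracked frames are identified in a fixed order:

1. *Likelihood filter* — a frame is flagged when any of its three landmarks
   has tracker confidence below the cut-off (default 0.95).
2. *Distance filter* — over the frames that pass stage 1, the per-frame
   Euclidean distances of the three landmark pairs (left-right, left-top,
   right-top) are summarised by mean and sample SD; a frame is then flagged
   when any pair deviates from its mean by more than k standard deviations
   (default k = 3, two-sided: gross mistracks can both stretch and collapse
   the head triangle).

Computing the distance statistics only on likelihood-passing frames keeps
gross mistracks from inflating the SD and hiding themselves.  Flags are
advisory until combined with the manual review: a ``keep`` override
revalidates a flagged frame, a ``drop`` override excludes a clean one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "PAIR_NAMES",
    "DistanceStats",
    "FilterReport",
    "likelihood_flags",
    "pair_distances",
    "distance_stats",
    "distance_outlier_flags",
    "build_filter_report",
    "apply_review",
    "sample_frames_for_review",
]

#: landmark pairs, as (name, index-into-LANDMARK_NAMES pairs)
PAIR_NAMES = ("left-right", "left-top", "right-top")
_PAIR_IDX = ((0, 2), (0, 1), (2, 1))  # LANDMARK_NAMES order: left, top, right


@dataclass(frozen=True)
class DistanceStats:
    """Mean and sample SD (n-1 denominator) of one pair's distances."""

    pair: str
    mean: float
    sd: float
    n: int


@dataclass
class FilterReport:
    """Per-frame QC flags plus the statistics that produced them.

    A frame is invalid iff (any flag is set and it is not overridden
    ``keep``) or it is overridden ``drop``.
    """

    frame_index: np.ndarray
    low_likelihood: np.ndarray
    distance_outlier: np.ndarray
    stats: Optional[tuple[DistanceStats, ...]]
    k: float
    likelihood_cutoff: float
    overrides: dict[int, str] = field(default_factory=dict)

    def frame_validity(self) -> np.ndarray:
        flagged = self.low_likelihood | self.distance_outlier
        valid = ~flagged
        if self.overrides:
            pos = {int(f): i for i, f in enumerate(self.frame_index)}
            for f, decision in self.overrides.items():
                valid[pos[int(f)]] = decision == "keep"
        return valid


def likelihood_flags(tracks, cutoff: float) -> np.ndarray:
    """Flag frames where any landmark's likelihood falls below the cut-off."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError(f"cutoff {cutoff} outside [0, 1]")
    return np.any(tracks.likelihood < cutoff, axis=1)


def pair_distances(tracks) -> np.ndarray:
    """(n, 3) Euclidean inter-landmark distances per frame, pair order
    :data:`PAIR_NAMES`."""
    out = np.empty((len(tracks), 3), dtype=float)
    for j, (a, b) in enumerate(_PAIR_IDX):
        diff = tracks.xy[:, a, :] - tracks.xy[:, b, :]
        out[:, j] = np.hypot(diff[:, 0], diff[:, 1])
    return out


def distance_stats(tracks, use_frames: Optional[np.ndarray] = None
                   ) -> tuple[DistanceStats, ...]:
    """Mean and sample SD of each pair's distances over ``use_frames``
    (a boolean mask or frame-position indices; default all frames)."""
    d = pair_distances(tracks)
    if use_frames is not None:
        d = d[np.asarray(use_frames)]
    n = d.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need at least 2 frames for distance stats, got {n}")
    return tuple(
        DistanceStats(pair=name, mean=float(d[:, j].mean()),
                      sd=float(d[:, j].std(ddof=1)), n=n)
        for j, name in enumerate(PAIR_NAMES)
    )


def distance_outlier_flags(tracks, stats: Sequence[DistanceStats], k: float,
                           atol: float = 1e-9) -> np.ndarray:
    """Flag frames where any pair distance deviates from its mean by more
    than k standard deviations (two-sided).

    ``atol`` (pixels) is a numerical floor on the deviation threshold so
    that a perfectly rigid head whose distances differ from the mean only
    by floating-point round-off is never flagged; in the sd = 0 regime a
    frame is flagged as soon as its distance differs from the mean by more
    than this floor.  At its default of 1e-9 px it is far below any
    physical displacement."""
    if not k > 0:
        raise ValidationError(f"k must be > 0, got {k}")
    d = pair_distances(tracks)
    flags = np.zeros(len(tracks), dtype=bool)
    for j, s in enumerate(stats):
        dev = np.abs(d[:, j] - s.mean)
        flags |= dev > max(k * s.sd, atol)
    return flags


def build_filter_report(tracks, cfg) -> FilterReport:
    """Run both QC stages on a video.

    Likelihood flags first; distance statistics over likelihood-passing
    frames only; distance flags applied to those frames.  If fewer than two
    frames survive stage 1 the distance stage is skipped with a warning.
    """
    cutoff = cfg.likelihood_cutoff
    k = cfg.distance_threshold_k
    low = likelihood_flags(tracks, cutoff)
    survivors = ~low
    if int(survivors.sum()) < 2:
        warnings.warn(
            "fewer than 2 frames pass the likelihood filter; distance stage skipped"
        )
        stats = None
        dist = np.zeros(len(tracks), dtype=bool)
    else:
        stats = distance_stats(tracks, survivors)
        dist = distance_outlier_flags(tracks, stats, k) & survivors
    return FilterReport(
        frame_index=tracks.frame_index.copy(),
        low_likelihood=low,
        distance_outlier=dist,
        stats=stats,
        k=k,
        likelihood_cutoff=cutoff,
    )


def apply_review(report: FilterReport, decisions: Sequence[tuple[int, str]]
                 ) -> FilterReport:
    """Record manual review decisions; returns a new report.

    Each decision is ``(frame, "keep" | "drop")``.  Re-applying the same
    decision is a no-op; a later decision for the same frame replaces the
    earlier one.  Unknown frames raise :class:`ValidationError`.
    """
    known = set(int(f) for f in report.frame_index)
    overrides = dict(report.overrides)
    for frame, decision in decisions:
        if decision not in ("keep", "drop"):
            raise ValidationError(f"decision must be keep or drop, got {decision!r}")
        if int(frame) not in known:
            raise ValidationError(f"review decision for unknown frame {frame}")
        overrides[int(frame)] = decision
    return replace(report, overrides=overrides)


def sample_frames_for_review(tracks, n: int, seed: int) -> list[int]:
    """Uniform sample of ``n`` distinct frame indices for visual inspection,
    sorted, reproducible given ``seed``.  (At least ~100 frames per subject
    is a sensible check of tracking quality.)"""
    total = len(tracks)
    if n > total:
        raise ValidationError(f"cannot sample {n} of {total} frames")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(tracks.frame_index, size=n, replace=False)
    return sorted(int(f) for f in chosen)
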
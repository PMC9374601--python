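import numpy as np
import pytest

from eyeuse.headgeom import VisualFieldConfig, build_sectors, classify_angles
from eyeuse.qc import FilterReport
from eyeuse.trackio import LANDMARK_NAMES, FramePose, Landmark, TrackTable


def make_pose(left, right, top, frame_index=0, likelihood=1.0):
    coords = {"leftHead": left, "rightHead": right, "topHead": top}
    return FramePose(
        frame_index,
        {n: Landmark(n, float(xy[0]), float(xy[1]), likelihood) for n, xy in coords.items()},
    )


def make_tracks(poses_xy, fps=25.0, likelihood=None, video_id="test"):
    """Build a TrackTable from a list of (left, right, top) coordinate
    triples; likelihood may be a scalar, or an (n, 3) array."""
    n = len(poses_xy)
    xy = np.empty((n, 3, 2), dtype=float)
    for i, (left, right, top) in enumerate(poses_xy):
        xy[i, LANDMARK_NAMES.index("leftHead")] = left
        xy[i, LANDMARK_NAMES.index("rightHead")] = right
        xy[i, LANDMARK_NAMES.index("topHead")] = top
    if likelihood is None:
        lik = np.ones((n, 3))
    else:
        lik = np.broadcast_to(np.asarray(likelihood, dtype=float), (n, 3)).copy()
    return TrackTable(video_id=video_id, fps=fps, frame_index=np.arange(n),
                      xy=xy, likelihood=lik)


def make_report(tracks, low_likelihood=None, distance_outlier=None,
                k=3.0, cutoff=0.95):
    n = len(tracks)
    return FilterReport(
        frame_index=tracks.frame_index.copy(),
        low_likelihood=np.zeros(n, bool) if low_likelihood is None
        else np.asarray(low_likelihood, bool),
        distance_outlier=np.zeros(n, bool) if distance_outlier is None
        else np.asarray(distance_outlier, bool),
        stats=None, k=k, likelihood_cutoff=cutoff,
    )


def wrap_np(x):
    a = np.remainder(np.asarray(x, dtype=float) + 180.0, 360.0) - 180.0
    a = np.where(a == -180.0, 180.0, a)
    return a


def dense_attribution(interval, sectors, n=100_000):
    """Independent sampling oracle for arc attribution: classify n equally
    spaced angles inside the interval and return sector frequencies."""
    offsets = (np.arange(n) + 0.5) / n * interval.width
    angles = wrap_np(interval.start + offsets)
    idx, labels = classify_angles(angles, sectors)
    counts = np.bincount(idx, minlength=len(labels)).astype(float) / n
    return {label: counts[i] for i, label in enumerate(labels)}


def random_field_config(rng):
    f, l, b = rng.dirichlet((1.0, 1.0, 1.0)) * 177.0 + 1.0
    return VisualFieldConfig(frontal_halfwidth=f, lateral_width=l,
                             blind_halfwidth=180.0 - f - l)


@pytest.fixture
def canonical_pose():
    """Eyes at (-1,0)/(1,0), topHead at (0,1): origin (0,0), heading (0,1),
    animal's left toward -x."""
    return make_pose((-1.0, 0.0), (1.0, 0.0), (0.0, 1.0))


@pytest.fixture
def chick_cfg():
    return VisualFieldConfig()


@pytest.fixture
def chick_sectors(chick_cfg):
    return build_sectors(chick_cfg)
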
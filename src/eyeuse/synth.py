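"""Ground-truthed synthetic sessions in the exact input dialect.

The generator emulates a head-restrained viewing trial: a bird's head near
a fixed position inspecting a stimulus placed some distance away, filmed
from above.  The noise-free head pose follows a wrapped Gaussian random
walk in heading and a Gaussian random walk in position; the three landmarks
are then placed on a rigid head template (fixed eye separation and
origin-to-topHead length) and perturbed by isotropic Gaussian noise.
Outlier frames — emulating gross mistracks where the tracker teleports a
label — displace one uniformly chosen landmark by a fixed magnitude in a
random direction and give it a low likelihood.

Ground-truth sector scores are computed from the *noise-free* poses with
the same scoring code, so a noise-free, outlier-free session reproduces
them exactly.  All randomness comes from one ``numpy.random.default_rng``
(PCG64) seed; outputs are bit-reproducible for a given seed.

Defaults mirror the validation experiment's scale: eye separation 58 px,
~25 fps for ~30 s, and a circular stimulus of radius 29 px placed 580 px
away (a 2-cm-diameter cylinder 20 cm from the head at ~29 px/cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fieldscore import Stimulus, score_video
from .headgeom import VisualFieldConfig
from .trackio import SessionConfig, TrackTable, LANDMARK_NAMES

__all__ = ["SynthParams", "generate_session", "write_dlc_csv", "default_stimulus"]


def default_stimulus() -> Stimulus:
    """The default synthetic stimulus: a 29-px-radius circle 580 px in
    front of the default start position."""
    return Stimulus.circle("cylinder", center=(640.0, 70.0), radius=29.0)


@dataclass
class SynthParams:
    """Parameters of one synthetic session (pixels, degrees, frames)."""

    n_frames: int = 750
    fps: float = 25.0
    eye_separation: float = 58.0
    head_length: float = 40.0
    heading_walk_sd: float = 3.0       # deg / frame
    position_walk_sd: float = 1.0      # px / frame
    landmark_noise_sd: float = 1.0     # px, isotropic per landmark
    outlier_rate: float = 0.02
    outlier_displacement: float = 60.0  # px
    likelihood_good: tuple[float, float] = (0.99, 0.01)   # (mean, spread)
    likelihood_bad: tuple[float, float] = (0.6, 0.15)
    stimuli: list[Stimulus] = field(default_factory=lambda: [default_stimulus()])
    start_position: tuple[float, float] = (640.0, 650.0)
    start_heading: Optional[float] = None  # deg; default: toward first stimulus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 0:
            raise ValidationError("n_frames must be >= 0")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValidationError("outlier_rate must be in [0, 1]")
        for name in ("fps", "eye_separation", "head_length"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("heading_walk_sd", "position_walk_sd", "landmark_noise_sd",
                     "outlier_displacement"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.stimuli:
            raise ValidationError("need at least one stimulus")


def _clipped_normal(rng, mean: float, spread: float, size) -> np.ndarray:
    return np.clip(rng.normal(mean, spread, size=size), 0.0, 1.0)


def generate_session(p: SynthParams
                     ) -> tuple[TrackTable, pd.DataFrame, np.ndarray]:
    """Generate one session.

    Returns ``(tracks, ground_truth, outlier_flags)``: the noisy
    TrackTable, the per-frame ground-truth score table computed from the
    noise-free poses (every frame valid), and the boolean array of frames
    that received an injected outlier.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_frames

    # --- noise-free trajectory (draw order is part of the contract) ------
    if p.start_heading is None:
        s0 = np.asarray(p.stimuli[0].center if p.stimuli[0].center is not None
                        else p.stimuli[0].border_a, dtype=float)
        d = s0 - np.asarray(p.start_position, dtype=float)
        phi0 = np.degrees(np.arctan2(d[1], d[0]))
    else:
        phi0 = p.start_heading
    phi = phi0 + np.concatenate([[0.0], np.cumsum(rng.normal(0.0, p.heading_walk_sd,
                                                             max(n - 1, 0)))])
    pos = np.asarray(p.start_position, dtype=float) + np.concatenate(
        [np.zeros((1, 2)), np.cumsum(rng.normal(0.0, p.position_walk_sd,
                                                (max(n - 1, 0), 2)), axis=0)]
    )[:n] if n else np.zeros((0, 2))

    rad = np.radians(phi[:n]) if n else np.zeros(0)
    h = np.stack([np.cos(rad), np.sin(rad)], axis=1)          # heading
    perp = np.stack([-np.sin(rad), np.cos(rad)], axis=1)      # +90 deg from h

    clean = np.empty((n, 3, 2), dtype=float)
    clean[:, LANDMARK_NAMES.index("leftHead"), :] = pos + 0.5 * p.eye_separation * perp
    clean[:, LANDMARK_NAMES.index("rightHead"), :] = pos - 0.5 * p.eye_separation * perp
    clean[:, LANDMARK_NAMES.index("topHead"), :] = pos + p.head_length * h

    # --- measurement noise, outliers, likelihoods ------------------------
    noisy = clean + rng.normal(0.0, p.landmark_noise_sd, size=clean.shape)
    outlier = rng.random(n) < p.outlier_rate
    which = rng.integers(0, 3, size=n)
    direction = rng.uniform(0.0, 2.0 * np.pi, size=n)
    lik = _clipped_normal(rng, *p.likelihood_good, (n, 3))
    lik_bad = _clipped_normal(rng, *p.likelihood_bad, n)

    for i in np.flatnonzero(outlier):
        j = which[i]
        noisy[i, j, 0] += p.outlier_displacement * np.cos(direction[i])
        noisy[i, j, 1] += p.outlier_displacement * np.sin(direction[i])
        lik[i, j] = lik_bad[i]

    tracks = TrackTable(video_id=f"synthetic_seed{p.seed}", fps=p.fps,
                        frame_index=np.arange(n), xy=noisy, likelihood=lik)

    # --- ground truth from the noise-free poses --------------------------
    clean_tracks = TrackTable(video_id=tracks.video_id, fps=p.fps,
                              frame_index=np.arange(n),
                              xy=clean, likelihood=np.ones((n, 3)))
    cfg = SessionConfig(field_angles=VisualFieldConfig(), stimuli=list(p.stimuli),
                        fps=p.fps)
    ground_truth = score_video(clean_tracks, cfg)

    return tracks, ground_truth, outlier


def write_dlc_csv(tracks: TrackTable, path, scorer: str = "synthetic") -> None:
    """Write a TrackTable in the three-row-header tracking dialect, the
    exact format accepted by :func:`eyeuse.trackio.read_dlc_tracks`."""
    cols = pd.MultiIndex.from_tuples(
        [(scorer, name, coord) for name in LANDMARK_NAMES
         for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.empty((len(tracks), 9), dtype=float)
    for j, _ in enumerate(LANDMARK_NAMES):
        data[:, 3 * j] = tracks.xy[:, j, 0]
        data[:, 3 * j + 1] = tracks.xy[:, j, 1]
        data[:, 3 * j + 2] = tracks.likelihood[:, j]
    df = pd.DataFrame(data, index=pd.Index(tracks.frame_index, name=None), columns=cols)
    df.to_csv(path)


def params_dict(p: SynthParams) -> dict:
    """JSON/YAML-serialisable echo of the parameters actually used."""
    d = asdict(p)
    d["stimuli"] = [
        {k: v for k, v in asdict(s).items() if v is not None} for s in p.stimuli
    ]
    return d
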
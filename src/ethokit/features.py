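"""Per-frame kinematic features and windowed summary statistics.

The base feature set is fixed in-code so that exported classifiers can embed
the exact list of column names they were trained on:

* 66 pairwise keypoint distances (pixels);
* 12 per-keypoint speeds (pixels/second, central differences scaled by fps,
  one-sided at the sequence boundaries);
* centroid speed (pixels/second);
* body-axis heading, the angle of the base-neck -> base-tail vector
  (radians), and its angular velocity (radians/second, computed on the
  unwrapped heading);
* 8 internal joint angles (radians at the middle keypoint of each triple).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .pose import PoseSequence

__all__ = [
    "FeatureMatrix",
    "frame_features",
    "window_features",
    "WINDOW_STATS",
    "JOINT_ANGLE_TRIPLES",
]

#: statistics appended per base feature by :func:`window_features`
WINDOW_STATS = ("mean", "std", "min", "max", "median")

#: (a, b, c) triples: the angle is measured at b between rays b->a and b->c
JOINT_ANGLE_TRIPLES: tuple[tuple[str, str, str], ...] = (
    ("nose", "base_neck", "mid_spine"),
    ("base_neck", "mid_spine", "base_tail"),
    ("left_forepaw", "base_neck", "mid_spine"),
    ("right_forepaw", "base_neck", "mid_spine"),
    ("left_hind_paw", "base_tail", "mid_spine"),
    ("right_hind_paw", "base_tail", "mid_spine"),
    ("mid_spine", "base_tail", "mid_tail"),
    ("base_tail", "mid_tail", "tip_tail"),
)


@dataclass
class FeatureMatrix:
    """Frame x feature array with named columns.

    ``window_size`` is 0 for a per-frame matrix and records the ``w`` used
    for a windowed one.  ``valid_mask`` flags frames usable for training and
    prediction (pose gaps propagate here).
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    fps: float
    window_size: int = 0
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = tuple(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (frames x features)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} names for {self.values.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.values.shape[0],):
                raise ValueError("valid_mask length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.feature_names))

    def to_csv(self, path) -> str:
        self.to_dataframe().to_csv(path, index=False)
        return str(path)


def _derivative(x: np.ndarray, fps: float) -> np.ndarray:
    """Central difference along axis 0, one-sided at the edges, scaled to /s."""
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / 2.0
    d[0] = x[1] - x[0]
    d[-1] = x[-1] - x[-2]
    return d * fps


def _angle_at(b_to_a: np.ndarray, b_to_c: np.ndarray) -> np.ndarray:
    dot = (b_to_a * b_to_c).sum(axis=1)
    na = np.linalg.norm(b_to_a, axis=1)
    nc = np.linalg.norm(b_to_c, axis=1)
    denom = np.where(na * nc == 0, 1.0, na * nc)
    return np.arccos(np.clip(dot / denom, -1.0, 1.0))


def frame_features(seq: PoseSequence, valid_mask: np.ndarray | None = None) -> FeatureMatrix:
    """Compute the fixed per-frame feature set from a pose sequence.

    Parameters
    ----------
    seq : PoseSequence
        Input keypoints; must span at least 2 frames (velocities are
        undefined otherwise).
    valid_mask : ndarray of bool, optional
        Per-frame validity (e.g. from gap interpolation); stored on the
        result and honored by :func:`window_features`.
    """
    if seq.n_frames < 2:
        raise ValueError("frame_features requires at least 2 frames (velocities)")
    names = list(seq.keypoint_names)
    idx = {n: i for i, n in enumerate(names)}
    pts = seq.keypoints  # (n, k, 2)

    cols: list[np.ndarray] = []
    colnames: list[str] = []

    for i, j in combinations(range(len(names)), 2):
        cols.append(np.linalg.norm(pts[:, i] - pts[:, j], axis=1))
        colnames.append(f"dist_{names[i]}_{names[j]}")

    vel = _derivative(pts, seq.fps)  # (n, k, 2) px/s
    for i, n in enumerate(names):
        cols.append(np.linalg.norm(vel[:, i], axis=1))
        colnames.append(f"speed_{n}")

    centroid = pts.mean(axis=1)
    cols.append(np.linalg.norm(_derivative(centroid, seq.fps), axis=1))
    colnames.append("speed_centroid")

    axis_vec = pts[:, idx["base_tail"]] - pts[:, idx["base_neck"]]
    heading = np.arctan2(axis_vec[:, 1], axis_vec[:, 0])
    cols.append(heading)
    colnames.append("heading")
    cols.append(_derivative(np.unwrap(heading), seq.fps))
    colnames.append("angular_velocity")

    for a, b, c in JOINT_ANGLE_TRIPLES:
        cols.append(_angle_at(pts[:, idx[a]] - pts[:, idx[b]], pts[:, idx[c]] - pts[:, idx[b]]))
        colnames.append(f"angle_{a}_{b}_{c}")

    return FeatureMatrix(
        np.column_stack(cols),
        tuple(colnames),
        fps=seq.fps,
        window_size=0,
        valid_mask=valid_mask,
    )


def window_features(base: FeatureMatrix, w: int) -> FeatureMatrix:
    """Append windowed summary statistics over frames ``[t-w, t+w]``.

    For every base feature the mean, standard deviation (population, ddof=0),
    min, max and median over the window are appended.  Windows clamp at the
    sequence boundaries so every frame keeps a row.  Frames flagged invalid
    in ``base.valid_mask`` are excluded from the window statistics; a window
    with no valid frame yields NaN statistics for that frame.

    ``w = 0`` reproduces the base values for all five statistics (std 0).
    """
    if w < 0:
        raise ValueError(f"window size must be non-negative, got {w}")
    df = base.to_dataframe()
    df_masked = df.where(pd.Series(base.valid_mask, index=df.index), other=np.nan)
    roll = df_masked.rolling(window=2 * w + 1, center=True, min_periods=1)

    stat_frames = {
        "mean": roll.mean(),
        "std": roll.std(ddof=0),
        "min": roll.min(),
        "max": roll.max(),
        "median": roll.median(),
    }
    pieces = [df]
    colnames = list(base.feature_names)
    for stat in WINDOW_STATS:
        sdf = stat_frames[stat]
        sdf.columns = [f"{c}__w{w}_{stat}" for c in df.columns]
        pieces.append(sdf)
        colnames.extend(sdf.columns)
    out = pd.concat(pieces, axis=1)
    return FeatureMatrix(
        out.to_numpy(),
        tuple(colnames),
        fps=base.fps,
        window_size=w,
        valid_mask=base.valid_mask.copy(),
    )
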
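"""Pose-keypoint sequences: HDF5 I/O, validation, and gap interpolation.

File dialect
------------
A pose file is an HDF5 file with a single group ``/poseest`` containing

* ``points`` — float or unsigned int, shape ``(n_frames, 12, 2)``, pixel
  coordinates ``(x, y)`` with the origin at the top-left of the image,
  x rightward, y downward;
* ``confidence`` — float, shape ``(n_frames, 12)``, values in ``[0, 1]``;

and group attributes ``fps`` (frames per second) and ``keypoint_names``
(ordered list of 12 strings).  Frame indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "KEYPOINT_NAMES",
    "N_KEYPOINTS",
    "PoseSequence",
    "PoseFormatError",
    "PoseQualityReport",
    "read_pose",
    "write_pose",
    "validate_pose",
    "interpolate_low_confidence",
]

#: Documented ordering of the 12 tracked body parts.
KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_ear",
    "right_ear",
    "base_neck",
    "left_forepaw",
    "right_forepaw",
    "mid_spine",
    "left_hind_paw",
    "right_hind_paw",
    "base_tail",
    "mid_tail",
    "tip_tail",
)

N_KEYPOINTS = len(KEYPOINT_NAMES)

_POSE_GROUP = "poseest"
_POINTS_DSET = f"{_POSE_GROUP}/points"
_CONF_DSET = f"{_POSE_GROUP}/confidence"


class PoseFormatError(ValueError):
    """Raised when a pose file or sequence violates the dialect."""


@dataclass
class PoseSequence:
    """Per-frame keypoint coordinates and confidences for one video.

    Attributes
    ----------
    keypoints : ndarray, shape (n_frames, 12, 2)
        Pixel coordinates, ``(x, y)`` per keypoint.
    confidence : ndarray, shape (n_frames, 12)
        Detection confidence in ``[0, 1]``.
    fps : float
        Frame rate in frames per second.
    keypoint_names : tuple of str
        Ordered keypoint labels; defaults to :data:`KEYPOINT_NAMES`.
    """

    keypoints: np.ndarray
    confidence: np.ndarray
    fps: float = 30.0
    keypoint_names: tuple[str, ...] = field(default=KEYPOINT_NAMES)

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64)
        self.confidence = np.asarray(self.confidence, dtype=np.float64)
        self.keypoint_names = tuple(self.keypoint_names)
        if self.keypoints.ndim != 3 or self.keypoints.shape[2] != 2:
            raise PoseFormatError(
                f"keypoints must have shape (n_frames, k, 2), got {self.keypoints.shape}"
            )
        if self.confidence.shape != self.keypoints.shape[:2]:
            raise PoseFormatError(
                "confidence shape "
                f"{self.confidence.shape} does not match keypoints "
                f"{self.keypoints.shape[:2]}"
            )
        if len(self.keypoint_names) != self.keypoints.shape[1]:
            raise PoseFormatError(
                f"{len(self.keypoint_names)} keypoint names for "
                f"{self.keypoints.shape[1]} keypoints"
            )
        if self.keypoints.shape[0] < 1:
            raise PoseFormatError("a pose sequence needs at least one frame")
        if not np.isfinite(self.keypoints).all():
            raise PoseFormatError("keypoints contain non-finite coordinates")
        if (self.keypoints < 0).any():
            raise PoseFormatError("keypoints contain negative pixel coordinates")
        if ((self.confidence < 0) | (self.confidence > 1)).any():
            raise PoseFormatError("confidence values outside [0, 1]")
        if not self.fps > 0:
            raise PoseFormatError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.keypoints.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.keypoints.shape[1]


def read_pose(path) -> PoseSequence:
    """Read a pose file in the documented HDF5 dialect.

    Raises
    ------
    PoseFormatError
        If a required dataset is missing, shapes disagree, or confidences
        fall outside ``[0, 1]``.  The message names the offending dataset.
    """
    with h5py.File(path, "r") as f:
        if _POSE_GROUP not in f:
            raise PoseFormatError(f"missing group '/{_POSE_GROUP}' in {path}")
        grp = f[_POSE_GROUP]
        for name in ("points", "confidence"):
            if name not in grp:
                raise PoseFormatError(f"missing dataset '/{_POSE_GROUP}/{name}' in {path}")
        points = np.asarray(grp["points"], dtype=np.float64)
        conf = np.asarray(grp["confidence"], dtype=np.float64)
        fps = float(grp.attrs.get("fps", 30.0))
        names = grp.attrs.get("keypoint_names")
        if names is None:
            names = KEYPOINT_NAMES
        else:
            names = tuple(n.decode() if isinstance(n, bytes) else str(n) for n in names)
    if points.ndim != 3 or points.shape[2] != 2:
        raise PoseFormatError(
            f"dataset '/{_POINTS_DSET}' has shape {points.shape}, expected (n, k, 2)"
        )
    if conf.shape != points.shape[:2]:
        raise PoseFormatError(
            f"dataset '/{_CONF_DSET}' has shape {conf.shape}, expected {points.shape[:2]}"
        )
    if ((conf < 0) | (conf > 1)).any():
        raise PoseFormatError(f"dataset '/{_CONF_DSET}' has values outside [0, 1]")
    return PoseSequence(points, conf, fps=fps, keypoint_names=names)


def write_pose(seq: PoseSequence, path) -> str:
    """Write ``seq`` to ``path`` in the documented dialect; returns the path."""
    with h5py.File(path, "w") as f:
        grp = f.create_group(_POSE_GROUP)
        grp.create_dataset("points", data=seq.keypoints.astype(np.float64))
        grp.create_dataset("confidence", data=seq.confidence.astype(np.float64))
        grp.attrs["fps"] = float(seq.fps)
        grp.attrs["keypoint_names"] = [str(n) for n in seq.keypoint_names]
    return str(path)


@dataclass
class PoseQualityReport:
    """Coverage summary produced by :func:`validate_pose`."""

    min_confidence: float
    keypoint_coverage: np.ndarray  # per keypoint, fraction of frames >= threshold
    frame_valid: np.ndarray  # per frame, True if all keypoints >= threshold
    overall_coverage: float  # fraction of (frame, keypoint) cells >= threshold

    def as_dict(self) -> dict:
        return {
            "min_confidence": self.min_confidence,
            "keypoint_coverage": self.keypoint_coverage.tolist(),
            "frame_valid_fraction": float(self.frame_valid.mean()),
            "overall_coverage": self.overall_coverage,
        }


def validate_pose(seq: PoseSequence, min_confidence: float = 0.3) -> PoseQualityReport:
    """Report pose coverage at a confidence threshold (report-only, no errors)."""
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must be in [0, 1]")
    ok = seq.confidence >= min_confidence
    return PoseQualityReport(
        min_confidence=min_confidence,
        keypoint_coverage=ok.mean(axis=0),
        frame_valid=ok.all(axis=1),
        overall_coverage=float(ok.mean()),
    )


def interpolate_low_confidence(
    seq: PoseSequence, min_confidence: float = 0.3, max_gap: int = 5
) -> tuple[PoseSequence, np.ndarray]:
    """Fill short low-confidence gaps by linear interpolation.

    Keypoint coordinates with confidence below ``min_confidence`` are linearly
    interpolated across runs of at most ``max_gap`` frames (using the nearest
    confident frames on each side).  Longer runs, and runs touching the
    sequence boundary, are left in place and the affected frames are marked
    invalid for downstream feature extraction.

    Returns
    -------
    (PoseSequence, ndarray)
        The repaired sequence and a boolean per-frame validity mask.
    """
    n, k = seq.confidence.shape
    pts = seq.keypoints.copy()
    frame_valid = np.ones(n, dtype=bool)
    for j in range(k):
        low = seq.confidence[:, j] < min_confidence
        if not low.any():
            continue
        # run-length encode the low-confidence stretches
        idx = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
        for start, stop in zip(idx[::2], idx[1::2]):  # [start, stop) is a low run
            gap = stop - start
            if gap <= max_gap and start > 0 and stop < n:
                left, right = start - 1, stop
                t = np.arange(1, gap + 1) / (gap + 1)
                pts[start:stop, j, :] = (
                    (1 - t)[:, None] * pts[left, j, :] + t[:, None] * pts[right, j, :]
                )
            else:
                frame_valid[start:stop] = False
    repaired = PoseSequence(
        pts, seq.confidence, fps=seq.fps, keypoint_names=seq.keypoint_names
    )
    return repaired, frame_valid
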
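"""Frame-level behavior labels, bout intervals, and stitch/filter post-processing."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIOR",
    "NOT_BEHAVIOR",
    "UNLABELED",
    "Ethogram",
    "Bout",
    "bouts_from_frames",
    "frames_from_bouts",
    "stitch_bouts",
    "filter_bouts",
    "read_ethogram_csv",
    "write_ethogram_csv",
    "read_bouts_json",
    "write_bouts_json",
]

BEHAVIOR = 1
NOT_BEHAVIOR = 0
UNLABELED = -1


class Bout(NamedTuple):
    """Contiguous behavior interval, 0-based inclusive frame indices."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Ethogram:
    """Per-frame ternary label track for one behavior in one video.

    ``labels`` take values 1 (behavior), 0 (not behavior) and -1 (unlabeled);
    ``probabilities``, when present, give the per-frame behavior probability
    in [0, 1] (NaN allowed for frames without a score).
    """

    labels: np.ndarray
    probabilities: np.ndarray | None = None
    fps: float = 30.0
    behavior_name: str = "behavior"
    source: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D array")
        bad = ~np.isin(self.labels, (BEHAVIOR, NOT_BEHAVIOR, UNLABELED))
        if bad.any():
            raise ValueError(f"labels contain values outside {{1, 0, -1}} at {np.flatnonzero(bad)[:5]}")
        if self.probabilities is not None:
            self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
            if self.probabilities.shape != self.labels.shape:
                raise ValueError("probabilities length must match labels")
            p = self.probabilities[~np.isnan(self.probabilities)]
            if ((p < 0) | (p > 1)).any():
                raise ValueError("probabilities outside [0, 1]")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def behavior_mask(self) -> np.ndarray:
        return self.labels == BEHAVIOR

    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED


def bouts_from_frames(e: Ethogram) -> list[Bout]:
    """Extract maximal runs of behavior frames as sorted, disjoint bouts.

    Unlabeled frames break runs exactly like not-behavior frames.
    """
    x = (e.labels == BEHAVIOR).view(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], x, [0]))))
    return [Bout(int(s), int(t - 1)) for s, t in zip(edges[::2], edges[1::2])]


def _check_sorted_disjoint(bouts: Sequence[Bout]) -> None:
    prev_end = -1
    for b in bouts:
        if b.start > b.end or b.start < 0:
            raise ValueError(f"invalid bout {b}")
        if b.start <= prev_end:
            raise ValueError(f"bouts unsorted or overlapping at {b}")
        prev_end = b.end


def frames_from_bouts(
    bouts: Sequence[Bout], n_frames: int, fps: float = 30.0, behavior_name: str = "behavior"
) -> Ethogram:
    """Render sorted disjoint bouts as a binary ethogram of ``n_frames`` frames."""
    _check_sorted_disjoint([Bout(*b) for b in bouts])
    labels = np.zeros(n_frames, dtype=np.int8)
    for b in bouts:
        if b[1] >= n_frames:
            raise ValueError(f"bout {tuple(b)} exceeds n_frames={n_frames}")
        labels[b[0] : b[1] + 1] = BEHAVIOR
    return Ethogram(labels, fps=fps, behavior_name=behavior_name)


def stitch_bouts(bouts: Sequence[Bout], gap_threshold: int) -> list[Bout]:
    """Merge neighboring bouts separated by a gap strictly below the threshold.

    The gap between consecutive bouts is the count of non-behavior frames
    between them (``start_next - end_prev - 1``).  Merging is transitive:
    chains of close bouts collapse into one.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be non-negative")
    bouts = [Bout(*b) for b in bouts]
    _check_sorted_disjoint(bouts)
    if not bouts:
        return []
    merged = [bouts[0]]
    for b in bouts[1:]:
        gap = b.start - merged[-1].end - 1
        if gap < gap_threshold:
            merged[-1] = Bout(merged[-1].start, b.end)
        else:
            merged.append(b)
    return merged


def filter_bouts(bouts: Sequence[Bout], min_length: int) -> list[Bout]:
    """Retain bouts of length at least ``min_length`` frames."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [Bout(*b) for b in bouts if b[1] - b[0] + 1 >= min_length]


# ---------------------------------------------------------------------------
# serialization

def write_ethogram_csv(e: Ethogram, path) -> str:
    df = pd.DataFrame({"frame": np.arange(e.n_frames), "label": e.labels})
    if e.probabilities is not None:
        df["probability"] = e.probabilities
    df.to_csv(path, index=False)
    return str(path)


def read_ethogram_csv(path, fps: float = 30.0, behavior_name: str = "behavior") -> Ethogram:
    df = pd.read_csv(path)
    probs = df["probability"].to_numpy() if "probability" in df.columns else None
    return Ethogram(
        df["label"].to_numpy(), probabilities=probs, fps=fps, behavior_name=behavior_name
    )


def write_bouts_json(bouts: Sequence[Bout], path) -> str:
    with open(path, "w") as fh:
        json.dump([{"start": int(b[0]), "end": int(b[1])} for b in bouts], fh)
    return str(path)


def read_bouts_json(path) -> list[Bout]:
    with open(path) as fh:
        recs = json.load(fh)
    return [Bout(int(r["start"]), int(r["end"])) for r in recs]
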
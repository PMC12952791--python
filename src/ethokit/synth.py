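"""Seeded synthetic-data generators: scripted pose sequences with ground-truth
ethograms, annotator-pair label noise, and strain panels with known genetic
architecture.

Every generator is a pure function of its parameters and the seed.  The
kinematic generators are deliberately simple rigid-body models: they exist to
make the scripted behaviors separable in the documented feature space, not to
be biomechanically realistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import BEHAVIOR, Bout, Ethogram
from .genetics import GenotypeMatrix
from .pose import KEYPOINT_NAMES, PoseSequence

__all__ = [
    "BehaviorScript",
    "AnnotatorNoise",
    "synth_pose",
    "synth_annotator_pair",
    "synth_panel",
]

#: rigid template in body coordinates (x along the body axis, nose positive)
_TEMPLATE = {
    "nose": (62.0, 0.0),
    "left_ear": (50.0, -12.0),
    "right_ear": (50.0, 12.0),
    "base_neck": (40.0, 0.0),
    "left_forepaw": (28.0, -16.0),
    "right_forepaw": (28.0, 16.0),
    "mid_spine": (0.0, 0.0),
    "left_hind_paw": (-18.0, -18.0),
    "right_hind_paw": (-18.0, 18.0),
    "base_tail": (-36.0, 0.0),
    "mid_tail": (-62.0, 0.0),
    "tip_tail": (-90.0, 0.0),
}

_ARENA = 800.0  # px, square arena
_MARGIN = 110.0


@dataclass
class BehaviorScript:
    """Parameters of one scripted behavior alternating with idle.

    ``kind`` selects the kinematic generator; ``bout_frames`` and
    ``gap_frames`` are inclusive uniform ranges for bout and inter-bout gap
    lengths.  Oscillation frequencies must respect Nyquist (< fps / 2).
    """

    name: str = "turn_left"
    kind: str = "turn_left"
    bout_frames: tuple[int, int] = (30, 90)
    gap_frames: tuple[int, int] = (60, 180)
    angular_speed: float = 2.5  # rad/s during turn bouts
    osc_freq: float = 7.0  # Hz, groom oscillation
    osc_amp: float = 10.0  # px
    jitter_px: float = 2.0  # per-keypoint gaussian noise

    def __post_init__(self) -> None:
        if self.kind not in ("turn_left", "turn_right", "groom", "rear_proxy", "idle"):
            raise ValueError(f"unknown kinematic generator {self.kind!r}")
        if self.bout_frames[0] < 1 or self.bout_frames[0] > self.bout_frames[1]:
            raise ValueError("bout_frames must be a valid range with minimum >= 1")
        if self.gap_frames[0] < 1 or self.gap_frames[0] > self.gap_frames[1]:
            raise ValueError("gap_frames must be a valid range with minimum >= 1")


@dataclass
class AnnotatorNoise:
    """Label-noise model for one annotator.

    ``dilation`` extends (positive) or erodes (negative) every bout boundary
    by that many frames; ``jitter_sd`` adds gaussian jitter to each boundary;
    ``false_bout_rate`` is the expected number of spurious short bouts per
    frame; ``missed_bout_probability`` drops whole bouts.
    """

    dilation: int = 0
    jitter_sd: float = 0.0
    false_bout_rate: float = 0.0
    false_bout_length: tuple[int, int] = (1, 3)
    missed_bout_probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missed_bout_probability <= 1.0:
            raise ValueError("missed_bout_probability must be in [0, 1]")
        if self.false_bout_rate < 0:
            raise ValueError("false_bout_rate must be non-negative")
        if self.false_bout_length[0] < 1 or self.false_bout_length[0] > self.false_bout_length[1]:
            raise ValueError("false_bout_length must be a valid range with minimum >= 1")


def _schedule_bouts(
    rng: np.random.Generator, script: BehaviorScript, n_frames: int
) -> list[Bout]:
    """Semi-Markov alternation of gaps and bouts, starting with a gap."""
    bouts: list[Bout] = []
    t = int(rng.integers(script.gap_frames[0], script.gap_frames[1] + 1))
    while t < n_frames:
        length = int(rng.integers(script.bout_frames[0], script.bout_frames[1] + 1))
        end = min(t + length - 1, n_frames - 1)
        bouts.append(Bout(t, end))
        t = end + 1 + int(rng.integers(script.gap_frames[0], script.gap_frames[1] + 1))
    return bouts


def synth_pose(
    script: BehaviorScript, n_frames: int, fps: float = 30.0, seed: int = 0
) -> tuple[PoseSequence, Ethogram]:
    """Generate a scripted pose sequence and its ground-truth ethogram.

    Idle frames drift slowly (small random-walk heading, slow forward
    locomotion); turn bouts rotate the body axis at the scripted angular
    speed; groom bouts freeze the centroid and oscillate nose and forepaws
    at the scripted frequency; rear_proxy bouts contract the body axis.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    if script.kind == "groom" and script.osc_freq >= fps / 2:
        raise ValueError(
            f"oscillation frequency {script.osc_freq} Hz violates Nyquist at {fps} fps"
        )
    rng = np.random.default_rng(seed)
    bouts = [] if script.kind == "idle" else _schedule_bouts(rng, script, n_frames)
    in_bout = np.zeros(n_frames, dtype=bool)
    for b in bouts:
        in_bout[b.start : b.end + 1] = True

    template = np.array([_TEMPLATE[k] for k in KEYPOINT_NAMES])  # (12, 2)
    # body heading (the axis orientation) and travel bearing are decoupled so
    # that wall avoidance never injects angular-velocity signal into idle
    heading = rng.uniform(0, 2 * np.pi)
    bearing = rng.uniform(0, 2 * np.pi)
    center = np.array([rng.uniform(_MARGIN, _ARENA - _MARGIN) for _ in range(2)])
    turn_sign = -1.0 if script.kind == "turn_left" else 1.0
    dt = 1.0 / fps

    pts = np.empty((n_frames, len(KEYPOINT_NAMES), 2))
    for t in range(n_frames):
        local = template.copy()
        if in_bout[t]:
            if script.kind in ("turn_left", "turn_right"):
                heading += turn_sign * script.angular_speed * dt
                speed = 10.0  # px/s, slow drift while turning
            elif script.kind == "groom":
                speed = 0.0
                osc = script.osc_amp * np.sin(2 * np.pi * script.osc_freq * t * dt)
                for name in ("nose", "left_forepaw", "right_forepaw"):
                    local[KEYPOINT_NAMES.index(name), 1] += osc
                # re-center so the oscillation leaves the body centroid still
                local -= local.mean(axis=0) - template.mean(axis=0)
            elif script.kind == "rear_proxy":
                speed = 0.0
                local[:, 0] *= 0.55  # body-axis contraction stands in for rearing
            else:  # pragma: no cover - idle bouts never scheduled
                speed = 0.0
        else:
            heading += rng.normal(0.0, 0.01) * dt ** 0.5  # slight heading wander
            bearing += rng.normal(0.0, 0.3) * dt ** 0.5
            speed = 40.0
        center = center + speed * dt * np.array([np.cos(bearing), np.sin(bearing)])
        # reflect the travel bearing off arena walls
        for d in range(2):
            if center[d] < _MARGIN:
                center[d] = 2 * _MARGIN - center[d]
                bearing = np.pi - bearing if d == 0 else -bearing
            elif center[d] > _ARENA - _MARGIN:
                center[d] = 2 * (_ARENA - _MARGIN) - center[d]
                bearing = np.pi - bearing if d == 0 else -bearing
        rot = np.array(
            [[np.cos(heading), -np.sin(heading)], [np.sin(heading), np.cos(heading)]]
        )
        pts[t] = center + local @ rot.T
    pts += rng.normal(0.0, script.jitter_px, size=pts.shape)
    pts = np.clip(pts, 0.0, _ARENA)
    conf = np.clip(rng.normal(0.95, 0.02, size=pts.shape[:2]), 0.0, 1.0)
    seq = PoseSequence(pts, conf, fps=fps)
    labels = np.where(in_bout, BEHAVIOR, 0).astype(np.int8)
    truth = Ethogram(labels, fps=fps, behavior_name=script.name, source="synth")
    return seq, truth


def _apply_noise(
    rng: np.random.Generator,
    truth: Sequence[Bout],
    noise: AnnotatorNoise,
    n_frames: int,
    fps: float,
    behavior_name: str,
    source: str,
) -> Ethogram:
    track = np.zeros(n_frames, dtype=np.int8)
    for b in truth:
        if rng.random() < noise.missed_bout_probability:
            continue
        start = b.start - noise.dilation
        end = b.end + noise.dilation
        if noise.jitter_sd > 0:
            start += int(round(rng.normal(0, noise.jitter_sd)))
            end += int(round(rng.normal(0, noise.jitter_sd)))
        start, end = max(0, start), min(n_frames - 1, end)
        if start <= end:
            track[start : end + 1] = BEHAVIOR
    n_false = rng.poisson(noise.false_bout_rate * n_frames)
    for _ in range(n_false):
        length = int(rng.integers(noise.false_bout_length[0], noise.false_bout_length[1] + 1))
        # only insert where the padded span is clear, so false bouts never
        # extend or bridge real bouts
        padded = np.convolve(track, np.ones(length + 2, dtype=int), mode="valid")
        candidates = np.flatnonzero(padded == 0)  # start-1 positions
        if candidates.size == 0:
            continue
        start = int(rng.choice(candidates)) + 1
        track[start : start + length] = BEHAVIOR
    return Ethogram(track, fps=fps, behavior_name=behavior_name, source=source)


def synth_annotator_pair(
    truth: Sequence[Bout],
    noise_a: AnnotatorNoise,
    noise_b: AnnotatorNoise,
    n_frames: int,
    seed: int = 0,
    fps: float = 30.0,
    behavior_name: str = "behavior",
) -> tuple[Ethogram, Ethogram]:
    """Derive two noisy annotator tracks from a ground-truth bout list."""
    truth = [Bout(*b) for b in truth]
    for b in truth:
        if b.start < 0 or b.end >= n_frames:
            raise ValueError(f"truth bout {tuple(b)} outside [0, {n_frames - 1}]")
    rng = np.random.default_rng(seed)
    a = _apply_noise(rng, truth, noise_a, n_frames, fps, behavior_name, "annotator_a")
    b = _apply_noise(rng, truth, noise_b, n_frames, fps, behavior_name, "annotator_b")
    return a, b


def synth_panel(
    n_strains: int,
    reps_per_strain: int,
    n_snps: int,
    n_causal: int,
    h2: float,
    seed: int = 0,
    ld_block_size: int = 1,
    ld_flip_prob: float = 0.05,
    maf_range: tuple[float, float] = (0.2, 0.8),
    missing_rate: float = 0.0,
    n_chrom: int = 4,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Simulate an inbred strain panel with a known genetic architecture.

    Strain genotypes are Bernoulli draws (optionally in LD blocks: SNPs in a
    block copy a shared latent allele with flip probability
    ``ld_flip_prob``).  ``n_causal`` evenly spaced SNPs carry normal effects;
    genetic values are scaled to variance ``h2`` and each animal adds
    residual noise of variance ``1 - h2``.  Animals replicate their strain's
    genotype; sexes alternate within strain.

    Returns ``(genotypes, phenotype_table, truth)`` where ``truth`` records
    the causal SNP indices, their effects, and the per-strain genetic values.
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0, 1)")
    if n_causal > n_snps:
        raise ValueError("n_causal cannot exceed n_snps")
    rng = np.random.default_rng(seed)
    n_blocks = -(-n_snps // ld_block_size)
    geno = np.empty((n_strains, n_snps))
    for blk in range(n_blocks):
        p = rng.uniform(*maf_range)
        latent = (rng.random(n_strains) < p).astype(float)
        lo, hi = blk * ld_block_size, min((blk + 1) * ld_block_size, n_snps)
        for s in range(lo, hi):
            flips = rng.random(n_strains) < ld_flip_prob
            geno[:, s] = np.where(flips, 1.0 - latent, latent)

    causal = (
        np.unique(np.linspace(0, n_snps - 1, n_causal).round().astype(int))
        if n_causal
        else np.array([], dtype=int)
    )
    genetic = np.zeros(n_strains)
    beta = np.array([])
    if h2 > 0 and causal.size:
        beta = rng.normal(size=causal.size)
        Zc = geno[:, causal]
        sd = Zc.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Zc = (Zc - Zc.mean(axis=0)) / sd
        raw = Zc @ beta
        raw_sd = raw.std(ddof=0)
        genetic = raw * np.sqrt(h2) / raw_sd if raw_sd > 0 else raw

    rows = []
    for s in range(n_strains):
        for r in range(reps_per_strain):
            rows.append(
                {
                    "animal": f"S{s:03d}_A{r}",
                    "strain": f"S{s:03d}",
                    "sex": "M" if r % 2 == 0 else "F",
                    "phenotype": genetic[s] + rng.normal(0, np.sqrt(1.0 - h2)),
                }
            )
    pheno = pd.DataFrame(rows)

    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno = np.where(mask, np.nan, geno)

    snps_per_chrom = -(-n_snps // n_chrom)
    chrom = np.array([f"chr{1 + k // snps_per_chrom}" for k in range(n_snps)])
    pos = np.concatenate(
        [np.arange((np.sum(chrom == c))) * 1000 + 1000 for c in pd.unique(chrom)]
    )
    g = GenotypeMatrix(
        geno,
        tuple(f"snp{k}" for k in range(n_snps)),
        chrom,
        pos,
        tuple(f"S{s:03d}" for s in range(n_strains)),
    )
    truth = {
        "h2": h2,
        "causal_index": causal,
        "beta": beta,
        "genetic_values": genetic,
    }
    return g, pheno, truth
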
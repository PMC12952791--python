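"""Bipartite bout graphs, overlap-based agreement, and the stitch/filter scan.

An ethograph compares the behavior bouts of two annotators (or classifiers)
as a bipartite graph: one node per bout on each side, and an edge between
every pair of temporally overlapping bouts, weighted by the interval
intersection-over-union.  Bouts with no overlapping partner are recorded as
"missed" (best overlap 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import Bout, Ethogram, bouts_from_frames, filter_bouts, stitch_bouts

__all__ = [
    "Ethograph",
    "bout_overlap",
    "build_ethograph",
    "bout_agreement",
    "scan_stitch_filter",
]


def bout_overlap(u: Bout, v: Bout) -> float:
    """Interval IoU: shared frames divided by union frames; symmetric, in [0, 1]."""
    u, v = Bout(*u), Bout(*v)
    inter = min(u.end, v.end) - max(u.start, v.start) + 1
    if inter <= 0:
        return 0.0
    union = max(u.end, v.end) - min(u.start, v.start) + 1
    return inter / union


@dataclass
class Ethograph:
    """Bipartite graph over the bouts of two tracks.

    ``edges`` holds ``(i, j, weight)`` triples indexing into ``U`` and ``V``;
    only overlapping pairs (weight > 0) are stored.  ``missed_u``/``missed_v``
    index bouts with no overlap on the other side.
    """

    U: list[Bout]
    V: list[Bout]
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def missed_u(self) -> list[int]:
        linked = {i for i, _, _ in self.edges}
        return [i for i in range(len(self.U)) if i not in linked]

    @property
    def missed_v(self) -> list[int]:
        linked = {j for _, j, _ in self.edges}
        return [j for j in range(len(self.V)) if j not in linked]

    def best_overlap(self, side: str) -> np.ndarray:
        """Max incident edge weight per bout on ``side`` ('U' or 'V'); 0 if missed."""
        if side not in ("U", "V"):
            raise ValueError("side must be 'U' or 'V'")
        n = len(self.U) if side == "U" else len(self.V)
        best = np.zeros(n)
        for i, j, w in self.edges:
            k = i if side == "U" else j
            best[k] = max(best[k], w)
        return best

    def to_networkx(self):
        """Export as a networkx Graph with node attributes side/start/end/length."""
        import networkx as nx

        g = nx.Graph()
        for side, bouts in (("U", self.U), ("V", self.V)):
            for k, b in enumerate(bouts):
                g.add_node(
                    (side, k), side=side, start=b.start, end=b.end, length=b.length,
                    bipartite=0 if side == "U" else 1,
                )
        for i, j, w in self.edges:
            g.add_edge(("U", i), ("V", j), weight=w)
        return g

    def to_json(self, path) -> str:
        payload = {
            "nodes": [
                {"side": side, "index": k, "start": b.start, "end": b.end}
                for side, bouts in (("U", self.U), ("V", self.V))
                for k, b in enumerate(bouts)
            ],
            "edges": [{"u": i, "v": j, "weight": w} for i, j, w in self.edges],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return str(path)


def build_ethograph(bouts_a: Sequence[Bout], bouts_b: Sequence[Bout]) -> Ethograph:
    """Build the bipartite overlap graph between two sorted disjoint bout lists."""
    U = [Bout(*b) for b in bouts_a]
    V = [Bout(*b) for b in bouts_b]
    for bouts in (U, V):
        for prev, cur in zip(bouts, bouts[1:]):
            if cur.start <= prev.end:
                raise ValueError(f"bout list unsorted or overlapping at {cur}")
    edges = []
    j0 = 0
    for i, u in enumerate(U):
        for j in range(j0, len(V)):
            v = V[j]
            if v.end < u.start:
                j0 = j + 1
                continue
            if v.start > u.end:
                break
            edges.append((i, j, bout_overlap(u, v)))
    return Ethograph(U=U, V=V, edges=edges)


def bout_agreement(g: Ethograph, w_star: float) -> float:
    """Fraction of bouts whose best overlap exceeds ``w_star``, averaged over sides.

    Each bout contributes its maximum incident edge weight (0 if missed); a
    side's agreement is the fraction of its bouts with best overlap strictly
    greater than ``w_star``, and the statistic is the mean of the two sides so
    it is symmetric under swapping annotators.  Two empty bout lists agree
    perfectly (1.0); one empty side scores 0 on both sides.
    """
    if not 0.0 <= w_star < 1.0:
        raise ValueError("w_star must be in [0, 1)")
    if not g.U and not g.V:
        return 1.0
    fracs = []
    for side in ("U", "V"):
        n = len(g.U) if side == "U" else len(g.V)
        fracs.append(float((g.best_overlap(side) > w_star).mean()) if n else 0.0)
    return float(np.mean(fracs))


def scan_stitch_filter(
    pred_a: Ethogram,
    pred_b: Ethogram,
    stitch_grid: Sequence[int],
    filter_grid: Sequence[int],
    w_star_list: Sequence[float],
) -> tuple[pd.DataFrame, tuple[int, int, float]]:
    """Grid-scan stitch and filter thresholds, scoring bout agreement.

    For every (stitch, filter, w_star) triple both tracks are post-processed
    (stitch first, then filter), the ethograph rebuilt, and the bout
    agreement recorded.  Returns the full table and the argmax triple
    (ties broken by table order).
    """
    if not (len(stitch_grid) and len(filter_grid) and len(w_star_list)):
        raise ValueError("scan grids must be non-empty")
    raw_a = bouts_from_frames(pred_a)
    raw_b = bouts_from_frames(pred_b)
    rows = []
    for s in stitch_grid:
        sa, sb = stitch_bouts(raw_a, s), stitch_bouts(raw_b, s)
        for f in filter_grid:
            fa, fb = filter_bouts(sa, f), filter_bouts(sb, f)
            graph = build_ethograph(fa, fb)
            for w_star in w_star_list:
                rows.append(
                    {
                        "stitch": s,
                        "filter": f,
                        "w_star": w_star,
                        "agreement": bout_agreement(graph, w_star),
                    }
                )
    table = pd.DataFrame(rows)
    best_row = table.loc[table["agreement"].idxmax()]
    best = (int(best_row["stitch"]), int(best_row["filter"]), float(best_row["w_star"]))
    return table, best
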
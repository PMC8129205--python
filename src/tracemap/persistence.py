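"""Topological summaries of neuronal trees.

A neuron's branching structure is summarized by the persistence diagram of
its dendritic tree under the path-distance-from-soma filtration: sweeping
from the distal tips toward the soma, each leaf starts a component at its
path distance (birth) and components merge at branch points, where the
elder rule keeps the component born farthest out alive and kills the
younger one (death = merge distance).  The diagram has exactly one point
per leaf; the root component dies at the soma (0).  Diagrams are compared
with the order-q Wasserstein matching distance, with the diagonal as a
sink (a point may be matched to its diagonal projection) and the L-infinity
ground metric; the optimal matching is solved exactly as an assignment
problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .swc import NeuronMorphology


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death) pairs in path-distance units.

    With the distal-to-proximal sweep, birth >= death for every point.
    """

    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) and np.any(self.points[:, 0] < self.points[:, 1] - 1e-9):
            raise ValueError("birth must be >= death under this filtration")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["birth", "death"]).to_csv(
            path, index=False
        )


def persistence_diagram(n: NeuronMorphology) -> PersistenceDiagram:
    """Branch-decomposition persistence diagram of the dendritic tree.

    One point per terminal tip: the tip's path distance from the soma is
    the branch's birth; the death is the path distance of the merge node
    where the branch is absorbed by an older (longer-reaching) branch, per
    the elder rule.  The globally longest branch of each stem survives to
    the soma and dies at 0.
    """
    pd_map = n.path_distances()
    children = n.dendrite_children_map()
    stems = n.stem_ids()
    points: list[tuple[float, float]] = []

    # carrier[v] = birth value of the branch still alive at v
    def process(nid: int) -> float:
        kids = children.get(nid, [])
        if not kids:
            return pd_map[nid]
        births = [process(k) for k in kids]
        # elder rule: the farthest-reaching branch survives the merge
        births.sort(reverse=True)
        for b in births[1:]:
            points.append((b, pd_map[nid]))
        return births[0]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        for s in stems:
            surv = process(s)
            points.append((surv, 0.0))
    finally:
        sys.setrecursionlimit(old)
    return PersistenceDiagram(np.array(points).reshape(-1, 2))


def _linf(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.abs(p[:, None, :] - q[None, :, :]).max(axis=2)


def wasserstein_dist(
    a: PersistenceDiagram, b: PersistenceDiagram, q: float = 1.0
) -> float:
    """Order-q Wasserstein distance between diagrams.

    Points may be matched across diagrams (L-infinity ground cost) or to
    their own diagonal projection (cost = half the persistence); the
    optimal partial matching is found with an exact assignment solve on
    the diagonal-augmented cost matrix.
    """
    if q < 1:
        raise ValueError("order q must be >= 1")
    pa, pb = a.points, b.points
    na, nb = len(pa), len(pb)
    if na == 0 and nb == 0:
        return 0.0
    diag_a = np.abs(pa[:, 0] - pa[:, 1]) / 2.0 if na else np.empty(0)
    diag_b = np.abs(pb[:, 0] - pb[:, 1]) / 2.0 if nb else np.empty(0)
    size = na + nb
    cost = np.zeros((size, size))
    if na and nb:
        cost[:na, :nb] = _linf(pa, pb) ** q
    big = 0.0
    if na:
        cost[:na, nb:] = np.inf
        cost[:na, nb:][np.arange(na), np.arange(na)] = diag_a**q
    if nb:
        cost[na:, :nb] = np.inf
        cost[na:, :nb][np.arange(nb), np.arange(nb)] = diag_b**q
    cost[na:, nb:] = big  # diagonal-to-diagonal pairs are free
    # replace inf with a finite bound exceeding any useful assignment
    finite = cost[np.isfinite(cost)]
    bound = (finite.max() + 1.0) * size if len(finite) else 1.0
    cost = np.where(np.isfinite(cost), cost, bound)
    rows, cols = linear_sum_assignment(cost)
    total = float(cost[rows, cols].sum())
    return total ** (1.0 / q)


def group_distance_summary(
    diagrams: list[PersistenceDiagram],
    groups,
    q: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pairwise Wasserstein matrix plus per-group-pair means.

    Returns ``(pairwise, summary)``: the symmetric zero-diagonal distance
    matrix over neurons, and the mean distance for every ordered-free group
    pair (within-group entries average the off-diagonal pairs only).
    """
    if len(diagrams) < 2:
        raise ValueError("need at least 2 neurons")
    groups = list(groups)
    if len(groups) != len(diagrams):
        raise ValueError("groups must label every diagram")
    m = len(diagrams)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = wasserstein_dist(
                diagrams[i], diagrams[j], q=q
            )
    pairwise = pd.DataFrame(dist)
    names = sorted(set(map(str, groups)))
    gl = np.array(list(map(str, groups)))
    records = []
    for i, g1 in enumerate(names):
        for g2 in names[i:]:
            a = np.flatnonzero(gl == g1)
            b = np.flatnonzero(gl == g2)
            if g1 == g2:
                vals = [dist[x, y] for x in a for y in b if x < y]
            else:
                vals = [dist[x, y] for x in a for y in b]
            records.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "mean_distance": float(np.mean(vals)) if vals else np.nan,
                }
            )
    return pairwise, pd.DataFrame.from_records(records)
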
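"""Connectivity analysis of injection-by-target annotation matrices.

Per-case tracer annotations (labeled-pixel density for anterograde tracers,
labeled-cell counts for retrograde) are aggregated into a single weighted
matrix, filtered with tracer-kind-specific minimum thresholds (0.0045 for
pixel density, 8 for cell counts), and row-normalized so every injection's
total labeling equals that of the strongest injection.  The matrix is cast
as a weighted bipartite graph (injections | targets) and partitioned by
Louvain modularity maximization at resolution gamma = 1.0; because single
runs are stochastic, 100 runs are summarized by consensus reclustering of
the co-assignment matrix.  Downstream summaries: community-sorted matrix
orderings, injection-colored pixel maps, per-level stacked-bar proportions,
tertile strength classes, and hierarchical clustering of L1-normalized
projection vectors under the cosine metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"

DEFAULT_THRESHOLD_ANTERO = 0.0045  # labeled-pixel density
DEFAULT_THRESHOLD_RETRO = 8.0  # labeled-cell count
DEFAULT_GAMMA = 1.0
DEFAULT_N_RUNS = 100
GRID_CELL_PX = 175  # annotation grid granularity, pixels


@dataclass
class AnnotationMatrix:
    """Injections x targets weighted matrix with per-injection tracer kind.

    ``values`` rows are injection ids; columns are target ids (ROI names or
    ``(atlas_level, grid_row, grid_col)`` tuples for grid-resolved data).
    """

    values: pd.DataFrame
    tracer_kind: dict  # injection id -> ANTEROGRADE | RETROGRADE
    colors: dict = field(default_factory=dict)  # injection id -> color

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("annotation values must be non-negative")
        if self.values.columns.duplicated().any():
            raise ValueError("target ids must be unique")
        missing = set(self.values.index) - set(self.tracer_kind)
        if missing:
            raise ValueError(f"tracer kind missing for injections: {missing}")
        bad = set(self.tracer_kind.values()) - {ANTEROGRADE, RETROGRADE}
        if bad:
            raise ValueError(f"unknown tracer kinds: {bad}")

    @property
    def injections(self) -> list:
        return list(self.values.index)

    @property
    def targets(self) -> list:
        return list(self.values.columns)

    def copy(self) -> "AnnotationMatrix":
        return AnnotationMatrix(
            self.values.copy(), dict(self.tracer_kind), dict(self.colors)
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.insert(0, "tracer_kind", [self.tracer_kind[i] for i in df.index])
        df.to_csv(path, index_label="injection_id")


@dataclass
class CommunityPartition:
    """Node -> community assignment over injections and targets.

    Nodes are tagged tuples ``("inj", id)`` / ``("tgt", id)`` so injection
    and target namespaces cannot collide.  Community ids are contiguous
    from 0, ordered by first appearance in sorted node order.
    """

    assignment: dict
    gamma: float
    provenance: str = "single-run"

    def __post_init__(self) -> None:
        cids = sorted(set(self.assignment.values()))
        if cids != list(range(len(cids))):
            remap = {c: k for k, c in enumerate(cids)}
            self.assignment = {n: remap[c] for n, c in self.assignment.items()}

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, nodes: list) -> np.ndarray:
        return np.array([self.assignment[n] for n in nodes])

    def community_members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for n in sorted(self.assignment, key=str):
            out.setdefault(self.assignment[n], []).append(n)
        return out


def inj_node(i) -> tuple:
    return ("inj", i)


def tgt_node(t) -> tuple:
    return ("tgt", t)


# ---------------------------------------------------------------------------
# matrix construction and preprocessing


def aggregate(cases: list[AnnotationMatrix]) -> AnnotationMatrix:
    """Combine per-case annotations into one matrix.

    One row per injection; targets absent from a case contribute 0; target
    columns duplicated across (or within) cases are summed.  An injection id
    reported with conflicting tracer kinds is an error.
    """
    if not cases:
        raise ValueError("no cases to aggregate")
    kinds: dict = {}
    colors: dict = {}
    for case in cases:
        for inj, kind in case.tracer_kind.items():
            if kinds.get(inj, kind) != kind:
                raise ValueError(f"conflicting tracer kind for injection {inj!r}")
            kinds[inj] = kind
        colors.update(case.colors)
    frames = []
    for case in cases:
        df = case.values
        if df.columns.duplicated().any():  # defensive; ctor forbids it
            df = df.T.groupby(level=0).sum().T
        frames.append(df)
    combined = pd.concat(frames, axis=0)
    combined = combined.T.groupby(level=0, sort=False).sum().T
    combined = combined.groupby(level=0, sort=False).sum()
    return AnnotationMatrix(combined.fillna(0.0), kinds, colors)


def apply_thresholds(
    m: AnnotationMatrix,
    t_antero: float = DEFAULT_THRESHOLD_ANTERO,
    t_retro: float = DEFAULT_THRESHOLD_RETRO,
) -> AnnotationMatrix:
    """Zero out entries below the tracer-kind-specific minimum.

    Entries exactly at the threshold meet it and are kept; anything smaller
    is treated as a potential false positive and removed.
    """
    if t_antero < 0 or t_retro < 0:
        raise ValueError("thresholds must be non-negative")
    out = m.copy()
    for inj in out.injections:
        t = t_antero if out.tracer_kind[inj] == ANTEROGRADE else t_retro
        row = out.values.loc[inj].to_numpy(float)
        row[row < t] = 0.0
        out.values.loc[inj] = row
    return out


def normalize_rows(m: AnnotationMatrix) -> AnnotationMatrix:
    """Scale each injection's labeling total up to the maximum row total.

    Within-row proportions are preserved exactly; the strongest injection's
    row is untouched.  Rows that are entirely zero are left unchanged with
    a warning.
    """
    import warnings

    totals = m.values.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("all rows are zero; nothing to normalize")
    target = float(totals.max())
    out = m.copy()
    for inj, total in totals.items():
        if total == 0:
            warnings.warn(f"injection {inj!r} has no labeling; left as zero")
            continue
        if total != target:
            out.values.loc[inj] *= target / float(total)
    return out


# ---------------------------------------------------------------------------
# community detection


def to_bipartite_graph(m: AnnotationMatrix) -> nx.Graph:
    """Weighted bipartite graph over injections and targets."""
    g = nx.Graph()
    g.add_nodes_from(inj_node(i) for i in m.injections)
    g.add_nodes_from(tgt_node(t) for t in m.targets)
    vals = m.values.to_numpy(float)
    for a, inj in enumerate(m.injections):
        for b, tgt in enumerate(m.targets):
            w = vals[a, b]
            if w > 0:
                g.add_edge(inj_node(inj), tgt_node(tgt), weight=float(w))
    return g


def _louvain_partition(
    g: nx.Graph, gamma: float, seed: int, provenance: str
) -> CommunityPartition:
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma, seed=seed
    )
    comms = sorted(comms, key=lambda c: str(min(c, key=str)))
    assignment = {n: k for k, nodes in enumerate(comms) for n in nodes}
    return CommunityPartition(assignment, gamma=gamma, provenance=provenance)


def louvain_runs(
    m: AnnotationMatrix,
    gamma: float = DEFAULT_GAMMA,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
) -> list[CommunityPartition]:
    """Repeated Louvain modularity maximization on the bipartite graph.

    The greedy optimizer depends on node visiting order, so each run uses an
    independent seed derived from the root seed.
    """
    g = to_bipartite_graph(m)
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges; check thresholds")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    return [
        _louvain_partition(g, gamma, int(s), provenance="single-run")
        for s in run_seeds
    ]


def coassignment_matrix(
    partitions: list[CommunityPartition], nodes: list
) -> np.ndarray:
    """Fraction of runs assigning each node pair to the same community."""
    labels = np.stack([p.labels_for(nodes) for p in partitions])
    n = len(nodes)
    co = np.zeros((n, n))
    for lab in labels:
        co += lab[:, None] == lab[None, :]
    return co / len(partitions)


def consensus(
    partitions: list[CommunityPartition],
    tau: float = 0.5,
    seed: int = 0,
    max_iter: int = 50,
) -> CommunityPartition:
    """Consensus community structure over stochastic runs.

    Iteratively reclusters the tau-thresholded co-assignment matrix with
    Louvain until all reclustering runs agree, then polishes assignments so
    each node sits in the community maximizing its mean co-assignment
    (ties to the lower community id).
    """
    if not partitions:
        raise ValueError("need at least one partition")
    node_sets = {frozenset(p.assignment) for p in partitions}
    if len(node_sets) > 1:
        raise ValueError("partitions cover different node sets")
    nodes = sorted(partitions[0].assignment, key=str)
    gamma = partitions[0].gamma
    rng = np.random.default_rng(seed)

    current = partitions
    co = coassignment_matrix(current, nodes)
    for _ in range(max_iter):
        labels = np.stack([p.labels_for(nodes) for p in current])
        if all(np.array_equal(labels[0], lab) for lab in labels[1:]):
            break
        thr = np.where(co >= tau, co, 0.0)
        np.fill_diagonal(thr, 0.0)
        g = nx.Graph()
        g.add_nodes_from(range(len(nodes)))
        ii, jj = np.nonzero(np.triu(thr, 1))
        g.add_weighted_edges_from(
            (int(i), int(j), float(thr[i, j])) for i, j in zip(ii, jj)
        )
        n_rep = min(len(current), 20)
        current = []
        for _ in range(n_rep):
            comms = nx.community.louvain_communities(
                g, weight="weight", seed=int(rng.integers(0, 2**31 - 1))
            )
            comms = sorted(comms, key=min)
            assignment = {
                nodes[i]: k for k, cc in enumerate(comms) for i in cc
            }
            current.append(CommunityPartition(assignment, gamma=gamma))
        co = coassignment_matrix(current, nodes)

    assignment = dict(zip(nodes, current[0].labels_for(nodes)))
    assignment = _polish(assignment, nodes, coassignment_matrix(partitions, nodes))
    return CommunityPartition(
        {n: int(c) for n, c in assignment.items()},
        gamma=gamma,
        provenance=f"consensus-of-{len(partitions)}",
    )


def _polish(assignment: dict, nodes: list, co: np.ndarray) -> dict:
    """Move each node to the community with maximal mean co-assignment.

    Ties between positive scores resolve to the lower community id; a node
    with no positive co-assignment to any community stays where it is.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    for _ in range(10):
        changed = False
        for n in nodes:
            scores = {}
            for c in sorted(set(assignment.values())):
                members = [idx[v] for v in nodes if assignment[v] == c and v != n]
                scores[c] = float(np.mean(co[idx[n], members])) if members else 0.0
            best = max(scores.values())
            if best <= 1e-12:
                continue
            best_c = min(c for c, s in scores.items() if s >= best - 1e-12)
            if best_c != assignment[n]:
                assignment[n] = best_c
                changed = True
        if not changed:
            break
    return assignment


# ---------------------------------------------------------------------------
# visual summaries


def reorder_for_matrix(
    m: AnnotationMatrix, p: CommunityPartition
) -> tuple[list, list]:
    """Row/column orderings placing communities in contiguous blocks.

    Rows and columns are grouped by community id; within a community they
    are sorted by descending total strength so the strongest connections of
    each grouped injection set fall along the diagonal.
    """
    for i in m.injections:
        if inj_node(i) not in p.assignment:
            raise ValueError(f"partition missing injection {i!r}")
    for t in m.targets:
        if tgt_node(t) not in p.assignment:
            raise ValueError(f"partition missing target {t!r}")
    row_tot = m.values.sum(axis=1)
    col_tot = m.values.sum(axis=0)
    rows = sorted(
        m.injections,
        key=lambda i: (p.assignment[inj_node(i)], -row_tot[i], str(i)),
    )
    cols = sorted(
        m.targets,
        key=lambda t: (p.assignment[tgt_node(t)], -col_tot[t], str(t)),
    )
    return rows, cols


@dataclass
class ColorCodedMap:
    atlas_level: int
    raster: np.ndarray  # (H, W, 3) float RGB in [0, 1]
    legend: dict  # injection id -> color
    uncolored_grids: list = field(default_factory=list)


def _grid_of_pixel(level: int, y: int, x: int, cell_px: int) -> tuple:
    return (level, y // cell_px, x // cell_px)


def color_code(
    p: CommunityPartition,
    m: AnnotationMatrix,
    segmentations: dict[int, np.ndarray],
    colors: dict | None = None,
    cell_px: int = GRID_CELL_PX,
) -> list[ColorCodedMap]:
    """Color each segmented pixel by the injection owning its grid cell.

    For a segmented pixel, the grid cell's consensus community is looked up;
    among the injections of that community, the one with the greatest
    annotation value at that grid owns the pixel and supplies its color.
    Grids whose community contains no injection are flagged and left
    uncolored.
    """
    colors = colors if colors is not None else m.colors
    comm_inj: dict[int, list] = {}
    for node, c in p.assignment.items():
        if node[0] == "inj":
            comm_inj.setdefault(c, []).append(node[1])
    maps = []
    for level in sorted(segmentations):
        seg = np.asarray(segmentations[level], dtype=bool)
        rgb = np.zeros(seg.shape + (3,))
        uncolored = []
        owner_cache: dict[tuple, object] = {}
        for y, x in zip(*np.nonzero(seg)):
            grid = _grid_of_pixel(level, int(y), int(x), cell_px)
            if grid not in owner_cache:
                owner_cache[grid] = _grid_owner(grid, p, m, comm_inj)
                if owner_cache[grid] is None:
                    uncolored.append(grid)
            owner = owner_cache[grid]
            if owner is not None:
                rgb[y, x] = colors[owner]
        maps.append(
            ColorCodedMap(
                atlas_level=level,
                raster=rgb,
                legend={i: colors[i] for i in m.injections if i in colors},
                uncolored_grids=uncolored,
            )
        )
    return maps


def _grid_owner(grid, p: CommunityPartition, m: AnnotationMatrix, comm_inj):
    node = tgt_node(grid)
    if node not in p.assignment or grid not in m.values.columns:
        return None
    injections = comm_inj.get(p.assignment[node], [])
    if not injections:
        return None
    col = m.values.loc[injections, [grid]].iloc[:, 0]
    if float(col.max()) <= 0:
        return None
    return col.idxmax()


def stacked_bar_data(
    m: AnnotationMatrix,
    roi_lookup: dict,
    roi_subset: set | None = None,
    top_n_rois: int = 2,
) -> pd.DataFrame:
    """Per-atlas-level labeling proportions for stacked bar charts.

    For grid-resolved matrices (columns ``(level, row, col)``) returns, per
    level and injection, the fraction of that injection's total labeling on
    the level, plus the ``top_n_rois`` ROIs with the highest summed label on
    the level.  ``roi_lookup`` maps a grid cell to its ROI name; an optional
    ROI subset restricts the analysis (the focused chart variant).
    """
    cols = list(m.values.columns)
    if roi_subset is not None:
        cols = [c for c in cols if roi_lookup.get(c) in roi_subset]
    levels = sorted({c[0] for c in cols})
    records = []
    for level in levels:
        level_cols = [c for c in cols if c[0] == level]
        level_vals = m.values[level_cols]
        roi_sums: dict = {}
        for c in level_cols:
            roi = roi_lookup.get(c, "unassigned")
            roi_sums[roi] = roi_sums.get(roi, 0.0) + float(level_vals[c].sum())
        top = sorted(roi_sums, key=lambda r: (-roi_sums[r], str(r)))[:top_n_rois]
        for inj in m.injections:
            total = float(m.values.loc[inj, cols].sum()) if cols else 0.0
            frac = float(level_vals.loc[inj].sum()) / total if total else 0.0
            records.append(
                {
                    "atlas_level": level,
                    "injection_id": inj,
                    "fraction": frac,
                    "top_rois": tuple(top),
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class ProjectionClustering:
    linkage_matrix: np.ndarray
    leaf_order: list
    case_ids: list

    def cut(self, n_clusters: int) -> dict:
        labels = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.case_ids, (int(v) for v in labels)))


def cluster_projection_vectors(
    vectors: pd.DataFrame, method: str = "average"
) -> ProjectionClustering:
    """Hierarchical clustering of per-case projection vectors.

    Rows are cases, columns target regions.  Vectors are L1-normalized to
    projection fractions; pairwise cosine distances feed agglomerative
    linkage (average by default).
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 cases to cluster")
    totals = vectors.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero projection vector for cases: {list(zero.index)}")
    norm = vectors.div(totals, axis=0)
    dist = pdist(norm.to_numpy(float), metric="cosine")
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    z = linkage(dist, method=method)
    order = [vectors.index[i] for i in leaves_list(z)]
    return ProjectionClustering(
        linkage_matrix=z, leaf_order=order, case_ids=list(vectors.index)
    )


def tertile_bins(strengths) -> np.ndarray:
    """Bin connection strengths into tertiles: strong / moderate / weak.

    Values tied with a tertile boundary are assigned to the stronger bin,
    so an all-equal input is uniformly strong.
    """
    vals = np.asarray(strengths, dtype=float)
    if vals.ndim != 1 or len(vals) < 3:
        raise ValueError("need at least 3 strength values")
    if np.any(vals < 0):
        raise ValueError("strengths must be positive")
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    out = np.where(vals >= q2, "strong", np.where(vals >= q1, "moderate", "weak"))
    return out.astype(object)
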
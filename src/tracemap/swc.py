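"""Neuron morphologies with SWC semantics.

A reconstruction is a rooted tree of 3D sample points with radii, stored in
the standard SWC convention (columns id, type, x, y, z, radius, parent;
parent of the root is -1).  Somata may be multi-node (a point cloud of
type-1 samples hanging off the root), which is how mesh-derived somata are
commonly deposited; dendrites are type-3 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SOMA_TYPE = 1
DENDRITE_TYPE = 3

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


@dataclass
class NeuronMorphology:
    """Rooted tree of 3D nodes with radii (SWC semantics).

    Attributes
    ----------
    ids, types, parent : int arrays of shape (n,)
        Node identifiers, SWC structure types, and parent identifiers
        (-1 for the single root).
    xyz : float array of shape (n, 3)
    radius : float array of shape (n,)
    group_label : optional cohort/domain tag carried through analyses.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    group_label: str | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.validate()
        self._index = {nid: i for i, nid in enumerate(self.ids)}

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            raise ValueError("node ids must be unique")
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must have shape (n, 3)")
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        idset = set(self.ids.tolist())
        for p in self.parent:
            if p != -1 and p not in idset:
                raise ValueError(f"parent id {p} not present")
        # acyclicity: each node must reach the root through parent pointers
        index = {nid: i for i, nid in enumerate(self.ids)}
        state = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 on path, 2 done
        for start in range(n):
            path = []
            i = start
            while state[i] == 0:
                state[i] = 1
                path.append(i)
                p = self.parent[i]
                if p == -1:
                    break
                i = index[p]
                if state[i] == 1:
                    raise ValueError("parent pointers contain a cycle")
            for j in path:
                state[j] = 2

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_id(self) -> int:
        return int(self.ids[np.flatnonzero(self.parent == -1)[0]])

    def node_index(self, node_id: int) -> int:
        return self._index[node_id]

    def children_map(self) -> dict[int, list[int]]:
        """Map node id -> list of child ids, in id order."""
        out: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for nid, p in zip(self.ids, self.parent):
            if p != -1:
                out[int(p)].append(int(nid))
        return out

    def soma_center(self) -> np.ndarray:
        """Centroid of soma-type nodes; falls back to the root position."""
        soma = self.types == SOMA_TYPE
        if np.any(soma):
            return self.xyz[soma].mean(axis=0)
        return self.xyz[self.node_index(self.root_id)]

    def path_distances(self) -> dict[int, float]:
        """Cumulative edge length from the root, per node id."""
        out: dict[int, float] = {self.root_id: 0.0}
        children = self.children_map()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            pi = self.node_index(nid)
            for c in children[nid]:
                ci = self.node_index(c)
                out[c] = out[nid] + float(
                    np.linalg.norm(self.xyz[ci] - self.xyz[pi])
                )
                stack.append(c)
        return out

    # -- dendrite-restricted views ----------------------------------------

    def dendrite_ids(self) -> list[int]:
        return [int(i) for i in self.ids[self.types == DENDRITE_TYPE]]

    def dendrite_children_map(self) -> dict[int, list[int]]:
        """Children map restricted to dendrite nodes (soma links removed)."""
        dend = set(self.dendrite_ids())
        out: dict[int, list[int]] = {i: [] for i in dend}
        for nid, p in zip(self.ids, self.parent):
            if int(nid) in dend and int(p) in dend:
                out[int(p)].append(int(nid))
        return out

    def stem_ids(self) -> list[int]:
        """Dendrite nodes whose parent is not a dendrite (branch roots)."""
        dend = set(self.dendrite_ids())
        return [
            int(nid)
            for nid, p in zip(self.ids, self.parent)
            if int(nid) in dend and int(p) not in dend
        ]

    def dendrite_branches(self) -> list[list[int]]:
        """Maximal unbranched dendrite polylines.

        Each branch is a list of node ids running from a branch root (a stem
        origin or a bifurcation child) to the next bifurcation or tip,
        inclusive of both endpoints.
        """
        children = self.dendrite_children_map()
        branches = []
        starts = list(self.stem_ids())
        while starts:
            nid = starts.pop(0)
            branch = [nid]
            while True:
                kids = children.get(branch[-1], [])
                if len(kids) == 1:
                    branch.append(kids[0])
                else:
                    starts = kids + starts
                    break
            branches.append(branch)
        return branches

    def subtree(self, keep_ids: set[int]) -> "NeuronMorphology":
        """Restriction to ``keep_ids``; kept nodes must remain connected."""
        mask = np.array([int(i) in keep_ids for i in self.ids])
        return NeuronMorphology(
            ids=self.ids[mask],
            types=self.types[mask],
            xyz=self.xyz[mask],
            radius=self.radius[mask],
            parent=self.parent[mask],
            group_label=self.group_label,
        )

    def with_xyz(self, xyz: np.ndarray) -> "NeuronMorphology":
        return replace(self, xyz=np.asarray(xyz, dtype=float), _index={})

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "type": self.types,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
                "parent": self.parent,
            }
        )

    def to_swc(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write("# " + " ".join(SWC_COLUMNS) + "\n")
            df.to_csv(fh, sep=" ", header=False, index=False)


def read_swc(path: str | Path, group_label: str | None = None) -> NeuronMorphology:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=SWC_COLUMNS,
    )
    return NeuronMorphology(
        ids=df["id"].to_numpy(int),
        types=df["type"].to_numpy(int),
        xyz=df[["x", "y", "z"]].to_numpy(float),
        radius=df["radius"].to_numpy(float),
        parent=df["parent"].to_numpy(int),
        group_label=group_label,
    )
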
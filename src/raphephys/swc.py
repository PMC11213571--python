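"""SWC neuron-reconstruction reading/writing and the DendriteTree container.

Standard 7-column SWC: id, type, x, y, z, radius, parent (-1 for the root).
Coordinates are micrometers. The tree must have a single root of soma type
(type 1), valid parent references, and no cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

SOMA_TYPE = 1
DENDRITE_TYPE = 3


class StructureError(ValueError):
    """Cycles, orphan nodes, or multiple/absent roots."""


@dataclass
class DendriteTree:
    """SWC node table with validated topology.

    Arrays are aligned by row; ``parent_index`` holds the row index of each
    node's parent (-1 for the root), precomputed from SWC ids on load.
    """

    ids: np.ndarray        # int, original SWC ids
    types: np.ndarray      # int
    xyz: np.ndarray        # (n, 3) float, um
    radius: np.ndarray     # float, um
    parent_index: np.ndarray  # int row index, -1 for root

    def __post_init__(self):
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_index(self) -> int:
        roots = np.flatnonzero(self.parent_index == -1)
        return int(roots[0])

    def children(self, index: int) -> np.ndarray:
        return np.flatnonzero(self.parent_index == index)

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise StructureError("empty SWC")
        roots = np.flatnonzero(self.parent_index == -1)
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        if self.types[roots[0]] != SOMA_TYPE:
            raise StructureError("root node must be of soma type (1)")
        bad = (self.parent_index < -1) | (self.parent_index >= n)
        if np.any(bad):
            raise StructureError("parent reference out of range")
        # acyclicity + connectivity: walk each node to the root
        for start in range(n):
            seen = 0
            i = start
            while i != -1:
                i = int(self.parent_index[i])
                seen += 1
                if seen > n:
                    raise StructureError("cycle detected in parent links")

    def topology_hash(self) -> tuple:
        """Canonical recursive topology signature, invariant to node ids,
        coordinates and child ordering."""
        children = [list(self.children(i)) for i in range(self.n_nodes)]

        def sig(i: int) -> tuple:
            return tuple(sorted(sig(c) for c in children[i]))

        return sig(self.root_index)


def read_swc(path: str | Path) -> DendriteTree:
    """Parse a standard 7-column SWC file into a :class:`DendriteTree`."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise StructureError(f"line {ln}: expected 7 columns, got {len(parts)}")
            rows.append(parts)
    if not rows:
        raise StructureError("no nodes in SWC file")
    ids = np.array([int(r[0]) for r in rows])
    types = np.array([int(r[1]) for r in rows])
    xyz = np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
    radius = np.array([float(r[5]) for r in rows])
    parents = np.array([int(r[6]) for r in rows])
    if len(np.unique(ids)) != len(ids):
        raise StructureError("duplicate node ids")
    id_to_row = {int(i): k for k, i in enumerate(ids)}
    parent_index = np.empty(len(ids), dtype=int)
    for k, p in enumerate(parents):
        if p == -1:
            parent_index[k] = -1
        elif int(p) == int(ids[k]):
            raise StructureError(f"node {ids[k]} is its own parent")
        elif int(p) not in id_to_row:
            raise StructureError(f"node {ids[k]} references unknown parent {p}")
        else:
            parent_index[k] = id_to_row[int(p)]
    return DendriteTree(ids=ids, types=types, xyz=xyz, radius=radius, parent_index=parent_index)


def write_swc(tree: DendriteTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(tree.n_nodes):
            pid = -1 if tree.parent_index[k] == -1 else int(tree.ids[tree.parent_index[k]])
            x, y, z = tree.xyz[k]
            fh.write(
                f"{int(tree.ids[k])} {int(tree.types[k])} "
                f"{x:.6g} {y:.6g} {z:.6g} {tree.radius[k]:.6g} {pid}\n"
            )
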
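"""Soma-contour shape descriptors and dendritic-tree statistics.

Soma contours are 2-D polygons traced around the cell body (um); metrics
are area, perimeter, the major/minor axes of the moments-equivalent ellipse
(image-analysis "fit ellipse" convention: same area and second central
moments), and circularity = 4*pi*area/perimeter^2, which is 1 for a circle
and decreases for elongated or complex shapes. Dendritic trees come from
3-D SWC reconstructions; primary dendrites are the children of the soma
root, and for trees built of binary branch points the identity
``terminations = bifurcations + stems`` holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .swc import SOMA_TYPE, DendriteTree


class GeometryError(ValueError):
    """Invalid contour (self-intersecting, degenerate)."""


@dataclass(frozen=True)
class SomaContour:
    """Closed simple polygon, vertices (n, 2) in um (last vertex implicit)."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("contour needs >= 3 two-dimensional vertices")
        poly = Polygon(v)
        if not poly.is_simple or not poly.is_valid:
            raise GeometryError("contour is self-intersecting")
        if poly.area <= 0:
            raise GeometryError("contour has non-positive area")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class SomaMetrics:
    area: float         # um^2
    perimeter: float    # um
    major_axis: float   # um
    minor_axis: float   # um
    circularity: float  # 4*pi*area/perimeter^2, in (0, 1]


@dataclass
class TreeMetrics:
    n_primary_dendrites: int
    n_bifurcations: int
    n_terminations: int
    total_length: float                 # um
    primary_dendrite_lengths: list[float]  # um, subtree length per stem


def _polygon_second_moments(v: np.ndarray) -> tuple[float, float, float]:
    """Central second moments (covariance of the uniform density over the
    polygon interior): (var_xx, var_yy, cov_xy). Shoelace-based closed form."""
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    x0, y0 = x - cx, y - cy
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    cross = x0 * y1 - x1 * y0
    ixx = np.sum(cross * (y0 * y0 + y0 * y1 + y1 * y1)) / 12.0
    iyy = np.sum(cross * (x0 * x0 + x0 * x1 + x1 * x1)) / 12.0
    ixy = np.sum(cross * (x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0)) / 24.0
    a = abs(area)
    sign = 1.0 if area > 0 else -1.0
    return sign * iyy / a, sign * ixx / a, sign * ixy / a  # var_x, var_y, cov


def soma_metrics(contour: SomaContour) -> SomaMetrics:
    """Shape descriptors of a traced soma outline.

    The major/minor axes are those of the ellipse with the same normalized
    second central moments as the polygon (lengths 4*sqrt(eigenvalue), the
    full axes of that ellipse).
    """
    poly = contour.polygon
    area = poly.area
    perimeter = poly.exterior.length
    var_x, var_y, cov = _polygon_second_moments(contour.vertices)
    cov_mat = np.array([[var_x, cov], [cov, var_y]])
    eig = np.linalg.eigvalsh(cov_mat)
    eig = np.clip(eig, 0.0, None)
    minor, major = 4.0 * np.sqrt(eig)
    return SomaMetrics(
        area=float(area),
        perimeter=float(perimeter),
        major_axis=float(major),
        minor_axis=float(minor),
        circularity=4.0 * math.pi * area / perimeter**2,
    )


def tree_metrics(tree: DendriteTree) -> TreeMetrics:
    """Counts and lengths of a dendritic tree.

    Primary dendrites are the children of the soma root; bifurcations are
    non-soma nodes with >= 2 children (a node with c > 2 children counts as
    c - 1 bifurcations); terminations are non-soma leaves. Lengths are
    summed 3-D Euclidean segment lengths.
    """
    root = tree.root_index
    n = tree.n_nodes
    child_count = np.zeros(n, dtype=int)
    for k in range(n):
        p = tree.parent_index[k]
        if p >= 0:
            child_count[p] += 1

    stems = tree.children(root)
    non_soma = np.arange(n) != root
    if np.any(child_count[non_soma] > 2):
        import logging

        logging.getLogger(__name__).warning(
            "tree has nodes with >2 children; each counted as (children - 1) bifurcations"
        )
    n_bif = int(np.sum(np.maximum(child_count[non_soma] - 1, 0) * (child_count[non_soma] >= 2)))
    n_term = int(np.sum((child_count == 0) & non_soma))

    seg_len = np.zeros(n)
    for k in range(n):
        p = tree.parent_index[k]
        if p >= 0:
            seg_len[k] = np.linalg.norm(tree.xyz[k] - tree.xyz[p])
    total = float(np.sum(seg_len))

    # per-stem subtree length
    children = [list(tree.children(i)) for i in range(n)]

    def subtree_length(i: int) -> float:
        out = 0.0
        stack = [i]
        while stack:
            j = stack.pop()
            out += seg_len[j]
            stack.extend(children[j])
        return out

    per_stem = [float(subtree_length(s)) for s in stems]
    return TreeMetrics(
        n_primary_dendrites=len(stems),
        n_bifurcations=n_bif,
        n_terminations=n_term,
        total_length=total,
        primary_dendrite_lengths=per_stem,
    )
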
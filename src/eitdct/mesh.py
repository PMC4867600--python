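"""Triangular FEM meshes for the 2D EIT forward problem.

Two mesh constructors are provided:

* :func:`build_mesh` — deterministic Delaunay mesh of an arbitrary simple
  polygon (the thorax boundary), with ``n_elec`` electrode nodes placed
  equidistantly by arc length, counter-clockwise from the ventral midline.
* :func:`symmetric_disk_mesh` — a structured disk mesh that is exactly
  invariant under rotation by one electrode spacing, used to verify
  rotational symmetries of the forward map.

Meshes can be written/read as a plain text format (node / element /
electrode sections).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .geometry import polygon_area
from .phantom import GeometryError, ThoraxPhantom


@dataclass(frozen=True)
class Mesh:
    """A triangular mesh with electrode node groups on the boundary.

    ``elements`` are node index triples with positive (counter-clockwise)
    orientation.  ``electrode_nodes`` holds one ordered group of boundary node
    indices per electrode, counter-clockwise starting at the ventral midline.
    """

    nodes: np.ndarray  # (n_nodes, 2)
    elements: np.ndarray  # (n_elem, 3) int
    electrode_nodes: tuple[tuple[int, ...], ...]

    @property
    def n_elem(self) -> int:
        return len(self.elements)

    @property
    def n_elec(self) -> int:
        return len(self.electrode_nodes)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)


def _arc_lengths(boundary: np.ndarray) -> tuple[np.ndarray, float]:
    closed = np.vstack([boundary, boundary[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s, float(s[-1])


def _interp_boundary(boundary: np.ndarray, s_query: np.ndarray) -> np.ndarray:
    s, total = _arc_lengths(boundary)
    closed = np.vstack([boundary, boundary[:1]])
    sq = np.mod(s_query, total)
    x = np.interp(sq, s, closed[:, 0])
    y = np.interp(sq, s, closed[:, 1])
    return np.column_stack([x, y])


def build_mesh(phantom: ThoraxPhantom, n_elec: int = 16,
               target_n_elem: int = 1000) -> Mesh:
    """Mesh the phantom's thorax polygon with equidistant boundary electrodes.

    The construction is a pure function of its arguments: boundary nodes are
    placed at fixed arc-length positions (electrode positions among them) and
    interior nodes on a regular grid, then triangulated with Delaunay and
    clipped to the polygon.  The achieved element count is close to
    ``target_n_elem`` (within roughly +-30%).
    """
    if n_elec < 8 or n_elec % 2:
        raise ValueError("n_elec must be even and >= 8")
    if target_n_elem < 200:
        raise ValueError("target_n_elem must be >= 200")
    boundary = np.asarray(phantom.boundary, float)
    area = polygon_area(boundary)
    if area < 0:
        boundary = boundary[::-1]
        area = -area
    if area <= 0 or len(boundary) < 3:
        raise GeometryError("degenerate boundary polygon")
    poly = Polygon(boundary)
    if not poly.is_valid:
        raise GeometryError("boundary polygon is self-intersecting")

    _, perimeter = _arc_lengths(boundary)
    h = np.sqrt(2.0 * area / target_n_elem)
    gap = perimeter / n_elec
    per_gap = max(1, int(round(gap / h)))
    s = np.arange(n_elec * per_gap) * (gap / per_gap)
    bnodes = _interp_boundary(boundary, s)
    elec_groups = tuple((e * per_gap,) for e in range(n_elec))

    xs = np.arange(boundary[:, 0].min() + h / 2, boundary[:, 0].max(), h)
    ys = np.arange(boundary[:, 1].min() + h / 2, boundary[:, 1].max(), h)
    X, Y = np.meshgrid(xs, ys)
    grid = np.column_stack([X.ravel(), Y.ravel()])
    pts = shapely.points(grid)
    inside = shapely.contains(poly, pts)
    far = shapely.distance(pts, poly.exterior) > 0.45 * h
    interior = grid[inside & far]

    nodes = np.vstack([bnodes, interior])
    tri = Delaunay(nodes)
    cent = nodes[tri.simplices].mean(axis=1)
    keep = shapely.contains(poly, shapely.points(cent))
    elements = tri.simplices[keep]

    # enforce counter-clockwise element orientation
    p = nodes[elements]
    signed = (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    flip = signed < 0
    elements[flip] = elements[flip][:, ::-1]
    return Mesh(nodes=nodes, elements=np.ascontiguousarray(elements),
                electrode_nodes=elec_groups)


def symmetric_disk_mesh(n_elec: int = 16, n_rings: int = 6,
                        radius: float = 1.0, per_sector: int = 2) -> Mesh:
    """Structured disk mesh exactly invariant under rotation by 2*pi/n_elec.

    Rings of ``n_elec * per_sector`` nodes are connected by consistently
    split quads, so rotating node labels by one electrode spacing is a mesh
    automorphism.  Electrode e sits at angle ``pi/2 + 2*pi*e/n_elec``
    (counter-clockwise from the top).
    """
    nb = n_elec * per_sector
    nodes = [np.zeros(2)]
    ring_start = [None]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        th = np.pi / 2 + 2 * np.pi * np.arange(nb) / nb
        ring_start.append(len(nodes))
        nodes.extend(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    nodes = np.asarray(nodes)

    elements = []
    s1 = ring_start[1]
    for i in range(nb):
        elements.append([0, s1 + (i + 1) % nb, s1 + i])
    for k in range(1, n_rings):
        a, b = ring_start[k], ring_start[k + 1]
        for i in range(nb):
            j = (i + 1) % nb
            elements.append([a + i, b + j, b + i])
            elements.append([a + i, a + j, b + j])
    elements = np.asarray(elements)

    # fix orientation to counter-clockwise
    p = nodes[elements]
    signed = (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    flip = signed < 0
    elements[flip] = elements[flip][:, ::-1]

    outer = ring_start[n_rings]
    elec_groups = tuple((outer + e * per_sector,) for e in range(n_elec))
    return Mesh(nodes=nodes, elements=elements, electrode_nodes=elec_groups)


def write_mesh(mesh: Mesh, path: str | Path) -> None:
    """Write the plain-text mesh format (node / element / electrode sections)."""
    lines = ["# nodes: index x y"]
    for i, (x, y) in enumerate(mesh.nodes):
        lines.append(f"n {i} {x:.17g} {y:.17g}")
    lines.append("# elements: index n1 n2 n3 (0-based)")
    for i, (a, b, c) in enumerate(mesh.elements):
        lines.append(f"e {i} {a} {b} {c}")
    lines.append("# electrodes: index node...")
    for i, grp in enumerate(mesh.electrode_nodes):
        lines.append("el " + str(i) + " " + " ".join(str(n) for n in grp))
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh(path: str | Path) -> Mesh:
    nodes, elements, elecs = [], [], {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "n":
            nodes.append((float(parts[2]), float(parts[3])))
        elif parts[0] == "e":
            elements.append(tuple(int(v) for v in parts[2:5]))
        elif parts[0] == "el":
            elecs[int(parts[1])] = tuple(int(v) for v in parts[2:])
    groups = tuple(elecs[i] for i in sorted(elecs))
    return Mesh(nodes=np.asarray(nodes, float),
                elements=np.asarray(elements, int), electrode_nodes=groups)
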
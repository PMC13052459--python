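"""By-water least-cost distances on a rasterised seascape.

The seascape is a binary raster (water = 1, land = 0) with square pixels
(default 40 m). Movement between water cells follows a 16-direction
transition topology: the 8 king moves (orthogonal, weight = 1 pixel;
diagonal, weight = sqrt(2) pixels) plus the 8 knight moves (weight =
sqrt(5) pixels). A knight move is admitted only if at least one of the two
orthogonally adjacent intermediate cells on its path is water, so paths
cannot jump across a thin land barrier. Shortest paths are computed with
Dijkstra's algorithm on the sparse cell graph, giving by-water distances
with a precision of about one pixel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_M = 40.0

# (drow, dcol, weight in pixels) for the king neighbourhood
_KING = [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
         (-1, -1, math.sqrt(2)), (-1, 1, math.sqrt(2)),
         (1, -1, math.sqrt(2)), (1, 1, math.sqrt(2))]
_KNIGHT = [(dr, dc, math.sqrt(5))
           for dr, dc in [(-2, -1), (-2, 1), (2, -1), (2, 1),
                          (-1, -2), (-1, 2), (1, -2), (1, 2)]]


@dataclass
class WaterGrid:
    """Binary water mask on a regular grid.

    ``mask[i, j]`` is truthy for water. Row 0 is the *southern* edge; the
    planar coordinate of cell centre (i, j) is
    ``origin + pixel_size * (j + 0.5, i + 0.5)``.
    """

    mask: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_M
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("water mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.mask.any():
            raise ValueError("water mask contains no water cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid cell containing planar point (x, y)."""
        j = int(np.floor((x - self.origin[0]) / self.pixel_size))
        i = int(np.floor((y - self.origin[1]) / self.pixel_size))
        return i, j

    def centre_of(self, i: int, j: int) -> tuple[float, float]:
        return (self.origin[0] + (j + 0.5) * self.pixel_size,
                self.origin[1] + (i + 0.5) * self.pixel_size)

    def to_files(self, grid_path, header_path) -> None:
        """Write the mask as a 0/1 CSV grid plus a small key=value header."""
        np.savetxt(grid_path, self.mask.astype(int), fmt="%d", delimiter=",")
        with open(header_path, "w") as fh:
            fh.write(f"pixel_size={self.pixel_size}\n")
            fh.write(f"origin_x={self.origin[0]}\n")
            fh.write(f"origin_y={self.origin[1]}\n")

    @classmethod
    def from_files(cls, grid_path, header_path) -> "WaterGrid":
        mask = np.loadtxt(grid_path, dtype=int, delimiter=",", ndmin=2)
        kv = {}
        with open(header_path) as fh:
            for line in fh:
                if "=" in line:
                    k, v = line.strip().split("=", 1)
                    kv[k] = float(v)
        return cls(mask=mask, pixel_size=kv["pixel_size"],
                   origin=(kv["origin_x"], kv["origin_y"]))


@dataclass
class MovementGraph:
    """Sparse shortest-path graph over the water cells of a grid."""

    grid: WaterGrid
    directions: int
    adjacency: csr_matrix          # weights in metres
    node_index: np.ndarray         # mask-shaped; -1 on land, else node id
    nodes: np.ndarray              # (n_nodes, 2) array of (i, j)

    def snap(self, x: float, y: float, max_pixels: int = 3) -> int:
        """Node id of the water cell nearest (x, y), within ``max_pixels``."""
        i, j = self.grid.cell_of(x, y)
        nrow, ncol = self.grid.shape
        best, best_d2 = -1, float("inf")
        for di in range(-max_pixels, max_pixels + 1):
            for dj in range(-max_pixels, max_pixels + 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < nrow and 0 <= jj < ncol and self.node_index[ii, jj] >= 0:
                    d2 = di * di + dj * dj
                    if d2 < best_d2:
                        best, best_d2 = self.node_index[ii, jj], d2
        if best < 0:
            raise ValueError(
                f"point ({x}, {y}) is on land with no water cell "
                f"within {max_pixels} pixels")
        return int(best)


def build_graph(grid: WaterGrid, directions: int = 16) -> MovementGraph:
    """Build the movement graph over water cells.

    ``directions`` is 4 (orthogonal), 8 (king) or 16 (king + knight).
    Knight moves are excluded when both orthogonal intermediate cells on the
    move's path are land.
    """
    if directions not in (4, 8, 16):
        raise ValueError("directions must be 4, 8 or 16")
    mask = grid.mask
    nrow, ncol = mask.shape
    node_index = -np.ones(mask.shape, dtype=np.int64)
    water_ij = np.argwhere(mask)
    node_index[mask] = np.arange(len(water_ij))

    moves = _KING[:4] if directions == 4 else list(_KING)
    if directions == 16:
        moves = moves + _KNIGHT

    rows, cols, data = [], [], []
    wi, wj = water_ij[:, 0], water_ij[:, 1]
    for dr, dc, w in moves:
        ti, tj = wi + dr, wj + dc
        ok = (ti >= 0) & (ti < nrow) & (tj >= 0) & (tj < ncol)
        ok[ok] &= mask[ti[ok], tj[ok]]
        if abs(dr) + abs(dc) == 3:  # knight: check intermediate cells
            sr, sc = np.sign(dr), np.sign(dc)
            if abs(dc) == 2:
                m1 = (wi, wj + sc)
                m2 = (wi + dr, wj + sc)
            else:
                m1 = (wi + sr, wj)
                m2 = (wi + sr, wj + dc)
            inter_ok = np.zeros(len(wi), dtype=bool)
            for mi, mj in (m1, m2):
                inb = (mi >= 0) & (mi < nrow) & (mj >= 0) & (mj < ncol)
                good = np.zeros(len(wi), dtype=bool)
                good[inb] = mask[mi[inb], mj[inb]]
                inter_ok |= good
            ok &= inter_ok
        src = node_index[wi[ok], wj[ok]]
        dst = node_index[ti[ok], tj[ok]]
        rows.append(src)
        cols.append(dst)
        data.append(np.full(len(src), w * grid.pixel_size))
    n = len(water_ij)
    adjacency = coo_matrix(
        (np.concatenate(data) if data else np.empty(0),
         (np.concatenate(rows) if rows else np.empty(0, dtype=int),
          np.concatenate(cols) if cols else np.empty(0, dtype=int))),
        shape=(n, n)).tocsr()
    return MovementGraph(grid=grid, directions=directions,
                         adjacency=adjacency, node_index=node_index,
                         nodes=water_ij)


def water_distance(graph: MovementGraph, origin: tuple[float, float],
                   destination: tuple[float, float]) -> float:
    """By-water shortest-path distance between two planar points, in km.

    Returns ``inf`` when the points lie in disconnected water bodies.
    """
    s = graph.snap(*origin)
    t = graph.snap(*destination)
    d = dijkstra(graph.adjacency, directed=False, indices=s,
                 min_only=False)[t]
    if not np.isfinite(d):
        logger.warning("points %s and %s are not connected by water",
                       origin, destination)
    return float(d) / 1000.0


def distance_matrix(graph: MovementGraph,
                    points: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """All pairwise by-water distances (km) between labelled points.

    Disconnected pairs get ``inf``. The result is symmetric with zero
    diagonal by construction of the undirected graph.
    """
    labels = list(points)
    nodes = [graph.snap(*points[lab]) for lab in labels]
    dist = dijkstra(graph.adjacency, directed=False, indices=nodes) / 1000.0
    out = dist[:, nodes]
    out = (out + out.T) / 2.0  # symmetrise away float noise
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=labels, columns=labels)


def array_representative_points(receivers: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Representative point per array: its median-rank receiver's position."""
    points = {}
    for array_id, grp in receivers.groupby("array_id"):
        g = grp.sort_values("rank").reset_index(drop=True)
        mid = g.iloc[(len(g) - 1) // 2]
        points[str(array_id)] = (float(mid["x"]), float(mid["y"]))
    return points


@dataclass
class PathwayPolyline:
    """Minimum-distance water-constrained route linking array passage points."""

    tag_id: str
    vertices: list[tuple[float, float]] = field(default_factory=list)
    length_km: float = 0.0


def shortest_path_vertices(graph: MovementGraph, origin, destination):
    """Vertex list (cell centres) and length (km) of one water shortest path."""
    s = graph.snap(*origin)
    t = graph.snap(*destination)
    dist, pred = dijkstra(graph.adjacency, directed=False, indices=s,
                          return_predecessors=True)
    if not np.isfinite(dist[t]):
        return None, float("inf")
    path = [t]
    while path[-1] != s:
        path.append(pred[path[-1]])
    path.reverse()
    verts = [graph.grid.centre_of(*graph.nodes[k]) for k in path]
    return verts, float(dist[t]) / 1000.0


def pathway_polyline(
    tag_id: str,
    passage_points: list[tuple[float, float]],
    graph: MovementGraph,
) -> PathwayPolyline | None:
    """Concatenate water shortest paths between successive passage points.

    ``passage_points`` are the first-detection receiver positions at the
    arrays the fish visited, in visit order. Returns ``None`` (logged) when
    fewer than two arrays were visited.
    """
    if len(passage_points) < 2:
        logger.info("tag %s visited fewer than two arrays; no polyline", tag_id)
        return None
    vertices: list[tuple[float, float]] = []
    total = 0.0
    for a, b in zip(passage_points, passage_points[1:]):
        verts, d = shortest_path_vertices(graph, a, b)
        if verts is None:
            logger.warning("tag %s: no water path between %s and %s",
                           tag_id, a, b)
            return None
        if vertices:
            verts = verts[1:]
        vertices.extend(verts)
        total += d
    return PathwayPolyline(tag_id=tag_id, vertices=vertices, length_km=total)
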
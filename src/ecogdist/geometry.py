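"""Electrode/lesion geometry on cortical surface meshes.

This module holds the spatial core of the analysis: binary lesion volumes in
world (mm) coordinates, triangulated cortical surfaces, electrode grids and
strips with partially known positions, and the three lesion-electrode distance
models used throughout the package:

``d_edge``
    Euclidean distance from a point to the closest lesion voxel (edge of the
    lesion).
``d_com``
    Euclidean distance from a point to the lesion's centre of mass (COM).
``d_geo``
    The geodesic model: a straight segment from the COM to the cortical
    surface plus the shortest on-surface path from that entry point to the
    electrode.

All coordinates are world millimetres.  Voxel index ``i`` maps to the centre
of voxel ``i`` through the affine (0-based indices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "LesionVolume",
    "CorticalSurface",
    "ElectrodeArray",
    "BipolarChannel",
    "center_of_mass",
    "lesion_volume_cm3",
    "euclidean_edge_distance",
    "euclidean_com_distance",
    "geodesic_distance",
    "geodesic_distances",
    "bipolar_midpoint",
    "extrapolate_grid",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class LesionVolume:
    """A binary lesion segmentation with an index-to-world affine.

    Parameters
    ----------
    mask : (I, J, K) array of bool
        Foreground voxels are lesion tissue.  Must contain at least one
        foreground voxel.
    affine : (4, 4) array
        Maps 0-based voxel indices to the voxel-centre world coordinate (mm).
    """

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("lesion mask must be a 3-D array")
        if not self.mask.any():
            raise ValueError(
                "lesion mask has no foreground voxels: degenerate segmentation"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        self._world = None
        self._tree = None
        self._com = None

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def foreground_world(self) -> np.ndarray:
        """World coordinates (mm) of all foreground voxel centres."""
        if self._world is None:
            idx = np.argwhere(self.mask).astype(float)
            self._world = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return self._world

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.foreground_world())
        return self._tree

    def contains(self, point: np.ndarray) -> bool:
        """Whether ``point`` falls inside a foreground voxel."""
        inv = np.linalg.inv(self.affine)
        ijk = np.rint(inv[:3, :3] @ np.asarray(point, float) + inv[:3, 3])
        ijk = ijk.astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.mask.shape):
            return False
        return bool(self.mask[tuple(ijk)])


@dataclass
class CorticalSurface:
    """A triangulated cortical surface in world millimetres.

    The mesh must be a single connected component with strictly positive
    edge lengths; both are validated at construction.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) triangle array")
        n = len(self.vertices)
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= n:
            raise ValueError("face indices out of range")
        self._tree = None
        self._proj = None
        self._graphs: dict[int, sparse.csr_matrix] = {}
        edges = self._edge_array()
        lengths = np.linalg.norm(
            self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]], axis=1
        )
        if np.any(lengths <= 0):
            raise ValueError("mesh has zero-length edges")
        adj = self.edge_graph()
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValueError(f"mesh is not connected ({n_comp} components)")

    def _edge_array(self) -> np.ndarray:
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_graph(self) -> sparse.csr_matrix:
        """Symmetric sparse edge-length graph of the mesh (1-ring)."""
        return self.ring_graph(1)

    def ring_graph(self, n_ring: int = 1) -> sparse.csr_matrix:
        """Graph joining vertices at most ``n_ring`` mesh edges apart.

        Edge weights are straight-line (chord) distances between the two
        vertices; for ``n_ring == 1`` this is exactly the mesh edge graph.
        Larger rings add near-tangent shortcuts that cut the lattice
        anisotropy of on-graph shortest paths.
        """
        if n_ring < 1:
            raise ValueError("n_ring must be >= 1")
        if n_ring in self._graphs:
            return self._graphs[n_ring]
        n = len(self.vertices)
        e = self._edge_array()
        a = sparse.coo_matrix(
            (np.ones(len(e), bool), (e[:, 0], e[:, 1])), shape=(n, n)
        )
        a = (a + a.T + sparse.identity(n, dtype=bool)).tocsr()
        reach = a.copy()
        for _ in range(n_ring - 1):
            reach = (reach @ a).astype(bool)
        reach = sparse.triu(reach, k=1).tocoo()
        w = np.linalg.norm(
            self.vertices[reach.row] - self.vertices[reach.col], axis=1
        )
        g = sparse.coo_matrix((w, (reach.row, reach.col)), shape=(n, n))
        g = (g + g.T).tocsr()
        self._graphs[n_ring] = g
        return g

    def vertex_tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.vertices)
        return self._tree

    def nearest_vertex(self, point: np.ndarray) -> int:
        """Index of the vertex closest to ``point``; ties go to the lowest index."""
        tree = self.vertex_tree()
        d, i = tree.query(np.asarray(point, float), k=2)
        if abs(d[0] - d[1]) < 1e-12:
            return int(min(i[0], i[1]))
        return int(i[0])

    def projector(self) -> "SurfaceProjector":
        if self._proj is None:
            self._proj = SurfaceProjector(self)
        return self._proj

    @property
    def max_edge_length(self) -> float:
        e = self._edge_array()
        return float(
            np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
            ).max()
        )


@dataclass
class ElectrodeArray:
    """A rows x cols electrode grid or strip with partially known positions.

    ``coordinates`` is an (n_rows * n_cols, 3) array in row-major electrode
    order; unknown positions are NaN.  ``visible`` flags electrodes whose
    positions were observed (e.g. on an intraoperative photograph) rather
    than extrapolated.
    """

    array_id: str
    n_rows: int
    n_cols: int
    coordinates: np.ndarray
    visible: np.ndarray
    nominal_spacing: float = 10.0

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 2:
            raise ValueError("array must have at least 2 electrodes")
        if self.nominal_spacing <= 0:
            raise ValueError("nominal_spacing must be positive")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        n = self.n_rows * self.n_cols
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (n_rows*n_cols, 3)")
        if self.visible.shape != (n,):
            raise ValueError("visible must have one flag per electrode")
        known = self.visible & np.isfinite(self.coordinates).all(axis=1)
        if known.sum() < 2:
            raise ValueError(
                f"array {self.array_id}: need >=2 visible electrodes with "
                "coordinates"
            )

    def index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def rc(self, i: int) -> tuple[int, int]:
        return divmod(i, self.n_cols)

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def known_mask(self) -> np.ndarray:
        return np.isfinite(self.coordinates).all(axis=1)


@dataclass
class BipolarChannel:
    """One bipolar channel: two adjacent electrodes and their midpoint."""

    channel_id: str
    electrode_a: int
    electrode_b: int
    midpoint: np.ndarray
    d_edge: float = np.nan
    d_com: float = np.nan
    d_geo: float = np.nan


# --------------------------------------------------------------------------
# point-to-surface projection (no spatial-index dependency)
# --------------------------------------------------------------------------


class SurfaceProjector:
    """Closest-point queries against a triangle mesh.

    Candidate triangles are those incident to the ``k`` vertices nearest the
    query point; for the smooth, well-shaped meshes used here this is exact
    for all practical purposes and needs only a KD-tree over vertices.
    """

    def __init__(self, surface: CorticalSurface, k: int = 8):
        self.surface = surface
        self.k = min(k, len(surface.vertices))
        self.tree = surface.vertex_tree()
        faces = surface.faces
        incident: list[list[int]] = [[] for _ in range(len(surface.vertices))]
        for fi, f in enumerate(faces):
            for v in f:
                incident[v].append(fi)
        self._incident = [np.array(ix, dtype=np.int64) for ix in incident]
        self._tri = surface.vertices[faces]  # (m, 3, 3)

    def project(self, point: np.ndarray) -> tuple[np.ndarray, float]:
        """Return (closest point on surface, distance)."""
        cp, d, _ = self.project_face(point)
        return cp, d

    def project_face(self, point: np.ndarray) -> tuple[np.ndarray, float, int]:
        """Return (closest point, distance, index of the face it lies on)."""
        p = np.asarray(point, dtype=float)
        _, vi = self.tree.query(p, k=self.k)
        vi = np.atleast_1d(vi)
        fids = np.unique(np.concatenate([self._incident[v] for v in vi]))
        tri = self._tri[fids]
        cp = _closest_point_on_triangles(p, tri)
        d = np.linalg.norm(cp - p, axis=1)
        j = int(np.argmin(d))
        return cp[j], float(d[j]), int(fids[j])

    def face_normal(self, face_id: int) -> np.ndarray:
        a, b, c = self._tri[face_id]
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n)

    def distance(self, point: np.ndarray) -> float:
        return self.project(point)[1]


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle in ``tri`` (m, 3, 3).

    Vectorised version of the standard region-classification algorithm
    (Ericson, *Real-Time Collision Detection*, ch. 5).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(d1 - d3 == 0, 1.0, d1 - d3)
    v = (d1 / denom)[:, None]
    out[m] = (a + v * ab)[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(d2 - d6 == 0, 1.0, d2 - d6)
    w = (d2 / denom)[:, None]
    out[m] = (a + w * ac)[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom == 0, 1.0, denom)
    w = ((d4 - d3) / denom)[:, None]
    out[m] = (b + w * (c - b))[m]
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = (vb / denom)[:, None]
    w = (vc / denom)[:, None]
    out[m] = (a + v * ab + w * ac)[m]
    return out


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------


def center_of_mass(lesion: LesionVolume) -> np.ndarray:
    """Unweighted mean world coordinate of all foreground voxel centres (mm)."""
    if lesion._com is None:
        lesion._com = lesion.foreground_world().mean(axis=0)
    return lesion._com


def lesion_volume_cm3(lesion: LesionVolume) -> float:
    """Lesion volume: foreground voxel count x voxel volume, in cm^3."""
    return float(lesion.n_foreground * np.prod(lesion.voxel_size) / 1000.0)


def euclidean_edge_distance(point: np.ndarray, lesion: LesionVolume) -> float:
    """Euclidean distance (mm) from ``point`` to the closest lesion voxel.

    A point lying inside a foreground voxel gets distance 0 (electrodes
    essentially never do in practice; the convention keeps the measure
    well defined).  Otherwise the minimum distance to any foreground voxel
    centre is returned.
    """
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    if lesion.contains(p):
        return 0.0
    d, _ = lesion._kdtree().query(p)
    return float(d)


def euclidean_com_distance(point: np.ndarray, lesion: LesionVolume) -> float:
    """Euclidean distance (mm) from ``point`` to the lesion centre of mass."""
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    return float(np.linalg.norm(p - center_of_mass(lesion)))


def geodesic_distances(
    points: np.ndarray,
    lesion: LesionVolume,
    surface: CorticalSurface,
    n_ring: int = 3,
    snap_tol: float | None = None,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Geodesic lesion distance for many electrode points at once.

    The distance is ``L1 + L2``: ``L1`` the straight segment from the lesion
    COM to its nearest surface vertex ``P``, and ``L2`` the shortest on-graph
    path from ``P`` to the vertex nearest each electrode, computed on the
    ``n_ring`` chord graph of the mesh (``n_ring=1`` is the raw edge graph).

    Electrode points must lie within ``snap_tol`` of the surface (default:
    the longest mesh edge) — electrodes sit on the cortex, so a distant
    point signals a localization problem and raises, naming the electrode.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if snap_tol is None:
        snap_tol = surface.max_edge_length
    proj = surface.projector()
    for i, p in enumerate(pts):
        d = proj.distance(p)
        if d > snap_tol:
            name = labels[i] if labels is not None else f"#{i}"
            raise ValueError(
                f"electrode {name} is {d:.2f} mm from the surface "
                f"(snap tolerance {snap_tol:.2f} mm)"
            )
    com = center_of_mass(lesion)
    p_idx = surface.nearest_vertex(com)
    l1 = float(np.linalg.norm(com - surface.vertices[p_idx]))
    targets = np.array([surface.nearest_vertex(p) for p in pts])
    graph = surface.ring_graph(n_ring)
    dist = dijkstra(graph, directed=False, indices=p_idx)
    l2 = dist[targets]
    if np.any(~np.isfinite(l2)):
        raise ValueError(
            "surface entry point and electrode lie in disconnected mesh parts"
        )
    return l1 + l2


def geodesic_distance(
    point: np.ndarray,
    lesion: LesionVolume,
    surface: CorticalSurface,
    n_ring: int = 3,
    snap_tol: float | None = None,
    label: str | None = None,
) -> float:
    """Geodesic lesion distance (mm) for a single electrode point."""
    labels = [label] if label is not None else None
    return float(
        geodesic_distances(
            np.asarray(point, float)[None, :],
            lesion,
            surface,
            n_ring=n_ring,
            snap_tol=snap_tol,
            labels=labels,
        )[0]
    )


def bipolar_midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spatial midpoint of two neighbouring electrode coordinates (mm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("electrode coordinates must be finite")
    return (a + b) / 2.0


# --------------------------------------------------------------------------
# grid extrapolation
# --------------------------------------------------------------------------


def _march_point(
    proj: SurfaceProjector,
    x_prev: np.ndarray,
    x_cur: np.ndarray,
    spacing: float,
    max_iter: int = 120,
    tol: float = 1e-10,
) -> np.ndarray:
    """Next lattice point on the surface continuing the x_prev -> x_cur line.

    Alternates projection onto the surface with rescaling to chord length
    ``spacing`` from ``x_cur``; on a plane this is exact, on smooth curved
    surfaces it converges to the intersection of the chord sphere with the
    surface on the continuation side.
    """
    d = x_cur - x_prev
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("degenerate direction: coincident support electrodes")
    y = x_cur + spacing * d / nrm
    for _ in range(max_iter):
        ys, _ = proj.project(y)
        v = ys - x_cur
        n = np.linalg.norm(v)
        if n == 0:
            ys = ys + 1e-9
            v = ys - x_cur
            n = np.linalg.norm(v)
        y_new = x_cur + spacing * v / n
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def _corner_point(
    proj: SurfaceProjector,
    x_a: np.ndarray,
    x_b: np.ndarray,
    x_diag: np.ndarray,
    spacing: float,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> np.ndarray:
    """Complete a lattice quad: point at chord ``spacing`` from both ``x_a``
    and ``x_b``, seeded at the parallelogram completion away from ``x_diag``."""
    y = x_a + x_b - x_diag
    for _ in range(max_iter):
        ys, _ = proj.project(y)
        v = ys - x_a
        n = np.linalg.norm(v)
        y1 = x_a + spacing * v / n if n > 0 else ys
        v = y1 - x_b
        n = np.linalg.norm(v)
        y_new = x_b + spacing * v / n if n > 0 else y1
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def _has_adjacent_visible_pair(array: ElectrodeArray) -> bool:
    vis = array.visible & array.known_mask()
    for i in range(array.n_electrodes):
        if not vis[i]:
            continue
        r, c = array.rc(i)
        if c + 1 < array.n_cols and vis[array.index(r, c + 1)]:
            return True
        if r + 1 < array.n_rows and vis[array.index(r + 1, c)]:
            return True
    return False


def extrapolate_grid(
    array: ElectrodeArray,
    surface: CorticalSurface,
    chord_tol: float = 0.2,
    snap_tol: float = 1.0,
) -> ElectrodeArray:
    """Fill in hidden electrode positions on the cortical surface.

    Visible electrodes anchor the array; missing electrodes (NaN
    coordinates) are placed sequentially on the surface so that the chord
    distance between layout-adjacent electrodes equals ``nominal_spacing``,
    marching outward with two rules:

    * **in-line**: two consecutive known electrodes in the same row or
      column define the continuation direction for the next one;
    * **corner**: an L of three known electrodes is completed to a lattice
      quad (both new chords equal the spacing).

    Visible electrodes are never moved; the operation is idempotent.

    Raises
    ------
    ValueError
        Fewer than 2 visible electrodes, no layout-adjacent visible pair,
        a visible electrode off the surface by more than ``snap_tol``, or
        infeasible placement (rules cannot reach some electrode, or a
        placed point violates the chord/snap tolerances).
    """
    if not _has_adjacent_visible_pair(array):
        raise ValueError(
            f"array {array.array_id}: no layout-adjacent pair of visible "
            "electrodes to define a direction"
        )
    proj = surface.projector()
    vis = array.visible & array.known_mask()
    for i in np.flatnonzero(vis):
        d = proj.distance(array.coordinates[i])
        if d > snap_tol:
            raise ValueError(
                f"array {array.array_id}: visible electrode {i} is "
                f"{d:.2f} mm from the surface (snap tolerance {snap_tol} mm)"
            )

    coords = array.coordinates.copy()
    known = array.known_mask().copy()
    s = array.nominal_spacing
    R, C = array.n_rows, array.n_cols
    idx = array.index

    def try_place(r: int, c: int) -> bool:
        # corner completion first: it pins the chord to BOTH lattice
        # neighbours, which keeps rows from drifting on curved surfaces
        for dr in (-1, 1):
            for dc in (-1, 1):
                r1, c1 = r + dr, c + dc
                if not (0 <= r1 < R and 0 <= c1 < C):
                    continue
                if known[idx(r1, c)] and known[idx(r, c1)] and known[idx(r1, c1)]:
                    coords[idx(r, c)] = _corner_point(
                        proj,
                        coords[idx(r, c1)],
                        coords[idx(r1, c)],
                        coords[idx(r1, c1)],
                        s,
                    )
                    return True
        # in-line along the row, both directions
        for dc in (-1, 1):
            c1, c2 = c + dc, c + 2 * dc
            if 0 <= c2 < C and known[idx(r, c1)] and known[idx(r, c2)]:
                coords[idx(r, c)] = _march_point(
                    proj, coords[idx(r, c2)], coords[idx(r, c1)], s
                )
                return True
        # in-line along the column
        for dr in (-1, 1):
            r1, r2 = r + dr, r + 2 * dr
            if 0 <= r2 < R and known[idx(r1, c)] and known[idx(r2, c)]:
                coords[idx(r, c)] = _march_point(
                    proj, coords[idx(r2, c)], coords[idx(r1, c)], s
                )
                return True
        return False

    missing = [i for i in range(R * C) if not known[i]]
    while missing:
        progressed = False
        for i in list(missing):
            r, c = array.rc(i)
            if try_place(r, c):
                known[i] = True
                missing.remove(i)
                progressed = True
        if not progressed:
            raise ValueError(
                f"array {array.array_id}: placement infeasible — electrodes "
                f"{missing} cannot be reached from the visible set"
            )

    # verify the result
    for i in range(R * C):
        if array.known_mask()[i]:
            continue  # pre-existing coordinates are not re-checked
        d = proj.distance(coords[i])
        if d > snap_tol:
            raise ValueError(
                f"array {array.array_id}: extrapolated electrode {i} is "
                f"{d:.2f} mm off the surface (placement infeasible)"
            )
    for r in range(R):
        for c in range(C):
            for r2, c2 in ((r, c + 1), (r + 1, c)):
                if r2 >= R or c2 >= C:
                    continue
                chord = np.linalg.norm(coords[idx(r, c)] - coords[idx(r2, c2)])
                if abs(chord - s) > chord_tol:
                    raise ValueError(
                        f"array {array.array_id}: chord between ({r},{c}) and "
                        f"({r2},{c2}) is {chord:.3f} mm, outside "
                        f"{s} +/- {chord_tol} mm (placement infeasible)"
                    )

    return ElectrodeArray(
        array_id=array.array_id,
        n_rows=R,
        n_cols=C,
        coordinates=coords,
        visible=array.visible.copy(),
        nominal_spacing=s,
    )
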
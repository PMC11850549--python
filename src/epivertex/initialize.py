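"""Initial conditions: centroidal Voronoi tilings and deterministic fixtures.

A disordered but uniform confluent tiling of the square box ``[0, L]^2`` is
produced by Lloyd's algorithm: random seed points are moved to the centroids
of their Voronoi tiles until the tiling is (numerically) centroidal.  Straight
box walls are obtained by mirroring seed points across each wall within a
cutoff distance, so that the walls themselves are Voronoi bisectors.  The
outermost vertex layers are then clamped, emulating attachment to a rigid
surrounding tissue.

Cells whose centroid falls inside the centred ``L_a x L_a`` square become
*active* (they may grow, divide and ingress); all others are *passive*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

from .mesh import ACTIVE, PASSIVE, OUTER, MeshError, TissueMesh, \
    mesh_from_indexed_polygons


class LloydConvergenceError(Exception):
    """Lloyd iteration failed to reach the displacement tolerance."""


@dataclass
class InitConfig:
    """Everything needed to build one initial tissue.

    ``lloyd_tol`` is the maximum per-seed displacement between consecutive
    Lloyd iterations, measured relative to the box size ``L``.
    ``mirror_cutoff`` (default ``2 L / sqrt(N)``, about two cell diameters)
    sets how deep a layer of seeds is mirrored across the walls.
    ``clamp_rings`` counts how many vertex rings beyond the wall vertices are
    frozen (the wall vertices themselves are always clamped).
    """

    n_cells: int = 1000
    box_size: float = 50.0
    patch_size: float = 20.0
    lloyd_tol: float = 5e-5
    mirror_cutoff: float | None = None
    p0_active: float = 3.60
    p0_passive: float = 3.80
    target_perimeter_mean: float = 5.98
    target_perimeter_sd: float = 0.3
    seed: int = 0
    clamp_rings: int = 1
    lloyd_max_iter: int = 5000
    target_perimeter_from_tiling: bool = False

    def __post_init__(self):
        if not (0 < self.patch_size < self.box_size):
            raise ValueError("require 0 < patch_size < box_size")
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells")
        if self.target_perimeter_sd < 0:
            raise ValueError("target_perimeter_sd must be >= 0")
        if self.lloyd_tol <= 0:
            raise ValueError("lloyd_tol must be > 0")

    @property
    def effective_mirror_cutoff(self) -> float:
        if self.mirror_cutoff is not None:
            return self.mirror_cutoff
        return 2.0 * self.box_size / np.sqrt(self.n_cells)


# ---------------------------------------------------------------------- #
# Lloyd relaxation
# ---------------------------------------------------------------------- #

def _mirror_pad(points: np.ndarray, L: float, cutoff: float) -> np.ndarray:
    """Reflect seeds near walls (and corners) so walls become bisectors."""
    p = points
    pads = [p]
    near_l = p[:, 0] < cutoff
    near_r = p[:, 0] > L - cutoff
    near_b = p[:, 1] < cutoff
    near_t = p[:, 1] > L - cutoff
    for mask, sx, sy in ((near_l, -1, 1), (near_r, -1, 1),
                         (near_b, 1, -1), (near_t, 1, -1)):
        q = p[mask].copy()
        if sx < 0:
            q[:, 0] = -q[:, 0] if mask is near_l else 2 * L - q[:, 0]
        if sy < 0:
            q[:, 1] = -q[:, 1] if mask is near_b else 2 * L - q[:, 1]
        pads.append(q)
    for mx, my, cx, cy in ((near_l, near_b, 0.0, 0.0),
                           (near_l, near_t, 0.0, L),
                           (near_r, near_b, L, 0.0),
                           (near_r, near_t, L, L)):
        q = p[mx & my].copy()
        q[:, 0] = 2 * cx - q[:, 0]
        q[:, 1] = 2 * cy - q[:, 1]
        pads.append(q)
    return np.concatenate(pads)


def _voronoi_regions(points: np.ndarray, L: float, cutoff: float):
    """Voronoi tiling of the padded seed set.

    Returns ``(vertices, regions)`` where ``regions[i]`` lists CCW-ordered
    Voronoi-vertex indices of seed ``i``'s tile.  The cutoff is doubled (up
    to the box size) if some tile is unbounded or pokes out of the box, which
    can happen for strongly non-uniform seeds early in a Lloyd run.
    """
    eps = 1e-9 * L
    cut = cutoff
    while True:
        vor = Voronoi(_mirror_pad(points, L, cut))
        regions = []
        ok = True
        for i in range(len(points)):
            reg = vor.regions[vor.point_region[i]]
            if -1 in reg or len(reg) < 3:
                ok = False
                break
            verts = vor.vertices[reg]
            if (verts.min() < -eps) or (verts.max() > L + eps):
                ok = False
                break
            # CCW order by angle about the seed (tiles are convex)
            ang = np.arctan2(verts[:, 1] - points[i, 1],
                             verts[:, 0] - points[i, 0])
            regions.append([reg[j] for j in np.argsort(ang)])
        if ok:
            return vor.vertices, regions
        if cut >= L:
            raise MeshError("cannot bound all Voronoi tiles inside the box")
        cut = min(2 * cut, L)


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    q = np.roll(pts, -1, axis=0)
    w = pts[:, 0] * q[:, 1] - q[:, 0] * pts[:, 1]
    a = 0.5 * np.sum(w)
    return (pts + q).T @ w / (6.0 * a)


def _all_centroids(verts: np.ndarray, regions: list[list[int]]) -> np.ndarray:
    """Area centroids of many polygons sharing a vertex table (vectorised)."""
    lens = np.array([len(r) for r in regions])
    flat = np.concatenate([np.asarray(r) for r in regions])
    offs = np.concatenate([[0], np.cumsum(lens)])[:-1]
    nxt = np.concatenate([np.asarray(r[1:] + r[:1]) for r in regions])
    p = verts[flat]
    q = verts[nxt]
    w = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    a = 0.5 * np.add.reduceat(w, offs)
    cx = np.add.reduceat((p[:, 0] + q[:, 0]) * w, offs) / (6.0 * a)
    cy = np.add.reduceat((p[:, 1] + q[:, 1]) * w, offs) / (6.0 * a)
    return np.c_[cx, cy]


def lloyd_relax(points: np.ndarray, box_size: float, tol: float = 5e-5,
                cutoff: float | None = None,
                max_iter: int = 5000) -> np.ndarray:
    """Iterate seeds -> tile centroids until the tiling is centroidal.

    Convergence: the maximum seed displacement between consecutive
    iterations, divided by ``box_size``, drops below ``tol``.
    """
    pts = np.array(points, float)
    L = box_size
    if cutoff is None:
        cutoff = 2.0 * L / np.sqrt(max(len(pts), 1))
    for _ in range(max_iter):
        verts, regions = _voronoi_regions(pts, L, cutoff)
        new = _all_centroids(verts, regions)
        disp = np.max(np.linalg.norm(new - pts, axis=1)) / L
        pts = new
        if disp < tol:
            return pts
    raise LloydConvergenceError(
        f"no convergence after {max_iter} iterations "
        f"(residual {disp:.3e} >= tol {tol:.3e})")


# ---------------------------------------------------------------------- #
# mesh construction
# ---------------------------------------------------------------------- #

def _snap_and_merge(verts: np.ndarray, regions: list[list[int]], L: float):
    """Snap near-wall Voronoi vertices exactly onto the walls and merge
    numerically duplicate wall vertices (cocircular corner degeneracies)."""
    v = verts.copy()
    snap = 1e-7 * L
    for k in (0, 1):
        v[np.abs(v[:, k]) < snap, k] = 0.0
        v[np.abs(v[:, k] - L) < snap, k] = L
    # merge coincident wall vertices
    used = sorted({i for reg in regions for i in reg})
    alias = {}
    wall = [i for i in used
            if v[i, 0] in (0.0, L) or v[i, 1] in (0.0, L)]
    for a_i, i in enumerate(wall):
        for j in wall[a_i + 1:]:
            if j in alias or i in alias:
                continue
            if np.hypot(*(v[i] - v[j])) < 1e-6 * L:
                alias[j] = i
    if alias:
        regions = [[alias.get(i, i) for i in reg] for reg in regions]
        regions = [[i for k, i in enumerate(reg)
                    if i != reg[(k + 1) % len(reg)]] for reg in regions]
    return v, regions


def build_initial_tiling(config: InitConfig,
                         rng: np.random.Generator | None = None
                         ) -> TissueMesh:
    """Random seeds -> Lloyd-relaxed centroidal Voronoi tiling -> clamped mesh.

    The returned mesh is confluent on ``[0, L]^2`` with ``n_cells`` cells;
    boundary junctions lie exactly on the box walls and the outermost vertex
    layers are clamped.  Cell types/targets are not yet assigned (see
    :func:`assign_types_and_targets`).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.box_size
    pts = rng.uniform(0.0, L, size=(config.n_cells, 2))
    pts = lloyd_relax(pts, L, tol=config.lloyd_tol,
                      cutoff=config.effective_mirror_cutoff,
                      max_iter=config.lloyd_max_iter)
    verts, regions = _voronoi_regions(pts, L,
                                      config.effective_mirror_cutoff)
    verts, regions = _snap_and_merge(verts, regions, L)
    mesh = mesh_from_indexed_polygons(verts, regions, L=L,
                                      L_a=config.patch_size)
    clamp_boundary_layers(mesh, rings=config.clamp_rings)
    return mesh


def clamp_boundary_layers(mesh: TissueMesh, rings: int = 1):
    """Clamp wall vertices plus ``rings`` rings of neighbours inward."""
    layer = set(int(v) for v in mesh.boundary_vertices())
    clamped = set(layer)
    for _ in range(rings):
        nxt = set()
        for v in layer:
            for h in mesh.vertex_outgoing(v):
                nxt.add(int(mesh.he_origin[mesh.he_twin[h]]))
        layer = nxt - clamped
        clamped |= layer
    for v in clamped:
        mesh.clamp_vertex(v)


def sample_target_perimeter(rng: np.random.Generator, mu: float,
                            sigma: float) -> float:
    """Normal draw, resampled in the (astronomically unlikely) case P <= 0."""
    while True:
        p = rng.normal(mu, sigma)
        if p > 0:
            return float(p)


def assign_types_and_targets(mesh: TissueMesh, config: InitConfig,
                             rng: np.random.Generator) -> TissueMesh:
    """Partition cells into active patch / passive surround and set targets.

    Active cells draw their target perimeter from N(mu, sigma) with target
    area ``(P0 / p0_active)^2``; passive cells share the fixed pair
    ``(P0_passive, (P0_passive / p0_passive)^2)``.  The patch membership test
    uses the cell's area centroid in the half-open centred square.
    """
    L, La = config.box_size, config.patch_size
    lo, hi = (L - La) / 2.0, (L + La) / 2.0
    mu, sigma = config.target_perimeter_mean, config.target_perimeter_sd
    if config.target_perimeter_from_tiling:
        mu = float(np.mean([mesh.cell_perimeter(c)
                            for c in mesh.alive_cells()]))
    for c in mesh.alive_cells():
        cx, cy = mesh.cell_centroid(c)
        if lo <= cx < hi and lo <= cy < hi:
            P0 = sample_target_perimeter(rng, mu, sigma)
            mesh.c_kind[c] = ACTIVE
            mesh.c_P0[c] = P0
            mesh.c_A0[c] = (P0 / config.p0_active) ** 2
        else:
            mesh.c_kind[c] = PASSIVE
            mesh.c_P0[c] = mu if config.target_perimeter_from_tiling \
                else config.target_perimeter_mean
            mesh.c_A0[c] = (mesh.c_P0[c] / config.p0_passive) ** 2
    mesh.seed = config.seed
    return mesh


def build_tissue(config: InitConfig,
                 rng: np.random.Generator | None = None) -> TissueMesh:
    """Convenience wrapper: tiling + clamping + types/targets."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mesh = build_initial_tiling(config, rng)
    return assign_types_and_targets(mesh, config, rng)


# ---------------------------------------------------------------------- #
# deterministic fixtures
# ---------------------------------------------------------------------- #

def make_hexagonal_fixture(rows: int, cols: int, side: float = 1.0,
                           clamp_boundary: bool = False) -> TissueMesh:
    """Regular pointy-top honeycomb patch of ``rows x cols`` unit cells.

    Corner coordinates are generated on an exact integer lattice (multiples
    of ``sqrt(3)/2 * side`` in x and ``side / 2`` in y) so shared vertices
    deduplicate exactly.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows, cols must be >= 1")
    keys: dict[tuple[int, int], int] = {}
    coords: list[tuple[int, int]] = []
    polys = []
    # CCW corner offsets in lattice units
    offs = [(1, -1), (1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2)]
    for j in range(rows):
        for i in range(cols):
            kx0 = 2 * i + (j % 2)
            ky0 = 3 * j
            ids = []
            for ox, oy in offs:
                key = (kx0 + ox, ky0 + oy)
                if key not in keys:
                    keys[key] = len(coords)
                    coords.append(key)
                ids.append(keys[key])
            polys.append(ids)
    lat = np.asarray(coords, float)
    pts = np.empty_like(lat)
    pts[:, 0] = lat[:, 0] * (np.sqrt(3.0) / 2.0 * side)
    pts[:, 1] = lat[:, 1] * (side / 2.0)
    mesh = mesh_from_indexed_polygons(pts, polys)
    A0 = 3.0 * np.sqrt(3.0) / 2.0 * side ** 2
    for c in mesh.alive_cells():
        mesh.c_A0[c] = A0
        mesh.c_P0[c] = 6.0 * side
        mesh.c_kind[c] = ACTIVE
    if clamp_boundary:
        for v in mesh.boundary_vertices():
            mesh.clamp_vertex(int(v))
    return mesh


def make_polygon_cell(points, A0: float | None = None,
                      P0: float | None = None,
                      kind: int = ACTIVE) -> TissueMesh:
    """Single-cell mesh from an explicit vertex loop (unit-test workhorse)."""
    pts = np.asarray(points, float)
    mesh = mesh_from_indexed_polygons(pts, [list(range(len(pts)))])
    c = int(mesh.alive_cells()[0])
    mesh.c_A0[c] = mesh.cell_area(c) if A0 is None else A0
    mesh.c_P0[c] = mesh.cell_perimeter(c) if P0 is None else P0
    mesh.c_kind[c] = kind
    return mesh


def regular_polygon(n: int, side: float = 1.0,
                    center=(0.0, 0.0)) -> np.ndarray:
    """Vertices of a regular n-gon with given side length, CCW."""
    R = side / (2.0 * np.sin(np.pi / n))
    ang = np.arange(n) * 2.0 * np.pi / n
    return np.c_[center[0] + R * np.cos(ang), center[1] + R * np.sin(ang)]
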
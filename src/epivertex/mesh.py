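"""Half-edge (doubly connected edge list) mesh for 2D vertex-model tissues.

The tissue is a confluent polygonal tiling of a square (or free-floating)
domain.  Cells are counterclockwise-wound faces; every undirected junction is
a pair of twinned half-edges; the unbounded region outside the tiling is a
single outer face with id ``OUTER``.  Vertices are the dynamical degrees of
freedom of the model; cells carry the target area/perimeter that enter the
shape energy.

All entities live in flat numpy arrays with append-only ids: dead entries are
tombstoned (``alive`` flags) and ids are never reused within a run, so event
logs can refer to cells and junctions long after they have disappeared.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

#: face id of the single unbounded outer face
OUTER = -1

#: coincidence tolerance for geometric predicates, in simulation length units
COORD_TOL = 1e-9

ACTIVE = 1
PASSIVE = 0

_KIND_NAMES = {ACTIVE: "active", PASSIVE: "passive"}
_KIND_CODES = {v: k for k, v in _KIND_NAMES.items()}


class MeshError(Exception):
    """Structural error in a tissue mesh or an invalid mesh operation."""


@dataclass
class _Compiled:
    """Flat index arrays for the current topology (positions not included).

    Rebuilt lazily whenever the topology version changes; all heavy per-step
    numerics (forces, areas, T1 scans, observable sampling) run off these
    arrays with fancy indexing into the live position array.
    """

    he: np.ndarray          # alive interior half-edge ids (cell != OUTER)
    o: np.ndarray           # origin vertex id per half-edge
    no: np.ndarray          # origin of next half-edge (head vertex)
    po: np.ndarray          # origin of prev half-edge
    hc: np.ndarray          # compact cell index per half-edge
    cells: np.ndarray       # alive cell ids, ascending (compact order)
    cell_index: dict        # cell id -> compact index
    free_verts: np.ndarray  # alive, unclamped vertex ids
    t1_he: np.ndarray       # interior junction candidates for T1 (he id)
    t1_a: np.ndarray        # their origin vertex
    t1_b: np.ndarray        # their head vertex
    nbr_cell: np.ndarray    # cell id on the twin side per half-edge (OUTER ok)


class TissueMesh:
    """Mutable polygonal tiling: vertices, half-edges ("junctions"), cells."""

    _INIT_CAP = 32

    def __init__(self, L: float | None = None, L_a: float | None = None):
        cap = self._INIT_CAP
        self.vx = np.zeros((cap, 2))
        self.v_alive = np.zeros(cap, bool)
        self.v_clamped = np.zeros(cap, bool)

        self.he_origin = np.full(cap, -9, np.int64)
        self.he_twin = np.full(cap, -9, np.int64)
        self.he_next = np.full(cap, -9, np.int64)
        self.he_prev = np.full(cap, -9, np.int64)
        self.he_cell = np.full(cap, -9, np.int64)
        self.he_alive = np.zeros(cap, bool)

        self.c_kind = np.zeros(cap, np.int8)
        self.c_A0 = np.zeros(cap)
        self.c_P0 = np.zeros(cap)
        self.c_gen = np.zeros(cap, np.int64)
        self.c_alive = np.zeros(cap, bool)
        self.c_he = np.full(cap, -9, np.int64)  # one alive half-edge per cell

        self.nv = 0
        self.nh = 0
        self.nc = 0

        self.L = L
        self.L_a = L_a
        self.time = 0.0
        self.seed: int | None = None

        self.topology_version = 0
        self._cache: _Compiled | None = None
        self._clamp_ref: dict[int, tuple[float, float]] = {}

    # ------------------------------------------------------------------ #
    # storage management
    # ------------------------------------------------------------------ #

    def _grow_v(self):
        cap = len(self.v_alive)
        self.vx = np.concatenate([self.vx, np.zeros((cap, 2))])
        self.v_alive = np.concatenate([self.v_alive, np.zeros(cap, bool)])
        self.v_clamped = np.concatenate([self.v_clamped, np.zeros(cap, bool)])

    def _grow_h(self):
        cap = len(self.he_alive)
        for name in ("he_origin", "he_twin", "he_next", "he_prev", "he_cell"):
            setattr(self, name, np.concatenate(
                [getattr(self, name), np.full(cap, -9, np.int64)]))
        self.he_alive = np.concatenate([self.he_alive, np.zeros(cap, bool)])

    def _grow_c(self):
        cap = len(self.c_alive)
        self.c_kind = np.concatenate([self.c_kind, np.zeros(cap, np.int8)])
        self.c_A0 = np.concatenate([self.c_A0, np.zeros(cap)])
        self.c_P0 = np.concatenate([self.c_P0, np.zeros(cap)])
        self.c_gen = np.concatenate([self.c_gen, np.zeros(cap, np.int64)])
        self.c_alive = np.concatenate([self.c_alive, np.zeros(cap, bool)])
        self.c_he = np.concatenate([self.c_he, np.full(cap, -9, np.int64)])

    def bump(self):
        """Invalidate compiled caches after a topological change."""
        self.topology_version += 1
        self._cache = None

    # ------------------------------------------------------------------ #
    # entity creation / removal
    # ------------------------------------------------------------------ #

    def new_vertex(self, pos, clamped: bool = False) -> int:
        if self.nv == len(self.v_alive):
            self._grow_v()
        v = self.nv
        self.nv += 1
        self.vx[v] = pos
        self.v_alive[v] = True
        if clamped:
            self.clamp_vertex(v)
        self.bump()
        return v

    def new_halfedge(self, origin=-9, twin=-9, nxt=-9, prv=-9, cell=-9) -> int:
        if self.nh == len(self.he_alive):
            self._grow_h()
        h = self.nh
        self.nh += 1
        self.he_origin[h] = origin
        self.he_twin[h] = twin
        self.he_next[h] = nxt
        self.he_prev[h] = prv
        self.he_cell[h] = cell
        self.he_alive[h] = True
        self.bump()
        return h

    def new_cell(self, kind=PASSIVE, A0=1.0, P0=1.0, generation=0) -> int:
        if self.nc == len(self.c_alive):
            self._grow_c()
        c = self.nc
        self.nc += 1
        self.c_kind[c] = kind
        self.c_A0[c] = A0
        self.c_P0[c] = P0
        self.c_gen[c] = generation
        self.c_alive[c] = True
        self.bump()
        return c

    def kill_vertex(self, v: int):
        self.v_alive[v] = False
        self._clamp_ref.pop(v, None)
        self.bump()

    def kill_halfedge(self, h: int):
        self.he_alive[h] = False
        self.bump()

    def kill_cell(self, c: int):
        self.c_alive[c] = False
        self.bump()

    def clamp_vertex(self, v: int):
        self.v_clamped[v] = True
        self._clamp_ref[v] = (float(self.vx[v, 0]), float(self.vx[v, 1]))

    # ------------------------------------------------------------------ #
    # traversal
    # ------------------------------------------------------------------ #

    def cell_halfedges(self, c: int) -> list[int]:
        """Half-edges of cell ``c`` in counterclockwise cycle order."""
        h0 = int(self.c_he[c])
        out = [h0]
        h = int(self.he_next[h0])
        while h != h0:
            out.append(h)
            if len(out) > self.nh:
                raise MeshError(f"unclosed cycle for cell {c}")
            h = int(self.he_next[h])
        return out

    def cell_vertex_ids(self, c: int) -> list[int]:
        return [int(self.he_origin[h]) for h in self.cell_halfedges(c)]

    def cell_polygon(self, c: int) -> np.ndarray:
        """(k, 2) array of the cell's vertex positions in CCW order."""
        return self.vx[self.cell_vertex_ids(c)]

    def cell_size(self, c: int) -> int:
        return len(self.cell_halfedges(c))

    def vertex_outgoing(self, v: int) -> list[int]:
        """Outgoing half-edges around vertex ``v`` in CCW order."""
        cand = np.where(self.he_alive[: self.nh]
                        & (self.he_origin[: self.nh] == v))[0]
        if len(cand) == 0:
            return []
        start = int(cand[0])
        order = [start]
        e = int(self.he_twin[self.he_prev[start]])
        while e != start:
            order.append(e)
            if len(order) > len(cand):
                raise MeshError(f"broken rotation order at vertex {v}")
            e = int(self.he_twin[self.he_prev[e]])
        if len(order) != len(cand):
            raise MeshError(f"rotation order missed edges at vertex {v}")
        return order

    def vertex_degree(self, v: int) -> int:
        return int(np.count_nonzero(
            self.he_alive[: self.nh] & (self.he_origin[: self.nh] == v)))

    def alive_cells(self) -> np.ndarray:
        return np.where(self.c_alive[: self.nc])[0]

    def boundary_vertices(self) -> np.ndarray:
        """Vertices on the outer rim (origins of outer-face half-edges)."""
        mask = self.he_alive[: self.nh] & (self.he_cell[: self.nh] == OUTER)
        return np.unique(self.he_origin[: self.nh][mask])

    # ------------------------------------------------------------------ #
    # geometry
    # ------------------------------------------------------------------ #

    def cell_area(self, c: int) -> float:
        """Signed shoelace area of the CCW vertex loop (positive if valid)."""
        p = self.cell_polygon(c)
        if len(p) < 3:
            raise MeshError(f"degenerate cell {c}: fewer than 3 vertices")
        x, y = p[:, 0], p[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def cell_perimeter(self, c: int) -> float:
        p = self.cell_polygon(c)
        if len(p) < 3:
            raise MeshError(f"degenerate cell {c}: fewer than 3 vertices")
        return float(np.sum(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)))

    def cell_centroid(self, c: int) -> np.ndarray:
        """Area centroid of the cell polygon (not the vertex mean)."""
        p = self.cell_polygon(c)
        if len(p) < 3:
            raise MeshError(f"degenerate cell {c}: fewer than 3 vertices")
        q = np.roll(p, -1, axis=0)
        w = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        a = 0.5 * np.sum(w)
        if abs(a) < 1e-300:
            return p.mean(axis=0)
        return (p + q).T @ w / (6.0 * a)

    def neighbour_count(self, c: int) -> int:
        """Number of distinct cells sharing at least one junction with ``c``."""
        nbrs = {int(self.he_cell[self.he_twin[h]])
                for h in self.cell_halfedges(c)}
        nbrs.discard(OUTER)
        return len(nbrs)

    def total_area(self) -> float:
        cache = self.compiled()
        if len(cache.he) == 0:
            return 0.0
        p = self.vx[cache.o]
        q = self.vx[cache.no]
        return float(0.5 * np.sum(p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]))

    def areas(self) -> np.ndarray:
        """Areas of alive cells, aligned with ``compiled().cells``."""
        cache = self.compiled()
        p = self.vx[cache.o]
        q = self.vx[cache.no]
        w = 0.5 * (p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1])
        return np.bincount(cache.hc, weights=w, minlength=len(cache.cells))

    def perimeters(self) -> np.ndarray:
        cache = self.compiled()
        el = np.linalg.norm(self.vx[cache.no] - self.vx[cache.o], axis=1)
        return np.bincount(cache.hc, weights=el, minlength=len(cache.cells))

    # ------------------------------------------------------------------ #
    # compiled cache
    # ------------------------------------------------------------------ #

    def compiled(self) -> _Compiled:
        if self._cache is None:
            self._cache = self._build_cache()
        return self._cache

    def _build_cache(self) -> _Compiled:
        nh = self.nh
        alive = self.he_alive[:nh]
        interior = alive & (self.he_cell[:nh] >= 0)
        he = np.where(interior)[0]
        o = self.he_origin[he]
        no = self.he_origin[self.he_next[he]]
        po = self.he_origin[self.he_prev[he]]
        cells = np.where(self.c_alive[: self.nc])[0]
        cell_index = {int(c): i for i, c in enumerate(cells)}
        remap = np.full(self.nc if self.nc else 1, -1, np.int64)
        if len(cells):
            remap[cells] = np.arange(len(cells))
        hc = remap[self.he_cell[he]]
        free = np.where(self.v_alive[: self.nv]
                        & ~self.v_clamped[: self.nv])[0]
        # T1 candidates: interior junctions (real cell on both sides),
        # unclamped endpoints, counted once per undirected junction
        tw = self.he_twin[he]
        twin_cell = self.he_cell[tw]
        cand = (twin_cell >= 0) & (he < tw)
        a = o[cand]
        b = no[cand]
        okv = ~(self.v_clamped[a] | self.v_clamped[b])
        return _Compiled(
            he=he, o=o, no=no, po=po, hc=hc, cells=cells,
            cell_index=cell_index, free_verts=free,
            t1_he=he[cand][okv], t1_a=a[okv], t1_b=b[okv],
            nbr_cell=twin_cell,
        )

    # ------------------------------------------------------------------ #
    # counts / validation
    # ------------------------------------------------------------------ #

    def counts(self) -> tuple[int, int, int]:
        """(V, E_undirected, F_cells) over alive entities, outer face excluded."""
        V = int(np.count_nonzero(self.v_alive[: self.nv]))
        E = int(np.count_nonzero(self.he_alive[: self.nh])) // 2
        F = int(np.count_nonzero(self.c_alive[: self.nc]))
        return V, E, F

    def euler_characteristic(self) -> int:
        V, E, F = self.counts()
        return V - E + F

    def validate(self) -> list[str]:
        """Structural + geometric audit; returns a list of violations."""
        bad: list[str] = []
        nh = self.nh
        for h in np.where(self.he_alive[:nh])[0]:
            t = self.he_twin[h]
            if not (0 <= t < nh and self.he_alive[t]):
                bad.append(f"junction {h}: dead or missing twin {t}")
                continue
            if self.he_twin[t] != h:
                bad.append(f"junction {h}: twin(twin) != self")
            n = self.he_next[h]
            if not (0 <= n < nh and self.he_alive[n]):
                bad.append(f"junction {h}: dead next {n}")
            elif self.he_prev[n] != h:
                bad.append(f"junction {h}: next/prev mismatch")
            elif self.he_origin[t] != self.he_origin[n]:
                bad.append(f"junction {h}: twin origin != head")
            if not self.v_alive[self.he_origin[h]]:
                bad.append(f"junction {h}: dead origin vertex")
        if bad:
            return bad  # pointer soup: skip cycle-based checks

        for c in self.alive_cells():
            h0 = int(self.c_he[c])
            if not (0 <= h0 < nh and self.he_alive[h0]
                    and self.he_cell[h0] == c):
                bad.append(f"cell {c}: stale cell->halfedge anchor")
                continue
            try:
                loop = self.cell_halfedges(c)
            except MeshError as e:
                bad.append(str(e))
                continue
            vids = [int(self.he_origin[h]) for h in loop]
            if len(vids) < 3:
                bad.append(f"cell {c}: fewer than 3 vertices")
            if len(set(vids)) != len(vids):
                bad.append(f"cell {c}: non-simple cycle (repeated vertex)")
            for h in loop:
                if self.he_cell[h] != c:
                    bad.append(f"cell {c}: cycle strays into cell "
                               f"{self.he_cell[h]}")
                    break
            try:
                if self.cell_area(c) <= 0:
                    bad.append(f"cell {c}: non-positive area")
            except MeshError as e:
                bad.append(str(e))

        V, E, F = self.counts()
        if V - E + F != 1:
            bad.append(f"Euler characteristic {V - E + F} != 1 "
                       f"(V={V}, E={E}, F={F})")

        if self.L is not None and not bad:
            tot = sum(self.cell_area(c) for c in self.alive_cells())
            if abs(tot - self.L ** 2) > 1e-6 * self.L ** 2:
                bad.append(f"confluence broken: sum(areas)={tot!r} "
                           f"vs L^2={self.L ** 2!r}")

        for v, (x, y) in self._clamp_ref.items():
            if self.v_alive[v] and (self.vx[v, 0] != x or self.vx[v, 1] != y):
                bad.append(f"clamped vertex {v} moved")

        boundary = set(int(v) for v in self.boundary_vertices())
        for v in np.where(self.v_alive[: self.nv])[0]:
            if int(v) not in boundary and self.vertex_degree(int(v)) < 3:
                bad.append(f"interior vertex {v}: degree < 3")
        return bad

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #

    def parameter_hash(self, params=None) -> str:
        payload = json.dumps(
            {"L": self.L, "L_a": self.L_a,
             "params": None if params is None else vars(params)},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "format": "epivertex-mesh",
            "version": 1,
            "L": self.L,
            "L_a": self.L_a,
            "time": self.time,
            "seed": self.seed,
            "parameter_hash": self.parameter_hash(),
            "vertices": {
                "id": np.arange(self.nv)[self.v_alive[: self.nv]].tolist(),
                "x": self.vx[: self.nv, 0][self.v_alive[: self.nv]].tolist(),
                "y": self.vx[: self.nv, 1][self.v_alive[: self.nv]].tolist(),
                "clamped":
                    self.v_clamped[: self.nv][self.v_alive[: self.nv]]
                    .astype(int).tolist(),
            },
            "junctions": {
                "id": np.arange(self.nh)[self.he_alive[: self.nh]].tolist(),
                "origin":
                    self.he_origin[: self.nh][self.he_alive[: self.nh]]
                    .tolist(),
                "twin":
                    self.he_twin[: self.nh][self.he_alive[: self.nh]].tolist(),
                "next":
                    self.he_next[: self.nh][self.he_alive[: self.nh]].tolist(),
                "cell":
                    self.he_cell[: self.nh][self.he_alive[: self.nh]].tolist(),
            },
            "cells": {
                "id": np.arange(self.nc)[self.c_alive[: self.nc]].tolist(),
                "kind": [_KIND_NAMES[int(k)] for k in
                         self.c_kind[: self.nc][self.c_alive[: self.nc]]],
                "A0": self.c_A0[: self.nc][self.c_alive[: self.nc]].tolist(),
                "P0": self.c_P0[: self.nc][self.c_alive[: self.nc]].tolist(),
                "generation":
                    self.c_gen[: self.nc][self.c_alive[: self.nc]].tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueMesh":
        if d.get("format") != "epivertex-mesh":
            raise MeshError("not an epivertex mesh snapshot")
        m = cls(L=d["L"], L_a=d["L_a"])
        m.time = d.get("time", 0.0)
        m.seed = d.get("seed")
        vids = d["vertices"]["id"]
        nv = (max(vids) + 1) if vids else 0
        hids = d["junctions"]["id"]
        nhh = (max(hids) + 1) if hids else 0
        cids = d["cells"]["id"]
        ncc = (max(cids) + 1) if cids else 0
        while len(m.v_alive) < nv:
            m._grow_v()
        while len(m.he_alive) < nhh:
            m._grow_h()
        while len(m.c_alive) < ncc:
            m._grow_c()
        m.nv, m.nh, m.nc = nv, nhh, ncc
        vv = d["vertices"]
        for i, v in enumerate(vids):
            m.vx[v] = (vv["x"][i], vv["y"][i])
            m.v_alive[v] = True
            if vv["clamped"][i]:
                m.clamp_vertex(v)
        jj = d["junctions"]
        for i, h in enumerate(hids):
            m.he_origin[h] = jj["origin"][i]
            m.he_twin[h] = jj["twin"][i]
            m.he_next[h] = jj["next"][i]
            m.he_cell[h] = jj["cell"][i]
            m.he_alive[h] = True
        for h in hids:
            m.he_prev[m.he_next[h]] = h
        cc = d["cells"]
        for i, c in enumerate(cids):
            m.c_kind[c] = _KIND_CODES[cc["kind"][i]]
            m.c_A0[c] = cc["A0"][i]
            m.c_P0[c] = cc["P0"][i]
            m.c_gen[c] = cc["generation"][i]
            m.c_alive[c] = True
        # anchor one half-edge per cell
        for i, h in enumerate(hids):
            c = jj["cell"][i]
            if c >= 0:
                m.c_he[c] = h
        m.bump()
        return m

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TissueMesh":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_vtk(self, path):
        """Write the tiling as legacy-VTK polygonal data (visualization)."""
        vids = np.where(self.v_alive[: self.nv])[0]
        remap = {int(v): i for i, v in enumerate(vids)}
        cells = [self.cell_vertex_ids(c) for c in self.alive_cells()]
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nepivertex tissue\n"
                     "ASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(vids)} double\n")
            for v in vids:
                fh.write(f"{self.vx[v, 0]!r} {self.vx[v, 1]!r} 0.0\n")
            size = sum(len(c) + 1 for c in cells)
            fh.write(f"POLYGONS {len(cells)} {size}\n")
            for c in cells:
                fh.write(" ".join([str(len(c))]
                                  + [str(remap[v]) for v in c]) + "\n")
            fh.write(f"CELL_DATA {len(cells)}\nSCALARS kind int 1\n"
                     "LOOKUP_TABLE default\n")
            for c in self.alive_cells():
                fh.write(f"{int(self.c_kind[c])}\n")
            fh.write("SCALARS generation int 1\nLOOKUP_TABLE default\n")
            for c in self.alive_cells():
                fh.write(f"{int(self.c_gen[c])}\n")


# ---------------------------------------------------------------------- #
# construction from polygon soup
# ---------------------------------------------------------------------- #

def mesh_from_indexed_polygons(coords: np.ndarray,
                               polygons: list[list[int]],
                               L: float | None = None,
                               L_a: float | None = None) -> TissueMesh:
    """Build a half-edge mesh from polygons sharing a common vertex table.

    ``polygons`` lists, per cell, indices into ``coords``; winding is fixed
    to counterclockwise automatically.  Edges referenced from exactly one
    polygon become the outer rim.
    """
    mesh = TissueMesh(L=L, L_a=L_a)
    vmap: dict[int, int] = {}
    edge_map: dict[tuple[int, int], int] = {}
    coords = np.asarray(coords, float)

    for poly in polygons:
        pts = coords[poly]
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        ids = list(poly) if area > 0 else list(poly)[::-1]
        for i in ids:
            if i not in vmap:
                vmap[i] = mesh.new_vertex(coords[i])
        c = mesh.new_cell()
        k = len(ids)
        hes = [mesh.new_halfedge(origin=vmap[ids[j]], cell=c)
               for j in range(k)]
        for j in range(k):
            mesh.he_next[hes[j]] = hes[(j + 1) % k]
            mesh.he_prev[hes[j]] = hes[(j - 1) % k]
            key = (vmap[ids[j]], vmap[ids[(j + 1) % k]])
            if key in edge_map:
                raise MeshError(f"duplicate directed edge {key}")
            edge_map[key] = hes[j]
        mesh.c_he[c] = hes[0]

    # twin linking; leftover directed edges bound the outer face
    outer_out: dict[int, int] = {}
    for (a, b), h in edge_map.items():
        if mesh.he_twin[h] >= 0:
            continue
        rev = edge_map.get((b, a))
        if rev is not None:
            mesh.he_twin[h] = rev
            mesh.he_twin[rev] = h
        else:
            o = mesh.new_halfedge(origin=b, cell=OUTER)
            mesh.he_twin[h] = o
            mesh.he_twin[o] = h
            outer_out[b] = o
    for b, o in outer_out.items():
        head = mesh.he_origin[mesh.he_twin[o]]
        nxt = outer_out.get(int(head))
        if nxt is None:
            raise MeshError("outer rim is not a closed loop")
        mesh.he_next[o] = nxt
        mesh.he_prev[nxt] = o
    mesh.bump()
    return mesh


def mesh_from_polygons(polygons, L=None, L_a=None,
                       tol: float = COORD_TOL) -> TissueMesh:
    """Like :func:`mesh_from_indexed_polygons` but with raw coordinates.

    Vertices are deduplicated by rounding to a grid of spacing ``tol``.
    """
    coords: list = []
    key_to_id: dict = {}
    idx_polys = []
    for poly in polygons:
        ids = []
        for p in np.asarray(poly, float):
            key = (round(p[0] / tol), round(p[1] / tol))
            if key not in key_to_id:
                key_to_id[key] = len(coords)
                coords.append(p)
            ids.append(key_to_id[key])
        idx_polys.append(ids)
    return mesh_from_indexed_polygons(np.asarray(coords), idx_polys,
                                      L=L, L_a=L_a)
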
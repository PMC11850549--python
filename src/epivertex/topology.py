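"""Topological moves: T1 intercalation, T2 collapse, vertex resolution,
division-edge insertion, and type conversion of encircled cells.

Every move is a local half-edge pointer surgery that preserves the Euler
characteristic (V - E + F = 1 for the disk-like tiling) and confluence.
Moves that would produce an invalid polygon (a cell with fewer than three
vertices, a pinched face, a clamped vertex dragged along) are rejected
without mutating the mesh, and the rejection is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import ACTIVE, OUTER, PASSIVE, MeshError, TissueMesh
from .initialize import sample_target_perimeter


@dataclass
class TopologicalEvent:
    """One time-stamped morphological change of the tissue."""

    time: float
    kind: str                      # t1 | t2 | division | vertex_resolution |
    #                                type_conversion | *_rejected
    cells: tuple = ()
    junction: int | None = None
    daughters: tuple = ()
    vertex: int | None = None


class EventLog:
    """Append-only record of topological events."""

    def __init__(self):
        self.events: list[TopologicalEvent] = []

    def append(self, ev: TopologicalEvent):
        self.events.append(ev)

    def __len__(self):
        return len(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"time": e.time, "kind": e.kind,
                 "cells": ";".join(str(c) for c in e.cells),
                 "junction": e.junction,
                 "daughters": ";".join(str(c) for c in e.daughters),
                 "vertex": e.vertex} for e in self.events]
        return pd.DataFrame(
            rows, columns=["time", "kind", "cells", "junction",
                           "daughters", "vertex"])

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


class MoveRejected(Exception):
    """A precondition of a topological move failed; the mesh is unchanged."""


def _rot90(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


# ---------------------------------------------------------------------- #
# T1 intercalation
# ---------------------------------------------------------------------- #

def t1_transition(mesh: TissueMesh, junction: int, params,
                  check_length: bool = True) -> TopologicalEvent:
    """Neighbour exchange across a short junction.

    The junction is rotated 90 degrees about its midpoint and set to length
    ``1.02 * ell_T1``; the two cells that shared it lose one vertex each and
    the two flanking cells gain the new junction.  Vertex and edge counts
    are unchanged.
    """
    h = int(junction)
    if not mesh.he_alive[h]:
        raise MoveRejected(f"junction {h} is dead")
    t = int(mesh.he_twin[h])
    a = int(mesh.he_origin[h])
    b = int(mesh.he_origin[t])
    A = int(mesh.he_cell[h])
    B = int(mesh.he_cell[t])
    if A == OUTER or B == OUTER:
        raise MoveRejected(f"junction {h} borders the outer face")
    if mesh.v_clamped[a] or mesh.v_clamped[b]:
        raise MoveRejected(f"junction {h} touches a clamped vertex")
    if mesh.cell_size(A) <= 3 or mesh.cell_size(B) <= 3:
        raise MoveRejected(f"junction {h}: a triangle cell would degenerate")
    ra, rb = mesh.vx[a].copy(), mesh.vx[b].copy()
    e = rb - ra
    elen = float(np.hypot(*e))
    if check_length and elen >= params.ell_T1:
        raise MoveRejected(f"junction {h} not shorter than ell_T1")
    if elen < 1e-300:
        raise MoveRejected(f"junction {h} has zero length")

    p_h, n_h = int(mesh.he_prev[h]), int(mesh.he_next[h])
    p_t, n_t = int(mesh.he_prev[t]), int(mesh.he_next[t])
    d1 = int(mesh.he_twin[p_h])   # outgoing from a, flanking cell D
    c1 = int(mesh.he_twin[p_t])   # outgoing from b, flanking cell C
    D = int(mesh.he_cell[d1])
    C = int(mesh.he_cell[c1])
    if len({A, B, C, D}) < 4 or C == OUTER or D == OUTER:
        raise MoveRejected(f"junction {h}: flanking cells not distinct")
    p_d1, p_c1 = int(mesh.he_prev[d1]), int(mesh.he_prev[c1])

    # detach the junction from cells A and B
    mesh.he_next[p_h] = n_h
    mesh.he_prev[n_h] = p_h
    mesh.he_next[p_t] = n_t
    mesh.he_prev[n_t] = p_t
    if mesh.c_he[A] == h:
        mesh.c_he[A] = n_h
    if mesh.c_he[B] == t:
        mesh.c_he[B] = n_t
    # cell A keeps vertex a, cell B keeps vertex b
    mesh.he_origin[n_h] = a
    mesh.he_origin[n_t] = b
    # re-insert the junction between the flanking cells
    mesh.he_origin[h] = b
    mesh.he_cell[h] = D
    mesh.he_next[p_d1] = h
    mesh.he_prev[h] = p_d1
    mesh.he_next[h] = d1
    mesh.he_prev[d1] = h
    mesh.he_origin[t] = a
    mesh.he_cell[t] = C
    mesh.he_next[p_c1] = t
    mesh.he_prev[t] = p_c1
    mesh.he_next[t] = c1
    mesh.he_prev[c1] = t

    # rotate about the midpoint and re-open at the post-T1 length
    m = 0.5 * (ra + rb)
    u = _rot90(e / elen)
    half = 0.5 * params.ell_T1_new
    mesh.vx[a] = m + half * u
    mesh.vx[b] = m - half * u
    mesh.bump()
    return TopologicalEvent(time=mesh.time, kind="t1",
                            cells=(A, B, C, D), junction=h)


# ---------------------------------------------------------------------- #
# T2 collapse (cell ingression)
# ---------------------------------------------------------------------- #

def collapse_cell(mesh: TissueMesh, cell: int
                  ) -> tuple[TopologicalEvent, int]:
    """Remove a cell by collapsing its boundary into a single vertex.

    The new vertex sits at the cell centroid and typically has coordination
    higher than three; callers should follow up with
    :func:`resolve_high_coordination_vertex`.
    """
    c = int(cell)
    if not mesh.c_alive[c]:
        raise MoveRejected(f"cell {c} is dead")
    loop = mesh.cell_halfedges(c)
    verts = [int(mesh.he_origin[h]) for h in loop]
    if any(mesh.v_clamped[v] for v in verts):
        raise MoveRejected(f"cell {c} touches a clamped vertex")
    nbrs = [int(mesh.he_cell[mesh.he_twin[h]]) for h in loop]
    if OUTER in nbrs:
        raise MoveRejected(f"cell {c} touches the outer rim")
    if len(set(nbrs)) != len(nbrs):
        raise MoveRejected(f"cell {c} shares two junctions with a neighbour")
    for n in nbrs:
        if mesh.cell_size(n) <= 3:
            raise MoveRejected(
                f"cell {c}: neighbour {n} would become degenerate")

    centroid = mesh.cell_centroid(c)
    vstar = mesh.new_vertex(centroid)
    for h in loop:
        g = int(mesh.he_twin[h])
        n_cell = int(mesh.he_cell[g])
        gn, gp = int(mesh.he_next[g]), int(mesh.he_prev[g])
        mesh.he_next[gp] = gn
        mesh.he_prev[gn] = gp
        if mesh.c_he[n_cell] == g:
            mesh.c_he[n_cell] = gn
        mesh.kill_halfedge(g)
        mesh.kill_halfedge(h)
    # re-anchor all surviving spokes at the collapse vertex
    sel = mesh.he_alive[: mesh.nh] & np.isin(mesh.he_origin[: mesh.nh], verts)
    mesh.he_origin[: mesh.nh][sel] = vstar
    for v in verts:
        mesh.kill_vertex(v)
    mesh.kill_cell(c)
    ev = TopologicalEvent(time=mesh.time, kind="t2", cells=(c,),
                          vertex=vstar)
    return ev, vstar


# ---------------------------------------------------------------------- #
# high-coordination vertex resolution
# ---------------------------------------------------------------------- #

def _split_once(mesh: TissueMesh, v: int, params,
                rng: np.random.Generator) -> tuple[int, int]:
    """Split one vertex of coordination >= 4 along a random admissible cut.

    Two CCW-adjacent spokes move to a new vertex connected to the old one by
    a junction of length ``ell_T1_new``.  Returns (new vertex, new junction).
    """
    spokes = mesh.vertex_outgoing(v)
    m = len(spokes)
    if m < 4:
        raise MoveRejected(f"vertex {v} has coordination {m} < 4")
    start = int(rng.integers(m))
    choice = None
    for off in range(m):
        i = (start + off) % m
        e_i = spokes[i]
        e_j = spokes[(i + 1) % m]
        c_prev = int(mesh.he_cell[spokes[(i - 1) % m]])
        c_mid = int(mesh.he_cell[e_i])
        c_next = int(mesh.he_cell[e_j])
        if len({c_prev, c_mid, c_next}) == 3 \
                and OUTER not in (c_prev, c_next):
            choice = (e_i, e_j, c_prev, c_next, spokes[(i - 1) % m],
                      spokes[(i + 2) % m])
            break
    if choice is None:
        raise MeshError(f"no admissible cut at vertex {v}")
    e_i, e_j, C1, C2, _, e_after = choice

    # geometry: displace the pair midway along the mean spoke direction
    def _unit(e):
        head = mesh.vx[int(mesh.he_origin[mesh.he_twin[e]])]
        d = head - mesh.vx[v]
        n = np.hypot(*d)
        return d / n if n > 1e-12 else np.zeros(2)

    direction = _unit(e_i) + _unit(e_j)
    nrm = np.hypot(*direction)
    if nrm < 1e-9:
        perp = _rot90(_unit(e_i))
        direction = perp
        nrm = np.hypot(*direction)
    direction = direction / nrm
    ell = params.ell_T1_new
    old_pos = mesh.vx[v].copy()
    w = mesh.new_vertex(old_pos + 0.5 * ell * direction)
    if not mesh.v_clamped[v]:
        mesh.vx[v] = old_pos - 0.5 * ell * direction
    else:
        mesh.vx[w] = old_pos + ell * direction

    tw_ei = int(mesh.he_twin[e_i])        # ends at v (will end at w)
    tw_after = int(mesh.he_twin[e_after])  # ends at v, stays at v
    g1 = mesh.new_halfedge(origin=w, cell=C1)   # w -> v in C1
    g2 = mesh.new_halfedge(origin=v, cell=C2)   # v -> w in C2
    mesh.he_twin[g1] = g2
    mesh.he_twin[g2] = g1
    # face C1: ... tw_ei -> g1 -> e_{i-1} ...
    e_before = int(mesh.he_next[tw_ei])
    mesh.he_next[tw_ei] = g1
    mesh.he_prev[g1] = tw_ei
    mesh.he_next[g1] = e_before
    mesh.he_prev[e_before] = g1
    # face C2: ... tw_after -> g2 -> e_j ...
    mesh.he_next[tw_after] = g2
    mesh.he_prev[g2] = tw_after
    mesh.he_next[g2] = int(e_j)
    mesh.he_prev[e_j] = g2
    # the moved pair now originates at w
    mesh.he_origin[e_i] = w
    mesh.he_origin[e_j] = w
    mesh.bump()
    return w, g1


def resolve_high_coordination_vertex(mesh: TissueMesh, vertex: int, params,
                                     rng: np.random.Generator
                                     ) -> list[TopologicalEvent]:
    """Split a vertex of coordination >= 4 until only 3-valent vertices
    remain (an n-valent vertex requires exactly n - 3 splits)."""
    events: list[TopologicalEvent] = []
    stack = [int(vertex)]
    while stack:
        v = stack.pop()
        while mesh.v_alive[v] and mesh.vertex_degree(v) > 3:
            w, g = _split_once(mesh, v, params, rng)
            events.append(TopologicalEvent(
                time=mesh.time, kind="vertex_resolution",
                junction=g, vertex=w))
            if mesh.vertex_degree(w) > 3:
                stack.append(w)
    return events


# ---------------------------------------------------------------------- #
# division-edge insertion
# ---------------------------------------------------------------------- #

def _split_junction(mesh: TissueMesh, h: int, pos) -> int:
    """Insert a vertex at ``pos`` on junction ``h`` (and its twin)."""
    t = int(mesh.he_twin[h])
    both_clamped = bool(mesh.v_clamped[mesh.he_origin[h]]
                        and mesh.v_clamped[mesh.he_origin[t]])
    u = mesh.new_vertex(pos, clamped=both_clamped)
    h2 = mesh.new_halfedge(origin=u, cell=int(mesh.he_cell[h]))
    t2 = mesh.new_halfedge(origin=u, cell=int(mesh.he_cell[t]))
    nh, nt = int(mesh.he_next[h]), int(mesh.he_next[t])
    mesh.he_next[h] = h2
    mesh.he_prev[h2] = h
    mesh.he_next[h2] = nh
    mesh.he_prev[nh] = h2
    mesh.he_next[t] = t2
    mesh.he_prev[t2] = t
    mesh.he_next[t2] = nt
    mesh.he_prev[nt] = t2
    mesh.he_twin[h] = t2
    mesh.he_twin[t2] = h
    mesh.he_twin[h2] = t
    mesh.he_twin[t] = h2
    mesh.bump()
    return u


def insert_division_edge(mesh: TissueMesh, cell: int, axis_direction,
                         rng: np.random.Generator | None = None
                         ) -> tuple[TopologicalEvent, tuple[int, int]]:
    """Divide a cell along the line through its centroid perpendicular to
    ``axis_direction`` (Hertwig's rule when the axis is the long axis).

    Both daughters inherit the parent's type and targets (callers re-sample
    targets for active daughters) and carry generation = parent + 1.
    """
    c = int(cell)
    if not mesh.c_alive[c]:
        raise MoveRejected(f"cell {c} is dead")
    axis = np.asarray(axis_direction, float)
    axis = axis / np.hypot(*axis)
    ctr = mesh.cell_centroid(c)
    loop = mesh.cell_halfedges(c)
    vids = [int(mesh.he_origin[h]) for h in loop]
    pts = mesh.vx[vids]
    # signed coordinate along the long axis; the cut is its zero level set
    f = (pts - ctr) @ axis
    scale = np.sqrt(abs(mesh.cell_area(c)))
    tol = 1e-9 * max(scale, 1.0)

    sites: list[tuple[str, int]] = []   # ('vertex', loop idx) / ('edge', idx)
    k = len(loop)
    for i in range(k):
        f0, f1 = f[i], f[(i + 1) % k]
        if abs(f0) <= tol:
            sites.append(("vertex", i))
        elif (f0 < -tol and f1 > tol) or (f0 > tol and f1 < -tol):
            sites.append(("edge", i))
    if len(sites) != 2:
        raise MoveRejected(
            f"cell {c}: division line crosses boundary at "
            f"{len(sites)} sites")

    cut_vertices: list[int] = []
    for kind, i in sites:
        if kind == "vertex":
            cut_vertices.append(vids[i])
        else:
            f0, f1 = f[i], f[(i + 1) % k]
            s = f0 / (f0 - f1)
            pos = pts[i] + s * (pts[(i + 1) % k] - pts[i])
            cut_vertices.append(_split_junction(mesh, loop[i], pos))
    u1, u2 = cut_vertices
    if u1 == u2:
        raise MoveRejected(f"cell {c}: degenerate division cut")

    # locate the cycle half-edges that originate at the cut vertices
    loop = mesh.cell_halfedges(c)
    s1 = s2 = None
    for h in loop:
        if mesh.he_origin[h] == u1:
            s1 = h
        elif mesh.he_origin[h] == u2:
            s2 = h
    if s1 is None or s2 is None:
        raise MeshError(f"cell {c}: lost cut vertices after splitting")
    if mesh.he_next[s1] == s2 or mesh.he_next[s2] == s1:
        raise MoveRejected(f"cell {c}: cut would create a two-sided cell")

    a1 = int(mesh.he_prev[s2])
    a2 = int(mesh.he_prev[s1])
    w1 = mesh.new_halfedge(origin=u2)   # u2 -> u1, closes daughter 1
    w2 = mesh.new_halfedge(origin=u1)   # u1 -> u2, closes daughter 2
    mesh.he_twin[w1] = w2
    mesh.he_twin[w2] = w1
    mesh.he_next[a1] = w1
    mesh.he_prev[w1] = a1
    mesh.he_next[w1] = s1
    mesh.he_prev[s1] = w1
    mesh.he_next[a2] = w2
    mesh.he_prev[w2] = a2
    mesh.he_next[w2] = s2
    mesh.he_prev[s2] = w2

    gen = int(mesh.c_gen[c]) + 1
    kind_c = int(mesh.c_kind[c])
    d_ids = []
    for w in (w1, w2):
        d = mesh.new_cell(kind=kind_c, A0=float(mesh.c_A0[c]),
                          P0=float(mesh.c_P0[c]), generation=gen)
        mesh.c_he[d] = w
        h = w
        while True:
            mesh.he_cell[h] = d
            h = int(mesh.he_next[h])
            if h == w:
                break
        d_ids.append(d)
    mesh.kill_cell(c)
    mesh.bump()
    ev = TopologicalEvent(time=mesh.time, kind="division", cells=(c,),
                          daughters=tuple(d_ids))
    return ev, (d_ids[0], d_ids[1])


# ---------------------------------------------------------------------- #
# type conversion of encircled cells
# ---------------------------------------------------------------------- #

def convert_encircled_cells(mesh: TissueMesh, rng: np.random.Generator,
                            params) -> list[TopologicalEvent]:
    """Flip the type of any cell fully surrounded by the opposite type.

    A passive cell that turns active draws a fresh target perimeter from
    N(mu, sigma); an active cell that turns passive adopts the fixed passive
    targets.
    """
    cache = mesh.compiled()
    ncells = len(cache.cells)
    if ncells == 0:
        return []
    own = cache.hc
    nbr = cache.nbr_cell
    rim = np.bincount(own[nbr == OUTER], minlength=ncells) > 0
    interior = nbr != OUTER
    own_kind = mesh.c_kind[cache.cells][own[interior]]
    nbr_kind = mesh.c_kind[nbr[interior]]
    same = np.bincount(own[interior], weights=(own_kind == nbr_kind),
                       minlength=ncells)
    encircled = (same == 0) & ~rim
    flips = [int(c) for c in cache.cells[encircled]]
    events = []
    for c in flips:
        if mesh.c_kind[c] == PASSIVE:
            mesh.c_kind[c] = ACTIVE
            P0 = sample_target_perimeter(rng, params.target_perimeter_mean,
                                         params.target_perimeter_sd)
            mesh.c_P0[c] = P0
            mesh.c_A0[c] = (P0 / params.p0_active) ** 2
        else:
            mesh.c_kind[c] = PASSIVE
            mesh.c_P0[c] = params.target_perimeter_mean
            mesh.c_A0[c] = (params.target_perimeter_mean
                            / params.p0_passive) ** 2
        events.append(TopologicalEvent(time=mesh.time,
                                       kind="type_conversion", cells=(c,)))
    return events
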
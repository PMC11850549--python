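"""Stochastic biology of the active patch: growth, division, ingression.

Active cells grow by linear inflation of their target area (dA0/dt = g) with
the target perimeter slaved to keep the target shape index fixed.  Division
and ingression are Bernoulli events evaluated once every few time steps with
logistic probabilities in the current cell area:

    P_div = 1 / (1 + exp(-alpha (A - A_d)))     (increasing in A)
    P_ing = 1 / (1 + exp(+beta  (A - A_i)))     (decreasing in A)

A_d and A_i are pinned to 1.6x and 0.3x the mean active-cell area measured
at the end of the passive relaxation and frozen thereafter.  Divisions obey
Hertwig's rule: the cut runs through the centroid perpendicular to the long
axis obtained from the gyration tensor of the cell's vertices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .mesh import ACTIVE, TissueMesh
from .initialize import sample_target_perimeter
from .topology import (EventLog, MoveRejected, TopologicalEvent,
                       collapse_cell, insert_division_edge,
                       resolve_high_coordination_vertex)


@dataclass(frozen=True)
class GrowthState:
    """Reference mean active area and the derived event areas (frozen)."""

    A_ref_mean: float   # mean active-cell area at t = t_rel
    A_d: float          # division half-probability area (1.6 * reference)
    A_i: float          # ingression half-probability area (0.3 * reference)
    t_ref: float

    @classmethod
    def from_mesh(cls, mesh: TissueMesh, params, t_ref: float
                  ) -> "GrowthState":
        cache = mesh.compiled()
        kinds = mesh.c_kind[cache.cells]
        areas = mesh.areas()
        act = areas[kinds == ACTIVE]
        if len(act) == 0:
            raise ValueError("no active cells to reference")
        mean = float(act.mean())
        return cls(A_ref_mean=mean,
                   A_d=params.div_area_factor * mean,
                   A_i=params.ing_area_factor * mean,
                   t_ref=t_ref)

    def install(self, params):
        """Write A_d / A_i into the parameter set used by the sweeps."""
        params.A_d = self.A_d
        params.A_i = self.A_i
        return params


def grow_targets(mesh: TissueMesh, params) -> TissueMesh:
    """One Euler step of target-area growth for all active cells.

    A0 <- A0 + g*dt and P0 <- p0_active * sqrt(A0); passive cells are
    untouched (their targets are time-independent).
    """
    cells = mesh.alive_cells()
    act = cells[mesh.c_kind[cells] == ACTIVE]
    mesh.c_A0[act] += params.g * params.dt
    mesh.c_P0[act] = params.p0_active * np.sqrt(mesh.c_A0[act])
    return mesh


def division_probability(area, params) -> np.ndarray | float:
    """Logistic division probability, 1/2 at A = A_d (overflow-safe)."""
    if params.A_d is None:
        raise ValueError("A_d not set; run the passive relaxation first")
    return expit(params.alpha * (np.asarray(area, float) - params.A_d))


def ingression_probability(area, params) -> np.ndarray | float:
    """Logistic ingression probability, 1/2 at A = A_i, decreasing in A."""
    if params.A_i is None:
        raise ValueError("A_i not set; run the passive relaxation first")
    return expit(-params.beta * (np.asarray(area, float) - params.A_i))


def long_axis(mesh: TissueMesh, cell: int,
              rng: np.random.Generator) -> np.ndarray:
    """Principal eigenvector of the gyration tensor of the cell's vertices.

    For (near-)isotropic cells -- relative eigenvalue gap below 1e-9 -- the
    axis is degenerate and a uniformly random direction is returned.
    """
    pts = mesh.cell_polygon(int(cell))
    rel = pts - pts.mean(axis=0)
    G = rel.T @ rel / len(rel)
    evals, evecs = np.linalg.eigh(G)    # ascending order
    scale = max(evals[1], 1e-300)
    if (evals[1] - evals[0]) / scale < 1e-9:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        return np.array([np.cos(ang), np.sin(ang)])
    return evecs[:, 1].copy()


def _sorted_active(mesh: TissueMesh) -> np.ndarray:
    cells = mesh.alive_cells()
    return cells[mesh.c_kind[cells] == ACTIVE]


def _active_areas(mesh: TissueMesh, ids: np.ndarray) -> np.ndarray:
    cache = mesh.compiled()
    areas = mesh.areas()
    return areas[[cache.cell_index[int(c)] for c in ids]]


def sweep_divisions(mesh: TissueMesh, params, rng: np.random.Generator,
                    log: EventLog | None = None
                    ) -> tuple[list[TopologicalEvent], set[int]]:
    """One division sweep over active cells in ascending id order.

    Returns the division events and the set of cell ids (parents that
    divided plus their daughters) to exempt from ingression this sweep.
    """
    ids = _sorted_active(mesh)
    events: list[TopologicalEvent] = []
    touched: set[int] = set()
    if len(ids) == 0:
        return events, touched
    areas = _active_areas(mesh, ids)
    u = rng.random(len(ids))
    chosen = ids[u < division_probability(areas, params)]
    for c in chosen:
        axis = long_axis(mesh, int(c), rng)
        try:
            ev, (d1, d2) = insert_division_edge(mesh, int(c), axis, rng)
        except MoveRejected:
            ev = TopologicalEvent(time=mesh.time, kind="division_rejected",
                                  cells=(int(c),))
            if log is not None:
                log.append(ev)
            continue
        for d in (d1, d2):
            if mesh.c_kind[d] == ACTIVE:
                P0 = sample_target_perimeter(
                    rng, params.target_perimeter_mean,
                    params.target_perimeter_sd)
                mesh.c_P0[d] = P0
                mesh.c_A0[d] = (P0 / params.p0_active) ** 2
        touched |= {int(c), int(d1), int(d2)}
        events.append(ev)
        if log is not None:
            log.append(ev)
    return events, touched


def sweep_ingressions(mesh: TissueMesh, params, rng: np.random.Generator,
                      log: EventLog | None = None,
                      exempt: set[int] | None = None
                      ) -> list[TopologicalEvent]:
    """One ingression sweep (T2 collapse + vertex resolution) over active
    cells not touched by a division this sweep."""
    exempt = exempt or set()
    ids = np.array([c for c in _sorted_active(mesh)
                    if int(c) not in exempt], dtype=np.int64)
    events: list[TopologicalEvent] = []
    if len(ids) == 0:
        return events
    areas = _active_areas(mesh, ids)
    u = rng.random(len(ids))
    chosen = ids[u < ingression_probability(areas, params)]
    for c in chosen:
        if not mesh.c_alive[int(c)]:
            continue
        try:
            ev, vstar = collapse_cell(mesh, int(c))
        except MoveRejected:
            ev = TopologicalEvent(time=mesh.time,
                                  kind="ingression_rejected",
                                  cells=(int(c),))
            if log is not None:
                log.append(ev)
            continue
        events.append(ev)
        if log is not None:
            log.append(ev)
        res = resolve_high_coordination_vertex(mesh, vstar, params, rng)
        events.extend(res)
        if log is not None:
            for r in res:
                log.append(r)
    return events
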
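"""Shape energy, analytic vertex forces, and cell pressure.

The mechanical energy of the tissue is

    E = sum_c [ K_A/2 (A_c - A_c0)^2 + K_P/2 (P_c - P_c0)^2 ],

summed over live cells.  Vertices move down the energy gradient with friction
coefficient zeta (overdamped dynamics); the force on vertex i is the analytic
negative gradient of E.  The area gradient is the standard shoelace form --
for vertex i of a CCW cell, dA/dr_i = 0.5 * (y_{i+1} - y_{i-1},
x_{i-1} - x_{i+1}) -- and the perimeter gradient is the sum of unit vectors
along the two incident junctions of the cell.  Clamped vertices report zero
force (exact immobility).

Cell pressure is P_r = -K_A (A_c - A_c0): a compressed cell (A < A0) is at
positive pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .mesh import TissueMesh


@dataclass
class ModelParams:
    """Model and scheduling constants, in simulation units.

    ``A_d`` / ``A_i`` (the areas at which the division and ingression
    probabilities equal 1/2) are derived from the mean active-cell area at
    the end of the passive relaxation (1.6x and 0.3x respectively) and are
    therefore ``None`` until a :class:`~epivertex.active.GrowthState` sets
    them.
    """

    K_A: float = 3.0            # area elastic modulus
    K_P: float = 1.0            # perimeter modulus (sets the energy scale)
    zeta: float = 1.0           # substrate friction coefficient
    g: float = 2.0e-3           # target-area growth rate of active cells
    alpha: float = 8.0          # division probability steepness
    beta: float = 6.0           # ingression probability steepness
    A_d: float | None = None    # division half-probability area
    A_i: float | None = None    # ingression half-probability area
    div_area_factor: float = 1.6   # A_d = 1.6 * mean active area at t_rel
    ing_area_factor: float = 0.3   # A_i = 0.3 * mean active area at t_rel
    ell_T1: float = 5.0e-3      # junction length triggering a T1
    dt: float = 5.0e-3          # Euler time step
    t_rel: float = 50.0         # passive relaxation time
    event_check_interval: int = 5  # steps between stochastic event sweeps
    p0_active: float = 3.60     # target shape index of active cells
    p0_passive: float = 3.80    # target shape index of passive cells
    target_perimeter_mean: float = 5.98
    target_perimeter_sd: float = 0.3

    def __post_init__(self):
        for name in ("K_A", "K_P", "zeta", "g", "alpha", "beta",
                     "ell_T1", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.event_check_interval < 1:
            raise ValueError("event_check_interval must be >= 1")

    @property
    def ell_T1_new(self) -> float:
        """Length of a junction immediately after a T1 (1.02 * ell_T1)."""
        return 1.02 * self.ell_T1

    def copy(self) -> "ModelParams":
        return replace(self)


@njit(cache=True)
def _geometry_kernel(pos, o, no, hc, ncells):
    """Per-cell areas and perimeters plus per-half-edge lengths."""
    nhe = o.shape[0]
    A = np.zeros(ncells)
    P = np.zeros(ncells)
    el = np.empty(nhe)
    for k in range(nhe):
        i = o[k]
        j = no[k]
        c = hc[k]
        A[c] += 0.5 * (pos[i, 0] * pos[j, 1] - pos[j, 0] * pos[i, 1])
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        l = (dx * dx + dy * dy) ** 0.5
        el[k] = l
        P[c] += l
    return A, P, el


@njit(cache=True)
def _force_kernel(pos, o, no, po, hc, A, P, A0, P0, KA, KP, nv):
    """Analytic negative gradient of the shape energy, per vertex."""
    nhe = o.shape[0]
    F = np.zeros((nv, 2))
    for k in range(nhe):
        i = o[k]
        c = hc[k]
        jn = no[k]
        jp = po[k]
        # area term: -K_A (A - A0) * dA/dr_i, dA via shoelace gradient
        ka = KA * (A[c] - A0[c])
        F[i, 0] -= ka * 0.5 * (pos[jn, 1] - pos[jp, 1])
        F[i, 1] -= ka * 0.5 * (pos[jp, 0] - pos[jn, 0])
        # perimeter term of the junction (i -> jn): pulls both endpoints
        kp = KP * (P[c] - P0[c])
        dx = pos[jn, 0] - pos[i, 0]
        dy = pos[jn, 1] - pos[i, 1]
        l = (dx * dx + dy * dy) ** 0.5
        if l > 1e-12:
            ux = dx / l
            uy = dy / l
            F[i, 0] += kp * ux
            F[i, 1] += kp * uy
            F[jn, 0] -= kp * ux
            F[jn, 1] -= kp * uy
    return F


def geometry(mesh: TissueMesh):
    """(areas, perimeters, edge_lengths) on the compiled cache ordering."""
    cache = mesh.compiled()
    pos = np.ascontiguousarray(mesh.vx[: mesh.nv])
    return _geometry_kernel(pos, cache.o, cache.no, cache.hc,
                            len(cache.cells))


def forces_and_geometry(mesh: TissueMesh, params: ModelParams):
    """Forces on all vertices plus the per-cell geometry used to build them.

    Returns ``(F, A, P, el)``: F is (nv, 2) aligned with vertex ids, with
    clamped vertices zeroed; A, P align with ``mesh.compiled().cells``.
    """
    cache = mesh.compiled()
    pos = np.ascontiguousarray(mesh.vx[: mesh.nv])
    A, P, el = _geometry_kernel(pos, cache.o, cache.no, cache.hc,
                                len(cache.cells))
    A0 = mesh.c_A0[cache.cells]
    P0 = mesh.c_P0[cache.cells]
    F = _force_kernel(pos, cache.o, cache.no, cache.po, cache.hc,
                      A, P, A0, P0, params.K_A, params.K_P, mesh.nv)
    F[mesh.v_clamped[: mesh.nv]] = 0.0
    return F, A, P, el


def vertex_forces(mesh: TissueMesh, params: ModelParams) -> np.ndarray:
    """Analytic force table, one row per vertex id (dead rows are zero)."""
    if mesh.nv == 0:
        return np.zeros((0, 2))
    return forces_and_geometry(mesh, params)[0]


def tissue_energy(mesh: TissueMesh, params: ModelParams) -> float:
    """Total shape energy over live cells (non-negative; 0 at all targets)."""
    cache = mesh.compiled()
    if len(cache.cells) == 0:
        return 0.0
    A, P, _ = geometry(mesh)
    dA = A - mesh.c_A0[cache.cells]
    dP = P - mesh.c_P0[cache.cells]
    return float(0.5 * params.K_A * np.dot(dA, dA)
                 + 0.5 * params.K_P * np.dot(dP, dP))


def cell_pressure(mesh: TissueMesh, cell: int, params: ModelParams) -> float:
    """P_r = -K_A (A_c - A_c0); positive for a compressed cell."""
    return -params.K_A * (mesh.cell_area(cell) - mesh.c_A0[cell])


def cell_pressures(mesh: TissueMesh, params: ModelParams) -> np.ndarray:
    """Pressures of all live cells, aligned with ``compiled().cells``."""
    cache = mesh.compiled()
    return -params.K_A * (mesh.areas() - mesh.c_A0[cache.cells])
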
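"""Homeostasis observables: fractional changes, pressures, shape statistics.

The homeostatic state is quantified by the fractional change in the number
(f_N) and total area (f_A) of active cells relative to a reference time, the
cumulative division/ingression counts, per-type mean pressures, the realised
shape index of active cells (P_c / sqrt(A_c)), and the distribution P_n of
active-cell neighbour counts.  Steady-state summaries are time averages over
a window after the system has reached homeostasis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .mesh import ACTIVE, OUTER, PASSIVE, TissueMesh

#: neighbour-count histogram columns recorded per sample
HIST_BINS = list(range(3, 13))


def fractional_changes(n_active: float, area_active: float,
                       n_active_ref: float, area_active_ref: float
                       ) -> tuple[float, float]:
    """f_N = N_a(t)/N_a(t_ref), f_A = A_a(t)/A_a(t_ref)."""
    if n_active_ref <= 0 or area_active_ref <= 0:
        raise ValueError("reference counts/areas must be positive")
    return n_active / n_active_ref, area_active / area_active_ref


def realised_shape_index(mesh: TissueMesh) -> tuple[float, float]:
    """Mean and population sd of P_c/sqrt(A_c) over active cells."""
    cache = mesh.compiled()
    kinds = mesh.c_kind[cache.cells]
    act = kinds == ACTIVE
    if not np.any(act):
        raise ValueError("no active cells")
    p = mesh.perimeters()[act] / np.sqrt(mesh.areas()[act])
    return float(p.mean()), float(p.std())


def mean_pressures(mesh: TissueMesh, params
                   ) -> tuple[float | None, float | None]:
    """Arithmetic mean pressure -K_A (A - A0) per cell type.

    Returns (active mean, passive mean); an empty population reports None.
    """
    cache = mesh.compiled()
    kinds = mesh.c_kind[cache.cells]
    pr = -params.K_A * (mesh.areas() - mesh.c_A0[cache.cells])
    out = []
    for kind in (ACTIVE, PASSIVE):
        sel = kinds == kind
        out.append(float(pr[sel].mean()) if np.any(sel) else None)
    return out[0], out[1]


def neighbour_counts_active(mesh: TissueMesh) -> np.ndarray:
    """Distinct-neighbour counts of all active cells (vectorised)."""
    cache = mesh.compiled()
    kinds = mesh.c_kind[cache.cells]
    act_mask = kinds[cache.hc] == ACTIVE
    nbr = cache.nbr_cell[act_mask]
    own = cache.hc[act_mask]
    keep = nbr != OUTER
    pairs = own[keep].astype(np.int64) * (mesh.nc + 1) + nbr[keep]
    uniq = np.unique(pairs)
    counts = np.bincount((uniq // (mesh.nc + 1)).astype(np.int64),
                         minlength=len(cache.cells))
    return counts[kinds == ACTIVE]


def neighbour_distribution(mesh: TissueMesh) -> dict[int, float]:
    """Normalised fraction P_n of active cells with n neighbours."""
    ns = neighbour_counts_active(mesh)
    if len(ns) == 0:
        raise ValueError("no active cells")
    vals, cnt = np.unique(ns, return_counts=True)
    return {int(v): float(c) / len(ns) for v, c in zip(vals, cnt)}


@dataclass
class SteadyStateSummary:
    """Time means (and sds) of the sampled observables over a window."""

    t_start: float
    t_end: float
    n_samples: int
    f_N: float
    f_N_sd: float
    f_A: float
    f_A_sd: float
    pressure_active: float
    pressure_passive: float
    pressure_ratio: float
    shape_index: float
    shape_index_sd: float
    mean_neighbours: float
    P_n: dict
    mean_active_area_ratio: float   # <A^a> / A^a(t_ref)

    def to_dict(self) -> dict:
        return asdict(self)


def steady_state_summary(series: pd.DataFrame,
                         t_ss: float | None = None,
                         window: float = 500.0) -> SteadyStateSummary:
    """Average the observable series over [t_ss, t_ss + window].

    With ``t_ss=None`` the window is anchored at the end of the run.
    Standard deviations use the population convention (divide by n).
    """
    t = series["t"].to_numpy()
    if t_ss is None:
        t_ss = float(t.max()) - window
    sel = series[(series["t"] >= t_ss) & (series["t"] <= t_ss + window)]
    if len(sel) < 2:
        raise ValueError("steady-state window holds fewer than 2 samples")
    hist_cols = [f"n{b}" for b in HIST_BINS] + ["n_over"]
    hist = sel[hist_cols].to_numpy(float)
    hist_frac = hist / hist.sum(axis=1, keepdims=True)
    mean_hist = hist_frac.mean(axis=0)
    bins = np.array(HIST_BINS + [13])
    p_act = sel["pressure_active"].mean()
    p_pas = sel["pressure_passive"].mean()
    return SteadyStateSummary(
        t_start=float(t_ss), t_end=float(t_ss + window),
        n_samples=len(sel),
        f_N=float(sel["f_N"].mean()), f_N_sd=float(sel["f_N"].std(ddof=0)),
        f_A=float(sel["f_A"].mean()), f_A_sd=float(sel["f_A"].std(ddof=0)),
        pressure_active=float(p_act),
        pressure_passive=float(p_pas),
        pressure_ratio=float(p_act / p_pas) if p_pas else float("nan"),
        shape_index=float(sel["p_r_mean"].mean()),
        shape_index_sd=float(sel["p_r_sd"].mean()),
        mean_neighbours=float((mean_hist * bins).sum()),
        P_n={int(b): float(v) for b, v in zip(bins, mean_hist)},
        mean_active_area_ratio=float(
            (sel["A_a"] / sel["N_a"]).mean()
            / (sel["A_a_ref"] / sel["N_a_ref"]).iloc[0]),
    )


def sample_observables(mesh: TissueMesh, params, t: float,
                       counters: dict, refs: dict) -> dict:
    """One observable record; cheap enough for the every-5-steps cadence."""
    cache = mesh.compiled()
    kinds = mesh.c_kind[cache.cells]
    areas = mesh.areas()
    perims = mesh.perimeters()
    act = kinds == ACTIVE
    n_a = int(act.sum())
    n_p = int(len(kinds) - n_a)
    a_a = float(areas[act].sum())
    pr = -params.K_A * (areas - mesh.c_A0[cache.cells])
    p_r = perims[act] / np.sqrt(np.abs(areas[act]))
    ns = neighbour_counts_active(mesh)
    hist = {f"n{b}": int(np.count_nonzero(ns == b)) for b in HIST_BINS}
    hist["n_over"] = int(np.count_nonzero(ns > HIST_BINS[-1]))
    row = {
        "t": t,
        "N_a": n_a,
        "N_p": n_p,
        "A_a": a_a,
        "A_total": float(areas.sum()),
        "f_N": n_a / refs["N_a_ref"],
        "f_A": a_a / refs["A_a_ref"],
        "N_a_ref": refs["N_a_ref"],
        "A_a_ref": refs["A_a_ref"],
        "Sigma_d": counters.get("divisions", 0),
        "Sigma_i": counters.get("ingressions", 0),
        "conversions_net": counters.get("conversions_net", 0),
        "pressure_active": float(pr[act].mean()) if n_a else np.nan,
        "pressure_passive": float(pr[~act].mean()) if n_p else np.nan,
        "p_r_mean": float(p_r.mean()) if n_a else np.nan,
        "p_r_sd": float(p_r.std()) if n_a else np.nan,
        "min_area": float(areas.min()),
    }
    row.update(hist)
    return row
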
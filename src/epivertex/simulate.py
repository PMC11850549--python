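"""Run orchestration: passive relaxation, the homeostasis phase, recording.

A run is: build the initial clamped tiling; relax it passively for ``t_rel``
(forces + T1s only) so the tissue settles near a local energy minimum;
measure the reference mean active area (fixing the division/ingression areas
A_d and A_i); then evolve with the full schedule.  Each step performs, in
this order: (1) first-order Euler update of unclamped vertices,
r <- r + dt * F / zeta; (2) a T1 sweep over junctions shorter than ell_T1
in ascending length order; (3) in the active phase, target growth every
step, and -- every ``event_check_interval`` steps -- division, ingression
and encircled-cell type-conversion sweeps; (4) a cheap stability audit
(positive cell areas).  Instability (cell overlap / negative areas) is a
first-class outcome reported in the result status, not a crash.

All randomness flows from one seeded generator in a fixed draw order, so a
run is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mechanics, observables
from .active import (GrowthState, grow_targets, sweep_divisions,
                     sweep_ingressions)
from .initialize import InitConfig, build_tissue
from .mechanics import ModelParams
from .mesh import ACTIVE, TissueMesh
from .topology import (EventLog, MoveRejected, convert_encircled_cells,
                       t1_transition)


@dataclass
class RunSchedule:
    """Timing of a run (simulation time units; one step = ``dt``)."""

    t_rel: float = 50.0
    t_end: float = 2000.0
    record_interval: int = 5       # steps between observable samples
    checkpoint_interval: int | None = None

    def __post_init__(self):
        if self.t_rel >= self.t_end:
            raise ValueError("require t_rel < t_end")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")


@dataclass
class RunConfig:
    init: InitConfig = field(default_factory=InitConfig)
    params: ModelParams = field(default_factory=ModelParams)
    schedule: RunSchedule = field(default_factory=RunSchedule)
    f_a_reference: str = "relaxed"   # 'initial' (t=0) or 'relaxed' (t=t_rel)

    _FLAT_KEYS = {
        "init": ["n_cells", "box_size", "patch_size", "lloyd_tol",
                 "mirror_cutoff", "p0_active", "p0_passive",
                 "target_perimeter_mean", "target_perimeter_sd", "seed",
                 "clamp_rings", "lloyd_max_iter",
                 "target_perimeter_from_tiling"],
        "params": ["K_A", "K_P", "zeta", "g", "alpha", "beta",
                   "div_area_factor", "ing_area_factor", "ell_T1", "dt",
                   "event_check_interval"],
        "schedule": ["t_rel", "t_end", "record_interval",
                     "checkpoint_interval"],
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kw = {"init": {}, "params": {}, "schedule": {}}
        for section, keys in cls._FLAT_KEYS.items():
            for k in keys:
                if k in d:
                    kw[section][k] = d.pop(k)
        top = {}
        if "f_a_reference" in d:
            top["f_a_reference"] = d.pop("f_a_reference")
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        init = InitConfig(**kw["init"])
        params = ModelParams(**kw["params"],
                             p0_active=init.p0_active,
                             p0_passive=init.p0_passive,
                             target_perimeter_mean=init.target_perimeter_mean,
                             target_perimeter_sd=init.target_perimeter_sd,
                             t_rel=kw["schedule"].get("t_rel", 50.0))
        sched = RunSchedule(**kw["schedule"])
        return cls(init=init, params=params, schedule=sched, **top)

    def to_dict(self) -> dict:
        out = {}
        for section in ("init", "params", "schedule"):
            src = vars(getattr(self, section))
            for k in self._FLAT_KEYS[section]:
                if k in src:
                    out[k] = src[k]
        out["f_a_reference"] = self.f_a_reference
        return out


@dataclass
class RunResult:
    status: str                 # 'ok' or 'unstable'
    mesh: TissueMesh
    series: pd.DataFrame
    events: EventLog
    growth: GrowthState | None
    refs: dict
    counters: dict
    config: RunConfig

    def summary(self, t_ss: float | None = None, window: float = 500.0):
        return observables.steady_state_summary(self.series, t_ss=t_ss,
                                                window=window)

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.series.to_csv(out / "observables.csv", index=False)
        self.events.to_csv(out / "events.csv")
        self.mesh.save(out / "snapshot_final.json")
        manifest = {
            "status": self.status,
            "seed": self.config.init.seed,
            "refs": self.refs,
            "counters": self.counters,
            "growth": None if self.growth is None else asdict(self.growth),
            "config": self.config.to_dict(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


class InstabilityError(Exception):
    """A cell reached non-positive area: the simulation left the physical
    regime (overlapping cells)."""


def t1_sweep(mesh: TissueMesh, params, log: EventLog | None = None) -> int:
    """Apply T1s to all interior junctions shorter than ell_T1.

    Junctions are processed in ascending length order; any junction whose
    endpoints were already displaced by an earlier T1 in the same sweep is
    skipped (retried next step).
    """
    cache = mesh.compiled()
    if len(cache.t1_he) == 0:
        return 0
    d = mesh.vx[cache.t1_b] - mesh.vx[cache.t1_a]
    lens = np.hypot(d[:, 0], d[:, 1])
    short = np.where(lens < params.ell_T1)[0]
    if len(short) == 0:
        return 0
    order = short[np.argsort(lens[short], kind="stable")]
    moved: set[int] = set()
    n_done = 0
    for k in order:
        h = int(cache.t1_he[k])
        a, b = int(cache.t1_a[k]), int(cache.t1_b[k])
        if a in moved or b in moved:
            continue
        try:
            ev = t1_transition(mesh, h, params, check_length=True)
        except MoveRejected:
            continue
        if log is not None:
            log.append(ev)
        moved.update((a, b))
        n_done += 1
    return n_done


def step(mesh: TissueMesh, params, rng: np.random.Generator,
         step_index: int, log: EventLog, counters: dict,
         growth: GrowthState | None = None,
         active_phase: bool = False) -> None:
    """Advance the tissue by one Euler step (see module docstring)."""
    F, A, P, el = mechanics.forces_and_geometry(mesh, params)
    if A.min() <= 0 or not np.isfinite(A).all():
        raise InstabilityError(
            f"non-positive cell area at t={mesh.time:.3f}")
    cache = mesh.compiled()
    free = cache.free_verts
    mesh.vx[free] += (params.dt / params.zeta) * F[free]
    mesh.time += params.dt

    counters["t1"] = counters.get("t1", 0) + t1_sweep(mesh, params, log)

    if active_phase:
        grow_targets(mesh, params)
        if step_index % params.event_check_interval == 0:
            div_events, touched = sweep_divisions(mesh, params, rng, log)
            counters["divisions"] = (counters.get("divisions", 0)
                                     + len(div_events))
            ing_events = sweep_ingressions(mesh, params, rng, log,
                                           exempt=touched)
            n_ing = sum(1 for e in ing_events if e.kind == "t2")
            counters["ingressions"] = counters.get("ingressions", 0) + n_ing
            conv = convert_encircled_cells(mesh, rng, params)
            for e in conv:
                log.append(e)
                sign = 1 if mesh.c_kind[e.cells[0]] == ACTIVE else -1
                counters["conversions_net"] = (
                    counters.get("conversions_net", 0) + sign)


def run_passive_relaxation(mesh: TissueMesh, params, schedule: RunSchedule,
                           log: EventLog, counters: dict,
                           recorder=None) -> GrowthState:
    """Evolve without growth/divisions/ingressions for t_rel; freeze the
    reference mean active area into a :class:`GrowthState`."""
    n_steps = int(round(schedule.t_rel / params.dt))
    rng = np.random.default_rng(0)  # unused during relaxation (no draws)
    for k in range(n_steps):
        step(mesh, params, rng, k, log, counters, active_phase=False)
        if recorder is not None and (k + 1) % schedule.record_interval == 0:
            recorder(mesh)
    growth = GrowthState.from_mesh(mesh, params, t_ref=schedule.t_rel)
    growth.install(params)
    return growth


def run(config: RunConfig, out_dir=None) -> RunResult:
    """Full pipeline: init -> passive relaxation -> homeostasis phase."""
    rng = np.random.default_rng(config.init.seed)
    params = config.params.copy()
    params.t_rel = config.schedule.t_rel
    mesh = build_tissue(config.init, rng)
    log = EventLog()
    counters: dict = {}
    rows: list[dict] = []

    cache = mesh.compiled()
    kinds = mesh.c_kind[cache.cells]
    areas0 = mesh.areas()
    refs = {
        "N_a_0": int((kinds == ACTIVE).sum()),
        "A_a_0": float(areas0[kinds == ACTIVE].sum()),
    }
    if refs["N_a_0"] == 0:
        raise ValueError("active patch contains no cells")

    status = "ok"
    growth = None
    sched = config.schedule
    try:
        n_rel = int(round(sched.t_rel / params.dt))
        for k in range(n_rel):
            step(mesh, params, rng, k + 1, log, counters,
                 active_phase=False)
        growth = GrowthState.from_mesh(mesh, params, t_ref=sched.t_rel)
        growth.install(params)

        cache = mesh.compiled()
        kinds = mesh.c_kind[cache.cells]
        areas = mesh.areas()
        refs["N_a_rel"] = int((kinds == ACTIVE).sum())
        refs["A_a_rel"] = float(areas[kinds == ACTIVE].sum())
        refs["N_a_ref"] = refs["N_a_rel"]
        refs["A_a_ref"] = (refs["A_a_rel"]
                           if config.f_a_reference == "relaxed"
                           else refs["A_a_0"])

        rows.append(observables.sample_observables(
            mesh, params, mesh.time, counters, refs))
        n_total = int(round(sched.t_end / params.dt))
        for k in range(n_rel, n_total):
            step(mesh, params, rng, k + 1, log, counters,
                 growth=growth, active_phase=True)
            if (k + 1) % sched.record_interval == 0:
                rows.append(observables.sample_observables(
                    mesh, params, mesh.time, counters, refs))
            if out_dir is not None and sched.checkpoint_interval \
                    and (k + 1) % sched.checkpoint_interval == 0:
                Path(out_dir).mkdir(parents=True, exist_ok=True)
                mesh.save(Path(out_dir) / f"snapshot_{k + 1:08d}.json")
    except InstabilityError:
        status = "unstable"

    series = pd.DataFrame(rows)
    result = RunResult(status=status, mesh=mesh, series=series, events=log,
                       growth=growth, refs=refs, counters=counters,
                       config=config)
    if out_dir is not None:
        result.save(out_dir)
    return result


def resume(mesh: TissueMesh, config: RunConfig, growth: GrowthState,
           counters: dict | None = None, refs: dict | None = None,
           rng: np.random.Generator | None = None) -> RunResult:
    """Continue a run from a snapshot to ``t_end`` (reduced bookkeeping:
    fractional changes are measured against the resumed state if no refs
    are provided)."""
    params = config.params.copy()
    growth.install(params)
    if rng is None:
        rng = np.random.default_rng(config.init.seed + 1)
    counters = counters or {}
    log = EventLog()
    cache = mesh.compiled()
    kinds = mesh.c_kind[cache.cells]
    areas = mesh.areas()
    if refs is None:
        n_a = int((kinds == ACTIVE).sum())
        refs = {"N_a_0": n_a, "A_a_0": float(areas[kinds == ACTIVE].sum()),
                "N_a_ref": n_a,
                "A_a_ref": float(areas[kinds == ACTIVE].sum())}
    rows = []
    sched = config.schedule
    k0 = int(round(mesh.time / params.dt))
    n_total = int(round(sched.t_end / params.dt))
    status = "ok"
    try:
        for k in range(k0, n_total):
            step(mesh, params, rng, k + 1, log, counters,
                 growth=growth, active_phase=True)
            if (k + 1) % sched.record_interval == 0:
                rows.append(observables.sample_observables(
                    mesh, params, mesh.time, counters, refs))
    except InstabilityError:
        status = "unstable"
    return RunResult(status=status, mesh=mesh, series=pd.DataFrame(rows),
                     events=log, growth=growth, refs=refs,
                     counters=counters, config=config)
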
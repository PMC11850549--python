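# epivertex

A two-dimensional vertex-model simulator of **homeostasis in confined
epithelial monolayers**: a central patch of proliferating ("active") cells
embedded in a passive epithelium that is clamped to the walls of a square
box.  The package is aimed at tissue-mechanics researchers who want a
seedable, testable reference implementation of the confined-epithelium
vertex model — including all topological moves and the full set of
homeostasis observables — without a multi-day HPC run.

## The model

The apical plane of the epithelium is a confluent polygonal tiling.  Each
cell `c` contributes a shape energy

```
E = Σ_c [ K_A/2 (A_c − A_c0)² + K_P/2 (P_c − P_c0)² ]
```

and vertices follow overdamped dynamics `ζ ṙ_i = F_i = −∇_{r_i} E`
(first-order Euler, no noise).  The target shape index
`p0 = P_c0/√A_c0` tunes solid-like vs fluid-like tissue; the regular
hexagon value `6/√(3√3/2) ≈ 3.722` and the regular pentagon value `≈ 3.81`
bracket the rigidity transition.

Cellular processes: T1 intercalations (junctions shorter than `ℓ_T1`
rotate 90° and re-open at `1.02 ℓ_T1`), linear target-area growth
`Ȧ_c0 = g`, stochastic division with logistic probability
`1/(1+exp(−α(A_c−A_d)))` along a Hertwig-rule plane (perpendicular to the
gyration-tensor long axis, through the centroid), stochastic ingression
(T2 collapse) with probability `1/(1+exp(β(A_c−A_i)))` followed by
resolution of high-coordination vertices, and passive↔active type
conversion of fully encircled cells.  `A_d` and `A_i` are 1.6× and 0.3×
the mean active-cell area measured after the initial passive relaxation.

Initial conditions are Lloyd-relaxed centroidal Voronoi tilings with
mirrored seed padding (straight walls) and clamped outer vertex layers.
The tissue lives in a half-edge mesh whose topological moves are local
pointer surgeries; `V − E + F = 1` and confluence (`Σ A_c = L²`) are
preserved by construction and audited by `TissueMesh.validate()`.

See `docs/methods.md` for assumptions, parameter meanings and defaults,
numerical choices, and known limitations.

## Worked example

```python
import epivertex as ev
from epivertex.simulate import RunConfig, RunSchedule

config = RunConfig(
    init=ev.InitConfig(n_cells=250, box_size=25.0, patch_size=10.0,
                       p0_active=3.60, p0_passive=3.80, seed=11),
    schedule=RunSchedule(t_rel=50.0, t_end=2000.0),
)
result = ev.run(config)
summary = result.summary(t_ss=1500.0, window=500.0)
print(f"f_N = {summary.f_N:.2f}  f_A = {summary.f_A:.2f}  "
      f"P_a/P_p = {summary.pressure_ratio:.2f}  "
      f"p_r = {summary.shape_index:.2f}  P_6 = {summary.P_n[6]:.2f}")
```

Output (one CPU, ~90 s):

```
f_N = 1.90  f_A = 1.94  P_a/P_p = 1.05  p_r = 3.94  P_6 = 0.38
```

Reading: starting from ~40 active cells, the patch grows and reaches a
dynamic steady state holding ~1.9× its post-relaxation cell count and
area, with divisions and ingressions continuing in balance (this run logs
257 divisions and 222 ingressions by `t = 2000`).  The active and passive
mean pressures agree to a few percent — the mechanical signature of
homeostasis — and the active tissue is disordered (realised shape index
3.94, hexagons the most common neighbour class, then pentagons).

## Command line

```bash
epivertex run --config run.yaml --seed 11 --out out/run1
epivertex validate --snapshot out/run1/snapshot_final.json
epivertex sweep --grid grid.yaml --out out/sweep
```

`run.yaml` is a flat mapping (`n_cells`, `box_size`, `patch_size`,
`p0_active`, `p0_passive`, `alpha`, `beta`, `g`, `t_rel`, `t_end`,
`seed`, ...).  Each run directory receives `observables.csv`,
`events.csv`, `snapshot_final.json`, `summary.json` and a manifest.

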
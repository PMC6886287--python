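# autofmo

Automatic tuning of importance factors for IMRT inverse planning, exercised
end-to-end on synthetic 2-D phantoms.

In intensity-modulated radiotherapy (IMRT), a fluence-map optimizer (FMO)
chooses beamlet intensities `x ≥ 0` that minimize a composite plan objective

```
f(D) = Σᵢ wᵢ fᵢ(D),      D = A x,
```

where `A` is the dose-influence matrix, each subscore `fᵢ` penalizes one
prescription constraint on one structure (target coverage, organ-at-risk
sparing), and the importance factors `wᵢ` encode clinical priorities.  In
practice those factors are tuned by a planner through trial and error.  This
package implements a prescription-value-based automation of that tuning, for
medical-physics researchers who want a desk-scale, fully reproducible
testbed for weight-adjustment strategies:

1. **Iterative adjustment** — after each inner FMO solve, every subscore's
   weight is corrected by a ratio of achieved to prescribed value (e.g.
   `D_min-pre / D_min-cur` for a minimum-dose goal, `V₂/V₁` for a maximum
   dose–volume goal, `NTCP_cur / NTCP_pre` for a complication-probability
   goal), then the weights are renormalized to sum to one:
   `w_new = w_old + k · factor`.  A violated goal gets factor > 1 (more
   pressure), an over-satisfied one factor < 1.
2. **Plan evaluation** — the plan is acceptable when the PTV volume
   receiving the prescribed minimum dose reaches 95 % and every
   dose–volume guideline on the organs at risk holds (strict `<` on the
   volume side).
3. **Compensation** — if evaluation fails, the correction factor of the
   most critical failing subscore (PTV first, otherwise the OAR subscore
   guarding the highest dose level) is multiplied by a coefficient `k`
   that grows arithmetically, `k = k₀ + (iter − 1) · steplength`, and the
   adjustment stage is rerun, up to `N_max` times.

Three objective models are provided: dose–volume (quadratic penalties with
a convex surrogate for maximum DV constraints), gEUD (linear overshoot of a
generalized-equivalent-uniform-dose target, `gEUD = ((1/N) Σ Dᵢᵃ)^{1/a}`),
and LKB NTCP (logarithmic overshoot of a Lyman–Kutcher–Burman complication
probability, `NTCP = Φ((gEUD_{1/n} − TD50)/(m·TD50))`).  The inner problem
is solved with L-BFGS on the *square roots* of the beamlet weights, which
keeps fluence nonnegative without bound constraints.

The package ships a synthetic planning geometry (a prostate-like 64×64
single slice: central PTV disk, posterior crescent-shaped rectum, anterior
bladder disk, normal-tissue ring, five coplanar parallel beams at gantry
angles 36°, 100°, 180°, 260°, 324°) and a simple analytic dose kernel
(exponential attenuation × Gaussian penumbra), so no external data are
needed.

## Worked example

```python
import autofmo as af

phantom = af.generate_phantom(af.default_prostate_spec())
A = af.compute_influence_matrix(phantom, af.default_beam_spec())
prescription = af.default_prostate_prescription()
result = af.run_automatic(phantom, A, prescription, model="dv")
```

Running `python examples/run_automatic_plan.py` prints:

```
acceptable plan: True
inner FMO solves used: 5 (budget 5*(1+10)=55)
PTV V(74 Gy) = 100.0%  (must reach 95%)
  rectum   V50 =  27.1% (guideline < 50%)
  rectum   V60 =   2.1% (guideline < 35%)
  ...
  bladder  V70 =   1.4% (guideline < 35%)
conformity index CI = 0.81 (1 = reference isodose matches the PTV)
homogeneity index HI = 1.010 (1 = perfectly uniform PTV dose)
```

The prescription (PTV minimum 74 Gy, mean 78 Gy; rectum 50 Gy/40 %,
65 Gy/25 %, 75 Gy/15 %; bladder 65 Gy/35 %, 70 Gy/30 %, 75 Gy/16 %) is met
after the five adjustment iterations alone — the compensation stage only
engages when a goal is initially missed (see
`examples/compensation_stage_demo.py`).  The other examples cover the
metric conventions (`plan_metrics_basics.py`) and a side-by-side of the
three objective models (`compare_objective_models.py`).

A thin CLI wraps the same pipeline and writes a report bundle (`dvh.csv`,
`metrics.csv`, `weights_history.csv`, `solver_trace.csv`,
`plan_report.json`, `config.yaml`):

```bash
autofmo run --model dv --out runs/demo       # exit 0 = acceptable, 2 = budget exhausted
```

Coordinate conventions: row-major 0-based voxel indexing, voxel centers at
`(i+0.5, j+0.5)·voxel_size`, physical origin at the grid center, gantry
angles clockwise from north.

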
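# Methods

## The optimization problem

A plan is a nonnegative beamlet-weight vector `x`; voxel doses are linear,
`D = A x`, with `A` the sparse dose-influence matrix (Gy per unit weight).
The plan objective is a weighted sum of subscores, `f(D) = Σᵢ wᵢ fᵢ(D)`,
with importance factors `wᵢ > 0` normalized to `Σ wᵢ = 1`.  Normalization
does not change the minimizer — it only fixes the scale — but keeps every
factor inside (0, 1) during the automatic updates.

Subscores (all per-voxel means over the structure, `H` the step function
with the strict convention `H(0) = 0`):

* `f_min(D) = (1/N) Σ H(D_min − Dᵢ)(D_min − Dᵢ)²` — PTV underdose.
* `f_mean(D) = (1/N) Σ (Dᵢ − D_mean)²` — deviation from the prescribed
  mean (used on the PTV; pushes toward uniformity).
* `f_dvmax(D) = (1/N) Σ H(Dᵢ − D₁) H(D₂ − Dᵢ)(Dᵢ − D₁)²` — convex
  surrogate of the maximum dose–volume constraint `V(D₁) ≤ V₁%`.  `D₂` is
  the dose level in the current plan whose hot volume equals `V₁%`
  (descending-rank quantile).  When the constraint already holds,
  `D₂ ≤ D₁` and the penalty window is empty.
* `f_gEUD(D) = max(gEUD_cur − gEUD_pre, 0)` with
  `gEUD = ((1/N) Σ Dᵢᵃ)^{1/a}` (OAR form, `a ≥ 1`).
* `f_NTCP(D) = max(ln(1 − NTCP_pre) − ln(1 − NTCP_LKB(D)), 0)` with
  `NTCP_LKB = Φ((gEUD_{1/n} − TD50)/(m·TD50))`.  The logarithmic form is
  the convex criterion that makes the NTCP goal gradient-friendly; if the
  NTCP saturates numerically at 1 the score is capped at 1e6 with a
  warning.

The three objective models share the two PTV subscores (min + mean) and
differ in the OAR terms: per-constraint `f_dvmax` (dose–volume model), one
`f_gEUD` per OAR (gEUD model), one `f_NTCP` per OAR (NTCP model).

## Inner solver

L-BFGS runs on `u` with `x = u²` elementwise (gradient
`∂f/∂uⱼ = 2uⱼ (Aᵀ ∂f/∂D)ⱼ`), which enforces nonnegative fluence without
bounds.  Two consequences are handled explicitly: `u = 0` is a stationary
point of the parameterization, so solves start from a strictly positive
uniform fluence scaled so the mean PTV dose equals the prescribed mean;
and the returned plan is the best iterate seen, guaranteeing the descent
property `f(x_out) ≤ f(x₀)`.  Defaults: 50 iterations per solve, relative
objective tolerance 1e-6, history 10.

**Frozen dose–volume windows.**  The voxel that defines `D₂` sits exactly
on the penalty-window edge, so re-sorting `D₂` inside a solve would make
the objective discontinuous there (an infinitesimal dose change moves that
voxel in or out of the window with a finite penalty jump).  Both the level
`D₂` *and* the window membership are therefore frozen at solver entry (the
reference plan) and refreshed between solves; within a solve the surrogate
is C¹ (quadratic hinge at `D₁` only).  Analytic gradients of every
subscore are validated against central finite differences on randomized
instances at 1e-5 relative error.

## Outer automation

Stage I starts from uniform factors `wᵢ = 1/l` and alternates five times:
inner solve → correction factors → weight update `w_new = w_old + k·factor`
→ renormalize.  Within a stage each solve warm-starts from the previous
plan's fluence (the correction factors are most meaningful against a
converged-ish plan; the granularity of the alternation is a free choice and
this one keeps the five iterations cheap and progressive).  Correction
factors are prescription/achieved ratios oriented so violation ⇒ factor >
1; they are clamped to [0.01, 100] so cold starts with zero dose warn and
saturate instead of dividing by zero.

Evaluation: PTV coverage `V_PTV(D_min-pre) ≥ 95%` first, then every OAR
dose–volume guideline with strict `<`.  On failure the compensation stage
reruns Stage I (again from uniform factors, so each `k` is assessed from
the same start) with `k = k₀ + (iter − 1)·steplength` applied to the
factor of the targeted subscores only: PTV subscores if coverage failed,
otherwise the single OAR subscore guarding the highest dose level among
the violated structures ("high-dose region first").  Per-model schedule
defaults: (k₀, steplength) = (1, 1) for the dose–volume model, (10, 5) for
gEUD, (1, 1) for NTCP; budget `N_max = 10` compensation iterations, hence
at most `5·(1+10) = 55` inner solves.  If no plan is acceptable the best
evaluated plan is returned, ranked lexicographically by (PTV satisfied,
number of satisfied criteria, lower objective), flagged unacceptable.

An optional post-pass (`push_coverage`) keeps adjusting while the plan
remains acceptable, keeping the last acceptable plan; it is off by default
because the stopping rule for "improve as far as possible" is otherwise
unconstrained.

## Synthetic phantom and dose model

The default case is a single 64×64 transverse slice at 2.5 mm voxels: a
circular 75 mm body, a central 12 mm PTV disk, a crescent-shaped rectum
stand-in hugging the PTV posteriorly, a 17 mm bladder disk anteriorly
(adjacent to the PTV, and deliberately larger than it — with a small
bladder the slice next to the PTV dominates its volume and no objective
can meet the high-dose volume guidelines, which is a geometric artifact
rather than a planning trade-off), and a 15 mm normal-tissue ring.  The
ring is 15 mm rather than the several-centimetre ring used clinically so
that it fits the 64×64 grid.  Five parallel-geometry coplanar beams
(gantry 36°/100°/180°/260°/324°, clockwise from north) carry 5 mm beamlets
over a ±25 mm aperture.

Dose deposition per beamlet is `exp(−μ·depth)` along the ray (depth = path
length inside the body from the entry point, marched at half-voxel steps)
times a Gaussian lateral penumbra `exp(−ℓ²/2σ²)`; defaults μ = 0.005/mm,
σ = 3 mm, with entries below 1e-4 of the beamlet maximum dropped for
sparsity.  These defaults were chosen so that five beams can conformally
cover the PTV with a realistic penumbra at this grid scale; they are
artifact parameters of the testbed, not measured beam data.

What the phantom does *not* emulate: 3-D scatter and divergent beams,
tissue heterogeneity, realistic organ shapes and wall structures,
inter-patient anatomical variation, delivery (leaf sequencing).  Passing
the end-to-end suites therefore demonstrates the mechanics and
self-consistency of the automation — factor dynamics, compensation
scheduling, evaluation logic — not clinical plan quality on patient CTs.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| PTV D_min / D_mean | 74 / 78 Gy | coverage and uniformity targets |
| rectum DV constraints | 50/40, 65/25, 75/15 (Gy/%) | optimization goals |
| bladder DV constraints | 65/35, 70/30, 75/16 (Gy/%) | optimization goals |
| evaluation guidelines | rectum V50<50 … V75<15; bladder V65<50 … V80<15 (%) | acceptability rules (distinct from the goals above) |
| gEUD_pre | 60 Gy (both OARs) | gEUD-model targets; exponents a = 1/n |
| NTCP_pre | 0.05 (both OARs) | NTCP-model targets |
| LKB rectum | TD50 76.9 Gy, m 0.13, n 0.09 | serial-type organ, near max-dose driven |
| LKB bladder | TD50 80 Gy, m 0.11, n 0.5 | intermediate volume effect |
| inner adjustment iterations | 5 | Stage-I alternations per pass |
| N_max | 10 | compensation passes |
| (k₀, steplength) | (1,1) / (10,5) / (1,1) | per model dv / gEUD / NTCP |

The LKB parameter defaults follow values commonly quoted in the
rectal/bladder complication literature; they are configuration defaults of
this testbed, exposed in the prescription schema.

## Numerical choices and degenerate inputs

* Strict step `H(0) = 0` everywhere: a constraint met exactly is
  penalty-free (and the boundary is measure-zero for continuous doses).
* Dose-at-volume and `D₂` use the exact descending-rank convention
  (`rank = ceil(N·x/100)`), no interpolation or binning anywhere; ties
  share eligibility.
* Volume queries are closed at the dose threshold (`≥ d`); evaluation
  guidelines are strict on the volume side.
* Correction factors clamp to [0.01, 100]; zero denominators warn and
  return the ceiling.
* The conformity index's reference volume is taken over the body mask
  (voxels outside the body receive no dose by construction); if no voxel
  reaches the reference dose, CI is 0 with a warning.
* `dv_min` constraints are implemented symmetrically to the maximum-DV
  surrogate (window `(D₂, D₁)`, deficit squared) but are experimental: no
  shipped prescription exercises them.
* `tcp` constraints are supported in the factor table through a
  user-supplied evaluator; no TCP dose-response model is shipped.

## Problem sizes

The default test and acceptance workloads use the 64×64 phantom (4 096
voxels, 50 beamlets, ~30 k nonzeros in `A`); a full automatic run is a few
hundred milliseconds and the entire suite runs in seconds.  These sizes
were chosen to make every end-to-end property cheap to assert; the code
paths are size-agnostic (sparse matrices throughout) and finer grids only
increase runtime.

## Known limitations

* 2-D single-slice geometry; the mathematics is dimension-agnostic but
  absolute dosimetric numbers do not transfer to 3-D.
* The analytic kernel has no scatter model; penumbra is a single Gaussian.
* Compensation targets one subscore at a time; simultaneous multi-organ
  escalation is not implemented (matching the targeted update form).
* The inner solver's iteration cap (50) is a pragmatic budget; pathological
  prescriptions may need more for tight convergence (the quadratic-oracle
  test raises it explicitly).
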
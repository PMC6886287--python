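"""Automatic importance-factor optimization.

The outer loop that makes inverse planning hands-free: after every inner
fluence-map solve, each subscore's importance factor is corrected by a
ratio of its prescription value to its achieved value (the weight
correction factor), the factors are renormalized, and the solve repeats.
If the fixed number of adjustment iterations does not yield an acceptable
plan, a compensation stage multiplies the correction factor of the most
critical failing subscore by a coefficient ``k`` that grows on an
arithmetic schedule ``k = k0 + (iter - 1) * steplength`` until the plan
becomes acceptable or the compensation budget is exhausted.

Acceptability is judged by two rules: the PTV volume receiving the
prescribed minimum dose must reach the coverage threshold (default 95 %),
and every dose-volume evaluation criterion on the organs at risk must hold
(strict inequality on the volume side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import metrics
from .dose import InfluenceMatrix
from .fmo import Plan, SolverConfig, initial_fluence, solve_fmo
from .objectives import (
    Constraint,
    Model,
    ObjectiveFunction,
    ObjectiveSpec,
    SubscoreSpec,
    build_objective_spec,
    normalize_weights,
    uniform_weights,
)
from .phantom import Phantom

FACTOR_FLOOR = 0.01
FACTOR_CEILING = 100.0

#: per-model compensation schedule defaults (k0, steplength)
MODEL_K_DEFAULTS: Dict[str, Tuple[float, float]] = {
    "dv": (1.0, 1.0),
    "geud": (10.0, 5.0),
    "ntcp": (1.0, 1.0),
}


class EvaluationCriterion(BaseModel):
    """One acceptability rule: V(dose_gy) must stay strictly below volume_pct."""

    model_config = ConfigDict(extra="forbid")

    structure: str
    dose_gy: float
    volume_pct: float


class Prescription(BaseModel):
    """Constraints driving the objective plus the plan-acceptability rules."""

    model_config = ConfigDict(extra="forbid")

    constraints: List[Constraint]
    ptv_coverage_pct: float = 95.0
    evaluation_criteria: List[EvaluationCriterion] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "Prescription":
        n_min = sum(1 for c in self.constraints if c.type == "min_dose")
        if n_min != 1:
            raise ValueError("prescription must contain exactly one PTV min_dose constraint")
        if not (0 < self.ptv_coverage_pct <= 100):
            raise ValueError("ptv_coverage_pct must lie in (0, 100]")
        return self

    @property
    def ptv_min_dose(self) -> float:
        return next(c.limit_gy for c in self.constraints if c.type == "min_dose")

    @property
    def ptv_mean_dose(self) -> float:
        return next(c.limit_gy for c in self.constraints if c.type == "mean_dose")

    @property
    def ptv_structure(self) -> str:
        return next(c.structure for c in self.constraints if c.type == "min_dose")


def default_prostate_prescription() -> Prescription:
    """Standard prostate prescription on the default phantom structures.

    PTV: minimum 74 Gy, mean 78 Gy.  Dose-volume constraints: rectum
    50 Gy/40 %, 65 Gy/25 %, 75 Gy/15 %; bladder 65 Gy/35 %, 70 Gy/30 %,
    75 Gy/16 %; plus a hot-spot constraint on the normal-tissue ring.
    gEUD targets of 60 Gy and NTCP targets of 0.05 for both organs at risk.

    The LKB parameter defaults (rectum TD50 76.9 Gy, m 0.13, n 0.09;
    bladder TD50 80 Gy, m 0.11, n 0.5) follow the values commonly quoted in
    the rectal-bleeding / bladder-complication literature and are exposed in
    the configuration for adjustment.
    """
    c = [
        Constraint(structure="ptv", type="min_dose", limit_gy=74.0),
        Constraint(structure="ptv", type="mean_dose", limit_gy=78.0),
        Constraint(structure="rectum", type="dv_max", dose_gy=50.0, volume_pct=40.0),
        Constraint(structure="rectum", type="dv_max", dose_gy=65.0, volume_pct=25.0),
        Constraint(structure="rectum", type="dv_max", dose_gy=75.0, volume_pct=15.0),
        Constraint(structure="bladder", type="dv_max", dose_gy=65.0, volume_pct=35.0),
        Constraint(structure="bladder", type="dv_max", dose_gy=70.0, volume_pct=30.0),
        Constraint(structure="bladder", type="dv_max", dose_gy=75.0, volume_pct=16.0),
        Constraint(structure="ring", type="dv_max", dose_gy=74.0, volume_pct=5.0),
        Constraint(structure="rectum", type="geud", limit_gy=60.0, exponent_a=1.0 / 0.09),
        Constraint(structure="bladder", type="geud", limit_gy=60.0, exponent_a=2.0),
        Constraint(
            structure="rectum", type="ntcp", probability=0.05, td50=76.9, m=0.13, n=0.09
        ),
        Constraint(
            structure="bladder", type="ntcp", probability=0.05, td50=80.0, m=0.11, n=0.5
        ),
    ]
    criteria = [
        EvaluationCriterion(structure="rectum", dose_gy=50.0, volume_pct=50.0),
        EvaluationCriterion(structure="rectum", dose_gy=60.0, volume_pct=35.0),
        EvaluationCriterion(structure="rectum", dose_gy=65.0, volume_pct=25.0),
        EvaluationCriterion(structure="rectum", dose_gy=70.0, volume_pct=20.0),
        EvaluationCriterion(structure="rectum", dose_gy=75.0, volume_pct=15.0),
        EvaluationCriterion(structure="bladder", dose_gy=65.0, volume_pct=50.0),
        EvaluationCriterion(structure="bladder", dose_gy=70.0, volume_pct=35.0),
        EvaluationCriterion(structure="bladder", dose_gy=75.0, volume_pct=25.0),
        EvaluationCriterion(structure="bladder", dose_gy=80.0, volume_pct=15.0),
    ]
    return Prescription(constraints=c, evaluation_criteria=criteria)


@dataclass
class CompensationState:
    """Arithmetic compensation schedule: k = k0 + (iteration - 1) * steplength."""

    k0: float
    steplength: float
    iteration: int = 0  # 0 = compensation not yet engaged

    @property
    def k(self) -> float:
        if self.iteration <= 0:
            return 1.0
        return self.k0 + (self.iteration - 1) * self.steplength


class LoopConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    inner_adjust_iters: int = 5
    max_compensation_iters: int = 10
    k0: Optional[float] = None  # None -> per-model default
    steplength: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "LoopConfig":
        if self.inner_adjust_iters <= 0 or self.max_compensation_iters <= 0:
            raise ValueError("iteration budgets must be positive")
        return self

    def schedule(self, model: str) -> Tuple[float, float]:
        k0_d, step_d = MODEL_K_DEFAULTS[model]
        return (
            self.k0 if self.k0 is not None else k0_d,
            self.steplength if self.steplength is not None else step_d,
        )


@dataclass
class EvaluationResult:
    ptv_satisfied: bool
    ptv_coverage_pct: float
    criteria: List[dict]  # structure, dose_gy, volume_pct, value_pct, satisfied
    all_satisfied: bool
    compensation_targets: List[int]


@dataclass
class RunHistory:
    """Per-outer-iteration record of the automatic run."""

    records: List[dict] = field(default_factory=list)
    evaluations: List[EvaluationResult] = field(default_factory=list)

    @property
    def n_solves(self) -> int:
        return len(self.records)


@dataclass
class AutoPlanResult:
    plan: Plan
    history: RunHistory
    evaluation: EvaluationResult
    acceptable: bool
    model: str
    weights: np.ndarray
    objective_spec: ObjectiveSpec
    k_final: float


# ---------------------------------------------------------------------------
# weight correction factors (per prescription-value penalty strategy)


def correction_factor(
    constraint: Constraint,
    d: np.ndarray,
    role: Literal["ptv_coverage", "oar_sparing"] = "oar_sparing",
    tcp_evaluator: Optional[Callable[[np.ndarray], float]] = None,
) -> float:
    """Weight correction factor: a ratio of achieved to prescribed value.

    The ratio is oriented so that a violated constraint gets a factor > 1
    (more importance next round) and an over-satisfied one a factor < 1.
    Results are clamped to ``[0.01, 100]``; a vanishing denominator (for
    example a cold start with zero dose) yields the ceiling with a warning
    rather than an error.
    """
    d = np.asarray(d, dtype=float)

    def ratio(num: float, den: float) -> float:
        if den <= 0:
            warnings.warn(
                f"zero denominator in correction factor for '{constraint.structure}' "
                f"({constraint.type}); clamped",
                stacklevel=3,
            )
            return FACTOR_CEILING
        return float(np.clip(num / den, FACTOR_FLOOR, FACTOR_CEILING))

    t = constraint.type
    if t == "min_dose":
        return ratio(constraint.limit_gy, float(d.min()))
    if t == "max_dose":
        return ratio(float(d.max()), constraint.limit_gy)
    if t == "mean_dose":
        cur, pre = float(d.mean()), constraint.limit_gy
        if role == "ptv_coverage":
            return ratio(max(cur, pre), min(cur, pre))
        return ratio(cur, pre)
    if t == "dv_max":
        v2 = 100.0 * np.count_nonzero(d >= constraint.dose_gy) / d.size
        return ratio(v2, constraint.volume_pct)
    if t == "dv_min":
        v2 = 100.0 * np.count_nonzero(d >= constraint.dose_gy) / d.size
        return ratio(constraint.volume_pct, v2)
    if t == "geud":
        g = metrics.geud(d, np.ones(d.size, dtype=bool), constraint.exponent_a)
        if constraint.exponent_a >= 1:
            return ratio(g, constraint.limit_gy)
        return ratio(constraint.limit_gy, g)
    if t == "ntcp":
        p = metrics.ntcp_lkb(
            d, np.ones(d.size, dtype=bool), constraint.td50, constraint.m, constraint.n
        )
        return ratio(p, constraint.probability)
    if t == "tcp":
        if tcp_evaluator is None:
            raise ValueError("tcp constraint requires a user-supplied tcp_evaluator")
        return ratio(constraint.probability, tcp_evaluator(d))
    raise NotImplementedError(t)


def update_weights(
    w_old: np.ndarray, factors: Sequence[float], k_per_subscore: Sequence[float]
) -> np.ndarray:
    """Additive update ``w_new = w_old + k * factor``, then renormalization."""
    w_old = np.asarray(w_old, dtype=float)
    factors = np.asarray(factors, dtype=float)
    k = np.asarray(k_per_subscore, dtype=float)
    if not (w_old.shape == factors.shape == k.shape):
        raise ValueError("weights, factors and k must have equal length")
    return normalize_weights(w_old + k * factors)


# ---------------------------------------------------------------------------
# plan evaluation


def evaluate_plan(
    dose: np.ndarray,
    prescription: Prescription,
    phantom: Phantom,
    objective_spec: ObjectiveSpec,
) -> EvaluationResult:
    """Acceptability check and selection of the compensation target.

    PTV coverage is checked first; if it fails, the PTV subscores are the
    compensation targets.  Otherwise any failing organ-at-risk criterion
    selects one OAR subscore, the one guarding the highest dose level
    (high-dose region first).
    """
    ptv_mask = phantom.masks[prescription.ptv_structure]
    cov = metrics.volume_at_dose(dose, ptv_mask, prescription.ptv_min_dose)
    ptv_ok = cov >= prescription.ptv_coverage_pct

    crit_rows: List[dict] = []
    violated_structs: Dict[str, float] = {}
    for cr in prescription.evaluation_criteria:
        v = metrics.volume_at_dose(dose, phantom.masks[cr.structure], cr.dose_gy)
        ok = v < cr.volume_pct
        crit_rows.append(
            {
                "structure": cr.structure,
                "dose_gy": cr.dose_gy,
                "volume_pct": cr.volume_pct,
                "value_pct": float(v),
                "satisfied": bool(ok),
            }
        )
        if not ok:
            violated_structs[cr.structure] = max(
                violated_structs.get(cr.structure, 0.0), cr.dose_gy
            )

    all_ok = ptv_ok and not violated_structs
    targets: List[int] = []
    if not ptv_ok:
        targets = [
            ss.index for ss in objective_spec.subscores if ss.role_in_objective == "ptv_coverage"
        ]
    elif violated_structs:
        candidates: List[Tuple[float, int]] = []
        for ss in objective_spec.subscores:
            c = ss.constraint
            if ss.role_in_objective != "oar_sparing" or c.structure not in violated_structs:
                continue
            key = c.dose_gy if c.dose_gy is not None else violated_structs[c.structure]
            candidates.append((key, ss.index))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        if candidates:
            targets = [candidates[0][1]]
    return EvaluationResult(
        ptv_satisfied=bool(ptv_ok),
        ptv_coverage_pct=float(cov),
        criteria=crit_rows,
        all_satisfied=bool(all_ok),
        compensation_targets=targets,
    )


def _plan_rank(ev: EvaluationResult, plan: Plan) -> Tuple:
    """Lexicographic plan quality: coverage first, then criteria, then objective."""
    n_ok = sum(1 for c in ev.criteria if c["satisfied"])
    return (int(ev.ptv_satisfied), n_ok, -plan.objective)


# ---------------------------------------------------------------------------
# the outer automatic loop


def run_automatic(
    phantom: Phantom,
    A: InfluenceMatrix,
    prescription: Prescription,
    model: Model = "dv",
    loop: Optional[LoopConfig] = None,
    solver: Optional[SolverConfig] = None,
    initial_weights: Optional[np.ndarray] = None,
    push_coverage: bool = False,
) -> AutoPlanResult:
    """Run the full automatic importance-factor optimization.

    Stage I runs ``inner_adjust_iters`` alternations of inner FMO solve and
    weight correction, starting from uniform importance factors (or
    ``initial_weights``).  If the resulting plan is not acceptable, the
    compensation stage repeats Stage I up to ``max_compensation_iters``
    times with the correction factor of the targeted subscore multiplied by
    ``k = k0 + (iter - 1) * steplength``.

    Returns the final plan (the best evaluated plan if none was acceptable),
    with ``acceptable`` indicating which case occurred.
    """
    loop = loop or LoopConfig()
    solver = solver or SolverConfig()
    k0, steplength = loop.schedule(model)

    spec = build_objective_spec(prescription.constraints, model)
    masks = {name: m for name, m in phantom.masks.items()}
    objfun = ObjectiveFunction(spec, masks, A.entries)
    ptv_mask = masks[prescription.ptv_structure]
    x_cold = initial_fluence(A, ptv_mask, prescription.ptv_mean_dose)

    if initial_weights is None:
        w_init = uniform_weights(len(spec))
    else:
        w_init = normalize_weights(initial_weights)

    history = RunHistory()

    def stage_one(k: float, targets: List[int], comp_iter: int) -> Plan:
        w = w_init.copy()
        x0 = x_cold
        plan = None
        for it in range(loop.inner_adjust_iters):
            plan = solve_fmo(A, objfun, w, x0, solver)
            x0 = plan.x  # warm start within the pass
            factors = np.array(
                [
                    correction_factor(ss.constraint, plan.dose[idx], ss.role_in_objective)
                    for ss, idx in zip(spec.subscores, objfun.indices)
                ]
            )
            k_vec = np.array([k if ss.index in targets else 1.0 for ss in spec.subscores])
            w_next = update_weights(w, factors, k_vec)
            history.records.append(
                {
                    "comp_iter": comp_iter,
                    "inner_iter": it,
                    "k": k if targets else 1.0,
                    "weights": w.copy(),
                    "factors": factors,
                    "weights_updated": w_next.copy(),
                    "objective": plan.objective,
                    "objective_start": plan.trace[0]["objective"] if plan.trace else plan.objective,
                    "subscores": plan.subscores.copy(),
                    "ptv_coverage_pct": metrics.volume_at_dose(
                        plan.dose, ptv_mask, prescription.ptv_min_dose
                    ),
                }
            )
            w = w_next
        return plan

    # Stage I (no compensation)
    plan = stage_one(1.0, [], comp_iter=0)
    ev = evaluate_plan(plan.dose, prescription, phantom, spec)
    history.evaluations.append(ev)
    best_plan, best_ev, best_rank = plan, ev, _plan_rank(ev, plan)
    k_final = 1.0

    if not ev.all_satisfied:
        state = CompensationState(k0=k0, steplength=steplength)
        targets = ev.compensation_targets
        for citer in range(1, loop.max_compensation_iters + 1):
            state.iteration = citer
            plan = stage_one(state.k, targets, comp_iter=citer)
            ev = evaluate_plan(plan.dose, prescription, phantom, spec)
            history.evaluations.append(ev)
            rank = _plan_rank(ev, plan)
            if rank > best_rank:
                best_plan, best_ev, best_rank = plan, ev, rank
            k_final = state.k
            if ev.all_satisfied:
                best_plan, best_ev = plan, ev
                break
            targets = ev.compensation_targets or targets
        else:
            plan, ev = best_plan, best_ev
    if ev.all_satisfied:
        best_plan, best_ev = plan, ev

    if push_coverage and best_ev.all_satisfied:
        # optional post-pass: keep adjusting while the plan stays acceptable
        w = w_init.copy()
        x0 = best_plan.x
        for _ in range(loop.inner_adjust_iters):
            trial = solve_fmo(A, objfun, w, x0, solver)
            tev = evaluate_plan(trial.dose, prescription, phantom, spec)
            if not tev.all_satisfied:
                break
            best_plan, best_ev = trial, tev
            x0 = trial.x
            factors = np.array(
                [
                    correction_factor(ss.constraint, trial.dose[idx], ss.role_in_objective)
                    for ss, idx in zip(spec.subscores, objfun.indices)
                ]
            )
            w = update_weights(w, factors, np.ones(len(spec)))

    final_weights = history.records[-1]["weights_updated"]
    return AutoPlanResult(
        plan=best_plan,
        history=history,
        evaluation=best_ev,
        acceptable=bool(best_ev.all_satisfied),
        model=model,
        weights=final_weights,
        objective_spec=spec,
        k_final=k_final,
    )
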
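"""Inner fluence-map optimization (FMO).

Minimizes the weighted plan objective over beamlet weights with L-BFGS,
using the square roots of the beamlet weights as optimization variables:
``x = u**2`` keeps fluence nonnegative without bound constraints.  One
consequence is that ``u = 0`` is a stationary point of the
parameterization, so the solver must be started from a strictly positive
fluence — :func:`initial_fluence` provides that cold start.

Dose-volume surrogate levels ``D2`` are refreshed once at solver entry
(from the starting fluence) and held fixed during the solve, which keeps
the inner problem smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import optimize, sparse

from .dose import InfluenceMatrix, compute_dose
from .objectives import ObjectiveFunction, ObjectiveSpec


@dataclass
class SolverConfig:
    max_lbfgs_iters: int = 50
    tol: float = 1e-6  # relative objective-change stopping tolerance
    history_size: int = 10

    def validate(self) -> None:
        if self.max_lbfgs_iters <= 0 or self.tol <= 0 or self.history_size <= 0:
            raise ValueError("solver configuration values must be positive")


@dataclass
class Plan:
    """Result of one inner solve: fluence, dose and objective breakdown."""

    x: np.ndarray
    dose: np.ndarray
    objective: float
    subscores: np.ndarray
    d2_levels: Dict[int, float] = field(default_factory=dict)
    trace: List[dict] = field(default_factory=list)
    converged: bool = True


class SolverDiagnosticsError(RuntimeError):
    """Non-finite objective or gradient during a solve; carries the state."""

    def __init__(self, message: str, u: np.ndarray, f: float):
        super().__init__(f"{message} (objective={f!r}, |u|={np.linalg.norm(u):.3g})")
        self.u = u
        self.f = f


def initial_fluence(A: InfluenceMatrix | sparse.spmatrix, ptv_mask: np.ndarray, d_mean: float) -> np.ndarray:
    """Uniform positive fluence scaled so the mean PTV dose equals ``d_mean``.

    The scalar least-squares fit of ``t * A 1`` to the prescribed mean:
    ``t = d_mean / mean_PTV(A 1)``.
    """
    mat = A.entries if isinstance(A, InfluenceMatrix) else A
    ones = np.ones(mat.shape[1])
    dose1 = np.asarray(mat @ ones).ravel()
    ptv = np.asarray(ptv_mask, dtype=bool).ravel()
    mean1 = dose1[ptv].mean()
    if mean1 <= 0:
        raise ValueError("no beamlet covers the PTV; cannot scale initial fluence")
    return (d_mean / mean1) * ones


def solve_fmo(
    A: InfluenceMatrix | sparse.spmatrix,
    objective: ObjectiveFunction,
    weights: np.ndarray,
    x0: np.ndarray,
    config: Optional[SolverConfig] = None,
) -> Plan:
    """Run L-BFGS on the square-root fluence variables from ``x0``.

    Returns the best (lowest-objective) iterate encountered.  Deterministic:
    identical inputs give identical plans.
    """
    config = config or SolverConfig()
    config.validate()
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("x0 must be nonnegative")
    w = np.asarray(weights, dtype=float)

    mat = A.entries if isinstance(A, InfluenceMatrix) else A
    dose0 = np.asarray(mat @ x0).ravel()
    d2s = objective.refresh_d2(dose0)

    u0 = np.sqrt(x0)
    best = {"f": np.inf, "u": u0.copy()}
    trace: List[dict] = []

    def fun(u: np.ndarray):
        f, g = objective.value_and_grad_u(u, w, d2s)
        if not np.isfinite(f) or not np.all(np.isfinite(g)):
            raise SolverDiagnosticsError("non-finite objective or gradient", u, f)
        if f < best["f"]:
            best["f"] = f
            best["u"] = u.copy()
        trace.append({"objective": f, "grad_norm": float(np.linalg.norm(g))})
        return f, g

    res = optimize.minimize(
        fun,
        u0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_lbfgs_iters,
            "maxcor": config.history_size,
            "ftol": config.tol,
        },
    )
    u_best = best["u"] if best["f"] <= res.fun else res.x
    x = u_best**2
    dose = np.asarray(mat @ x).ravel()
    vals = objective.subscore_values(dose, d2s)
    f_final = float(vals @ w)
    return Plan(
        x=x,
        dose=dose,
        objective=f_final,
        subscores=vals,
        d2_levels={i: st.d2 for i, st in d2s.items()},
        trace=trace,
        converged=bool(res.success) or res.status == 1,  # status 1 = iteration cap
    )
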
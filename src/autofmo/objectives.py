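"""Objective subscores, analytic gradients and the weighted plan objective.

The plan objective is a convex-surrogate composite

    f(D) = sum_i w_i f_i(D),

where each subscore ``f_i`` penalizes one prescription constraint on one
structure and the importance factors ``w_i`` are positive and normalized
to sum to one.  Three families of subscores are provided:

* dose-volume model: quadratic underdose penalty below a minimum dose,
  quadratic deviation from a mean dose, and the convex surrogate for a
  maximum dose-volume constraint (voxels in the window ``(D1, D2)``
  penalized quadratically, where ``D2`` is the current dose level whose
  hot volume equals the prescribed ``V1``);
* gEUD model: linear overshoot of a prescribed generalized equivalent
  uniform dose;
* NTCP model: logarithmic convex overshoot of a prescribed LKB
  complication probability.

The step function ``H`` is strict everywhere (``H(0) = 0``): a constraint
met exactly incurs no penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import sparse
from scipy.stats import norm

from . import metrics

ConstraintType = Literal[
    "min_dose", "max_dose", "mean_dose", "dv_max", "dv_min", "geud", "ntcp", "tcp"
]
Model = Literal["dv", "geud", "ntcp"]

#: score cap applied when an LKB NTCP saturates numerically at 1
NTCP_SCORE_CAP = 1e6


class Constraint(BaseModel):
    """One prescription constraint on one structure.

    Which fields are required depends on ``type``:

    ``min_dose``/``max_dose``/``mean_dose``
        ``limit_gy`` — the prescribed dose (Gy).
    ``dv_max``/``dv_min``
        ``dose_gy`` (D1) and ``volume_pct`` (V1): at most (at least) V1 % of
        the structure may receive >= D1 Gy.
    ``geud``
        ``limit_gy`` (prescribed gEUD) and ``exponent_a``.
    ``ntcp``/``tcp``
        ``probability`` (prescribed NTCP/TCP); NTCP also takes the LKB
        parameters ``td50``, ``m``, ``n``.
    """

    model_config = ConfigDict(extra="forbid")

    structure: str
    type: ConstraintType
    limit_gy: Optional[float] = None
    dose_gy: Optional[float] = None
    volume_pct: Optional[float] = None
    exponent_a: Optional[float] = None
    probability: Optional[float] = None
    td50: Optional[float] = None
    m: Optional[float] = None
    n: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "Constraint":
        t = self.type
        if t in ("min_dose", "max_dose", "mean_dose"):
            if self.limit_gy is None or self.limit_gy <= 0:
                raise ValueError(f"{t} constraint requires limit_gy > 0")
        elif t in ("dv_max", "dv_min"):
            if self.dose_gy is None or self.dose_gy <= 0:
                raise ValueError(f"{t} constraint requires dose_gy > 0")
            if self.volume_pct is None or not (0 < self.volume_pct < 100):
                raise ValueError(f"{t} constraint requires volume_pct in (0, 100)")
        elif t == "geud":
            if self.limit_gy is None or self.limit_gy <= 0:
                raise ValueError("geud constraint requires limit_gy > 0")
            if self.exponent_a is None or self.exponent_a == 0:
                raise ValueError("geud constraint requires a nonzero exponent_a")
        elif t in ("ntcp", "tcp"):
            if self.probability is None or not (0 < self.probability < 1):
                raise ValueError(f"{t} constraint requires probability in (0, 1)")
            if t == "ntcp":
                if any(v is None or v <= 0 for v in (self.td50, self.m, self.n)):
                    raise ValueError("ntcp constraint requires positive td50, m, n")
        return self


@dataclass
class SubscoreSpec:
    """A constraint bound into the objective at position ``index``."""

    constraint: Constraint
    role_in_objective: Literal["ptv_coverage", "oar_sparing"]
    index: int


@dataclass
class ObjectiveSpec:
    model: Model
    subscores: List[SubscoreSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subscores)


def normalize_weights(w: Sequence[float]) -> np.ndarray:
    """Normalize importance factors to sum to one, keeping each in (0, 1)."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("importance factors must be strictly positive")
    return w / w.sum()


def uniform_weights(l: int) -> np.ndarray:
    return np.full(l, 1.0 / l)


# ---------------------------------------------------------------------------
# subscores on a structure dose vector (strict step convention H(0) = 0)


def f_min(d: np.ndarray, d_min: float) -> float:
    """Mean squared underdose below ``d_min`` (PTV coverage penalty)."""
    d = np.asarray(d, dtype=float)
    under = np.maximum(d_min - d, 0.0)
    under[d_min - d <= 0] = 0.0
    return float(np.mean(under**2))


def grad_f_min(d: np.ndarray, d_min: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    g = np.where(d_min - d > 0, -2.0 * (d_min - d), 0.0)
    return g / d.size


def f_mean(d: np.ndarray, d_mean: float) -> float:
    """Mean squared deviation from the prescribed mean dose."""
    d = np.asarray(d, dtype=float)
    return float(np.mean((d - d_mean) ** 2))


def grad_f_mean(d: np.ndarray, d_mean: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    return 2.0 * (d - d_mean) / d.size


def compute_d2(d: np.ndarray, v1_pct: float) -> float:
    """Dose level whose hot volume in the current plan equals ``v1_pct`` %.

    Descending-rank convention: the dose of rank ``ceil(N * V1 / 100)``.
    """
    if not (0.0 < v1_pct <= 100.0):
        raise ValueError("v1_pct must lie in (0, 100]")
    d = np.sort(np.asarray(d, dtype=float))[::-1]
    rank = int(np.ceil(d.size * v1_pct / 100.0))
    return float(d[rank - 1])


def f_dvmax(d: np.ndarray, d1: float, d2: float) -> float:
    """Convex surrogate of a maximum dose-volume constraint.

    Penalizes voxels strictly inside ``(d1, d2)`` by their squared excess
    over ``d1``; when the constraint is already met (``d2 <= d1``) the
    window is empty and the score is zero.
    """
    d = np.asarray(d, dtype=float)
    active = (d - d1 > 0) & (d2 - d > 0)
    return float(np.sum((d[active] - d1) ** 2) / d.size)


def grad_f_dvmax(d: np.ndarray, d1: float, d2: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    active = (d - d1 > 0) & (d2 - d > 0)
    g = np.zeros_like(d)
    g[active] = 2.0 * (d[active] - d1)
    return g / d.size


def f_dvmin(d: np.ndarray, d1: float, d2: float) -> float:
    """Cold-volume counterpart of :func:`f_dvmax` (experimental).

    Penalizes voxels strictly inside ``(d2, d1)`` by their squared deficit
    below ``d1``.
    """
    d = np.asarray(d, dtype=float)
    active = (d1 - d > 0) & (d - d2 > 0)
    return float(np.sum((d[active] - d1) ** 2) / d.size)


def grad_f_dvmin(d: np.ndarray, d1: float, d2: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    active = (d1 - d > 0) & (d - d2 > 0)
    g = np.zeros_like(d)
    g[active] = 2.0 * (d[active] - d1)
    return g / d.size


def _geud_and_grad(d: np.ndarray, a: float) -> tuple[float, np.ndarray]:
    d = np.asarray(d, dtype=float)
    top = d.max()
    if top <= 0:
        return 0.0, np.zeros_like(d)
    s = d / top
    mean_pow = np.mean(s**a)
    g = top * mean_pow ** (1.0 / a)
    # d gEUD / d D_i = (1/N) (D_i / gEUD)^(a-1)
    with np.errstate(divide="ignore"):
        grad = (d / g) ** (a - 1.0) / d.size
    grad[~np.isfinite(grad)] = 0.0
    return float(g), grad


def f_geud(d: np.ndarray, geud_pre: float, a: float) -> float:
    """Linear overshoot of a prescribed gEUD (OAR form, a >= 1)."""
    g = metrics.geud(d, np.ones(np.asarray(d).size, dtype=bool), a)
    return float(max(g - geud_pre, 0.0))


def grad_f_geud(d: np.ndarray, geud_pre: float, a: float) -> np.ndarray:
    g, dg = _geud_and_grad(np.asarray(d, dtype=float), a)
    if g - geud_pre > 0:
        return dg
    return np.zeros(np.asarray(d).size)


def _ntcp_and_grad(
    d: np.ndarray, td50: float, m: float, n: float
) -> tuple[float, np.ndarray]:
    a = 1.0 / n
    g, dg = _geud_and_grad(np.asarray(d, dtype=float), a)
    t = (g - td50) / (m * td50)
    p = float(norm.cdf(t))
    dp = norm.pdf(t) / (m * td50) * dg
    return p, dp


def f_ntcp(d: np.ndarray, ntcp_pre: float, td50: float, m: float, n: float) -> float:
    """Logarithmic convex overshoot of a prescribed LKB NTCP.

    score = max(ln(1 - NTCP_pre) - ln(1 - NTCP_LKB(D)), 0); capped at
    :data:`NTCP_SCORE_CAP` if the NTCP saturates numerically at 1.
    """
    mask = np.ones(np.asarray(d).size, dtype=bool)
    p = metrics.ntcp_lkb(d, mask, td50, m, n)
    if p >= 1.0 - 1e-15:
        warnings.warn("NTCP numerically 1; subscore capped", stacklevel=2)
        return NTCP_SCORE_CAP
    return float(max(np.log(1.0 - ntcp_pre) - np.log(1.0 - p), 0.0))


def grad_f_ntcp(
    d: np.ndarray, ntcp_pre: float, td50: float, m: float, n: float
) -> np.ndarray:
    p, dp = _ntcp_and_grad(np.asarray(d, dtype=float), td50, m, n)
    if p >= 1.0 - 1e-15 or p <= ntcp_pre:
        return np.zeros(np.asarray(d).size)
    return dp / (1.0 - p)


def total_objective(subscores: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted sum ``sum_i w_i f_i``."""
    f = np.asarray(subscores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.shape != w.shape:
        raise ValueError("subscore and weight vectors must have equal length")
    return float(f @ w)


# ---------------------------------------------------------------------------
# objective assembly


def build_objective_spec(constraints: Sequence[Constraint], model: Model) -> ObjectiveSpec:
    """Select and order the subscores of the chosen objective model.

    Every model carries the PTV minimum-dose and mean-dose subscores first,
    followed by one subscore per matching OAR/normal-tissue constraint:
    ``dv_max``/``dv_min`` for the dose-volume model, ``geud`` for the gEUD
    model and ``ntcp`` for the NTCP model.
    """
    ptv_min = [c for c in constraints if c.type == "min_dose"]
    ptv_mean = [c for c in constraints if c.type == "mean_dose"]
    if len(ptv_min) != 1 or len(ptv_mean) != 1:
        raise ValueError("prescription needs exactly one min_dose and one mean_dose constraint")
    wanted: Dict[Model, tuple] = {
        "dv": ("dv_max", "dv_min"),
        "geud": ("geud",),
        "ntcp": ("ntcp",),
    }
    subs: List[SubscoreSpec] = [
        SubscoreSpec(ptv_min[0], "ptv_coverage", 0),
        SubscoreSpec(ptv_mean[0], "ptv_coverage", 1),
    ]
    for c in constraints:
        if c.type in wanted[model]:
            subs.append(SubscoreSpec(c, "oar_sparing", len(subs)))
    if len(subs) < 3:
        raise ValueError(f"prescription has no constraints for the '{model}' model")
    return ObjectiveSpec(model=model, subscores=subs)


@dataclass
class FrozenDV:
    """Per-solve state of one dose-volume surrogate.

    ``d2`` is the current-plan dose level whose hot volume equals the
    prescribed ``V1``; ``active`` flags the structure voxels strictly inside
    the penalty window at the reference plan.  Freezing the window (level
    and membership) for the duration of an inner solve is what makes the
    surrogate differentiable: the voxel that defines ``d2`` sits exactly on
    the window edge, so re-sorting inside a solve would make the objective
    discontinuous there.
    """

    d2: float
    active: np.ndarray


class ObjectiveFunction:
    """Binds an :class:`ObjectiveSpec` to structure masks and an influence matrix.

    The dose-volume surrogate windows are frozen per inner solve: call
    :meth:`refresh_d2` with the current dose at the start of a solve, then
    pass the returned mapping to :meth:`value_and_grad_u`.
    """

    def __init__(self, spec: ObjectiveSpec, masks: Dict[str, np.ndarray], A: sparse.spmatrix):
        self.spec = spec
        self.A = A.tocsr()
        self.indices: List[np.ndarray] = []
        for ss in spec.subscores:
            mask = np.asarray(masks[ss.constraint.structure], dtype=bool).ravel()
            if not mask.any():
                raise ValueError(f"structure '{ss.constraint.structure}' has an empty mask")
            self.indices.append(np.flatnonzero(mask))

    def refresh_d2(self, dose: np.ndarray) -> Dict[int, FrozenDV]:
        """Current-plan D2 level and active window for every dose-volume subscore."""
        d2s: Dict[int, FrozenDV] = {}
        for ss, idx in zip(self.spec.subscores, self.indices):
            c = ss.constraint
            if c.type not in ("dv_max", "dv_min"):
                continue
            d = dose[idx]
            d2 = compute_d2(d, c.volume_pct)
            if c.type == "dv_max":
                active = (d - c.dose_gy > 0) & (d2 - d > 0)
            else:
                active = (c.dose_gy - d > 0) & (d - d2 > 0)
            d2s[ss.index] = FrozenDV(d2=d2, active=active)
        return d2s

    def subscore_values(self, dose: np.ndarray, d2s: Dict[int, FrozenDV]) -> np.ndarray:
        vals = np.empty(len(self.spec.subscores))
        for k, (ss, idx) in enumerate(zip(self.spec.subscores, self.indices)):
            c = ss.constraint
            d = dose[idx]
            if c.type == "min_dose":
                vals[k] = f_min(d, c.limit_gy)
            elif c.type == "mean_dose":
                vals[k] = f_mean(d, c.limit_gy)
            elif c.type == "max_dose":
                vals[k] = f_min(-d, -c.limit_gy)  # squared overdose via reflection
            elif c.type == "dv_max":
                st = d2s[ss.index]
                excess = np.maximum(d[st.active] - c.dose_gy, 0.0)
                vals[k] = float(np.sum(excess**2) / d.size)
            elif c.type == "dv_min":
                st = d2s[ss.index]
                deficit = np.maximum(c.dose_gy - d[st.active], 0.0)
                vals[k] = float(np.sum(deficit**2) / d.size)
            elif c.type == "geud":
                vals[k] = f_geud(d, c.limit_gy, c.exponent_a)
            elif c.type == "ntcp":
                vals[k] = f_ntcp(d, c.probability, c.td50, c.m, c.n)
            else:
                raise NotImplementedError(f"no subscore shipped for constraint type '{c.type}'")
        return vals

    def _dose_gradient(self, dose: np.ndarray, weights: np.ndarray, d2s: Dict[int, FrozenDV]) -> np.ndarray:
        g_dose = np.zeros(dose.size)
        for ss, idx, w in zip(self.spec.subscores, self.indices, weights):
            c = ss.constraint
            d = dose[idx]
            if c.type == "min_dose":
                g = grad_f_min(d, c.limit_gy)
            elif c.type == "mean_dose":
                g = grad_f_mean(d, c.limit_gy)
            elif c.type == "max_dose":
                g = -grad_f_min(-d, -c.limit_gy)
            elif c.type == "dv_max":
                st = d2s[ss.index]
                g = np.zeros_like(d)
                g[st.active] = 2.0 * np.maximum(d[st.active] - c.dose_gy, 0.0) / d.size
            elif c.type == "dv_min":
                st = d2s[ss.index]
                g = np.zeros_like(d)
                g[st.active] = -2.0 * np.maximum(c.dose_gy - d[st.active], 0.0) / d.size
            elif c.type == "geud":
                g = grad_f_geud(d, c.limit_gy, c.exponent_a)
            elif c.type == "ntcp":
                g = grad_f_ntcp(d, c.probability, c.td50, c.m, c.n)
            else:
                raise NotImplementedError(c.type)
            g_dose[idx] += w * g
        return g_dose

    def value_and_grad_u(
        self, u: np.ndarray, weights: np.ndarray, d2s: Dict[int, FrozenDV]
    ) -> tuple[float, np.ndarray]:
        """Objective and gradient in the square-root beamlet parameterization.

        With x = u^2 elementwise and D = A x, the chain rule gives
        d f / d u_j = 2 u_j (A^T d f / d D)_j.
        """
        x = u**2
        dose = np.asarray(self.A @ x).ravel()
        vals = self.subscore_values(dose, d2s)
        f = total_objective(vals, weights)
        g_dose = self._dose_gradient(dose, weights, d2s)
        grad_u = 2.0 * u * np.asarray(self.A.T @ g_dose).ravel()
        return f, grad_u
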
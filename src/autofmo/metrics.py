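"""Plan-quality metrics: DVH, dose statistics, CI, HI, gEUD, LKB NTCP.

All metrics are computed exactly on voxels — no histogram binning and no
interpolation.  Volume queries use the closed convention ``V(d) = %
voxels with dose >= d``; dose-at-volume uses descending ranks, so
``D_x%`` is the dose of rank ``ceil(N * x / 100)`` when doses are sorted
from hottest to coldest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``volume_pct[k]`` is the percentage of structure voxels receiving at
    least ``dose_gy[k]``.
    """

    structure: str
    dose_gy: np.ndarray
    volume_pct: np.ndarray


def structure_dose(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Doses of the voxels belonging to ``mask`` (flattened order)."""
    mask = np.asarray(mask, dtype=bool).ravel()
    if not mask.any():
        raise ValueError("structure mask is empty")
    return np.asarray(dose, dtype=float).ravel()[mask]


def volume_at_dose(dose: np.ndarray, mask: np.ndarray, d: float) -> float:
    """V(d): percent of structure voxels with dose >= d."""
    sd = structure_dose(dose, mask)
    return 100.0 * np.count_nonzero(sd >= d) / sd.size


def dvh(dose: np.ndarray, mask: np.ndarray, structure: str = "", n_points: int = 201) -> DVHCurve:
    """Cumulative DVH evaluated on an ascending dose grid spanning [0, max]."""
    sd = structure_dose(dose, mask)
    top = max(float(sd.max()) * 1.02, 1e-9)
    grid = np.linspace(0.0, top, n_points)
    vol = 100.0 * (sd[None, :] >= grid[:, None]).mean(axis=1)
    return DVHCurve(structure=structure, dose_gy=grid, volume_pct=vol)


def dose_at_volume(dose: np.ndarray, mask: np.ndarray, x_pct: float) -> float:
    """D_x%: largest dose d with V(d) >= x_pct (descending-rank convention)."""
    if not (0.0 < x_pct <= 100.0):
        raise ValueError("x_pct must lie in (0, 100]")
    sd = np.sort(structure_dose(dose, mask))[::-1]
    rank = int(np.ceil(sd.size * x_pct / 100.0))
    return float(sd[rank - 1])


def conformity_index(
    dose: np.ndarray, ptv_mask: np.ndarray, body_mask: np.ndarray, ref_dose: float
) -> float:
    """CI = (V_t,ref / V_t) * (V_t,ref / V_ref).

    ``V_t`` is the PTV volume, ``V_t,ref`` the PTV volume at/above the
    reference dose and ``V_ref`` the body volume at/above it.  CI = 1 means
    the reference isodose coincides with the PTV.
    """
    if ref_dose <= 0:
        raise ValueError("ref_dose must be positive")
    ptv = structure_dose(dose, ptv_mask)
    body = structure_dose(dose, body_mask)
    v_t = ptv.size
    v_t_ref = int(np.count_nonzero(ptv >= ref_dose))
    v_ref = int(np.count_nonzero(body >= ref_dose))
    if v_ref == 0:
        warnings.warn("no voxel reaches the reference dose; CI set to 0", stacklevel=2)
        return 0.0
    return (v_t_ref / v_t) * (v_t_ref / v_ref)


def homogeneity_index(dose: np.ndarray, ptv_mask: np.ndarray) -> float:
    """HI = D_5% / D_95% over the PTV; 1 for a perfectly uniform dose."""
    sd = structure_dose(dose, ptv_mask)
    if sd.size < 20:
        raise ValueError("PTV must contain at least 20 voxels for D_5%")
    d95 = dose_at_volume(dose, ptv_mask, 95.0)
    if d95 <= 0:
        raise ValueError("D_95% is zero: PTV is unirradiated")
    return dose_at_volume(dose, ptv_mask, 5.0) / d95


def geud(dose: np.ndarray, mask: np.ndarray, a: float) -> float:
    """Generalized equivalent uniform dose, the power mean of exponent ``a``.

    gEUD = ((1/N) sum D_i^a)^(1/a).  a = 1 gives the mean dose; large a
    approaches the maximum; a < 0 (used for targets) requires strictly
    positive doses.
    """
    if a == 0:
        raise ValueError("gEUD exponent a must be nonzero")
    sd = structure_dose(dose, mask)
    if np.any(sd < 0):
        raise ValueError("doses must be nonnegative")
    if a < 0 and np.any(sd == 0):
        raise ValueError("gEUD with a < 0 is undefined for zero doses")
    # compute in a scaled frame for numerical stability at large |a|
    top = sd.max()
    if top == 0:
        return 0.0
    return float(top * np.mean((sd / top) ** a) ** (1.0 / a))


def ntcp_lkb(
    dose: np.ndarray, mask: np.ndarray, td50: float, m: float, n: float
) -> float:
    """Lyman-Kutcher-Burman NTCP.

    NTCP = Phi(t), t = (gEUD_a - TD50) / (m * TD50) with volume-effect
    exponent a = 1/n and Phi the standard normal CDF.
    """
    if td50 <= 0 or m <= 0 or n <= 0:
        raise ValueError("LKB parameters TD50, m, n must be positive")
    g = geud(dose, mask, a=1.0 / n)
    t = (g - td50) / (m * td50)
    return float(norm.cdf(t))


def plan_metrics_row(
    dose: np.ndarray,
    mask: np.ndarray,
    structure: str,
) -> dict:
    """Basic dose statistics of one structure as a flat record."""
    sd = structure_dose(dose, mask)
    return {
        "structure": structure,
        "n_voxels": int(sd.size),
        "d_min": float(sd.min()),
        "d_mean": float(sd.mean()),
        "d_max": float(sd.max()),
    }
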
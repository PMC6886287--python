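"""Beamlet dose-influence matrix and the linear dose model.

The influence matrix ``A`` maps beamlet weights ``x`` (arbitrary fluence
units) to voxel doses ``D = A x`` (Gy).  Each column is the dose footprint
of one parallel-ray beamlet: exponential attenuation with radiological
depth along the beam axis times a Gaussian lateral penumbra.  This is a
deliberately simple analytic kernel — adequate for exercising plan
optimization, not a clinical dose engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import sparse

from .phantom import BeamSpec, Phantom


@dataclass
class KernelConfig:
    """Analytic pencil-kernel parameters.

    mu_attenuation : linear attenuation coefficient, per mm.
    sigma_penumbra : lateral Gaussian falloff, mm.
    floor : entries below ``floor``  × (column max) are dropped for sparsity.
    """

    mu_attenuation: float = 0.005
    sigma_penumbra: float = 3.0
    floor: float = 1e-4

    def validate(self) -> None:
        if self.mu_attenuation <= 0 or self.sigma_penumbra <= 0:
            raise ValueError("kernel parameters must be positive")
        if not (0 <= self.floor < 1):
            raise ValueError("floor must lie in [0, 1)")


@dataclass
class InfluenceMatrix:
    """Sparse n_voxels × n_beamlets dose-deposition matrix (Gy per unit weight)."""

    entries: sparse.csr_matrix
    beamlet_index: List[Tuple[float, float]]  # (gantry angle deg, lateral offset mm)
    grid_shape: Tuple[int, int]

    @property
    def n_voxels(self) -> int:
        return self.entries.shape[0]

    @property
    def n_beamlets(self) -> int:
        return self.entries.shape[1]

    def save(self, matrix_path: str, sidecar_path: str) -> None:
        """Persist as text COO triplets plus a JSON sidecar with index maps."""
        coo = self.entries.tocoo()
        np.savetxt(
            matrix_path,
            np.column_stack([coo.row, coo.col, coo.data]),
            fmt=["%d", "%d", "%.17g"],
            header="row,col,value",
            comments="",
            delimiter=",",
        )
        sidecar = {
            "grid_shape": list(self.grid_shape),
            "n_voxels": self.n_voxels,
            "n_beamlets": self.n_beamlets,
            "beamlet_index": [[a, o] for a, o in self.beamlet_index],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, matrix_path: str, sidecar_path: str) -> "InfluenceMatrix":
        with open(sidecar_path) as fh:
            sc = json.load(fh)
        trip = np.loadtxt(matrix_path, delimiter=",", skiprows=1, ndmin=2)
        mat = sparse.csr_matrix(
            (trip[:, 2], (trip[:, 0].astype(int), trip[:, 1].astype(int))),
            shape=(sc["n_voxels"], sc["n_beamlets"]),
        )
        return cls(
            entries=mat,
            beamlet_index=[(a, o) for a, o in sc["beamlet_index"]],
            grid_shape=tuple(sc["grid_shape"]),
        )


def _depth_map(phantom: Phantom, direction: np.ndarray, step: float) -> np.ndarray:
    """Radiological depth (mm) of every voxel, marching back toward the source.

    Depth is the path length inside the body contour from the beam entry
    point to the voxel; voxels outside the body get depth 0 (they receive no
    dose anyway — the caller masks them out).
    """
    rows, cols = phantom.grid_shape
    centers = phantom.voxel_centers_mm()
    body = phantom.body_mask
    # max chord length through the grid
    extent = float(np.hypot(rows, cols)) * phantom.voxel_size
    n_steps = int(np.ceil(extent / step))
    taus = (np.arange(n_steps) + 0.5) * step
    # sample points: voxel center minus tau * direction (toward the source)
    half_w = cols * phantom.voxel_size / 2.0
    half_h = rows * phantom.voxel_size / 2.0
    depth = np.zeros(centers.shape[0])
    for tau in taus:
        pts = centers - tau * direction
        j = np.floor((pts[:, 0] + half_w) / phantom.voxel_size).astype(int)
        i = np.floor((half_h - pts[:, 1]) / phantom.voxel_size).astype(int)
        ok = (i >= 0) & (i < rows) & (j >= 0) & (j < cols)
        inside = np.zeros(centers.shape[0], dtype=bool)
        inside[ok] = body[i[ok], j[ok]]
        depth += inside * step
    return depth


def compute_influence_matrix(
    phantom: Phantom,
    beams: BeamSpec,
    kernel: KernelConfig | None = None,
) -> InfluenceMatrix:
    """Build the dose-influence matrix for a phantom and beam layout.

    Per beamlet: a parallel ray through the body; deposited dose is
    ``exp(-mu * depth)`` along the ray times a Gaussian lateral falloff
    ``exp(-l^2 / (2 sigma^2))``.  Entries below ``kernel.floor`` of the
    beamlet's maximum are dropped.
    """
    kernel = kernel or KernelConfig()
    kernel.validate()
    if not beams.gantry_angles_deg:
        raise ValueError("beam angle set is empty")

    centers = phantom.voxel_centers_mm()
    body_flat = phantom.body_mask.ravel()
    offsets = beams.beamlet_offsets()
    sigma = kernel.sigma_penumbra
    # lateral reach implied by the sparsity floor
    reach = sigma * np.sqrt(-2.0 * np.log(kernel.floor)) if kernel.floor > 0 else np.inf

    cols_data: List[sparse.csc_matrix] = []
    beamlet_index: List[Tuple[float, float]] = []
    n_vox = centers.shape[0]

    for angle in beams.gantry_angles_deg:
        th = np.deg2rad(angle)
        source_dir = np.array([np.sin(th), np.cos(th)])  # unit vector toward the source
        direction = -source_dir  # beam travel direction
        lateral = np.array([np.cos(th), -np.sin(th)])
        depth = _depth_map(phantom, direction, step=phantom.voxel_size / 2.0)
        axial = np.exp(-kernel.mu_attenuation * depth)
        lat_coord = centers @ lateral
        for off in offsets:
            l = lat_coord - off
            sel = body_flat & (np.abs(l) <= reach + phantom.voxel_size)
            vals = axial[sel] * np.exp(-(l[sel] ** 2) / (2.0 * sigma**2))
            if vals.size:
                vmax = vals.max()
                keep = vals >= kernel.floor * vmax
                rows_idx = np.flatnonzero(sel)[keep]
                vals = vals[keep]
            else:
                rows_idx = np.empty(0, dtype=int)
            col = sparse.csc_matrix(
                (vals, (rows_idx, np.zeros(len(rows_idx), dtype=int))), shape=(n_vox, 1)
            )
            cols_data.append(col)
            beamlet_index.append((float(angle), float(off)))

    A = sparse.hstack(cols_data, format="csr")
    return InfluenceMatrix(entries=A, beamlet_index=beamlet_index, grid_shape=phantom.grid_shape)


def compute_dose(A: InfluenceMatrix | sparse.spmatrix, x: np.ndarray) -> np.ndarray:
    """Voxel dose vector ``A @ x`` for nonnegative beamlet weights ``x``."""
    mat = A.entries if isinstance(A, InfluenceMatrix) else A
    x = np.asarray(x, dtype=float)
    if x.shape[0] != mat.shape[1]:
        raise ValueError(f"weight vector length {x.shape[0]} != n_beamlets {mat.shape[1]}")
    if np.any(x < 0):
        raise ValueError("beamlet weights must be nonnegative")
    return np.asarray(mat @ x).ravel()
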
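"""High-level run orchestration: config in, automatic plan out."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .autoplan import AutoPlanResult, run_automatic
from .config import RunConfig
from .dose import InfluenceMatrix, compute_influence_matrix
from .phantom import Phantom, generate_phantom


def build_case(cfg: RunConfig) -> Tuple[Phantom, InfluenceMatrix]:
    """Materialize the phantom and its dose-influence matrix."""
    phantom = generate_phantom(cfg.resolved_phantom_spec())
    A = compute_influence_matrix(phantom, cfg.beams, cfg.kernel.to_kernel_config())
    return phantom, A


def run_from_config(
    cfg: RunConfig,
    initial_weights: Optional[np.ndarray] = None,
) -> Tuple[AutoPlanResult, Phantom, InfluenceMatrix]:
    """Execute the automatic planning loop described by a :class:`RunConfig`."""
    phantom, A = build_case(cfg)
    result = run_automatic(
        phantom,
        A,
        cfg.resolved_prescription(),
        model=cfg.model,
        loop=cfg.loop,
        solver=cfg.solver.to_solver_config(),
        initial_weights=initial_weights,
        push_coverage=cfg.push_coverage,
    )
    return result, phantom, A
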
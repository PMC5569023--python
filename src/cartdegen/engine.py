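"""Iterative overload-driven collagen-fibril degeneration algorithm.

Each simulated gait cycle (iteration) yields, per element, a tensile
stress history S_t over the stance phase.  Wherever the local tensile
stress exceeds the collagen failure threshold T (default 7 MPa) the
element accrues a per-increment degeneration factor

    D_t = ((S_t - T) / T) / 100     for S_t > T
    D_t = 0                         for S_t <= T,

clamped to at most 1 (fully degenerated collagen).  The element's
degeneration level D, which multiplies the fibril network stiffness, then
evolves as a duration-weighted update

    D_i = D_{i-1} - D_{i-1} * (sum_t D_t * INC_t)^(1/1.5)   for i > 1
    D_1 = 1  (intact),

where INC_t is the increment duration (s).  D is clamped to [0, 1]; it is
non-increasing across iterations, and tissue never loaded above T is a
fixed point.  Outcome metrics report degeneration as 1 - D so that they
grow with severity: the per-region maximum of 1 - D, and the summed
volume of elements with any degeneration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import CartilageMesh
from .results import SubjectResult


@dataclass
class DegenerationConfig:
    """Algorithm settings.

    ``threshold_T``: collagen failure tensile stress (MPa).
    ``n_iterations``: gait cycles simulated, counting the intact state as
    iteration 1 (so ``n_iterations - 1`` degeneration updates occur).
    ``root_exponent``: the weighted stress-excess sum enters the update
    through its ``1/root_exponent`` power.
    ``degenerated_epsilon``: an element counts toward degenerated volume
    when 1 - D exceeds this.
    """

    threshold_T: float = 7.0
    n_iterations: int = 100
    root_exponent: float = 1.5
    degenerated_epsilon: float = 1e-9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_T <= 0.0:
            raise ValueError("threshold_T must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.root_exponent <= 0.0:
            raise ValueError("root_exponent must be positive")
        if self.degenerated_epsilon < 0.0:
            raise ValueError("degenerated_epsilon must be non-negative")


def degeneration_factor(S_t, T: float):
    """Per-increment degeneration factor: ((S_t - T)/T)/100 above the
    failure threshold (strict), 0 at or below it; clamped to [0, 1].

    Accepts a scalar or array of non-negative tensile stresses (MPa).
    """
    if T <= 0.0:
        raise ValueError("threshold T must be positive")
    S = np.asarray(S_t, dtype=float)
    if np.any(S < 0.0):
        raise ValueError("tensile stress must be non-negative")
    out = np.where(S > T, ((S - T) / T) / 100.0, 0.0)
    out = np.minimum(out, 1.0)
    if np.isscalar(S_t) or np.ndim(S_t) == 0:
        return float(out)
    return out


def update_element(D_prev: float, factors, durations, root_exponent: float = 1.5) -> float:
    """One degeneration update: D_new = D_prev * (1 - W^(1/root_exponent))
    with W = sum_t D_t * INC_t, clamped to [0, 1].  W = 0 returns D_prev
    exactly (subthreshold fixed point)."""
    f = np.asarray(factors, dtype=float)
    inc = np.asarray(durations, dtype=float)
    if f.shape != inc.shape:
        raise ValueError("factors and durations must have equal length")
    if np.any((f < 0.0) | (f > 1.0)):
        raise ValueError("factors must lie in [0, 1]")
    if np.any(inc <= 0.0):
        raise ValueError("durations must be positive")
    W = float(np.dot(f, inc))
    if W == 0.0:
        return D_prev
    decay = 1.0 - W ** (1.0 / root_exponent)
    return float(min(max(D_prev * decay, 0.0), 1.0))


@dataclass
class DegenerationState:
    """Per-element degeneration levels with optional full trajectory.

    ``trajectory`` has shape (n_iterations, n_elements); row i-1 holds the
    levels at iteration i (row 0 is the intact state, all ones).
    """

    element_ids: list[int]
    D: np.ndarray
    iteration: int
    trajectory: np.ndarray | None = None

    def as_mapping(self) -> dict[int, float]:
        return {eid: float(d) for eid, d in zip(self.element_ids, self.D)}


def _region_mask(mesh: CartilageMesh, region: str) -> np.ndarray:
    mask = np.array([e.region == region for e in mesh.elements])
    if not mask.any():
        raise ValueError(f"mesh has no elements in region {region!r}")
    return mask


def max_degeneration(state: DegenerationState, mesh: CartilageMesh, region: str) -> float:
    """Maximum over the region's elements of reported degeneration 1 - D."""
    mask = _region_mask(mesh, region)
    return float(np.max(1.0 - state.D[mask]))


def degenerated_volume(
    state: DegenerationState,
    mesh: CartilageMesh,
    region: str,
    epsilon: float = 1e-9,
) -> float:
    """Summed volume (mm^3) of region elements with 1 - D > epsilon."""
    if epsilon < 0.0:
        raise ValueError("epsilon must be non-negative")
    mask = _region_mask(mesh, region)
    volumes = np.array([e.volume for e in mesh.elements])
    degen = (1.0 - state.D) > epsilon
    return float(volumes[mask & degen].sum())


def run_subject(
    mesh: CartilageMesh,
    loading,
    params_by_region,
    config: DegenerationConfig,
    subject_id: str = "subject",
    group_label: str = "KL0",
) -> tuple[DegenerationState, SubjectResult]:
    """Simulate one subject for ``config.n_iterations`` gait cycles.

    Every iteration queries the loading model at the current degeneration
    levels, converts stress histories to per-increment factors and applies
    the weighted update per element.  Returns the final state (with full
    trajectory) and the endpoint metrics.
    """
    ids = mesh.element_ids()
    payload = getattr(loading, "histories", None) or getattr(loading, "strains", None)
    if payload is not None:
        missing = [eid for eid in ids if eid not in payload]
        if missing:
            raise ValueError(f"loading model missing elements: {missing[:5]}")
    n = len(ids)
    D = np.ones(n)
    traj = np.empty((config.n_iterations, n))
    traj[0] = D

    inv_root = 1.0 / config.root_exponent
    for i in range(1, config.n_iterations):
        d_map = {eid: float(d) for eid, d in zip(ids, D)}
        S = loading.stress_matrix(mesh, d_map, params_by_region)  # (n, n_inc)
        factors = degeneration_factor(S, config.threshold_T)
        W = factors @ loading.durations
        decay = np.where(W > 0.0, 1.0 - np.power(W, inv_root), 1.0)
        D = np.clip(D * decay, 0.0, 1.0)
        traj[i] = D

    state = DegenerationState(
        element_ids=ids, D=D, iteration=config.n_iterations, trajectory=traj
    )
    eps = config.degenerated_epsilon
    regions = mesh.regions()
    result = SubjectResult(
        subject_id=subject_id,
        group_label=group_label,
        max_degeneration_femoral=(
            max_degeneration(state, mesh, "femoral") if "femoral" in regions else 0.0
        ),
        max_degeneration_tibial=(
            max_degeneration(state, mesh, "tibial") if "tibial" in regions else 0.0
        ),
        degenerated_volume_femoral=(
            degenerated_volume(state, mesh, "femoral", eps) if "femoral" in regions else 0.0
        ),
        degenerated_volume_tibial=(
            degenerated_volume(state, mesh, "tibial", eps) if "tibial" in regions else 0.0
        ),
    )
    for region in regions:
        assert degenerated_volume(state, mesh, region, eps) <= mesh.total_volume(region) + 1e-9
    return state, result
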
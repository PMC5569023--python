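"""Synthetic KL-graded subject cohorts for end-to-end experiments.

Generates cohorts of simulated subjects in three radiographic severity
groups (KL0 radiographically intact, KL2 and KL3 osteoarthritic), each
subject consisting of a two-region grid cartilage mesh (femoral and
tibial patches) and a static contact-patch gait loading.  The stress
field is a 2-D Gaussian contact bump over the element grid multiplied by
a double-peaked stance waveform; group severity is encoded through both
the peak stress amplitude and the contact-patch size, so that KL0 peak
stresses stay mostly below the 7 MPa collagen failure threshold while
KL2/KL3 exceed it over progressively larger areas.  Subject-level
variability is multiplicative log-normal noise on the amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import DegenerationConfig, run_subject
from .loading import StaticFieldLoading, gait_waveform
from .materials import FEMORAL_CARTILAGE, TIBIAL_CARTILAGE
from .mesh import CartilageMesh, Element, FibrilSpec
from .results import SubjectResult

# element volumes (mm^3) for ~1 mm femoral and ~0.5 mm tibial hexahedra
_ELEM_VOLUME = {"femoral": 1.0, "tibial": 0.125}

DEFAULT_PARAMS = {"femoral": FEMORAL_CARTILAGE, "tibial": TIBIAL_CARTILAGE}


def _default_scales() -> dict[str, float]:
    # peak contact stress (MPa): KL0 below the 7 MPa failure threshold,
    # KL2/KL3 above it with the KL3 excess roughly twice the KL2 excess
    return {"KL0": 5.5, "KL2": 8.5, "KL3": 10.0}


def _default_patches() -> dict[str, float]:
    # Gaussian patch width (normalized half-extent units); larger contact
    # areas for higher severity groups
    return {"KL0": 0.10, "KL2": 0.22, "KL3": 0.38}


@dataclass
class CohortConfig:
    n_per_group: int = 7
    grid_dims: tuple[int, int] = (20, 20)
    load_scale_mean: dict[str, float] = field(default_factory=_default_scales)
    contact_patch_fraction: dict[str, float] = field(default_factory=_default_patches)
    noise_sd: float = 0.1
    seed: int = 0
    n_increments: int = 50
    stance_duration: float = 0.8

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.grid_dims[0] < 1 or self.grid_dims[1] < 1:
            raise ValueError("grid must contain at least one element")
        for g, s in self.load_scale_mean.items():
            if s <= 0.0:
                raise ValueError(f"load scale for {g} must be positive")
        for g, f in self.contact_patch_fraction.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"patch fraction for {g} must lie in (0, 1]")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")


def _grid_mesh(config: CohortConfig, name: str) -> CartilageMesh:
    nx, ny = config.grid_dims
    fibrils = lambda: [  # noqa: E731 - tiny local factory
        FibrilSpec(direction=np.array([1.0, 0.0, 0.0]), is_primary=True),
        FibrilSpec(direction=np.array([0.0, 0.0, 1.0]), is_primary=False),
    ]
    elements = []
    eid = 0
    for region in ("femoral", "tibial"):
        for _ in range(nx * ny):
            elements.append(
                Element(
                    id=eid,
                    volume=_ELEM_VOLUME[region],
                    depth_z=0.25,
                    region=region,
                    fibrils=fibrils(),
                )
            )
            eid += 1
    return CartilageMesh(
        elements=elements, name=name, stance_duration=config.stance_duration
    )


def _contact_patch(config: CohortConfig, width: float) -> np.ndarray:
    """Gaussian contact bump over the element grid, flattened row-major;
    normalized grid coordinates span [-1, 1] with the patch at centre."""
    nx, ny = config.grid_dims
    x = np.linspace(-1.0, 1.0, nx) if nx > 1 else np.zeros(1)
    y = np.linspace(-1.0, 1.0, ny) if ny > 1 else np.zeros(1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    return np.exp(-(X**2 + Y**2) / (2.0 * width**2)).ravel()


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[str, str, CartilageMesh, StaticFieldLoading]]:
    """Deterministically generate one synthetic cohort.

    Returns a list of (subject_id, group_label, mesh, loading) in group
    order KL0, KL2, KL3; identical config (including seed) reproduces the
    cohort bit-exactly.
    """
    rng = np.random.default_rng(config.seed)
    durations, waveform = gait_waveform(
        config.n_increments, config.stance_duration
    )
    nx, ny = config.grid_dims
    n_grid = nx * ny
    subjects = []
    for group in ("KL0", "KL2", "KL3"):
        patch = _contact_patch(config, config.contact_patch_fraction[group])
        for k in range(config.n_per_group):
            sid = f"{group}_{k:02d}"
            noise = float(np.exp(rng.normal(0.0, config.noise_sd))) if config.noise_sd > 0 else 1.0
            amp = config.load_scale_mean[group] * noise
            mesh = _grid_mesh(config, name=sid)
            histories = {}
            for e in mesh.elements:
                grid_idx = e.id % n_grid
                histories[e.id] = amp * patch[grid_idx] * waveform
            loading = StaticFieldLoading(histories, durations)
            subjects.append((sid, group, mesh, loading))
    return subjects


def run_cohort(
    cohort,
    params_by_region=None,
    config: DegenerationConfig | None = None,
) -> list[SubjectResult]:
    """Run the degeneration simulation for every subject of a cohort,
    preserving input order and group labels."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    params_by_region = params_by_region or DEFAULT_PARAMS
    config = config or DegenerationConfig()
    results = []
    for sid, group, mesh, loading in cohort:
        _, res = run_subject(
            mesh, loading, params_by_region, config,
            subject_id=sid, group_label=group,
        )
        results.append(res)
    return results
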
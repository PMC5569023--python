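"""Gait-loading surrogates: providers of per-element stress histories.

The degeneration algorithm needs, for every element and every gait cycle,
the tensile-stress history over the stance phase.  In a full
musculoskeletal pipeline these come from a finite-element contact
simulation; here they are supplied by pluggable surrogate models:

``StaticFieldLoading``
    Prescribed stress histories, scaled by a body-weight factor and
    independent of the tissue state (load control: the imposed stress
    stays as imposed while the tissue softens).

``StrainDrivenLoading``
    Prescribed fibril strain histories pushed through the viscoelastic
    fibril law; because the modulated fibril stress is proportional to the
    degeneration level D, softer tissue under fixed strain carries less
    stress (displacement control; degeneration is self-limiting).

The two regimes bracket the load-versus-displacement-control ambiguity of
replacing a contact solver with a surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .fibril import max_tensile_fibril_stress
from .materials import MaterialParams
from .mesh import CartilageMesh

_GRID_TOL = 1e-9


@dataclass
class GaitStressHistory:
    """Tensile-stress samples (MPa) for one element over one stance phase,
    with per-increment durations (s)."""

    element_id: int
    stresses_S_t: np.ndarray
    increment_durations_INC_t: np.ndarray

    def __post_init__(self) -> None:
        self.stresses_S_t = np.asarray(self.stresses_S_t, dtype=float)
        self.increment_durations_INC_t = np.asarray(
            self.increment_durations_INC_t, dtype=float
        )
        if self.stresses_S_t.shape != self.increment_durations_INC_t.shape:
            raise ValueError("stresses and durations must have equal length")
        if self.stresses_S_t.ndim != 1 or self.stresses_S_t.size == 0:
            raise ValueError("histories must be non-empty 1-D series")
        if np.any(self.stresses_S_t < 0.0):
            raise ValueError("tensile stresses must be non-negative")
        if np.any(self.increment_durations_INC_t <= 0.0):
            raise ValueError("increment durations must be positive")

    def check_stance(self, stance_duration: float) -> None:
        total = float(self.increment_durations_INC_t.sum())
        if abs(total - stance_duration) > _GRID_TOL:
            raise ValueError(
                f"element {self.element_id}: increments sum to {total}, "
                f"expected stance duration {stance_duration}"
            )


def gait_waveform(
    n_increments: int,
    stance_duration: float = 0.8,
    peak1: float = 1.0,
    peak2: float = 1.0,
    peak_times: tuple[float, float] = (0.25, 0.75),
    width: float = 0.12,
) -> tuple[np.ndarray, np.ndarray]:
    """Double-peaked stance-phase amplitude profile on a uniform grid.

    Models the two force maxima of walking (loading response and push-off)
    as Gaussian bumps at normalized ``peak_times``, each rescaled so its
    on-grid maximum equals the stated peak value; the profile takes the
    pointwise maximum of the two bumps so peak values are attained exactly.

    Returns ``(durations, amplitudes)``, each of length ``n_increments``;
    durations are uniform and sum to ``stance_duration``.
    """
    if n_increments < 2:
        raise ValueError("n_increments must be at least 2")
    if stance_duration <= 0.0:
        raise ValueError("stance_duration must be positive")
    if not (0.0 < peak_times[0] < peak_times[1] < 1.0):
        raise ValueError("peak_times must be ordered and lie in (0, 1)")
    if peak1 <= 0.0 or peak2 <= 0.0:
        raise ValueError("peaks must be positive")
    durations = np.full(n_increments, stance_duration / n_increments)
    # amplitude sampled at the end of each increment, normalized time
    tau = np.cumsum(durations) / stance_duration
    amps = np.zeros(n_increments)
    for pk, tp in ((peak1, peak_times[0]), (peak2, peak_times[1])):
        bump = np.exp(-((tau - tp) ** 2) / (2.0 * width**2))
        amps = np.maximum(amps, pk * bump / bump.max())
    return durations, amps


class StaticFieldLoading:
    """Degeneration-independent stress histories, scaled by body weight.

    ``histories`` maps element id to a stress series (MPa) on the shared
    uniform stance grid; amplitudes are multiplied by ``body_weight_scale``.
    """

    kind = "static_field"

    def __init__(
        self,
        histories: Mapping[int, np.ndarray],
        durations: np.ndarray,
        body_weight_scale: float = 1.0,
    ) -> None:
        if body_weight_scale <= 0.0:
            raise ValueError("body_weight_scale must be positive")
        self.durations = np.asarray(durations, dtype=float)
        self.histories = {int(k): np.asarray(v, dtype=float) for k, v in histories.items()}
        for eid, s in self.histories.items():
            if s.shape != self.durations.shape:
                raise ValueError(f"element {eid}: history does not share the stance grid")
        self.body_weight_scale = float(body_weight_scale)

    def _check_covers(self, mesh: CartilageMesh) -> None:
        missing = [e.id for e in mesh.elements if e.id not in self.histories]
        if missing:
            raise ValueError(f"loading model missing elements: {missing[:5]}")
        total = float(self.durations.sum())
        if abs(total - mesh.stance_duration) > _GRID_TOL:
            raise ValueError(
                f"increments sum to {total}, expected stance {mesh.stance_duration}"
            )

    def stress_matrix(
        self,
        mesh: CartilageMesh,
        D_per_element: Mapping[int, float],
        params_by_region: Mapping[str, MaterialParams],
    ) -> np.ndarray:
        """(n_elements, n_increments) stress array in mesh element order."""
        self._check_covers(mesh)
        _check_D(mesh, D_per_element)
        return self.body_weight_scale * np.stack(
            [self.histories[e.id] for e in mesh.elements]
        )

    def stress_histories(self, mesh, D_per_element, params_by_region):
        mat = self.stress_matrix(mesh, D_per_element, params_by_region)
        return [
            GaitStressHistory(e.id, row, self.durations.copy())
            for e, row in zip(mesh.elements, mat)
        ]


class StrainDrivenLoading:
    """Fibril-strain-controlled histories evaluated through the
    viscoelastic fibril law at the element's current degeneration level.

    ``strains`` maps element id to an array of shape
    (n_fibrils, n_increments).  The modulated fibril stress is exactly
    proportional to D, so the tensile history at degeneration D equals
    D times the intact-tissue (D = 1) history; the intact history is
    computed once per element and cached.
    """

    kind = "strain_driven"

    def __init__(
        self,
        strains: Mapping[int, np.ndarray],
        durations: np.ndarray,
        body_weight_scale: float = 1.0,
    ) -> None:
        if body_weight_scale <= 0.0:
            raise ValueError("body_weight_scale must be positive")
        self.durations = np.asarray(durations, dtype=float)
        self.strains = {int(k): np.atleast_2d(np.asarray(v, dtype=float)) for k, v in strains.items()}
        self.body_weight_scale = float(body_weight_scale)
        self._base: dict[int, np.ndarray] = {}

    def _base_history(self, element, params: MaterialParams) -> np.ndarray:
        if element.id not in self._base:
            if not element.has_primary_and_secondary():
                raise ValueError(
                    f"element {element.id}: strain-driven loading requires at "
                    "least one primary and one secondary fibril"
                )
            series = self.body_weight_scale * self.strains[element.id]
            self._base[element.id] = max_tensile_fibril_stress(
                element, 1.0, series, self.durations, params
            )
        return self._base[element.id]

    def stress_matrix(
        self,
        mesh: CartilageMesh,
        D_per_element: Mapping[int, float],
        params_by_region: Mapping[str, MaterialParams],
    ) -> np.ndarray:
        missing = [e.id for e in mesh.elements if e.id not in self.strains]
        if missing:
            raise ValueError(f"loading model missing elements: {missing[:5]}")
        total = float(self.durations.sum())
        if abs(total - mesh.stance_duration) > _GRID_TOL:
            raise ValueError(
                f"increments sum to {total}, expected stance {mesh.stance_duration}"
            )
        _check_D(mesh, D_per_element)
        rows = []
        for e in mesh.elements:
            base = self._base_history(e, params_by_region[e.region])
            rows.append(D_per_element[e.id] * base)
        return np.stack(rows)

    def stress_histories(self, mesh, D_per_element, params_by_region):
        mat = self.stress_matrix(mesh, D_per_element, params_by_region)
        return [
            GaitStressHistory(e.id, row, self.durations.copy())
            for e, row in zip(mesh.elements, mat)
        ]


def _check_D(mesh: CartilageMesh, D_per_element: Mapping[int, float]) -> None:
    for e in mesh.elements:
        if e.id not in D_per_element:
            raise ValueError(f"missing degeneration level for element {e.id}")
        d = D_per_element[e.id]
        if not (0.0 <= d <= 1.0):
            raise ValueError(f"element {e.id}: D = {d} outside [0, 1]")


def write_loading(model, path: str | Path) -> None:
    """Serialize a loading model to the structured-text spec format."""
    lines = [
        "# cartdegen-loading v1",
        f"kind {model.kind}",
        f"body_weight_scale {model.body_weight_scale!r}",
        "durations " + " ".join(repr(float(d)) for d in model.durations),
    ]
    if model.kind == "static_field":
        for eid, s in model.histories.items():
            lines.append(f"stresses {eid} " + " ".join(repr(float(v)) for v in s))
    else:
        for eid, arr in model.strains.items():
            for row in arr:
                lines.append(f"strains {eid} " + " ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_loading(path: str | Path):
    """Read a loading model from the structured-text spec format."""
    kind = None
    scale = 1.0
    durations = None
    stresses: dict[int, np.ndarray] = {}
    strains: dict[int, list[np.ndarray]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if tok[0] == "kind":
            kind = tok[1]
        elif tok[0] == "body_weight_scale":
            scale = float(tok[1])
        elif tok[0] == "durations":
            durations = np.array([float(v) for v in tok[1:]])
        elif tok[0] == "stresses":
            stresses[int(tok[1])] = np.array([float(v) for v in tok[2:]])
        elif tok[0] == "strains":
            strains.setdefault(int(tok[1]), []).append(
                np.array([float(v) for v in tok[2:]])
            )
        else:
            raise ValueError(f"{path}:{lineno}: unknown record {tok[0]!r}")
    if kind is None or durations is None:
        raise ValueError(f"{path}: missing kind or durations header")
    if kind == "static_field":
        return StaticFieldLoading(stresses, durations, body_weight_scale=scale)
    if kind == "strain_driven":
        return StrainDrivenLoading(
            {k: np.stack(v) for k, v in strains.items()}, durations,
            body_weight_scale=scale,
        )
    raise ValueError(f"{path}: unknown loading kind {kind!r}")
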
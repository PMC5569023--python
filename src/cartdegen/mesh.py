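"""Cartilage mesh domain types and their plain-text file format.

The spatial domain is a collection of (hexahedral) elements carrying a
volume, a normalized depth coordinate, a region tag (femoral or tibial
cartilage) and a set of collagen fibril specifications.  Element
connectivity is not needed by the degeneration algorithm, which operates
element-wise, so only per-element scalars are stored.

File format (structured text, ``# cartdegen-mesh v1``)::

    # cartdegen-mesh v1
    name <label>
    stance_duration <seconds>
    element <id> <region> <volume_mm3> <depth_z> <n_fibrils>
    fibril <dx> <dy> <dz> <is_primary 0/1> <rho> <C>
    ...

Floats are serialized with ``repr`` and therefore round-trip bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

REGIONS = ("femoral", "tibial")

_UNIT_TOL = 1e-9


@dataclass
class FibrilSpec:
    """One collagen fibril bundle within an element.

    ``direction`` is a unit 3-vector; ``density_rho`` is the dimensionless
    fibril density weight and ``primary_fraction_C`` the dimensionless
    fraction between primary and secondary fibril contributions.
    """

    direction: np.ndarray
    is_primary: bool
    density_rho: float = 1.0
    primary_fraction_C: float = 1.0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3,):
            raise ValueError("fibril direction must be a 3-vector")
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > _UNIT_TOL:
            raise ValueError(f"fibril direction must be unit-norm, |e| = {norm}")
        if self.density_rho < 0.0:
            raise ValueError("density_rho must be non-negative")
        if self.primary_fraction_C <= 0.0:
            raise ValueError("primary_fraction_C must be positive")


@dataclass
class Element:
    id: int
    volume: float  # mm^3
    depth_z: float  # normalized, 0 = surface, 1 = deep
    region: str
    fibrils: list[FibrilSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.volume <= 0.0:
            raise ValueError(f"element {self.id}: volume must be positive")
        if not (0.0 <= self.depth_z <= 1.0):
            raise ValueError(f"element {self.id}: depth_z must lie in [0, 1]")
        if self.region not in REGIONS:
            raise ValueError(f"element {self.id}: unknown region {self.region!r}")
        if not self.fibrils:
            raise ValueError(f"element {self.id}: fibrils must be non-empty")

    def has_primary_and_secondary(self) -> bool:
        flags = {f.is_primary for f in self.fibrils}
        return flags == {True, False}


@dataclass
class CartilageMesh:
    elements: list[Element]
    name: str = "mesh"
    stance_duration: float = 0.8  # seconds of stance phase per gait cycle

    def __post_init__(self) -> None:
        ids = [e.id for e in self.elements]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate element ids: {dup}")
        if self.stance_duration <= 0.0:
            raise ValueError("stance_duration must be positive")
        if self.total_volume() <= 0.0:
            raise ValueError("mesh total volume must be strictly positive")

    def total_volume(self, region: str | None = None) -> float:
        return float(
            sum(e.volume for e in self.elements if region is None or e.region == region)
        )

    def element_ids(self) -> list[int]:
        return [e.id for e in self.elements]

    def regions(self) -> set[str]:
        return {e.region for e in self.elements}

    def __len__(self) -> int:
        return len(self.elements)


class MeshParseError(ValueError):
    """Raised when a mesh file is malformed; carries the offending line number."""


def write_mesh(mesh: CartilageMesh, path: str | Path) -> None:
    r = lambda v: repr(float(v))  # noqa: E731 - full-precision scalar repr
    lines = ["# cartdegen-mesh v1", f"name {mesh.name}",
             f"stance_duration {r(mesh.stance_duration)}"]
    for e in mesh.elements:
        lines.append(
            f"element {e.id} {e.region} {r(e.volume)} {r(e.depth_z)} {len(e.fibrils)}"
        )
        for f in e.fibrils:
            d = f.direction
            lines.append(
                f"fibril {r(d[0])} {r(d[1])} {r(d[2])} {int(f.is_primary)} "
                f"{r(f.density_rho)} {r(f.primary_fraction_C)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh(path: str | Path) -> CartilageMesh:
    """Read and validate a mesh file; see the module docstring for the format."""
    text = Path(path).read_text().splitlines()
    name = "mesh"
    stance = 0.8
    elements: list[Element] = []
    # header fields of the element block currently being read
    pending: dict | None = None
    pending_fibrils = 0

    def err(lineno: int, msg: str) -> MeshParseError:
        return MeshParseError(f"{path}:{lineno}: {msg}")

    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        try:
            if tok[0] == "name":
                name = " ".join(tok[1:])
            elif tok[0] == "stance_duration":
                stance = float(tok[1])
            elif tok[0] == "element":
                if pending is not None and pending_fibrils > 0:
                    raise err(lineno, f"element {pending['id']} is missing fibril lines")
                eid, region, vol, z, nf = (
                    int(tok[1]), tok[2], float(tok[3]), float(tok[4]), int(tok[5]),
                )
                if nf < 1:
                    raise err(lineno, f"element {eid} declares {nf} fibrils")
                # defer Element construction until fibrils are collected
                pending = {"id": eid, "region": region, "volume": vol,
                           "depth_z": z, "fibrils": []}
                pending_fibrils = nf
            elif tok[0] == "fibril":
                if pending is None or pending_fibrils == 0:
                    raise err(lineno, "fibril line outside an element block")
                spec = FibrilSpec(
                    direction=np.array([float(tok[1]), float(tok[2]), float(tok[3])]),
                    is_primary=bool(int(tok[4])),
                    density_rho=float(tok[5]),
                    primary_fraction_C=float(tok[6]),
                )
                pending["fibrils"].append(spec)
                pending_fibrils -= 1
                if pending_fibrils == 0:
                    elements.append(Element(**pending))
                    pending = None
            else:
                raise err(lineno, f"unknown record {tok[0]!r}")
        except MeshParseError:
            raise
        except (ValueError, IndexError) as exc:
            raise err(lineno, str(exc)) from exc

    if pending is not None and pending_fibrils > 0:
        raise MeshParseError(f"{path}: truncated file, element {pending['id']} incomplete")
    return CartilageMesh(elements=elements, name=name, stance_duration=stance)


def export_vtk(
    mesh: CartilageMesh,
    path: str | Path,
    cell_data: dict[str, Sequence[float]] | None = None,
    grid_dims: tuple[int, int] | None = None,
) -> None:
    """Write a legacy-ASCII VTK unstructured grid of unit-cube cells for
    visualizing per-element scalar fields (e.g. degeneration maps).

    Geometry is schematic: elements are laid out as unit hexahedra on a
    ``grid_dims`` raster (or a single row) since the mesh type stores no
    nodal coordinates.  Intended for qualitative inspection only.
    """
    n = len(mesh.elements)
    nx = grid_dims[0] if grid_dims else n
    pts: list[tuple[float, float, float]] = []
    cells: list[list[int]] = []
    for k in range(n):
        i, j = k % nx, k // nx
        base = len(pts)
        for dz in (0.0, 1.0):
            for (dx, dy) in ((0, 0), (1, 0), (1, 1), (0, 1)):
                pts.append((i + dx, j + dy, dz))
        cells.append([base + m for m in (0, 1, 2, 3, 4, 5, 6, 7)])
    out = [
        "# vtk DataFile Version 3.0",
        f"cartdegen mesh {mesh.name}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} float",
    ]
    out += [f"{x} {y} {z}" for x, y, z in pts]
    out.append(f"CELLS {n} {9 * n}")
    out += ["8 " + " ".join(map(str, c)) for c in cells]
    out.append(f"CELL_TYPES {n}")
    out += ["12"] * n  # VTK_HEXAHEDRON
    if cell_data:
        out.append(f"CELL_DATA {n}")
        for field_name, values in cell_data.items():
            if len(values) != n:
                raise ValueError(f"cell_data field {field_name!r} has wrong length")
            out.append(f"SCALARS {field_name} float 1")
            out.append("LOOKUP_TABLE default")
            out += [repr(float(v)) for v in values]
    Path(path).write_text("\n".join(out) + "\n")
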
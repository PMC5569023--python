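"""Fibril-reinforced poroviscoelastic (FRPVE) material parameters.

Cartilage is modelled as a nonfibrillar matrix (proteoglycans and
interstitial fluid) reinforced by a collagen fibril network with
well-oriented primary fibrils and randomly-oriented secondary fibrils.
This module carries the scalar material constants of that model and the
depth-dependent fluid-fraction profile.  The permeability ``k_0`` and the
fluid-fraction coefficients are carried for completeness but are not
consumed by the degeneration surrogate, which solves no consolidation
problem.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class MaterialParams:
    """Scalar constants of the FRPVE cartilage material.

    Parameters
    ----------
    E_m : float
        Nonfibrillar matrix modulus (MPa).
    E_0 : float
        Initial (strain-independent) fibril network modulus (MPa).
    E_eps : float
        Strain-dependent fibril network modulus (MPa).
    nu_m : float
        Poisson's ratio of the nonfibrillar matrix (dimensionless).
    eta : float
        Viscoelastic damping coefficient of the fibril network (MPa s).
    k_0 : float
        Initial permeability (x 1e-15 m^4 / N s).  Carried, unused by the
        surrogate (no poroelastic solve).
    n_f_surface, n_f_slope : float
        Coefficients of the linear fluid-fraction depth profile
        ``n_f(z) = n_f_surface - n_f_slope * z``.  Carried, unused by the
        surrogate.
    """

    E_m: float
    E_0: float
    E_eps: float
    nu_m: float
    eta: float
    k_0: float = 0.0
    n_f_surface: float = 0.8
    n_f_slope: float = 0.15

    def __post_init__(self) -> None:
        for name in ("E_m", "E_0", "E_eps", "eta"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if not (0.0 <= self.nu_m < 0.5):
            raise ValueError(f"nu_m must lie in [0, 0.5), got {self.nu_m}")

    def with_(self, **kwargs) -> "MaterialParams":
        return replace(self, **kwargs)


# Literature parameter sets for human knee cartilage.  The permeability
# split between the two sites follows the typical tibial > femoral ordering
# reported for human knee cartilage; neither value enters the surrogate.
TIBIAL_CARTILAGE = MaterialParams(
    E_m=0.106, E_0=0.18, E_eps=23.6, nu_m=0.15, eta=1062.0, k_0=18.0
)
FEMORAL_CARTILAGE = MaterialParams(
    E_m=0.215, E_0=0.92, E_eps=150.0, nu_m=0.15, eta=1062.0, k_0=6.0
)

PRESETS = {"tibial": TIBIAL_CARTILAGE, "femoral": FEMORAL_CARTILAGE}


def fluid_fraction(depth_z: float, params: MaterialParams) -> float:
    """Fluid fraction at normalized depth ``z`` (0 = articular surface,
    1 = deep zone): ``n_f = n_f_surface - n_f_slope * z``.

    Raises
    ------
    ValueError
        If ``depth_z`` lies outside [0, 1].
    """
    if not (0.0 <= depth_z <= 1.0):
        raise ValueError(f"depth_z must lie in [0, 1], got {depth_z}")
    return params.n_f_surface - params.n_f_slope * depth_z
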
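"""Per-element strain components and the von Mises scalar.

Strain is evaluated once per element at the element center, giving one
strain triple (eps_x, eps_y, gamma_xy) and one von Mises value per
pixel. The von Mises equivalent strain used here is

    eps_vM = sqrt(eps_x^2 + eps_y^2 - eps_x*eps_y + (3/4)*gamma_xy^2)

(engineering shear convention). It is non-negative, rotation invariant
and positively homogeneous of degree 1, which is all the destruction
loop relies on; the 2/3-prefactor deviatoric variant differs only by a
constant factor and is available via ``convention="deviatoric"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem_core import FemSystem, strain_displacement_matrix

__all__ = [
    "StrainField",
    "element_strain",
    "von_mises",
    "von_mises_form",
    "compute_strain_field",
    "B_CENTER",
]

#: Strain-displacement matrix at the element center.
B_CENTER = strain_displacement_matrix(0.0, 0.0)

# Quadratic form M with eps_vM^2 = eps^T M eps (equivalent-strain form).
_M_EQUIVALENT = np.array(
    [[1.0, -0.5, 0.0], [-0.5, 1.0, 0.0], [0.0, 0.0, 0.75]]
)


def von_mises_form(convention: str = "equivalent") -> np.ndarray:
    """Quadratic form of the chosen von Mises convention."""
    if convention == "equivalent":
        return _M_EQUIVALENT
    if convention == "deviatoric":
        return (4.0 / 9.0) * _M_EQUIVALENT
    raise ValueError(f"unknown von Mises convention {convention!r}")


@dataclass(frozen=True)
class StrainField:
    """Element-center strains for every member element.

    ``components[k]`` and ``von_mises[k]`` follow the element scan order
    of the NodeMap; ``argmax`` is the first index attaining the maximum
    (lowest (row, column) scan order on ties).
    """

    components: np.ndarray  # (M, 3)
    von_mises: np.ndarray  # (M,)
    argmax: int
    max_value: float


def element_strain(u_e: np.ndarray) -> np.ndarray:
    """Strain 3-vector at the center of one element from its 8 nodal dofs."""
    u_e = np.asarray(u_e, dtype=float)
    if u_e.shape != (8,):
        raise ValueError("u_e must have 8 entries")
    return B_CENTER @ u_e


def von_mises(strain: np.ndarray, convention: str = "equivalent") -> np.ndarray:
    """Von Mises scalar of one strain triple or an (M, 3) batch."""
    strain = np.asarray(strain, dtype=float)
    m = von_mises_form(convention)
    q = np.einsum("...i,ij,...j->...", strain, m, strain)
    return np.sqrt(np.maximum(q, 0.0))


def compute_strain_field(
    system: FemSystem, u: np.ndarray, convention: str = "equivalent"
) -> StrainField:
    """Evaluate all element strains and their von Mises values at once."""
    u = np.asarray(u, dtype=float)
    if u.shape != (system.n_dofs,):
        raise ValueError(f"displacement vector must have length {system.n_dofs}")
    u_e = u[system.node_map.element_dofs]  # (M, 8)
    eps = u_e @ B_CENTER.T
    vm = von_mises(eps, convention)
    argmax = int(np.argmax(vm))
    return StrainField(eps, vm, argmax, float(vm[argmax]))
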
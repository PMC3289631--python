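"""Plane-stress bilinear quadrilateral elements and the regularized system solve.

Each foreground pixel is a unit-square element with bilinear shape
functions, so the 8x8 element stiffness is a fixed matrix scaled by the
element's Young's modulus. The assembled system matrix is singular
(rigid-body modes); instead of picking support nodes, a weak spring to
ground is added at every dof — ``K_reg = K + c*I`` with ``c`` a small
fraction of the largest diagonal entry — which makes the system positive
definite without biasing the strain field noticeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid_model import MaterialField, NodeMap

__all__ = [
    "elasticity_matrix",
    "strain_displacement_matrix",
    "element_stiffness",
    "assemble",
    "solve",
    "FemSystem",
    "SolverError",
]

# Reference-square corner coordinates, counterclockwise from lower-left,
# matching the node order in NodeMap.element_nodes.
_XI = np.array([-1.0, 1.0, 1.0, -1.0])
_ETA = np.array([-1.0, -1.0, 1.0, 1.0])

#: Above this many dofs the direct factorization is replaced by
#: diagonally preconditioned conjugate gradients.
DEFAULT_DIRECT_SOLVER_CUTOFF = 400_000


class SolverError(RuntimeError):
    """Linear solve failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (relative residual {residual:.3e})")
        self.residual = residual


def elasticity_matrix(e: float, nu: float, plane: str = "stress") -> np.ndarray:
    """Hooke's-law matrix D relating (eps_x, eps_y, gamma_xy) to stress.

    Plane stress (default) models a thin slice free to contract out of
    plane; plane strain is offered for completeness.
    """
    if e <= 0:
        raise ValueError("Young's modulus must be positive")
    if not (0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    if plane == "stress":
        return (e / (1 - nu**2)) * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1 - nu) / 2]]
        )
    if plane == "strain":
        c = e / ((1 + nu) * (1 - 2 * nu))
        return c * np.array(
            [
                [1 - nu, nu, 0.0],
                [nu, 1 - nu, 0.0],
                [0.0, 0.0, (1 - 2 * nu) / 2],
            ]
        )
    raise ValueError(f"plane must be 'stress' or 'strain', got {plane!r}")


def shape_gradients(xi: float, eta: float) -> np.ndarray:
    """(2, 4) derivatives of the bilinear shape functions w.r.t. (xi, eta)."""
    dxi = 0.25 * _XI * (1 + _ETA * eta)
    deta = 0.25 * _ETA * (1 + _XI * xi)
    return np.vstack([dxi, deta])


def strain_displacement_matrix(xi: float, eta: float) -> np.ndarray:
    """3x8 matrix B with strain = B @ u_e on the unit-square element.

    Rows are (eps_x, eps_y, gamma_xy); dof order is (u1x, u1y, ..., u4y)
    counterclockwise from the lower-left node. The physical element is
    the unit square, so d/dx = 2*d/dxi and d/dy = 2*d/deta.
    """
    if not (-1 <= xi <= 1 and -1 <= eta <= 1):
        raise ValueError("(xi, eta) must lie in the reference square")
    g = 2.0 * shape_gradients(xi, eta)  # physical-space gradients
    b = np.zeros((3, 8))
    b[0, 0::2] = g[0]
    b[1, 1::2] = g[1]
    b[2, 0::2] = g[1]
    b[2, 1::2] = g[0]
    return b


@lru_cache(maxsize=8)
def _unit_stiffness(nu: float, plane: str) -> np.ndarray:
    """Element stiffness for E = 1, via 2x2 Gauss quadrature (exact here)."""
    d = elasticity_matrix(1.0, nu, plane)
    k = np.zeros((8, 8))
    gp = 1.0 / np.sqrt(3.0)
    for xi in (-gp, gp):
        for eta in (-gp, gp):
            b = strain_displacement_matrix(xi, eta)
            # Jacobian determinant of unit square <- reference square is 1/4.
            k += 0.25 * b.T @ d @ b
    return 0.5 * (k + k.T)


def element_stiffness(e: float, nu: float, plane: str = "stress") -> np.ndarray:
    """8x8 symmetric stiffness of one unit-square pixel element.

    Linear in E; rank 5 (three 2D rigid-body modes in the null space).
    """
    if e <= 0:
        raise ValueError("Young's modulus must be positive")
    return e * _unit_stiffness(float(nu), plane)


@dataclass
class FemSystem:
    """Assembled, weak-spring-regularized pixel FEM system."""

    node_map: NodeMap
    material: MaterialField
    K: sp.csr_matrix
    K_reg: sp.csr_matrix
    spring_coefficient: float
    plane: str = "stress"
    solver_cutoff: int = DEFAULT_DIRECT_SOLVER_CUTOFF
    _solve: object = field(default=None, repr=False, compare=False)

    @property
    def n_dofs(self) -> int:
        return 2 * self.node_map.n_nodes

    def solver(self):
        """Cached linear solver for K_reg (factorization reused across loads)."""
        if self._solve is None:
            if self.n_dofs <= self.solver_cutoff:
                lu = spla.factorized(self.K_reg.tocsc())
                a = self.K_reg

                knorm = float(self.K_reg.diagonal().max())

                def direct(f, _lu=lu, _a=a, _k=knorm):
                    # Iterative refinement: the weak spring leaves the
                    # system ill-conditioned (~1/spring_factor), so a
                    # couple of refinement steps recover a residual at
                    # the backward-stable rounding floor.
                    u = _lu(f)
                    fnorm = np.linalg.norm(f)
                    best, best_r = u, np.inf
                    for _ in range(6):
                        r = f - _a @ u
                        rnorm = np.linalg.norm(r)
                        if rnorm < best_r:
                            best, best_r = u, rnorm
                        scale = fnorm + _k * np.linalg.norm(u)
                        if rnorm <= 4 * np.finfo(float).eps * scale:
                            break
                        u = u + _lu(r)
                    return best

                self._solve = direct
            else:
                a = self.K_reg
                m = spla.LinearOperator(
                    a.shape, matvec=lambda x: x / a.diagonal()
                )

                def cg_solve(f, _a=a, _m=m):
                    u, info = spla.cg(_a, f, rtol=1e-10, atol=0.0, M=_m, maxiter=20_000)
                    if info != 0:
                        raise SolverError(
                            "conjugate gradients did not converge",
                            float(
                                np.linalg.norm(_a @ u - f)
                                / max(np.linalg.norm(f), 1e-300)
                            ),
                        )
                    return u

                self._solve = cg_solve
        return self._solve


def assemble(
    material: MaterialField,
    node_map: NodeMap,
    spring_factor: float = 1e-11,
    plane: str = "stress",
    solver_cutoff: int = DEFAULT_DIRECT_SOLVER_CUTOFF,
) -> FemSystem:
    """Scatter all element stiffnesses into the sparse system matrix.

    ``spring_factor`` sets the ground-spring coefficient as a fraction of
    the largest diagonal entry of K. The default of 1e-11 sits far below
    the softest elastic mode of joint-like structures (two stiff regions
    hinging about a soft neck reach ~1e-9 of the max diagonal on large
    rasters), so the springs pin the rigid-body modes without competing
    with any physical deformation mode.
    """
    if spring_factor <= 0:
        raise ValueError("spring_factor must be positive")
    k1 = _unit_stiffness(float(material.poisson_ratio), plane)
    dofs = node_map.element_dofs  # (M, 8)
    m = len(dofs)
    # All elements share k1 up to the scalar E: one big broadcasted scatter.
    vals = material.youngs_modulus[:, None, None] * k1[None, :, :]
    rows = np.repeat(dofs, 8, axis=1)  # (M, 64)
    cols = np.tile(dofs, (1, 8))
    n = 2 * node_map.n_nodes
    K = sp.coo_matrix(
        (vals.reshape(m * 64), (rows.reshape(-1), cols.reshape(-1))), shape=(n, n)
    ).tocsr()
    c = spring_factor * float(K.diagonal().max())
    K_reg = (K + c * sp.identity(n, format="csr")).tocsr()
    return FemSystem(node_map, material, K, K_reg, c, plane, solver_cutoff)


def solve(system: FemSystem, f: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Nodal displacements under the load f.

    The accepted solution satisfies the backward-stable criterion
    ``||K_reg u - f|| <= rtol * (||f|| + ||K_reg|| ||u||)``: because the
    ground springs are deliberately orders of magnitude softer than the
    structure, an unbalanced load produces displacements of order
    ``||f||/c`` and a residual measured against ``||f||`` alone would be
    unattainable in floating point.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (system.n_dofs,):
        raise ValueError(f"force vector must have length {system.n_dofs}")
    if not np.all(np.isfinite(f)):
        raise ValueError("force vector contains non-finite entries")
    fnorm = np.linalg.norm(f)
    if fnorm == 0.0:
        return np.zeros_like(f)
    u = system.solver()(f)
    knorm = float(system.K_reg.diagonal().max())
    scale = fnorm + knorm * float(np.linalg.norm(u))
    residual = float(np.linalg.norm(system.K_reg @ u - f) / scale)
    if residual > rtol:
        raise SolverError("linear solve exceeded residual tolerance", residual)
    return u
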
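"""Loading-condition optimization: where and how hard to push on the object.

External forces live only on boundary nodes of the foreground and act
along outward surface normals, so each boundary node carries a single
scalar magnitude. The objective is the total von Mises strain inside
the ROI,

    Phi(f) = sum_{e in ROI} eps_vM(e),

which is positively homogeneous of degree 1 in the load, so the search
is constrained to the unit sphere ||f|| = 1 (otherwise ascent would
diverge by pure scaling). The ascent direction is the analytic gradient
obtained with one adjoint solve per iteration — dPhi/du is assembled
element-wise as B^T M eps / eps_vM, mapped back through the symmetric
system matrix, and contracted with the node normals — followed by
Armijo backtracking on the sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fem_core import FemSystem, solve
from .grid_model import ForegroundSet, NodeMap, PixelImage, RoiMask
from .strain_field import B_CENTER, von_mises_form

logger = logging.getLogger(__name__)

__all__ = [
    "BoundaryGeometry",
    "LoadVector",
    "OptimizerTrace",
    "boundary_geometry",
    "restrict_support",
    "initial_load",
    "roi_element_indices",
    "objective",
    "gradient",
    "optimize_load",
]

# (normal, node corner offsets) for each of the four pixel edges; a pixel
# edge is exposed when the neighbour across it is background.
_EDGES = (
    ((0, -1), (-1.0, 0.0), ((0, 0), (0, 1))),  # left:   nodes (i,j), (i,j+1)
    ((0, 1), (1.0, 0.0), ((1, 0), (1, 1))),  # right:  (i+1,j), (i+1,j+1)
    ((-1, 0), (0.0, -1.0), ((0, 0), (1, 0))),  # bottom: (i,j), (i+1,j)
    ((1, 0), (0.0, 1.0), ((0, 1), (1, 1))),  # top:    (i,j+1), (i+1,j+1)
)


@dataclass(frozen=True)
class BoundaryGeometry:
    """Boundary nodes, their outward unit normals and the weighted centroid."""

    node_ids: np.ndarray  # (B,)
    positions: np.ndarray  # (B, 2) lattice (i, j)
    normals: np.ndarray  # (B, 2) unit vectors
    center_of_mass: np.ndarray  # (2,) intensity-weighted, pixel units
    degenerate_count: int = 0


@dataclass
class LoadVector:
    """Scalar load magnitude per boundary node, directed along its normal.

    ``positions`` are lattice coordinates so magnitudes can be carried
    across foreground rebuilds during destruction (nodes that vanish
    simply drop out).
    """

    node_ids: np.ndarray
    positions: np.ndarray
    normals: np.ndarray
    magnitudes: np.ndarray

    @property
    def norm(self) -> float:
        # Normals are unit vectors at disjoint dofs, so ||f|| = ||s||.
        return float(np.linalg.norm(self.magnitudes))

    def normalized(self) -> "LoadVector":
        n = self.norm
        if n == 0:
            raise ValueError("cannot normalize a zero load")
        return LoadVector(
            self.node_ids, self.positions, self.normals, self.magnitudes / n
        )

    def with_magnitudes(self, s: np.ndarray) -> "LoadVector":
        return LoadVector(self.node_ids, self.positions, self.normals, s)

    def force_vector(self, n_dofs: int) -> np.ndarray:
        f = np.zeros(n_dofs)
        f[2 * self.node_ids] = self.magnitudes * self.normals[:, 0]
        f[2 * self.node_ids + 1] = self.magnitudes * self.normals[:, 1]
        return f


@dataclass
class OptimizerTrace:
    """Per-trial record of the projected gradient ascent."""

    objective_values: list = field(default_factory=list)
    steps: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    initial_objective: float = 0.0
    stationary: bool = False

    def record(self, phi: float, step: float, accepted: bool) -> None:
        self.objective_values.append(phi)
        self.steps.append(step)
        self.accepted.append(accepted)

    @property
    def accepted_objectives(self) -> list:
        return [
            p for p, a in zip(self.objective_values, self.accepted) if a
        ]


def boundary_geometry(
    fg: ForegroundSet, image: PixelImage, node_map: NodeMap
) -> BoundaryGeometry:
    """Find boundary nodes, outward normals and the weighted center of mass.

    A node is a boundary node when it touches at least one exposed pixel
    edge; its normal is the normalized sum of the outward normals of its
    exposed incident edges. A pinch point whose edge normals cancel falls
    back to the normal of its heaviest (highest-intensity) exposed edge.
    """
    mask = fg.mask
    h, w = mask.shape
    shape = (h + 1, w + 1)
    acc = np.zeros(shape + (2,))
    exposed_any = np.zeros(shape, dtype=bool)
    best_w = np.full(shape, -np.inf)
    best_normal = np.zeros(shape + (2,))

    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    edge_data = []
    for (dj, di), normal, corners in _EDGES:
        exposed = mask & ~padded[1 + dj : 1 + dj + h, 1 + di : 1 + di + w]
        ej, ei = np.nonzero(exposed)
        wts = image.values[ej, ei]
        edge_data.append((ej, ei, wts, normal, corners))
        for ci, cj in corners:
            acc[ej + cj, ei + ci, 0] += normal[0]
            acc[ej + cj, ei + ci, 1] += normal[1]
            exposed_any[ej + cj, ei + ci] = True
            np.maximum.at(best_w, (ej + cj, ei + ci), wts)
    # Second pass: remember the normal of each node's heaviest exposed edge.
    for ej, ei, wts, normal, corners in edge_data:
        for ci, cj in corners:
            hit = wts >= best_w[ej + cj, ei + ci]
            best_normal[ej[hit] + cj, ei[hit] + ci] = normal

    active = node_map.node_index >= 0
    bmask = exposed_any & active
    jj, ii = np.nonzero(bmask)
    node_ids = node_map.node_index[jj, ii]
    raw = acc[jj, ii]
    lens = np.linalg.norm(raw, axis=1)
    degenerate = lens < 1e-9
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info(
            "%d boundary nodes with cancelling edge normals; using the "
            "heaviest incident edge",
            n_deg,
        )
        raw[degenerate] = best_normal[jj[degenerate], ii[degenerate]]
        lens = np.linalg.norm(raw, axis=1)
    normals = raw / lens[:, None]

    ej, ei = np.nonzero(mask)
    v = image.values[ej, ei]
    g = np.array(
        [np.sum(v * (ei + 0.5)), np.sum(v * (ej + 0.5))]
    ) / v.sum()
    positions = np.column_stack([ii, jj]).astype(float)
    return BoundaryGeometry(node_ids, positions, normals, g, n_deg)


def restrict_support(
    geom: BoundaryGeometry, roi: RoiMask, margin: int = 1
) -> BoundaryGeometry:
    """Drop boundary nodes that touch the ROI dilated by ``margin`` pixels.

    Loading inside the region to be cut would trivially self-strain it,
    so the load support and the cut region are kept disjoint.
    """
    dil = ndimage.binary_dilation(roi.mask, iterations=margin) if margin else roi.mask
    h, w = roi.mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = dil
    ii = geom.positions[:, 0].astype(int)
    jj = geom.positions[:, 1].astype(int)
    # Node (i, j) touches pixels (i-1..i, j-1..j); padded index is shifted by 1.
    touches = (
        padded[jj, ii]
        | padded[jj + 1, ii]
        | padded[jj, ii + 1]
        | padded[jj + 1, ii + 1]
    )
    keep = ~touches
    if not keep.any():
        logger.warning(
            "ROI %r dilation covers every boundary node; keeping all of them",
            roi.id,
        )
        return geom
    return BoundaryGeometry(
        geom.node_ids[keep],
        geom.positions[keep],
        geom.normals[keep],
        geom.center_of_mass,
        geom.degenerate_count,
    )


def initial_load(geom: BoundaryGeometry) -> LoadVector:
    """Initial guess: push every boundary node away from the centroid.

    The raw direction (position - center of mass) is projected onto the
    node normal and the resulting magnitude vector normalized to 1.
    """
    if len(geom.node_ids) == 0:
        raise ValueError("no boundary nodes to load")
    raw = geom.positions - geom.center_of_mass
    s = np.einsum("ij,ij->i", raw, geom.normals)
    if np.linalg.norm(s) < 1e-12:
        logger.warning("all centroid projections vanish; using raw normals")
        s = np.ones(len(geom.node_ids))
    load = LoadVector(geom.node_ids, geom.positions.copy(), geom.normals, s)
    return load.normalized()


def roi_element_indices(node_map: NodeMap, roi: RoiMask) -> np.ndarray:
    """Indices (into the element scan order) of elements inside the ROI."""
    ej, ei = node_map.element_pixels.T
    idx = np.nonzero(roi.mask[ej, ei])[0]
    if len(idx) == 0:
        raise ValueError(f"ROI {roi.id!r} contains no structure")
    return idx


def _rigid_basis(node_map: NodeMap) -> np.ndarray:
    """Orthonormal basis of the three 2D rigid-body modes (2N, 3)."""
    pos = node_map.node_positions.astype(float)
    n = len(pos)
    basis = np.zeros((2 * n, 3))
    basis[0::2, 0] = 1.0
    basis[1::2, 1] = 1.0
    center = pos.mean(axis=0)
    basis[0::2, 2] = -(pos[:, 1] - center[1])
    basis[1::2, 2] = pos[:, 0] - center[0]
    q, _ = np.linalg.qr(basis)
    return q


def _phi_of(system: FemSystem, roi_elems: np.ndarray, f: np.ndarray, convention: str):
    u = solve(system, f)
    dofs = system.node_map.element_dofs[roi_elems]
    eps = u[dofs] @ B_CENTER.T
    m = von_mises_form(convention)
    vm = np.sqrt(np.maximum(np.einsum("ki,ij,kj->k", eps, m, eps), 0.0))
    return float(vm.sum()), u, eps, vm


def objective(
    system: FemSystem,
    roi: RoiMask,
    load: LoadVector,
    convention: str = "equivalent",
) -> float:
    """Total von Mises strain over ROI elements under the given load."""
    roi_elems = roi_element_indices(system.node_map, roi)
    phi, *_ = _phi_of(system, roi_elems, load.force_vector(system.n_dofs), convention)
    return phi


def gradient(
    system: FemSystem,
    roi: RoiMask,
    load: LoadVector,
    convention: str = "equivalent",
) -> np.ndarray:
    """Analytic dPhi/ds_i via one adjoint solve.

    For each ROI element, dPhi/du_e = B^T M eps / eps_vM (elements at
    exactly zero strain contribute a valid subgradient of 0); the
    assembled dPhi/du is pulled back through K_reg (symmetric, so the
    adjoint solve reuses the same factorization) and contracted with the
    load normals.
    """
    roi_elems = roi_element_indices(system.node_map, roi)
    f = load.force_vector(system.n_dofs)
    _, u, eps, vm = _phi_of(system, roi_elems, f, convention)
    m = von_mises_form(convention)
    # The direction M eps / eps_vM is pure rounding noise for elements
    # whose strain sits at the cancellation floor of B @ u_e; give those
    # the (valid) zero subgradient instead of amplifying the noise.
    floor = 64.0 * np.finfo(float).eps * float(np.abs(u).max())
    nz = vm > floor
    if not nz.all():
        logger.debug(
            "%d ROI elements at (numerically) zero strain; subgradient 0",
            int((~nz).sum()),
        )
    g_u = np.zeros(system.n_dofs)
    if nz.any():
        w = (eps[nz] @ m) / vm[nz, None]  # (n, 3) = M eps / eps_vM
        contrib = w @ B_CENTER  # (n, 8)
        np.add.at(g_u, system.node_map.element_dofs[roi_elems[nz]], contrib)
    # dPhi/du is orthogonal to the rigid-body modes analytically (rigid
    # motion is strain-free); project out the rounding-level residue so
    # it is not amplified by 1/c in the adjoint solve.
    rb = _rigid_basis(system.node_map)
    g_u -= rb @ (rb.T @ g_u)
    lam = system.solver()(g_u)
    # The exact adjoint K_reg^-1 (dPhi/du) also has zero rigid content
    # (rigid motion is strain-free, so Phi cannot depend on it); the
    # factorization reintroduces ~eps/c of it, so project again.
    lam -= rb @ (rb.T @ lam)
    return (
        lam[2 * load.node_ids] * load.normals[:, 0]
        + lam[2 * load.node_ids + 1] * load.normals[:, 1]
    )


def optimize_load(
    system: FemSystem,
    roi: RoiMask,
    f0: LoadVector,
    max_iter: int = 200,
    rtol: float = 1e-6,
    armijo_c: float = 1e-4,
    backtrack: float = 0.5,
    convention: str = "equivalent",
) -> tuple[LoadVector, OptimizerTrace]:
    """Projected gradient ascent of Phi on the unit sphere of magnitudes.

    Each iteration steps along the gradient component tangent to the
    sphere, backtracks until the Armijo sufficient-increase condition
    holds, and renormalizes. Stops on relative improvement below
    ``rtol``, a vanishing tangent gradient (stationary point), or
    ``max_iter``. Returns the best load seen; the accepted objective
    sequence is non-decreasing by construction.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    roi_elems = roi_element_indices(system.node_map, roi)
    conv = convention
    n_dofs = system.n_dofs

    def phi_of(s):
        f = f0.with_magnitudes(s).force_vector(n_dofs)
        return _phi_of(system, roi_elems, f, conv)[0]

    s = f0.magnitudes / np.linalg.norm(f0.magnitudes)
    phi = phi_of(s)
    trace = OptimizerTrace(initial_objective=phi)
    alpha = 1.0
    for _ in range(max_iter):
        g = gradient(system, roi, f0.with_magnitudes(s), conv)
        gt = g - (g @ s) * s
        gt_norm2 = float(gt @ gt)
        if np.sqrt(gt_norm2) <= 1e-12 * max(1.0, phi):
            trace.stationary = True
            break
        a = alpha
        accepted = False
        for _bt in range(60):
            cand = s + a * gt
            cand /= np.linalg.norm(cand)
            phi_cand = phi_of(cand)
            if phi_cand >= phi + armijo_c * a * gt_norm2:
                accepted = True
                break
            trace.record(phi_cand, a, False)
            a *= backtrack
        if not accepted:
            break
        trace.record(phi_cand, a, True)
        improvement = (phi_cand - phi) / max(phi, 1e-300)
        s, phi = cand, phi_cand
        alpha = a / backtrack  # try a slightly bolder step next time
        if improvement < rtol:
            break
    return f0.with_magnitudes(s), trace
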
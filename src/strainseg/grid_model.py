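"""Raster-to-mesh layer: image container, foreground extraction, node numbering, materials.

Geometry convention
-------------------
Pixel ``(i, j)`` has 0-based column ``i`` (x, rightwards) and row ``j``
(y, upwards in model space). It occupies the unit square
``[i, i+1] x [j, j+1]``; its four corners are lattice points and become
finite-element nodes. Arrays are indexed ``[j, i]`` (row-major, row 0 at
the *bottom* of the model); file readers in :mod:`strainseg.io` flip the
top-down row order of image files on read so that this convention holds
everywhere inside the package.

Every foreground pixel is one square bilinear element, so the element
geometry is fixed (side length 1) and only the per-element Young's
modulus varies, following a cube law in the normalized intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PixelImage",
    "ForegroundSet",
    "NodeMap",
    "MaterialField",
    "RoiMask",
    "extract_foreground",
    "build_node_map",
    "material_from_image",
]


@dataclass(frozen=True)
class PixelImage:
    """A 2D grayscale raster of non-negative intensities.

    ``values[j, i]`` is the intensity of pixel ``(i, j)`` in model-space
    orientation (``j`` grows upwards).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("image must be a 2D array")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("image must be at least 2x2 pixels")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if np.any(v < 0):
            raise ValueError("image contains negative intensities")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class ForegroundSet:
    """Pixels whose intensity reached the threshold; the element set.

    Membership shrinks only through destruction removals; the threshold
    used at construction is kept for the audit trail.
    """

    mask: np.ndarray
    threshold: float

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "ForegroundSet":
        return ForegroundSet(self.mask.copy(), self.threshold)

    def remove(self, pixel: tuple[int, int]) -> None:
        """Remove pixel ``(j, i)``; it must currently be a member."""
        j, i = pixel
        if not self.mask[j, i]:
            raise ValueError(f"pixel {pixel!r} is not a foreground member")
        self.mask[j, i] = False


def extract_foreground(image: PixelImage, threshold: float) -> ForegroundSet:
    """Threshold the image: pixels with intensity >= threshold are structure.

    Raises ``ValueError`` when nothing survives (no structure above
    threshold) — an all-background model has no mechanics to analyse.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = image.values >= threshold
    if not mask.any():
        raise ValueError("no structure above threshold")
    return ForegroundSet(mask, float(threshold))


@dataclass
class NodeMap:
    """Bijection between active lattice corners and contiguous node indices.

    Attributes
    ----------
    node_index : (H+1, W+1) int array; -1 for inactive corners, else the
        node number. Numbering is row-major over ``(j, i)`` and therefore
        deterministic for a given foreground.
    node_positions : (N, 2) int array of ``(i, j)`` lattice coordinates.
    element_pixels : (M, 2) int array of member pixels as ``(j, i)`` in
        scan order.
    element_nodes : (M, 4) node indices, counterclockwise from the
        lower-left corner: ``(i,j), (i+1,j), (i+1,j+1), (i,j+1)``.
    element_dofs : (M, 8) global dof indices; node ``n`` owns dofs
        ``(2n, 2n+1) = (x, y)``.
    """

    node_index: np.ndarray
    node_positions: np.ndarray
    element_pixels: np.ndarray
    element_nodes: np.ndarray
    element_dofs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        d = np.empty(self.element_nodes.shape + (2,), dtype=np.int64)
        d[..., 0] = 2 * self.element_nodes
        d[..., 1] = 2 * self.element_nodes + 1
        self.element_dofs = d.reshape(len(self.element_nodes), 8)

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def n_elements(self) -> int:
        return len(self.element_pixels)


def build_node_map(fg: ForegroundSet) -> NodeMap:
    """Number the corners of member pixels and list each element's nodes."""
    mask = fg.mask
    if not mask.any():
        raise ValueError("empty foreground")
    h, w = mask.shape
    corners = np.zeros((h + 1, w + 1), dtype=bool)
    corners[:-1, :-1] |= mask
    corners[:-1, 1:] |= mask
    corners[1:, :-1] |= mask
    corners[1:, 1:] |= mask

    node_index = np.full((h + 1, w + 1), -1, dtype=np.int64)
    jj, ii = np.nonzero(corners)  # row-major scan order
    node_index[jj, ii] = np.arange(len(jj))
    node_positions = np.column_stack([ii, jj]).astype(np.int64)  # (i, j)

    ej, ei = np.nonzero(mask)
    element_pixels = np.column_stack([ej, ei]).astype(np.int64)
    element_nodes = np.column_stack(
        [
            node_index[ej, ei],
            node_index[ej, ei + 1],
            node_index[ej + 1, ei + 1],
            node_index[ej + 1, ei],
        ]
    )
    return NodeMap(node_index, node_positions, element_pixels, element_nodes)


@dataclass(frozen=True)
class MaterialField:
    """Per-element Young's modulus plus one global Poisson ratio.

    ``youngs_modulus[k]`` corresponds to ``NodeMap.element_pixels[k]``.
    """

    youngs_modulus: np.ndarray
    poisson_ratio: float
    modulus_scale: float

    def __post_init__(self) -> None:
        if np.any(self.youngs_modulus <= 0):
            raise ValueError("Young's modulus must be positive everywhere")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


def material_from_image(
    image: PixelImage,
    fg: ForegroundSet,
    node_map: NodeMap,
    e0: float = 1.0,
    nu: float = 0.3,
    v_max: float | None = None,
) -> MaterialField:
    """Cube-law material: ``E(e) = E0 * (v / v_max)**3``.

    Bone stiffness grows roughly with the cube of density, and CT
    intensity is a density proxy, so dense regions become much stiffer
    than the faint interference region (intensity ratio r maps to
    modulus ratio r**3). Normalizing by the maximum foreground intensity
    makes the field invariant to a global intensity rescale.

    ``v_max`` may be pinned by the caller so the modulus field stays
    frozen while destruction shrinks the foreground.
    """
    if e0 <= 0:
        raise ValueError("E0 must be positive")
    ej, ei = node_map.element_pixels.T
    v = image.values[ej, ei]
    if np.any(v <= 0):
        raise ValueError("foreground pixel with zero intensity: singular material")
    if v_max is None:
        v_max = float(v.max())
    e = e0 * (v / v_max) ** 3
    return MaterialField(e, float(nu), float(e0))


@dataclass
class RoiMask:
    """User-drawn region believed to contain the interference region.

    Pixels outside the foreground are dropped with a warning (users
    draw masks roughly); an ROI with no foreground overlap is an error.
    """

    mask: np.ndarray
    id: str = "roi"

    @classmethod
    def from_raw(cls, raw: np.ndarray, fg: ForegroundSet, id: str = "roi") -> "RoiMask":
        raw = np.asarray(raw, dtype=bool)
        if raw.shape != fg.mask.shape:
            raise ValueError(
                f"ROI shape {raw.shape} does not match image {fg.mask.shape}"
            )
        kept = raw & fg.mask
        dropped = int(raw.sum() - kept.sum())
        if dropped:
            logger.warning(
                "ROI %r: dropped %d pixels outside the foreground", id, dropped
            )
        if not kept.any():
            raise ValueError(f"ROI {id!r} contains no structure")
        return cls(kept, id)

    @property
    def area(self) -> int:
        return int(self.mask.sum())
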
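"""Destruction loop, repair, ROI ranking and the full segmentation pipeline.

The destruction analogy: under the optimized load the interference
region carries the highest strain, so repeatedly deleting the
highest-strain ROI pixel (re-solving the shrunken structure each time)
eventually disconnects the object, exactly along its structurally weak
zone. The cut is then "repaired" — removed pixels are grown back onto
the neighbouring segments — so no foreground pixel is lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import Config
from .fem_core import assemble, solve
from .grid_model import (
    ForegroundSet,
    PixelImage,
    RoiMask,
    build_node_map,
    extract_foreground,
    material_from_image,
)
from .load_optimizer import (
    LoadVector,
    boundary_geometry,
    initial_load,
    optimize_load,
    restrict_support,
)
from .strain_field import compute_strain_field

logger = logging.getLogger(__name__)

__all__ = [
    "DestructionError",
    "DestructionState",
    "RoiRecord",
    "WeaknessRanking",
    "SegmentationResult",
    "destruction_loop",
    "repair",
    "rank_rois",
    "segment",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


class DestructionError(RuntimeError):
    """Destruction failed; carries the partial state for inspection."""

    def __init__(self, message: str, state: "DestructionState | None" = None):
        super().__init__(message)
        self.state = state


@dataclass
class DestructionState:
    """Outcome of one ROI's destruction pass."""

    foreground: ForegroundSet  # domain after removals (ROI's component only)
    removed: list  # (j, i) pixels in removal order
    strains_at_removal: list  # eps_vM of each removed pixel when removed
    iterations: int
    halting_cause: str


@dataclass
class RoiRecord:
    """Audit record for one ROI."""

    roi_id: str
    phi_star: float
    area: int
    weakness: float
    skipped: bool = False
    removed: list = field(default_factory=list)
    iterations: int = 0
    halting_cause: str = ""
    stationary: bool = False


@dataclass
class WeaknessRanking:
    """ROIs ordered by structural weakness (objective per unit area)."""

    order: list  # roi ids, weakness descending (ties by id)
    weakness: dict
    theta: float
    skipped: set

    @property
    def processed(self) -> list:
        return [r for r in self.order if r not in self.skipped]


@dataclass
class SegmentationResult:
    """Final labeling plus the per-ROI audit trail."""

    labels: np.ndarray  # 0 = background, 1..k = segments
    records: list  # RoiRecord per ROI, input order
    ranking: WeaknessRanking
    threshold: float

    @property
    def n_segments(self) -> int:
        return int(self.labels.max())


def _roi_component(mask: np.ndarray, roi_mask: np.ndarray, structure) -> np.ndarray:
    """The connected component of ``mask`` containing the ROI.

    Errors when the ROI's pixels straddle several components (the object
    is already decomposed where the cut was requested).
    """
    lab, _ = ndimage.label(mask, structure=structure)
    roi_labels = np.unique(lab[roi_mask & mask])
    roi_labels = roi_labels[roi_labels > 0]
    if len(roi_labels) == 0:
        raise DestructionError("ROI contains no remaining structure")
    if len(roi_labels) > 1:
        raise DestructionError("foreground is already decomposed across the ROI")
    return lab == roi_labels[0]


def destruction_loop(
    image: PixelImage,
    fg: ForegroundSet,
    roi: RoiMask,
    load: LoadVector,
    config: Config,
    max_removals: int | None = None,
    v_max: float | None = None,
) -> DestructionState:
    """Iteratively remove the highest-strain ROI pixel until decomposition.

    Each iteration reassembles the pixel FEM on the current foreground
    of the ROI's component, re-applies the optimized load (entries whose
    nodes vanished are dropped and the load renormalized), solves,
    and removes the ROI pixel with maximal von Mises strain. Halts when
    the component decomposes; hitting ``max_removals`` (default
    ``max_removals_factor`` times the ROI area) without decomposition is
    an error.
    """
    structure = _structure(config.connectivity)
    domain = _roi_component(fg.mask, roi.mask, structure)
    if max_removals is None:
        max_removals = int(np.ceil(config.max_removals_factor * roi.area))
    if v_max is None:
        jj, ii = np.nonzero(fg.mask)
        v_max = float(image.values[jj, ii].max())

    removed: list = []
    strains: list = []
    state = DestructionState(
        ForegroundSet(domain, fg.threshold), removed, strains, 0, ""
    )
    for it in range(1, max_removals + 1):
        sub = ForegroundSet(domain, fg.threshold)
        nm = build_node_map(sub)
        mat = material_from_image(
            image, sub, nm, config.e0, config.poisson_ratio, v_max=v_max
        )
        system = assemble(
            mat, nm, config.spring_factor, config.plane, config.solver_cutoff
        )
        # Carry load entries to the current numbering by lattice position.
        ii = load.positions[:, 0].astype(int)
        jj = load.positions[:, 1].astype(int)
        ids = nm.node_index[jj, ii]
        alive = ids >= 0
        if not alive.any():
            raise DestructionError("all load nodes were destroyed", state)
        s = load.magnitudes[alive]
        s = s / np.linalg.norm(s)
        f = np.zeros(system.n_dofs)
        f[2 * ids[alive]] = s * load.normals[alive, 0]
        f[2 * ids[alive] + 1] = s * load.normals[alive, 1]

        u = solve(system, f)
        sf = compute_strain_field(system, u, config.von_mises_convention)
        ej, ei = nm.element_pixels.T
        in_roi = roi.mask[ej, ei]
        if not in_roi.any():
            raise DestructionError("ROI exhausted before decomposition", state)
        roi_idx = np.nonzero(in_roi)[0]
        pick = roi_idx[int(np.argmax(sf.von_mises[roi_idx]))]
        pj, pi = nm.element_pixels[pick]
        domain = domain.copy()
        domain[pj, pi] = False
        removed.append((int(pj), int(pi)))
        strains.append(float(sf.von_mises[pick]))
        state.foreground = ForegroundSet(domain, fg.threshold)
        state.iterations = it
        _, n_comp = ndimage.label(domain, structure=structure)
        if n_comp > 1:
            state.halting_cause = "decomposed"
            logger.info(
                "ROI %r decomposed after %d removals", roi.id, it
            )
            return state
    state.halting_cause = "max_removals"
    raise DestructionError(
        f"ROI {roi.id!r} did not break within {max_removals} removals", state
    )


def repair(
    fg_after: np.ndarray, removed: list, connectivity: int = 4
) -> np.ndarray:
    """Label surviving components and grow them back over removed pixels.

    Components are numbered 1..k largest first (ties by scan order).
    Removed pixels are reassigned by simultaneous multi-source BFS
    restricted to the removed set; a removed pixel no front can reach is
    attached to the component with the nearest centroid.
    """
    structure = _structure(connectivity)
    lab, n = ndimage.label(fg_after, structure=structure)
    if n == 0 and not removed:
        return np.zeros_like(lab)
    # Relabel largest-first, deterministic on ties via first occurrence.
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable") + 1
    relabel = np.zeros(n + 1, dtype=lab.dtype)
    relabel[order] = np.arange(1, n + 1)
    labels = relabel[lab]

    if removed:
        rem = np.zeros_like(fg_after, dtype=bool)
        rj, ri = np.array(removed).T
        rem[rj, ri] = True
        big = np.iinfo(np.int64).max
        while True:
            pending = rem & (labels == 0)
            if not pending.any():
                break
            neigh = np.full(labels.shape, big, dtype=np.int64)
            l = np.where(labels > 0, labels.astype(np.int64), big)
            neigh[1:, :] = np.minimum(neigh[1:, :], l[:-1, :])
            neigh[:-1, :] = np.minimum(neigh[:-1, :], l[1:, :])
            neigh[:, 1:] = np.minimum(neigh[:, 1:], l[:, :-1])
            neigh[:, :-1] = np.minimum(neigh[:, :-1], l[:, 1:])
            newly = pending & (neigh < big)
            if not newly.any():
                # Isolated leftovers: nearest component centroid.
                centroids = ndimage.center_of_mass(
                    labels > 0, labels, index=np.arange(1, labels.max() + 1)
                )
                centroids = np.array(centroids)  # (k, 2) as (j, i)
                pj, pi = np.nonzero(pending)
                d = (centroids[:, 0][:, None] - (pj + 0.5)) ** 2 + (
                    centroids[:, 1][:, None] - (pi + 0.5)
                ) ** 2
                labels[pj, pi] = np.argmin(d, axis=0) + 1
                logger.warning(
                    "%d removed pixels unreachable by region growing; "
                    "assigned to nearest component",
                    len(pj),
                )
                break
            labels[newly] = neigh[newly]
    return labels


def rank_rois(
    roi_ids: list, objectives: list, areas: list, theta: float = 0.1
) -> WeaknessRanking:
    """Order ROIs by weakness = Phi*/area; mark doubtful ones skipped.

    An ROI drawn over solid material cannot concentrate much strain, so
    its weakness score is far below a genuine interference region's;
    anything under ``theta`` times the maximum is skipped.
    """
    if not roi_ids:
        raise ValueError("no ROIs to rank")
    weakness = {
        r: float(p) / float(a) for r, p, a in zip(roi_ids, objectives, areas)
    }
    order = sorted(roi_ids, key=lambda r: (-weakness[r], r))
    w_max = weakness[order[0]]
    skipped = {r for r in roi_ids if weakness[r] < theta * w_max}
    if len(skipped) == len(roi_ids):
        raise ValueError("no credible interference region among the ROIs")
    return WeaknessRanking(order, weakness, theta, skipped)


def segment(
    image: PixelImage, roi_masks: list, config: Config | None = None
) -> SegmentationResult:
    """Full pipeline: threshold, optimize loads, rank ROIs, destroy, repair.

    ``roi_masks`` may be raw boolean arrays or RoiMask instances. Every
    original foreground pixel ends up with a nonzero label; the number
    of labels is 1 plus the number of non-skipped ROIs when every
    destruction pass decomposes its component.
    """
    cfg = config or Config()
    fg0 = extract_foreground(image, cfg.threshold)
    nm0 = build_node_map(fg0)
    mat0 = material_from_image(image, fg0, nm0, cfg.e0, cfg.poisson_ratio)
    system0 = assemble(
        mat0, nm0, cfg.spring_factor, cfg.plane, cfg.solver_cutoff
    )
    geom0 = boundary_geometry(fg0, image, nm0)

    rois = []
    for k, rm in enumerate(roi_masks):
        if isinstance(rm, RoiMask):
            rois.append(RoiMask.from_raw(rm.mask, fg0, rm.id))
        else:
            rois.append(RoiMask.from_raw(np.asarray(rm), fg0, f"roi{k}"))

    records: dict[str, RoiRecord] = {}
    loads: dict[str, LoadVector] = {}
    for roi in rois:
        try:
            support = restrict_support(geom0, roi, margin=1)
            f0 = initial_load(support)
            f_star, trace = optimize_load(
                system0,
                roi,
                f0,
                max_iter=cfg.max_iter,
                rtol=cfg.opt_rtol,
                armijo_c=cfg.armijo_c,
                backtrack=cfg.armijo_backtrack,
                convention=cfg.von_mises_convention,
            )
        except Exception as exc:
            raise RuntimeError(f"ROI {roi.id!r}: load optimization failed") from exc
        acc = trace.accepted_objectives
        phi_star = max(acc) if acc else trace.initial_objective
        loads[roi.id] = f_star
        records[roi.id] = RoiRecord(
            roi_id=roi.id,
            phi_star=phi_star,
            area=roi.area,
            weakness=phi_star / roi.area,
            stationary=trace.stationary,
        )

    ranking = rank_rois(
        [r.id for r in rois],
        [records[r.id].phi_star for r in rois],
        [records[r.id].area for r in rois],
        theta=cfg.skip_theta,
    )
    for rid in ranking.skipped:
        records[rid].skipped = True
        records[rid].halting_cause = "skipped"
        logger.info("ROI %r skipped as doubtful (weakness %.3g)", rid, ranking.weakness[rid])

    roi_by_id = {r.id: r for r in rois}
    current = fg0.copy()
    removed_all: list = []
    for rid in ranking.processed:
        roi = roi_by_id[rid]
        try:
            state = destruction_loop(image, current, roi, loads[rid], cfg)
        except DestructionError as exc:
            raise DestructionError(f"ROI {rid!r}: {exc}", exc.state) from exc
        for (pj, pi) in state.removed:
            current.remove((pj, pi))
        removed_all.extend(state.removed)
        rec = records[rid]
        rec.removed = list(state.removed)
        rec.iterations = state.iterations
        rec.halting_cause = state.halting_cause

    labels = repair(current.mask, removed_all, cfg.connectivity)
    assert int((labels > 0).sum()) == fg0.count  # conservation of foreground
    return SegmentationResult(
        labels, [records[r.id] for r in rois], ranking, cfg.threshold
    )
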
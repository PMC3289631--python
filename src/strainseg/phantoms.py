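"""Synthetic test objects with known weak regions and ground truth.

The phantoms emulate the geometry this method targets: dense regions
(bone analogs) joined by a thin, fainter interference region (joint /
cartilage analog), with high aspect ratio around the neck. Intensity
noise is Gaussian, applied to structure pixels and truncated below so
that thresholding at the phantom's stated threshold recovers the
designed geometry exactly (a speckled neck would change the topology
of the test object, not just its intensities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_model import PixelImage

__all__ = ["PhantomSpec", "Phantom", "generate", "label_agreement"]

KINDS = ("dumbbell", "chain", "decoy_chain", "knee_like")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom.

    Intensities are 8-bit-like: dense blocks at 200, the interference
    neck at 60, thresholded at 50 — a conservative threshold well below
    the neck so faint structure is kept, as one would set it on a real
    CT slice. The cube law then makes the neck ~27x softer than the
    blocks. ``noise_sigma`` is the Gaussian noise level in intensity
    units (10 = 5% of the block intensity).
    """

    kind: str = "dumbbell"
    block_size: int = 20
    neck_width: int = 2
    neck_length: int = 6
    block_intensity: float = 200.0
    neck_intensity: float = 60.0
    noise_sigma: float = 0.0
    seed: int = 0
    margin: int = 4
    roi_margin: int = 2
    threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not (self.threshold < self.neck_intensity < self.block_intensity):
            raise ValueError(
                "need threshold < neck intensity < block intensity"
            )
        if self.neck_width < 1 or self.neck_length < 1:
            raise ValueError("neck must be at least 1x1 pixels")
        if self.block_size < self.neck_width + 2:
            raise ValueError("geometry too small to contain a neck")
        if self.margin < 1 or self.roi_margin < 0:
            raise ValueError("margins must be non-negative (outer margin >= 1)")


@dataclass(frozen=True)
class Phantom:
    """Generated image with its ROIs and ground truth."""

    image: PixelImage
    rois: list  # raw boolean masks, may spill outside the foreground
    truth: np.ndarray  # 0 = background, 1..k = true segments
    roi_is_real: list  # per ROI: does it cover a genuine interference region
    spec: PhantomSpec

    @property
    def threshold(self) -> float:
        return self.spec.threshold


def _blocks_and_necks(spec: PhantomSpec, n_blocks: int):
    """Geometry of an n-block chain joined by (n-1) necks; returns
    (base image array, list of neck slices, list of block slices)."""
    b, m, nl, nw = spec.block_size, spec.margin, spec.neck_length, spec.neck_width
    h = b + 2 * m
    w = n_blocks * b + (n_blocks - 1) * nl + 2 * m
    img = np.zeros((h, w))
    j0 = m + (b - nw) // 2
    blocks, necks = [], []
    x = m
    for k in range(n_blocks):
        blocks.append((slice(m, m + b), slice(x, x + b)))
        img[blocks[-1]] = spec.block_intensity
        if k < n_blocks - 1:
            necks.append((slice(j0, j0 + nw), slice(x + b, x + b + nl)))
            img[necks[-1]] = spec.neck_intensity
        x += b + nl
    return img, necks, blocks


def _roi_around(neck, shape, pad: int) -> np.ndarray:
    roi = np.zeros(shape, dtype=bool)
    js, is_ = neck
    roi[
        max(js.start - pad, 0) : min(js.stop + pad, shape[0]),
        max(is_.start - pad, 0) : min(is_.stop + pad, shape[1]),
    ] = True
    return roi


def _chain_truth(img, necks, blocks) -> np.ndarray:
    truth = np.zeros(img.shape, dtype=np.int64)
    for k, blk in enumerate(blocks, start=1):
        truth[blk] = k
    for k, (js, is_) in enumerate(necks, start=1):
        mid = (is_.start + is_.stop) // 2
        truth[js, is_.start : mid] = k
        truth[js, mid : is_.stop] = k + 1
    return truth


def _apply_noise(img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.noise_sigma == 0:
        return img
    rng = np.random.default_rng(spec.seed)
    fg = img > 0
    noisy = img.copy()
    noisy[fg] += rng.normal(0.0, spec.noise_sigma, size=int(fg.sum()))
    # Truncate so the designed geometry survives thresholding; clip at 0.
    noisy[fg] = np.maximum(noisy[fg], spec.threshold + 1.0)
    return np.clip(noisy, 0.0, None)


def generate(spec: PhantomSpec) -> Phantom:
    """Build the phantom named by ``spec.kind``; same seed, same output."""
    if spec.kind == "dumbbell":
        img, necks, blocks = _blocks_and_necks(spec, 2)
        rois = [_roi_around(necks[0], img.shape, spec.roi_margin)]
        truth = _chain_truth(img, necks, blocks)
        real = [True]
    elif spec.kind in ("chain", "decoy_chain"):
        img, necks, blocks = _blocks_and_necks(spec, 3)
        rois = [_roi_around(n, img.shape, spec.roi_margin) for n in necks]
        truth = _chain_truth(img, necks, blocks)
        real = [True, True]
        if spec.kind == "decoy_chain":
            # Decoy ROI over solid material: same footprint as a neck ROI,
            # centered in the middle block's interior.
            js, is_ = blocks[1]
            cj = (js.start + js.stop) // 2
            ci = (is_.start + is_.stop) // 2
            hh = (spec.neck_width + 2 * spec.roi_margin) // 2 + 1
            hw = (spec.neck_length + 2 * spec.roi_margin) // 2 + 1
            decoy = np.zeros(img.shape, dtype=bool)
            decoy[cj - hh : cj + hh, ci - hw : ci + hw] = True
            rois.append(decoy)
            real.append(False)
    elif spec.kind == "knee_like":
        img, rois, truth, real = _knee_like(spec)
    else:  # pragma: no cover - guarded by PhantomSpec
        raise ValueError(spec.kind)
    img = _apply_noise(img, spec)
    return Phantom(PixelImage(img), rois, truth, real, spec)


def _knee_like(spec: PhantomSpec):
    """Two rounded condyle-like blobs bridged by a thin soft band."""
    r = spec.block_size // 2
    m = spec.margin
    gap = spec.neck_length
    h = 4 * r + gap + 2 * m
    w = 2 * r + 2 * m
    img = np.zeros((h, w))
    cx = w / 2
    cy_bot = m + r
    cy_top = m + 3 * r + gap
    jj, ii = np.mgrid[0:h, 0:w]
    bot = (ii + 0.5 - cx) ** 2 + (jj + 0.5 - cy_bot) ** 2 <= r**2
    top = (ii + 0.5 - cx) ** 2 + (jj + 0.5 - cy_top) ** 2 <= r**2
    img[bot] = spec.block_intensity
    img[top] = spec.block_intensity
    nw = max(spec.neck_width, 1)
    band = (
        (jj >= cy_bot + r - 1)
        & (jj < cy_top - r + 1)
        & (np.abs(ii + 0.5 - cx) <= nw / 2)
    )
    img[band] = spec.neck_intensity
    mid = (cy_bot + r - 1 + cy_top - r + 1) / 2
    truth = np.zeros(img.shape, dtype=np.int64)
    truth[bot | (band & (jj < mid))] = 1
    truth[top | (band & (jj >= mid))] = 2
    roi = np.zeros(img.shape, dtype=bool)
    roi[
        int(cy_bot + r - 1 - spec.roi_margin) : int(cy_top - r + 1 + spec.roi_margin),
        int(cx - nw / 2 - spec.roi_margin) : int(np.ceil(cx + nw / 2 + spec.roi_margin)),
    ] = True
    return img, [roi], truth, [True]


def label_agreement(pred: np.ndarray, truth: np.ndarray) -> float:
    """Per-pixel agreement after greedy label matching by overlap.

    Label numbering is an arbitrary convention on both sides, so truth
    labels are greedily matched to distinct predicted labels by maximal
    overlap (largest truth region first); the score is the matched pixel
    fraction over the truth foreground.
    """
    pred = np.asarray(pred).astype(np.int64)
    truth = np.asarray(truth).astype(np.int64)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    t_labels = [int(t) for t in np.unique(truth) if t > 0]
    total = int((truth > 0).sum())
    if total == 0:
        raise ValueError("empty ground truth")
    t_labels.sort(key=lambda t: -int((truth == t).sum()))
    used: set = set()
    matched = 0
    for t in t_labels:
        region = truth == t
        cand = pred[region]
        counts = np.bincount(cand[cand > 0])
        for p in used:
            if p < len(counts):
                counts[p] = 0
        if counts.size and counts.max() > 0:
            p = int(np.argmax(counts))
            used.add(p)
            matched += int(counts[p])
    return matched / total
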
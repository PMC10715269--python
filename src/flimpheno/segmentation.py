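"""Single-cell segmentation from NAD(P)H intensity images.

Cells are detected on the smoothed intensity image (Gaussian blur, Otsu
threshold, hole filling so the dark nuclei stay inside their cells), touching
cells are split by a distance-transform watershed seeded at local maxima, and
nuclei are recovered per cell as the dominant dark interior region.  The
mitochondrial proxy mask marks the brightest 20% of each cell's cytoplasm
pixels.  Edge-touching cells are discarded so every retained cell has a
complete bounding box.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import clear_border, watershed
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)


@dataclass
class SegmentationLabels:
    """Integer label maps sharing one cell-id space.

    ``cells`` is 0 for background; ``nuclei`` and ``cytoplasm`` carry the same
    ids; ``mitochondria`` is a boolean mask inside cytoplasm.  ``bboxes`` maps
    cell id to (row0, col0, row1, col1), 0-based half-open.
    """

    cells: np.ndarray
    nuclei: np.ndarray
    cytoplasm: np.ndarray
    mitochondria: np.ndarray = None
    bboxes: dict = field(default_factory=dict)

    @property
    def cell_ids(self):
        ids = np.unique(self.cells)
        return ids[ids > 0]


def segment_cells(nadh_intensity: np.ndarray, smooth_sigma: float = 2.0,
                  min_area: int = 80, min_seed_distance: int = 8,
                  discard_edge: bool = True) -> SegmentationLabels:
    """Segment cells, nuclei and cytoplasm from an NAD(P)H intensity image."""
    img = np.asarray(nadh_intensity, dtype=float)
    if img.ndim != 2:
        raise ValueError("intensity image must be 2-D")
    if np.any(img < 0):
        raise ValueError("intensity image must be nonnegative")
    empty = lambda: SegmentationLabels(
        cells=np.zeros(img.shape, np.int32),
        nuclei=np.zeros(img.shape, np.int32),
        cytoplasm=np.zeros(img.shape, np.int32),
        mitochondria=np.zeros(img.shape, bool))
    if img.max() <= 0 or np.ptp(img) == 0:
        return empty()

    sm = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    fg = sm > threshold_otsu(sm)
    fg = ndimage.binary_fill_holes(fg)        # keep dark nuclei inside cells
    lab = cc_label(fg)
    sizes = np.bincount(lab.ravel())
    fg = sizes[lab] >= min_area
    fg &= lab > 0
    if not fg.any():
        return empty()

    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_seed_distance, labels=fg,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers = cc_label(fg)
    cells = watershed(-dist, markers, mask=fg).astype(np.int32)

    # drop small fragments and (optionally) edge-touching cells, relabel 1..n
    if discard_edge:
        cells = clear_border(cells)
    keep = [p.label for p in regionprops(cells) if p.area >= min_area]
    relabeled = np.zeros_like(cells)
    for new_id, old in enumerate(sorted(keep), start=1):
        relabeled[cells == old] = new_id
    cells = relabeled

    nuclei = np.zeros_like(cells)
    bboxes = {}
    for p in regionprops(cells):
        cid = p.label
        r0, c0, r1, c1 = p.bbox
        bboxes[cid] = (int(r0), int(c0), int(r1), int(c1))
        mask = cells == cid
        vals = sm[mask]
        # nucleus = dominant dark region inside the cell (Otsu within cell)
        try:
            t = threshold_otsu(vals)
        except ValueError:
            continue
        dark = mask & (sm < t)
        if not dark.any():
            continue
        lab = cc_label(dark)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        big = int(np.argmax(sizes))
        if sizes[big] >= 9:  # ignore speckle-sized dark patches
            nuclei[lab == big] = cid
    cytoplasm = np.where((cells > 0) & (nuclei == 0), cells, 0).astype(np.int32)

    logger.info("segment_cells: %d cells", len(bboxes))
    return SegmentationLabels(cells=cells, nuclei=nuclei, cytoplasm=cytoplasm,
                              mitochondria=np.zeros(img.shape, bool),
                              bboxes=bboxes)


def mitochondria_mask(labels: SegmentationLabels,
                      nadh_intensity: np.ndarray) -> SegmentationLabels:
    """Mark the brightest ceil(20%) of each cell's cytoplasm pixels.

    Ties are broken deterministically in row-major pixel order.  The remaining
    cytoplasm pixels form the cytosol compartment.  Returns the same labels
    object with ``mitochondria`` filled in.
    """
    img = np.asarray(nadh_intensity, dtype=float)
    if img.shape != labels.cells.shape:
        raise ValueError("intensity and label geometry differ")
    mito = np.zeros(img.shape, dtype=bool)
    flat_int = img.ravel()
    for cid in labels.cell_ids:
        cyto_flat = np.flatnonzero(labels.cytoplasm.ravel() == cid)
        if cyto_flat.size == 0:
            warnings.warn(f"cell {cid} has empty cytoplasm; empty mito mask",
                          stacklevel=2)
            continue
        k = math.ceil(0.20 * cyto_flat.size)
        # stable sort on descending intensity keeps row-major order for ties
        order = np.argsort(-flat_int[cyto_flat], kind="stable")
        chosen = cyto_flat[order[:k]]
        mito.ravel()[chosen] = True
    labels.mitochondria = mito
    return labels


def match_to_truth(labels: SegmentationLabels, true_cell_ids: np.ndarray,
                   iou_threshold: float = 0.7) -> dict:
    """Greedy one-to-one matching of detected cells to ground-truth cells.

    Returns {"n_true", "n_detected", "n_matched", "recall", "pairs"} where
    pairs maps true id -> (detected id, IoU).  Truth cells touching the image
    border are excluded from the denominator when the segmenter discards
    edge-touching cells.
    """
    true_ids = np.unique(true_cell_ids)
    true_ids = true_ids[true_ids > 0]
    pairs = {}
    used = set()
    for tid in true_ids:
        tmask = true_cell_ids == tid
        cand, best_iou = 0, 0.0
        for did in np.unique(labels.cells[tmask]):
            if did == 0 or did in used:
                continue
            dmask = labels.cells == did
            inter = np.logical_and(tmask, dmask).sum()
            union = np.logical_or(tmask, dmask).sum()
            iou = inter / union if union else 0.0
            if iou > best_iou:
                cand, best_iou = int(did), iou
        if cand and best_iou >= iou_threshold:
            pairs[int(tid)] = (cand, best_iou)
            used.add(cand)
    n_true = int(true_ids.size)
    return {"n_true": n_true, "n_detected": int(labels.cell_ids.size),
            "n_matched": len(pairs),
            "recall": len(pairs) / n_true if n_true else float("nan"),
            "pairs": pairs}
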
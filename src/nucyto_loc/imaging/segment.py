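"""Nucleus and cell segmentation, and per-cell compartment bookkeeping.

The scheme is deterministic and training-free: Otsu threshold + hole fill +
area filter for nuclei (from the nuclear-marker channel), then a seeded
watershed on the thresholded reporter channel to assign one cell per
nucleus.  Cytoplasm is the exact set difference cell minus nucleus.

Coordinates are 0-based ``(row, col)``; masks are sets of integer pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

logger = logging.getLogger(__name__)


def relabel_sequential_mask(labels: np.ndarray) -> np.ndarray:
    """Relabel a label image so labels form a contiguous set ``1..K``."""
    out, _, _ = relabel_sequential(np.asarray(labels))
    return out.astype(np.int32)


def segment_nuclei(nuclear_marker_frame: np.ndarray, min_area_px: int = 20) -> np.ndarray:
    """Segment nuclei from a nuclear-marker frame.

    Bright connected regions above an Otsu threshold are hole-filled,
    filtered by area and uniquely labelled.  A constant frame yields an
    empty mask with a warning rather than an error.
    """
    frame = np.asarray(nuclear_marker_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("segment_nuclei expects a 2D frame")
    if np.ptp(frame) == 0:
        logger.warning("constant nuclear-marker frame: no threshold, empty mask")
        return np.zeros(frame.shape, dtype=np.int32)
    thr = threshold_otsu(frame)
    fg = frame > thr
    fg = ndi.binary_fill_holes(fg)
    labels = cc_label(fg)
    if min_area_px > 1:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area_px)
        labels[np.isin(labels, small)] = 0
    return relabel_sequential_mask(labels)


def segment_cells(reporter_frame: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Assign one cell label per nucleus via seeded watershed.

    Foreground is the thresholded reporter frame (triangle threshold: the
    background dominates the histogram and the cytoplasm can sit far below
    a bright nucleus, which defeats Otsu); the watershed runs on the
    negated distance transform so touching cells split along the ridge
    between their nuclei.  Each cell contains its seed nucleus and
    inherits its label.
    """
    frame = np.asarray(reporter_frame, dtype=float)
    nuclei = np.asarray(nuclei)
    if frame.shape != nuclei.shape:
        raise ValueError("reporter frame and nuclei mask shapes differ")
    if nuclei.max() == 0:
        return np.zeros(frame.shape, dtype=np.int32)
    if np.ptp(frame) == 0:
        raise ValueError("constant reporter frame: no cell foreground")
    # hole-fill so a nucleus dimmer than the surrounding cytoplasm still
    # counts as cell foreground
    fg = ndi.binary_fill_holes(frame > threshold_triangle(frame))
    for lbl in np.unique(nuclei[nuclei > 0]):
        if not fg[nuclei == lbl].any():
            raise ValueError(f"nucleus seed {lbl} lies outside the reporter foreground")
    fg = fg | (nuclei > 0)
    distance = ndi.distance_transform_edt(fg)
    cells = watershed(-distance, markers=nuclei.astype(np.int32), mask=fg)
    return cells.astype(np.int32)


@dataclass
class CellCompartments:
    """Per-cell nucleus, cell and cytoplasm masks sharing one label space.

    ``nucleus_labels`` and ``cell_labels`` use the cell id for each valid
    cell; cytoplasm is always derived as the exact set difference.
    Invalid cells (empty cytoplasm, multiple nuclei, ...) are excluded
    from ``cell_ids`` and listed with a reason in ``exclusions``.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    cell_ids: list[int]
    exclusions: dict[int, str] = field(default_factory=dict)

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        return self.nucleus_labels == cell_id

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.cell_labels == cell_id

    def cytoplasm_mask(self, cell_id: int) -> np.ndarray:
        return self.cell_mask(cell_id) & ~self.nucleus_mask(cell_id)


def build_compartments(cells: np.ndarray, nuclei: np.ndarray) -> CellCompartments:
    """Pair each nucleus with the single cell containing it.

    Raises if a nucleus straddles two cells.  Cells with an empty
    cytoplasm (nucleus == cell) or with more than one nucleus are flagged
    invalid and excluded with a logged reason.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    if cells.shape != nuclei.shape:
        raise ValueError("cell and nucleus label images must share a shape")

    nucleus_out = np.zeros_like(cells, dtype=np.int32)
    nuclei_per_cell: dict[int, list[int]] = {}
    for lbl in np.unique(nuclei[nuclei > 0]):
        under = cells[nuclei == lbl]
        owners = np.unique(under[under > 0])
        if len(owners) > 1:
            raise ValueError(f"nucleus {lbl} spans cells {owners.tolist()}")
        if len(owners) == 0:
            logger.warning("nucleus %d lies in no cell; dropped", lbl)
            continue
        nuclei_per_cell.setdefault(int(owners[0]), []).append(int(lbl))

    cell_ids: list[int] = []
    exclusions: dict[int, str] = {}
    for cid in map(int, np.unique(cells[cells > 0])):
        owned = nuclei_per_cell.get(cid, [])
        if not owned:
            exclusions[cid] = "no nucleus"
        elif len(owned) > 1:
            exclusions[cid] = f"multiple nuclei ({len(owned)})"
        else:
            nuc_mask = (nuclei == owned[0]) & (cells == cid)
            cyto_area = int((cells == cid).sum() - nuc_mask.sum())
            if nuc_mask.sum() == 0:
                exclusions[cid] = "empty nucleus"
            elif cyto_area == 0:
                exclusions[cid] = "empty cytoplasm (nucleus == cell)"
            else:
                nucleus_out[nuc_mask] = cid
                cell_ids.append(cid)
    for cid, reason in exclusions.items():
        logger.info("cell %d excluded: %s", cid, reason)
    return CellCompartments(
        cell_labels=cells.astype(np.int32),
        nucleus_labels=nucleus_out,
        cell_ids=cell_ids,
        exclusions=exclusions,
    )
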
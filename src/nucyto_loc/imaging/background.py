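"""Background-level estimation."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def estimate_background(
    frame: np.ndarray,
    cells: np.ndarray | None = None,
    method: str = "outside",
    roi: np.ndarray | None = None,
    dilation_px: int = 3,
) -> float:
    """Estimate the additive background level of a frame.

    ``method="outside"`` (default): mean over pixels outside a
    ``dilation_px`` dilation of all cell masks, keeping halos out of the
    estimate.  ``method="roi"``: mean over an explicit boolean ROI.
    """
    frame = np.asarray(frame, dtype=float)
    if method == "roi":
        if roi is None:
            raise ValueError("roi method requires an explicit background ROI")
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != frame.shape:
            raise ValueError("ROI shape must match frame")
        if not roi.any():
            raise ValueError("background ROI is empty")
        return float(frame[roi].mean())
    if method != "outside":
        raise ValueError(f"unknown background method {method!r}")
    if cells is None:
        raise ValueError("outside method requires a cell label mask")
    fg = np.asarray(cells) > 0
    if dilation_px > 0:
        fg = ndi.binary_dilation(fg, iterations=dilation_px)
    outside = ~fg
    if not outside.any():
        raise ValueError("no background pixels outside dilated cells")
    return float(frame[outside].mean())
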
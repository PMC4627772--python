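"""Kymogram records and background-corrected trace extraction.

A record holds a space-by-time intensity matrix produced by repeatedly
scanning one line, plus phase bookkeeping (pre-bleach, bleach, post-bleach
line index ranges) and pixel ROIs along the line (bleach ROI, reference
region, background region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Phases:
    """Contiguous, ordered line-index ranges ``[start, stop)``."""

    pre: tuple[int, int]
    bleach: tuple[int, int]
    post: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (a, b) in (("pre", self.pre), ("bleach", self.bleach),
                             ("post", self.post)):
            if not 0 <= a < b:
                raise ValueError(f"phase {name} range {a, b} invalid")
        if self.pre[1] != self.bleach[0] or self.bleach[1] != self.post[0]:
            raise ValueError("phases must be contiguous and ordered pre/bleach/post")


def _as_roi_mask(roi, n_px: int) -> np.ndarray:
    """Accept a boolean mask or a (start, stop) pixel range."""
    if isinstance(roi, tuple) and len(roi) == 2 and np.isscalar(roi[0]):
        mask = np.zeros(n_px, dtype=bool)
        mask[int(roi[0]): int(roi[1])] = True
        return mask
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != (n_px,):
        raise ValueError("ROI mask length must equal the line length")
    return mask


@dataclass
class FRAPRecord:
    """Line-scan kymogram with phase and ROI bookkeeping.

    ``kymogram`` has shape ``(line_len_px, n_lines)`` (space along the
    line x time).  ``rois`` maps ``"bleach"``, ``"reference"`` and
    ``"background"`` to boolean masks over line pixels (tuples
    ``(start, stop)`` are also accepted).
    """

    kymogram: np.ndarray
    line_interval_s: float
    phases: Phases
    rois: dict[str, np.ndarray]
    pixel_size_um: float = 0.048

    def __post_init__(self) -> None:
        self.kymogram = np.asarray(self.kymogram, dtype=float)
        if self.kymogram.ndim != 2:
            raise ValueError("kymogram must be 2D (space x time)")
        n_px, n_lines = self.kymogram.shape
        if self.line_interval_s <= 0:
            raise ValueError("line_interval_s must be > 0")
        if self.phases.post[1] > n_lines:
            raise ValueError("phases extend past the kymogram")
        rois = {name: _as_roi_mask(m, n_px) for name, m in self.rois.items()}
        for name in ("bleach", "reference", "background"):
            if name not in rois:
                raise ValueError(f"missing ROI {name!r}")
            if not rois[name].any():
                raise ValueError(f"ROI {name!r} is empty")
        if (rois["bleach"] & rois["background"]).any():
            raise ValueError("bleach ROI and background region must be disjoint")
        if (rois["bleach"] & rois["reference"]).any():
            raise ValueError("reference region must exclude the bleach ROI")
        self.rois = rois

    @property
    def n_lines(self) -> int:
        return self.kymogram.shape[1]

    @property
    def line_times_s(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.line_interval_s


@dataclass
class Traces:
    """Background-corrected per-line intensities."""

    t_s: np.ndarray
    i_frap: np.ndarray
    i_ref: np.ndarray
    in_bleach_phase: np.ndarray  # bool per line; excluded from fitting
    negative_flagged: np.ndarray  # bool per line: corrected intensity < 0


def extract_traces(record: FRAPRecord) -> Traces:
    """Mean bleach-ROI and reference traces, background-corrected per line.

    Every line's background-region mean is subtracted from that same
    line's ROI means.  Lines acquired during the bleach phase are flagged
    so downstream normalization/fitting can exclude them; lines where the
    background exceeds an ROI mean are flagged, not dropped.
    """
    k = record.kymogram
    bg = k[record.rois["background"], :].mean(axis=0)
    i_frap = k[record.rois["bleach"], :].mean(axis=0) - bg
    i_ref = k[record.rois["reference"], :].mean(axis=0) - bg
    in_bleach = np.zeros(record.n_lines, dtype=bool)
    in_bleach[record.phases.bleach[0]: record.phases.bleach[1]] = True
    negative = (i_frap < 0) | (i_ref < 0)
    if negative.any():
        logger.warning("%d lines have background above ROI mean", int(negative.sum()))
    return Traces(
        t_s=record.line_times_s,
        i_frap=i_frap,
        i_ref=i_ref,
        in_bleach_phase=in_bleach,
        negative_flagged=negative,
    )
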
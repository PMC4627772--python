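"""Per-cell nucleo-cytoplasmic concentration index (CI).

    CI = (F_nuc - BG) / (F_cyto - BG)

where F_nuc and F_cyto are mean reporter intensities over the nucleus and
cytoplasm masks and BG is the background level.  The cytoplasmic mean is
computed by subtracting the nuclear intensity sum from the whole-cell sum
and dividing by the area difference, which equals the cytoplasm-mask mean
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..imaging.segment import CellCompartments
from ..imaging.stack import ImageStack

logger = logging.getLogger(__name__)

#: default denominator guard, as a fraction of the intensity range
DEFAULT_EPSILON_FRACTION = 1e-6


@dataclass
class CIMeasurement:
    cell_id: int
    time_s: float
    f_nuc: float
    f_cyto: float
    bg: float
    ci: float
    valid: bool
    reason: str = ""


def compute_ci(f_nuc: float, f_cyto: float, bg: float,
               epsilon: float = 1e-6) -> float:
    """Background-corrected nuclear/cytoplasmic intensity ratio.

    Returns NaN when the corrected cytoplasmic intensity is at or below
    ``epsilon`` (the measurement is invalid, never silently dropped).
    """
    denom = f_cyto - bg
    if not denom > epsilon:
        return float("nan")
    return (f_nuc - bg) / denom


def measure_frame(
    frame: np.ndarray,
    compartments: CellCompartments,
    bg: float,
    time_s: float = 0.0,
    epsilon: float | None = None,
) -> list[CIMeasurement]:
    """Measure CI for every valid cell of one reporter frame."""
    frame = np.asarray(frame, dtype=float)
    if epsilon is None:
        rng = float(np.ptp(frame))
        epsilon = DEFAULT_EPSILON_FRACTION * rng if rng > 0 else 1e-6
    out = []
    for cid in compartments.cell_ids:
        nuc = compartments.nucleus_mask(cid)
        cell = compartments.cell_mask(cid)
        nuc_sum = float(frame[nuc].sum())
        nuc_area = int(nuc.sum())
        cell_sum = float(frame[cell].sum())
        cell_area = int(cell.sum())
        f_nuc = nuc_sum / nuc_area
        f_cyto = (cell_sum - nuc_sum) / (cell_area - nuc_area)
        ci = compute_ci(f_nuc, f_cyto, bg, epsilon)
        valid = bool(np.isfinite(ci))
        if not valid:
            logger.info("cell %d at t=%.1fs: denominator <= epsilon, CI invalid",
                        cid, time_s)
        out.append(CIMeasurement(
            cell_id=cid, time_s=time_s, f_nuc=f_nuc, f_cyto=f_cyto,
            bg=bg, ci=ci, valid=valid,
            reason="" if valid else "denominator <= epsilon",
        ))
    return out


def track_timelapse(
    stack: ImageStack,
    compartments_per_frame: list[CellCompartments],
    backgrounds: list[float] | float,
) -> pd.DataFrame:
    """Per-cell CI time series over a stack with linked per-frame labels.

    ``compartments_per_frame`` must use consistent (already linked) cell
    ids across frames.  Cells absent from a frame are recorded as missing
    rows (``valid=False``, NaN intensities), never interpolated.
    """
    if len(compartments_per_frame) != stack.n_frames:
        raise ValueError("need one CellCompartments per frame")
    if np.isscalar(backgrounds):
        backgrounds = [float(backgrounds)] * stack.n_frames
    reporter = stack.channel("reporter")
    all_ids = sorted({cid for comp in compartments_per_frame
                      for cid in comp.cell_ids})
    if not all_ids:
        raise ValueError("no cells tracked in any frame")
    rows = []
    for f in range(stack.n_frames):
        t = float(stack.frame_times_s[f])
        comp = compartments_per_frame[f]
        measured = {m.cell_id: m for m in
                    measure_frame(reporter[f], comp, backgrounds[f], time_s=t)}
        for cid in all_ids:
            m = measured.get(cid)
            if m is None:
                rows.append({"cell_id": cid, "frame": f, "t_s": t,
                             "f_nuc": np.nan, "f_cyto": np.nan,
                             "bg": backgrounds[f], "ci": np.nan,
                             "valid": False, "reason": "missing"})
            else:
                rows.append({"cell_id": cid, "frame": f, "t_s": t,
                             "f_nuc": m.f_nuc, "f_cyto": m.f_cyto,
                             "bg": m.bg, "ci": m.ci,
                             "valid": m.valid, "reason": m.reason})
    return pd.DataFrame(rows)
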
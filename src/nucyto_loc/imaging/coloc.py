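"""Pixel-wise two-channel colocalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ColocalizationResult:
    histogram: np.ndarray
    a_edges: np.ndarray
    b_edges: np.ndarray
    pearson_r: float
    valid: bool
    reason: str = ""


def colocalization_scatter(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 64,
) -> ColocalizationResult:
    """Joint intensity histogram and Pearson correlation of two channels.

    A constant channel makes the correlation undefined; the result is then
    flagged (``valid=False``, ``pearson_r=nan``) rather than raising.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share a shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match channels")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    hist, a_edges, b_edges = np.histogram2d(a, b, bins=bins)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ColocalizationResult(hist, a_edges, b_edges, float("nan"),
                                    valid=False, reason="constant channel")
    r = float(stats.pearsonr(a, b).statistic)
    return ColocalizationResult(hist, a_edges, b_edges, r, valid=True)
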
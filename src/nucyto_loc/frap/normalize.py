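"""Double normalization of FRAP traces.

    y(t) = (I_ref_pre / I_ref(t)) * (I_frap(t) / I_frap_pre)

with the pre-bleach means taken over the full pre-bleach phase.  The
reference term cancels acquisition bleaching; the construction makes the
result invariant under global rescaling of the whole record.  Bleach-phase
lines are excluded and t = 0 at the first post-bleach line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .record import FRAPRecord, Traces, extract_traces


@dataclass
class NormalizedRecovery:
    """Double-normalized recovery: t in seconds since first post-bleach line."""

    t: np.ndarray
    y: np.ndarray
    i_frap_pre: float
    i_ref_pre: float
    y_pre: np.ndarray  # normalized pre-bleach samples (mean 1 by construction)


def double_normalize(traces: Traces, phases) -> NormalizedRecovery:
    """Apply the double-normalization formula to extracted traces."""
    pre0, pre1 = phases.pre
    post0, post1 = phases.post
    if pre1 <= pre0:
        raise ValueError("pre-bleach phase is empty")
    i_frap_pre = float(traces.i_frap[pre0:pre1].mean())
    i_ref_pre = float(traces.i_ref[pre0:pre1].mean())
    if i_frap_pre <= 0 or i_ref_pre <= 0:
        raise ValueError("non-positive pre-bleach mean; check background ROI")

    def norm(sl: slice) -> np.ndarray:
        ref = traces.i_ref[sl]
        if np.any(ref <= 0):
            raise ValueError("reference trace non-positive at a retained line")
        return (i_ref_pre / ref) * (traces.i_frap[sl] / i_frap_pre)

    y_post = norm(slice(post0, post1))
    y_pre = norm(slice(pre0, pre1))
    t_post = traces.t_s[post0:post1] - traces.t_s[post0]
    return NormalizedRecovery(
        t=t_post,
        y=y_post,
        i_frap_pre=i_frap_pre,
        i_ref_pre=i_ref_pre,
        y_pre=y_pre,
    )


def normalize_record(record: FRAPRecord) -> NormalizedRecovery:
    """Convenience: extract traces then double-normalize."""
    return double_normalize(extract_traces(record), record.phases)
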
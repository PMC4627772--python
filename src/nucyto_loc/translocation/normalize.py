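"""Min-max normalization of CI values across an experiment batch."""

from __future__ import annotations

import numpy as np


def normalize_minmax(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Map values to [0, 1] with the batch minimum at 0 and maximum at 1.

    The pool is whatever is passed in: normalize across all cells of all
    conditions of one batch so groups stay comparable.  The ``(min, max)``
    pair is returned for traceability and must be stored with outputs.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("all values equal: min-max normalization undefined")
    return (x - lo) / (hi - lo), (lo, hi)
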
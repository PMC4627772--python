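"""Plane projections."""

from __future__ import annotations

import numpy as np


def max_project(planes: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection across z-planes.

    Parameters
    ----------
    planes
        Array with the plane axis first (default) or at ``axis``.

    Returns
    -------
    numpy.ndarray
        Per-pixel maximum across planes.
    """
    planes = np.asarray(planes)
    if planes.size == 0 or planes.shape[axis] == 0:
        raise ValueError("max_project requires at least one plane")
    return planes.max(axis=axis)
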
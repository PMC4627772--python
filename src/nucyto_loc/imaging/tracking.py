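"""Frame-to-frame label linking by nearest centroid.

Segmentation runs per frame; identities are carried across frames by
matching centroids within a maximum displacement.  Ties are broken by
smallest distance, then lowest existing track id.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def _centroids(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return {}
    cents = ndi.center_of_mass(labels > 0, labels, ids)
    return {int(i): (float(c[0]), float(c[1])) for i, c in zip(ids, cents)}


def link_labels(
    previous: np.ndarray,
    current: np.ndarray,
    max_displacement_px: float = 10.0,
) -> tuple[np.ndarray, dict[int, int]]:
    """Relabel ``current`` so objects keep the ids they had in ``previous``.

    Greedy matching over candidate (previous id, current label) pairs
    sorted by centroid distance (ties: lowest previous id).  Unmatched
    current objects get fresh ids above every id seen so far.

    Returns the relabelled image and the ``current label -> track id`` map.
    """
    previous = np.asarray(previous)
    current = np.asarray(current)
    prev_cents = _centroids(previous)
    curr_cents = _centroids(current)

    pairs = []
    for pid, pc in prev_cents.items():
        for cid, cc in curr_cents.items():
            d = float(np.hypot(pc[0] - cc[0], pc[1] - cc[1]))
            if d <= max_displacement_px:
                pairs.append((d, pid, cid))
    pairs.sort()

    mapping: dict[int, int] = {}
    used_prev: set[int] = set()
    for d, pid, cid in pairs:
        if pid in used_prev or cid in mapping:
            continue
        mapping[cid] = pid
        used_prev.add(pid)

    next_id = max([0, *prev_cents.keys(), *mapping.values()]) + 1
    for cid in sorted(curr_cents):
        if cid not in mapping:
            mapping[cid] = next_id
            next_id += 1

    out = np.zeros_like(current, dtype=np.int32)
    for cid, tid in mapping.items():
        out[current == cid] = tid
    return out, mapping
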
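"""Multi-channel, multi-frame image stacks with physical calibration.

Stacks are stored as ``(frame, channel, y, x)`` float arrays.  On disk they
are multi-page TIFFs with one page per frame per channel (frame-major page
order) and a JSON metadata block in the ImageDescription tag carrying the
channel-role mapping, pixel size and frame times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

REQUIRED_ROLES = ("reporter", "nuclear_marker")


@dataclass
class ImageStack:
    """Time-lapse intensity data over ``(frame, channel, y, x)``.

    Parameters
    ----------
    intensities
        Non-negative, finite array of shape ``(T, C, Y, X)``.
    channel_roles
        Mapping from role name (``"reporter"``, ``"nuclear_marker"``) to
        channel index.
    pixel_size_um
        Physical pixel size in micrometres.
    frame_times_s
        Strictly increasing acquisition times, one per frame.
    """

    intensities: np.ndarray
    channel_roles: dict[str, int]
    pixel_size_um: float
    frame_times_s: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"intensities must be (frame, channel, y, x); got shape "
                f"{self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if not self.channel_roles:
            raise ValueError(
                "channel_roles is required; supply a mapping such as "
                "{'reporter': 0, 'nuclear_marker': 1}"
            )
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < self.intensities.shape[1]:
                raise ValueError(f"channel index {idx} for role {role!r} out of range")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.intensities.shape[0], dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frame_times_s.shape != (self.intensities.shape[0],):
            raise ValueError("frame_times_s length must match frame axis")
        if len(self.frame_times_s) > 1 and np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(frame, y, x)`` sub-stack for a channel role."""
        if role not in self.channel_roles:
            raise KeyError(f"unknown channel role {role!r}; have {sorted(self.channel_roles)}")
        return self.intensities[:, self.channel_roles[role]]

    def frame(self, index: int, role: str) -> np.ndarray:
        return self.channel(role)[index]


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF (frame-major page order).

    Metadata (channel roles, pixel size, frame times) goes into the
    ImageDescription tag as JSON so that a round trip preserves it.
    """
    t, c, y, x = stack.shape
    # keep native float64 pages so the write -> read round trip is exact
    pages = stack.intensities.reshape(t * c, y, x)
    meta = {
        "channel_roles": stack.channel_roles,
        "pixel_size_um": stack.pixel_size_um,
        "frame_times_s": list(map(float, stack.frame_times_s)),
        "n_channels": c,
    }
    tifffile.imwrite(path, pages, description=json.dumps(meta),
                     photometric="minisblack")


def read_stack(path, channel_roles: dict[str, int] | None = None,
               pixel_size_um: float | None = None,
               frame_times_s=None) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    Metadata missing from the file must be supplied via the keyword
    arguments (sidecar-config mode); a stack without a channel-role mapping
    is rejected.
    """
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    roles = channel_roles or meta.get("channel_roles")
    if not roles:
        raise ValueError(
            "stack has no channel-role metadata; pass channel_roles explicitly"
        )
    roles = {k: int(v) for k, v in roles.items()}
    n_channels = int(meta.get("n_channels", max(roles.values()) + 1))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"unexpected TIFF layout with shape {pages.shape}")
    n_pages = pages.shape[0]
    if n_pages % n_channels:
        raise ValueError(
            f"page count {n_pages} not divisible by channel count {n_channels}"
        )
    t = n_pages // n_channels
    data = pages.reshape(t, n_channels, *pages.shape[1:])
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError("pixel_size_um missing; pass it explicitly")
    times = frame_times_s if frame_times_s is not None else meta.get("frame_times_s")
    return ImageStack(
        intensities=np.asarray(data, dtype=float),
        channel_roles=roles,
        pixel_size_um=float(px),
        frame_times_s=None if times is None else np.asarray(times, dtype=float),
    )
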
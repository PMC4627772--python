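"""Render translocation time-lapse stacks from kinetic trajectories.

Cells are concentric disks (nucleus inside cell) on a flat background.
Noiseless pixel values are ``gain * concentration + background`` inside a
compartment and ``background`` elsewhere; the nuclear-marker channel is
bright inside nuclei only.  Optical blur (Gaussian), Poisson shot noise
and additive Gaussian read noise are applied in that order, all driven by
one explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ..imaging.stack import ImageStack
from .kinetics import Trajectory


@dataclass(frozen=True)
class CellSpec:
    """One circular cell: center (row, col), radii in pixels."""

    center: tuple[float, float]
    cell_radius: float
    nucleus_radius: float

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_radius < self.cell_radius:
            raise ValueError("need 0 < nucleus_radius < cell_radius")


@dataclass
class SyntheticScene:
    cells: list[CellSpec]
    gain: float = 100.0
    background: float = 10.0
    noise: tuple[float, float] = (0.0, 0.0)  # (poisson_scale, gaussian_sd)
    blur_sigma: float = 0.0
    pixel_size_um: float = 0.5
    frame_interval_s: float = 120.0
    seed: int = 0
    shape: tuple[int, int] = (128, 128)
    marker_level: float = 1.0

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        for i, a in enumerate(self.cells):
            for b in self.cells[i + 1:]:
                d = float(np.hypot(a.center[0] - b.center[0],
                                   a.center[1] - b.center[1]))
                if d < a.cell_radius + b.cell_radius:
                    raise ValueError("cells overlap")


@dataclass
class SceneGroundTruth:
    """True per-cell concentrations, CI and masks for a rendered scene."""

    times_s: np.ndarray
    true_nuclear: np.ndarray      # (n_frames, n_cells)
    true_cytoplasmic: np.ndarray  # (n_frames, n_cells)
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    background: float
    gain: float
    cell_ids: list[int] = field(default_factory=list)

    @property
    def true_ci(self) -> np.ndarray:
        return self.true_nuclear / self.true_cytoplasmic

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell_id, frame, t_s, true_N, true_C, true_CI."""
        rows = []
        for j, cid in enumerate(self.cell_ids):
            for f, t in enumerate(self.times_s):
                rows.append({
                    "cell_id": cid, "frame": f, "t_s": float(t),
                    "true_N": float(self.true_nuclear[f, j]),
                    "true_C": float(self.true_cytoplasmic[f, j]),
                    "true_CI": float(self.true_ci[f, j]),
                })
        return pd.DataFrame(rows)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def render_timelapse(
    scene: SyntheticScene,
    trajectories: Trajectory | list[Trajectory],
) -> tuple[ImageStack, SceneGroundTruth]:
    """Render a two-channel stack (reporter + nuclear marker) plus truth.

    ``trajectories`` is either one :class:`Trajectory` shared by all cells
    or one per cell.  Identical seeds give bit-identical stacks.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories] * len(scene.cells)
    if len(trajectories) != len(scene.cells):
        raise ValueError("need one trajectory per cell (or a single shared one)")
    n_frames = len(trajectories[0])
    times = trajectories[0].times_s
    for tr in trajectories[1:]:
        if len(tr) != n_frames or not np.array_equal(tr.times_s, times):
            raise ValueError("all trajectories must share the same time grid")

    shape = scene.shape
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    cyto_masks, nuc_masks = [], []
    for i, cell in enumerate(scene.cells):
        cid = i + 1
        cmask = _disk_mask(shape, cell.center, cell.cell_radius)
        nmask = _disk_mask(shape, cell.center, cell.nucleus_radius)
        nmask &= cmask
        cell_labels[cmask] = cid
        nucleus_labels[nmask] = cid
        nuc_masks.append(nmask)
        cyto_masks.append(cmask & ~nmask)

    rng = np.random.default_rng(scene.seed)
    data = np.empty((n_frames, 2, *shape), dtype=float)
    true_n = np.empty((n_frames, len(scene.cells)))
    true_c = np.empty_like(true_n)
    poisson_scale, gaussian_sd = scene.noise
    for f in range(n_frames):
        reporter = np.full(shape, scene.background, dtype=float)
        marker = np.full(shape, scene.background, dtype=float)
        for j, tr in enumerate(trajectories):
            n_conc = tr.nuclear[f]
            c_conc = tr.cytoplasmic[f]
            true_n[f, j] = n_conc
            true_c[f, j] = c_conc
            reporter[nuc_masks[j]] = scene.gain * n_conc + scene.background
            reporter[cyto_masks[j]] = scene.gain * c_conc + scene.background
            marker[nuc_masks[j]] = scene.gain * scene.marker_level + scene.background
        for ch, img in enumerate((reporter, marker)):
            if scene.blur_sigma > 0:
                img = ndi.gaussian_filter(img, scene.blur_sigma)
            if poisson_scale > 0:
                img = rng.poisson(np.clip(img, 0, None) * poisson_scale) / poisson_scale
            if gaussian_sd > 0:
                img = img + rng.normal(0.0, gaussian_sd, size=shape)
            data[f, ch] = np.clip(img, 0.0, None)

    stack = ImageStack(
        intensities=data,
        channel_roles={"reporter": 0, "nuclear_marker": 1},
        pixel_size_um=scene.pixel_size_um,
        frame_times_s=times.copy(),
    )
    truth = SceneGroundTruth(
        times_s=times.copy(),
        true_nuclear=true_n,
        true_cytoplasmic=true_c,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        background=scene.background,
        gain=scene.gain,
        cell_ids=list(range(1, len(scene.cells) + 1)),
    )
    return stack, truth
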
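"""Simulate line-scan FRAP kymograms with known mobility ground truth.

Recovery is reaction-limited: the bleach-ROI signal follows the closed
form ``I0 + A (1 - exp(-k t))`` with ``I0 = 1 - bleach_depth`` and
``A = mobile_fraction * bleach_depth`` (pre-bleach level 1).  A slow
whole-field acquisition-bleaching decay can be imposed on all cell signal;
the double normalization is expected to cancel it.  Default phase timing:
1 s pre-bleach, 150 ms bleach, 3 s recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..frap.record import FRAPRecord, Phases


@dataclass(frozen=True)
class FRAPSimSpec:
    mobile_fraction: float
    k_true: float
    bleach_depth: float = 1.0
    pre_s: float = 1.0
    bleach_s: float = 0.15
    post_s: float = 3.0
    line_rate_hz: float = 1000.0
    line_len_px: int = 256
    acq_bleach_rate: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    # line layout (pixels): background segment, bleach ROI, guard band
    background_px: int = 32
    bleach_width_px: int = 32
    guard_px: int = 5
    background_level: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.k_true <= 0:
            raise ValueError("k_true must be > 0")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in [0, 1]")
        for name in ("pre_s", "bleach_s", "post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.line_rate_hz <= 0:
            raise ValueError("line_rate_hz must be > 0")
        cell_px = self.line_len_px - self.background_px
        if self.bleach_width_px + 2 * self.guard_px >= cell_px:
            raise ValueError("bleach ROI (plus guard) wider than the cell segment")


@dataclass
class FRAPGroundTruth:
    mobile_fraction: float
    k_true: float
    bleach_depth: float
    true_i0: float
    true_amplitude: float

    @property
    def true_plateau(self) -> float:
        return self.true_i0 + self.true_amplitude

    @property
    def true_immobile_fraction_pct(self) -> float:
        return 100.0 * (1.0 - self.true_plateau)


def simulate_frap_record(spec: FRAPSimSpec) -> tuple[FRAPRecord, FRAPGroundTruth]:
    """Build a kymogram with pre/bleach/post phases at the spec's line rate.

    Identical seeds give identical records.  Line layout: a background
    segment of ``background_px`` pixels, then the cell, with the bleach
    ROI centred in the cell and a guard band excluded from the reference.
    """
    rate = spec.line_rate_hz
    n_pre = max(1, int(round(spec.pre_s * rate)))
    n_bleach = max(1, int(round(spec.bleach_s * rate)))
    n_post = max(1, int(round(spec.post_s * rate)))
    n_lines = n_pre + n_bleach + n_post
    n_px = spec.line_len_px

    bg_mask = np.zeros(n_px, dtype=bool)
    bg_mask[: spec.background_px] = True
    cell_mask = ~bg_mask
    cell_start = spec.background_px
    mid = cell_start + (n_px - cell_start) // 2
    b0 = mid - spec.bleach_width_px // 2
    bleach_mask = np.zeros(n_px, dtype=bool)
    bleach_mask[b0: b0 + spec.bleach_width_px] = True
    guard = np.zeros(n_px, dtype=bool)
    guard[max(0, b0 - spec.guard_px): b0 + spec.bleach_width_px + spec.guard_px] = True
    ref_mask = cell_mask & ~guard

    i0 = 1.0 - spec.bleach_depth
    amp = spec.mobile_fraction * spec.bleach_depth
    times = np.arange(n_lines) / rate
    t_post0 = times[n_pre + n_bleach]

    roi_signal = np.ones(n_lines)
    roi_signal[n_pre: n_pre + n_bleach] = i0
    t_rel = times[n_pre + n_bleach:] - t_post0
    roi_signal[n_pre + n_bleach:] = i0 + amp * (1.0 - np.exp(-spec.k_true * t_rel))

    decay = np.exp(-spec.acq_bleach_rate * times)
    kymo = np.empty((n_px, n_lines))
    kymo[:] = spec.background_level
    kymo[cell_mask, :] += decay[None, :]
    kymo[bleach_mask, :] += (roi_signal - 1.0) * decay[None, :]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        kymo = kymo + rng.normal(0.0, spec.noise_sd, size=kymo.shape)

    record = FRAPRecord(
        kymogram=kymo,
        line_interval_s=1.0 / rate,
        phases=Phases(
            pre=(0, n_pre),
            bleach=(n_pre, n_pre + n_bleach),
            post=(n_pre + n_bleach, n_lines),
        ),
        rois={"bleach": bleach_mask, "reference": ref_mask,
              "background": bg_mask},
    )
    truth = FRAPGroundTruth(
        mobile_fraction=spec.mobile_fraction,
        k_true=spec.k_true,
        bleach_depth=spec.bleach_depth,
        true_i0=i0,
        true_amplitude=amp,
    )
    return record, truth
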
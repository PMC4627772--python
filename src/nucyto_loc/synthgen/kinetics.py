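"""Two-compartment nuclear import/export kinetics.

A closed first-order exchange in molecular amounts,

    dn/dt = k_in(t) * c - k_out * n,      c = total - n,

with the import rate switching from ``k_in_base`` to ``k_in_stim`` at the
stimulus time.  Concentrations are amounts divided by compartment volume
(nuclear volume = ``vol_ratio``, cytoplasmic volume = 1), so total amount
``N*Vn + C*Vc`` is conserved and, with equal effective volumes, the
steady-state concentration ratio N/C tends to ``k_in/k_out``.

Integration is fixed-step classical RK4 with the step capped at 1/20 of
the local sampling interval; segments are split exactly at the stimulus
time so the rate switch is never smeared across a step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TranslocationKinetics:
    """Rates and geometry of the stimulus-switched two-compartment model."""

    k_in_base: float
    k_in_stim: float
    k_out: float
    t_stim: float
    vol_ratio: float = 1.0
    c_total: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_in_base", "k_in_stim", "k_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vol_ratio <= 0:
            raise ValueError("vol_ratio must be > 0")
        if self.c_total <= 0:
            raise ValueError("c_total must be > 0")

    def k_in_at(self, t: float) -> float:
        return self.k_in_stim if t >= self.t_stim else self.k_in_base


@dataclass
class Trajectory:
    """Per-time nuclear and cytoplasmic concentrations."""

    times_s: np.ndarray
    nuclear: np.ndarray
    cytoplasmic: np.ndarray

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def ratio(self) -> np.ndarray:
        return self.nuclear / self.cytoplasmic


def _rk4_segment(n: float, t0: float, t1: float, k_in: float, k_out: float,
                 total: float, max_step: float) -> float:
    """Advance the nuclear amount from t0 to t1 with constant rates."""
    span = t1 - t0
    if span <= 0:
        return n
    # accuracy/stability cap: the relaxation rate is k_in + k_out, and RK4
    # is only stable for h * rate below ~2.8; stay well under that
    rate = k_in + k_out
    if rate > 0:
        max_step = min(max_step, 0.1 / rate)
    steps = max(1, int(np.ceil(span / max_step)))
    h = span / steps

    def f(x: float) -> float:
        return k_in * (total - x) - k_out * x

    for _ in range(steps):
        k1 = f(n)
        k2 = f(n + 0.5 * h * k1)
        k3 = f(n + 0.5 * h * k2)
        k4 = f(n + h * k3)
        n = n + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return n


def simulate_kinetics(kinetics: TranslocationKinetics, times) -> Trajectory:
    """Integrate the exchange model over a strictly increasing time grid.

    The initial state is the equilibrium of the pre-stimulus rates (even
    split if both rates are zero).  Mass is conserved by construction
    since only the nuclear amount is integrated.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1D sequence")
    if times[0] < 0:
        raise ValueError("times must start at >= 0")
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    total = kinetics.c_total
    rate_sum = kinetics.k_in_base + kinetics.k_out
    n = total * (kinetics.k_in_base / rate_sum) if rate_sum > 0 else total / 2.0

    intervals = np.diff(times)
    base_step = intervals.min() / 20.0 if len(intervals) else 1.0
    if base_step <= 0:
        base_step = 1e-3

    amounts = np.empty(len(times))
    amounts[0] = n
    for i in range(1, len(times)):
        t0, t1 = times[i - 1], times[i]
        ts = kinetics.t_stim
        if t0 < ts < t1:
            n = _rk4_segment(n, t0, ts, kinetics.k_in_at(t0), kinetics.k_out,
                             total, base_step)
            n = _rk4_segment(n, ts, t1, kinetics.k_in_at(ts), kinetics.k_out,
                             total, base_step)
        else:
            n = _rk4_segment(n, t0, t1, kinetics.k_in_at(t0), kinetics.k_out,
                             total, base_step)
        amounts[i] = n

    v_n = kinetics.vol_ratio
    v_c = 1.0
    nuclear = amounts / v_n
    cytoplasmic = (total - amounts) / v_c
    return Trajectory(times_s=times, nuclear=nuclear, cytoplasmic=cytoplasmic)
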
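"""One-phase exponential recovery fitting, half-life and immobile fraction.

The model is ``I(t) = I0 + A * (1 - exp(-k t))`` fitted to all post-bleach
samples by nonlinear least squares.  Derived quantities are exact
identities of the fit: ``t_half = ln 2 / k`` and
``IF% = 100 * (1 - I0 - A)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .normalize import NormalizedRecovery

logger = logging.getLogger(__name__)

#: reliability limits: fits beyond these are flagged, not rejected
MAX_RESIDUAL_SD = 0.1
MAX_PLATEAU = 1.2


def _model(t: np.ndarray, i0: float, a: float, k: float) -> np.ndarray:
    return i0 + a * (1.0 - np.exp(-k * t))


@dataclass
class RecoveryFit:
    i0: float
    a: float
    k: float
    residual_sd: float
    converged: bool
    n_points: int
    reliable: bool = True
    flags: str = ""

    @property
    def t_half_s(self) -> float:
        return float(np.log(2.0) / self.k)

    @property
    def plateau(self) -> float:
        return self.i0 + self.a

    @property
    def immobile_fraction_pct(self) -> float:
        return 100.0 * (1.0 - self.i0 - self.a)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    i0 = float(np.mean(y[:5])) if len(y) >= 5 else float(y[0])
    tail = max(1, int(round(0.1 * len(y))))
    plateau0 = float(np.mean(y[-tail:]))
    a0 = max(plateau0 - i0, 1e-6)
    # log-linear regression of (plateau0 - y) against t over its positive part
    resid = plateau0 - y
    pos = resid > 1e-9
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, _, _, _, _ = stats.linregress(t[pos], np.log(resid[pos]))
        k0 = -float(slope)
    else:
        k0 = 1.0
    k0 = float(np.clip(k0, 1e-3, 1e3))
    return i0, a0, k0


def fit_one_phase(recovery: NormalizedRecovery) -> RecoveryFit:
    """Fit ``I0 + A (1 - exp(-k t))`` to a normalized recovery.

    Initialization: I0 = mean of the first 5 samples, plateau from the
    last 10% of samples, k from a log-linear regression of the residual
    decay.  Bounds: I0 in [0, 1.2], A in [0, 1.5], k in (1e-4, 1e4).
    Non-convergence yields a flagged fit with the initial guess, never a
    silent default.
    """
    t = np.asarray(recovery.t, dtype=float)
    y = np.asarray(recovery.y, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach samples")
    if t[0] != 0:
        raise ValueError("post-bleach time axis must start at 0")
    p0 = _initial_guess(t, y)
    p0 = (
        float(np.clip(p0[0], 0.0, 1.2)),
        float(np.clip(p0[1], 0.0, 1.5)),
        float(np.clip(p0[2], 1.01e-4, 9.9e3)),
    )
    bounds = ([0.0, 0.0, 1e-4], [1.2, 1.5, 1e4])
    try:
        popt, _ = optimize.curve_fit(_model, t, y, p0=p0, bounds=bounds,
                                     maxfev=20000)
        converged = True
    except RuntimeError:
        logger.warning("recovery fit did not converge")
        popt, converged = p0, False
    i0, a, k = map(float, popt)
    resid_sd = float(np.std(y - _model(t, i0, a, k), ddof=min(3, len(y) - 1)))
    flags = []
    if not converged:
        flags.append("no-convergence")
    if resid_sd > MAX_RESIDUAL_SD:
        flags.append("high-residual")
    if i0 + a > MAX_PLATEAU:
        flags.append("over-recovery")
    return RecoveryFit(
        i0=i0, a=a, k=k,
        residual_sd=resid_sd,
        converged=converged,
        n_points=len(y),
        reliable=not flags,
        flags=",".join(flags),
    )


def immobile_fraction(fit: RecoveryFit) -> float:
    """Percent immobile fraction, ``100 * (1 - plateau)``.

    A plateau above 1 gives a negative value (over-recovery); it is
    retained and the fit carries the flag.  Unconverged fits are refused.
    """
    if not fit.converged:
        raise ValueError("immobile fraction undefined for an unconverged fit")
    value = fit.immobile_fraction_pct
    if value < 0:
        logger.warning("over-recovery: plateau %.3f > 1", fit.plateau)
    return value


def _stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class MobilityComparison:
    metric: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    p_value: float
    stars: str


def compare_mobility(
    fits_a: list[RecoveryFit], fits_b: list[RecoveryFit]
) -> dict[str, MobilityComparison]:
    """Two-tailed unpaired t-tests on half-life and immobile fraction."""
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("need at least 2 fits per group")
    out = {}
    for metric, getter in (
        ("t_half_s", lambda f: f.t_half_s),
        ("immobile_fraction_pct", lambda f: f.immobile_fraction_pct),
    ):
        a = np.array([getter(f) for f in fits_a])
        b = np.array([getter(f) for f in fits_b])
        res = stats.ttest_ind(a, b)
        out[metric] = MobilityComparison(
            metric=metric,
            mean_a=float(a.mean()), sem_a=float(stats.sem(a)),
            mean_b=float(b.mean()), sem_b=float(stats.sem(b)),
            t_statistic=float(res.statistic),
            p_value=float(res.pvalue),
            stars=_stars(float(res.pvalue)),
        )
    return out
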
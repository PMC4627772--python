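"""Stimulus-response metrics of a CI time series.

Baseline is the pre-stimulus mean, peak the post-stimulus maximum and
plateau the mean over a final window; the decline-from-peak and
above-baseline percentages are both expressed relative to the
stimulation-induced rise (peak - baseline), so they sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ResponseMetrics:
    baseline_ci: float
    peak_ci: float
    plateau_ci: float
    time_to_peak_s: float
    pct_decline_from_peak: float
    pct_above_baseline: float
    defined: bool = True
    reason: str = ""


def response_metrics_from_values(
    baseline: float, peak: float, plateau: float,
    time_to_peak_s: float = float("nan"),
) -> ResponseMetrics:
    """Metrics from already-aggregated baseline/peak/plateau CI values."""
    rise = peak - baseline
    if rise <= 0:
        return ResponseMetrics(baseline, peak, plateau, time_to_peak_s,
                               float("nan"), float("nan"),
                               defined=False, reason="no response (peak <= baseline)")
    return ResponseMetrics(
        baseline_ci=baseline,
        peak_ci=peak,
        plateau_ci=plateau,
        time_to_peak_s=time_to_peak_s,
        pct_decline_from_peak=100.0 * (peak - plateau) / rise,
        pct_above_baseline=100.0 * (plateau - baseline) / rise,
    )


def response_metrics(
    times_s,
    ci,
    t_stim_s: float,
    plateau_window_s: float,
) -> ResponseMetrics:
    """Metrics from a CI time series with a stimulus at ``t_stim_s``.

    Baseline = mean of samples before the stimulus; peak = maximum after
    it; plateau = mean over the final ``plateau_window_s`` seconds.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(ci, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and ci must be matching 1D arrays")
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    pre = t < t_stim_s
    post = ~pre
    if not pre.any() or not post.any():
        raise ValueError("series must span both sides of the stimulus")
    late = t >= t[-1] - plateau_window_s
    if not (late & post).any():
        raise ValueError("plateau window contains no post-stimulus samples")
    baseline = float(y[pre].mean())
    peak_idx = int(np.argmax(y[post]))
    peak = float(y[post][peak_idx])
    time_to_peak = float(t[post][peak_idx] - t_stim_s)
    plateau = float(y[late & post].mean())
    return response_metrics_from_values(baseline, peak, plateau, time_to_peak)
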
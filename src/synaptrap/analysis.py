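"""Ensemble summary statistics: half-saturation time, mean squared
displacement, rise times and peak open probability."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SummaryStats", "half_saturation_time", "compute_msd",
           "rise_times_and_pomax", "interpolated_crossing"]


@dataclass
class SummaryStats:
    t_half: float | None = None          # s
    msd_curve: np.ndarray | None = None  # (t, MSD) pairs
    D_fit: float | None = None           # µm²/s
    rise_10_90: float | None = None      # s
    rise_20_80: float | None = None      # s
    Po_max: float | None = None


def interpolated_crossing(time: np.ndarray, curve: np.ndarray,
                          threshold: float, *, last_before: int | None = None,
                          ) -> float | None:
    """Linearly interpolated time of an upward crossing of ``threshold``.

    By default the first crossing is returned; with ``last_before`` the
    last upward crossing at or before that sample index is used (the
    guard against early stochastic spikes when locating rise times).
    Returns None if the curve never crosses.
    """
    time = np.asarray(time, dtype=float)
    curve = np.asarray(curve, dtype=float)
    above = curve >= threshold
    ups = np.nonzero(~above[:-1] & above[1:])[0]
    if above[0]:
        ups = np.concatenate(([-1], ups))
    if last_before is not None:
        ups = ups[ups < last_before]
        if ups.size == 0:
            return None
        i = int(ups[-1])
    else:
        if ups.size == 0:
            return None
        i = int(ups[0])
    if i < 0:
        return float(time[0])
    y0, y1 = curve[i], curve[i + 1]
    if y1 == y0:
        return float(time[i + 1])
    f = (threshold - y0) / (y1 - y0)
    return float(time[i] + f * (time[i + 1] - time[i]))


def half_saturation_time(time: np.ndarray, occupied_fraction: np.ndarray,
                         ) -> float | None:
    """First time the ensemble-mean occupied-scaffold fraction crosses
    0.5, linearly interpolated between samples; None if never."""
    time = np.asarray(time, dtype=float)
    occupied_fraction = np.asarray(occupied_fraction, dtype=float)
    if time.size == 0 or time.size != occupied_fraction.size:
        raise ValueError("need matching, non-empty time and fraction arrays")
    return interpolated_crossing(time, occupied_fraction, 0.5)


def compute_msd(time: np.ndarray, trajectories: np.ndarray,
                fit_window: tuple[float, float] | None = None,
                ) -> tuple[np.ndarray, float]:
    """Ensemble MSD and a diffusion-coefficient fit.

    ``trajectories`` has shape (n_particles, n_times, 2) in nm on the
    common grid ``time`` (s).  MSD(t) is the mean over particles of the
    squared planar displacement from each particle's initial position.
    ``D_fit`` (µm²/s) is the least-squares slope of MSD(t) over
    ``fit_window`` (defaults to the full range) divided by 4.

    Returns ``(msd_curve, D_fit)`` with ``msd_curve`` an (n_times, 2)
    array of (t, MSD in nm²) pairs.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3 or traj.shape[2] != 2:
        raise ValueError("trajectories must have shape (n, n_times, 2)")
    if traj.shape[0] < 1:
        raise ValueError("need at least one trajectory")
    time = np.asarray(time, dtype=float)
    disp = traj - traj[:, :1, :]
    msd = (disp ** 2).sum(axis=2).mean(axis=0)
    if fit_window is None:
        sel = np.ones_like(time, dtype=bool)
    else:
        sel = (time >= fit_window[0]) & (time <= fit_window[1])
    t_sel, m_sel = time[sel], msd[sel]
    if t_sel.size >= 2 and np.ptp(t_sel) > 0:
        slope = np.polyfit(t_sel, m_sel, 1)[0]  # nm²/s
        D_fit = slope / 4.0 * 1e-6              # µm²/s
    else:
        D_fit = 0.0
    return np.column_stack((time, msd)), float(D_fit)


def rise_times_and_pomax(time: np.ndarray, mean_open: np.ndarray,
                         n_receptors: int,
                         ) -> tuple[float | None, float | None, float]:
    """Rise times and peak open probability of an ensemble-mean trace.

    The peak is the maximum of the mean open count; ``Po_max`` is
    peak / n_receptors.  Rise times are the interpolated intervals
    between the 10%/90% (and 20%/80%) threshold crossings on the rising
    phase, taking for each threshold the last upward crossing at or
    before the peak.

    Returns ``(rise_10_90, rise_20_80, Po_max)`` in the units of
    ``time``; rise times are None for a flat-zero trace.
    """
    time = np.asarray(time, dtype=float)
    mean_open = np.asarray(mean_open, dtype=float)
    if n_receptors <= 0 or mean_open.size == 0:
        return None, None, 0.0
    i_peak = int(np.argmax(mean_open))
    peak = mean_open[i_peak]
    Po_max = float(peak) / n_receptors
    if peak <= 0:
        return None, None, 0.0

    def rise(lo_f: float, hi_f: float) -> float | None:
        t_lo = interpolated_crossing(time, mean_open, lo_f * peak,
                                     last_before=i_peak + 1)
        t_hi = interpolated_crossing(time, mean_open, hi_f * peak,
                                     last_before=i_peak + 1)
        if t_lo is None or t_hi is None:
            return None
        return t_hi - t_lo

    return rise(0.1, 0.9), rise(0.2, 0.8), Po_max
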
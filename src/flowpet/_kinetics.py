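"""Shared fine-grid numerics for the kinetic forward model and basis functions.

All operations work on a uniform fine time grid (default 0.1 s) so that the
forward model in :mod:`flowpet.core` and the basis-function regressors in
:mod:`flowpet.estimation` are built from bit-identical primitives: shift the
signal, convolve with an exponential, then frame-average through the running
integral.  Rates are per minute while time axes are in seconds; the 1/60
conversion is applied by the callers, not here (except inside the exponential
kernel itself).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import fftconvolve

#: default fine-grid spacing (s); >=10x finer than the shortest (1 s) frame
FINE_DT = 0.1

SEC_PER_MIN = 60.0


def resample_uniform(times: np.ndarray, values: np.ndarray, dt: float = FINE_DT):
    """Resample a sampled curve onto a uniform grid [0, t_end] with spacing dt."""
    t_end = float(times[-1])
    n = int(np.floor(t_end / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    v = np.interp(t, times, values)
    if times[0] > 0:
        v[t < times[0]] = 0.0
    return t, v


def cumtrapz0(y: np.ndarray, dt: float) -> np.ndarray:
    """Running trapezoidal integral, zero at the first sample."""
    return cumulative_trapezoid(y, dx=dt, initial=0.0)


def exp_decay_conv(ca: np.ndarray, dt: float, k2_per_min: float) -> np.ndarray:
    """Trapezoid-corrected convolution of ca(t) with exp(-k2*t/60).

    Returns the convolution integral in (input units)*s; divide by 60 to pair
    with rate constants expressed per minute.
    """
    n = ca.size
    g = np.exp(-(k2_per_min / SEC_PER_MIN) * np.arange(n) * dt)
    out = fftconvolve(ca, g)[:n] * dt
    # endpoint correction turns the rectangle rule into the trapezoid rule
    out -= 0.5 * dt * (ca[0] * g + ca * g[0])
    return out


def shift_right(t: np.ndarray, y: np.ndarray, delta: float) -> np.ndarray:
    """y(t - delta) on the same grid, zero-filled before the original origin."""
    if delta == 0.0:
        return y
    if delta < 0:
        raise ValueError("shift must be non-negative")
    return np.interp(t - delta, t, y, left=0.0)


def frame_average(t: np.ndarray, y: np.ndarray, starts: np.ndarray,
                  ends: np.ndarray) -> np.ndarray:
    """Mean of y over each [start, end) interval via the running integral."""
    dt = t[1] - t[0]
    M = cumtrapz0(y, dt)
    hi = np.interp(ends, t, M)
    lo = np.interp(starts, t, M)
    return (hi - lo) / (ends - starts)


def aath_frame_regressors(t, ca, starts, ends, k2, tc, td,
                          integral=None, conv=None):
    """Frame-averaged AATH regressors (vascular, tissue) for one grid node.

    The vascular regressor carries coefficient F, the tissue regressor K1
    (both mL/min/cm^3), hence the 1/60 second-to-minute conversion.
    """
    dt = t[1] - t[0]
    I = cumtrapz0(ca, dt) if integral is None else integral
    C = exp_decay_conv(ca, dt, k2) if conv is None else conv
    b1 = (frame_average(t, shift_right(t, I, td), starts, ends)
          - frame_average(t, shift_right(t, I, td + tc), starts, ends)) / SEC_PER_MIN
    b2 = frame_average(t, shift_right(t, C, td + tc), starts, ends) / SEC_PER_MIN
    return b1, b2


def s1tc_frame_regressors(t, ca, starts, ends, k2, td, conv=None):
    """Frame-averaged S1TC regressors (blood, tissue) for one grid node.

    The blood regressor carries the dimensionless coefficient vb (no unit
    conversion); the tissue regressor carries K1.
    """
    dt = t[1] - t[0]
    C = exp_decay_conv(ca, dt, k2) if conv is None else conv
    b1 = frame_average(t, shift_right(t, ca, td), starts, ends)
    b2 = frame_average(t, shift_right(t, C, td), starts, ends) / SEC_PER_MIN
    return b1, b2
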
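"""Kinetic models for early-dynamic PET blood-flow quantification.

Two tissue models are implemented:

* **S1TC** — the standard one-tissue compartment model, which assumes the
  tracer mixes instantaneously in the regional vascular volume.  Its impulse
  response is ``vb`` at t=0 and ``K1*exp(-k2*t)`` afterwards.
* **AATH** — the adiabatic approximation to tissue homogeneity, a distributed
  model with an explicit plug-flow vascular phase: the response equals the
  blood flow ``F`` for ``0 <= t < Tc`` (the mean vascular transit time) and
  decays as ``K1*exp(-k2*(t-Tc))`` in the tissue phase.

The measured tissue curve is the convolution of the delayed arterial input
with the impulse response, ``Q(t) = Ca(t - td) (x) R(t)``, frame-averaged over
the PET acquisition schedule.  Identities connecting the parameters:
``K1 = F*E`` (extraction fraction) and ``Tc = vb/F`` (transit time equals
blood volume over flow).

Units: F and K1 in mL/min/cm^3, k2 in 1/min, vb in mL/cm^3 (fraction), all
time axes (frames, Tc, td) in seconds.  Every exponential and convolution
integral therefore applies an explicit 1/60 conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from ._kinetics import (
    FINE_DT,
    SEC_PER_MIN,
    aath_frame_regressors,
    resample_uniform,
    s1tc_frame_regressors,
)

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "ArterialInput",
    "S1TCParams",
    "AATHParams",
    "KineticParams",
    "s1tc_irf",
    "aath_irf",
    "extraction_fraction",
    "vascular_transit_time",
    "forward_tac",
]

_EPS = 1e-9


def _as_float_array(x) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered PET frame intervals (seconds) defining a temporal sampling."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = _as_float_array(self.starts)
        ends = _as_float_array(self.ends)
        if starts.ndim != 1 or starts.shape != ends.shape:
            raise ValueError("starts and ends must be 1-D arrays of equal length")
        if starts.size < 2:
            raise ValueError("a frame schedule needs at least 2 frames")
        if np.any(starts < 0):
            raise ValueError("frame times must be non-negative")
        if np.any(ends <= starts):
            raise ValueError("each frame end must exceed its start")
        if np.any(starts[1:] < ends[:-1] - _EPS):
            raise ValueError("frames must be ordered and non-overlapping")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)

    @classmethod
    def htr_early_dynamic(cls) -> "FrameSchedule":
        """The high-temporal-resolution early-dynamic protocol:
        60 frames of 1 s followed by 30 frames of 2 s (2 min total)."""
        durations = np.concatenate([np.ones(60), 2.0 * np.ones(30)])
        return cls.from_durations(durations)

    @classmethod
    def from_durations(cls, durations, start: float = 0.0) -> "FrameSchedule":
        durations = _as_float_array(durations)
        edges = start + np.concatenate([[0.0], np.cumsum(durations)])
        return cls(edges[:-1], edges[1:])

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def n_frames(self) -> int:
        return self.starts.size

    def is_contiguous(self) -> bool:
        return bool(np.allclose(self.starts[1:], self.ends[:-1], atol=1e-9))

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration (kBq/mL) for one region or voxel."""

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        values = _as_float_array(self.values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise ValueError("values length must equal the frame count")
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")
        object.__setattr__(self, "values", values)

    def with_values(self, values, label: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, values,
                                 self.label if label is None else label)


@dataclass(frozen=True)
class ArterialInput:
    """Arterial input function Ca(t) sampled on a uniform fine grid (s, kBq/mL)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times)
        values = _as_float_array(self.values)
        if times.ndim != 1 or times.shape != values.shape or times.size < 2:
            raise ValueError("times and values must be matching 1-D arrays")
        d = np.diff(times)
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("arterial input must be uniformly sampled")
        if d[0] > 0.5 + _EPS:
            raise ValueError("arterial input spacing must be <= 0.5 s")
        if np.any(values < -1e-9):
            raise ValueError("arterial input values must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", np.maximum(values, 0.0))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class S1TCParams:
    """One-tissue compartment parameters.

    vb: blood volume fraction (mL/cm^3, in [0, 1]); K1: blood-to-tissue
    transport rate (mL/min/cm^3); k2: clearance rate (1/min); td: time delay
    (s) between the arterial sampling site and the local vasculature.
    """

    vb: float
    K1: float
    k2: float
    td: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.vb <= 1.0 + _EPS:
            raise ValueError("vb must lie in [0, 1]")
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("K1 and k2 must be non-negative")

    @property
    def n_free(self) -> int:
        return 4


@dataclass(frozen=True)
class AATHParams:
    """Distributed (AATH) model parameters.

    F: blood flow (mL/min/cm^3); K1: transport rate with K1 <= F so the
    extraction fraction E = K1/F lies in [0, 1]; k2: clearance rate (1/min);
    Tc: mean vascular transit time (s); td: time delay (s).  The derived
    blood volume vb = F*Tc/60 must not exceed 1.
    """

    F: float
    K1: float
    k2: float
    Tc: float
    td: float = 0.0

    def __post_init__(self):
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if self.K1 < 0 or self.k2 < 0 or self.Tc < 0:
            raise ValueError("K1, k2 and Tc must be non-negative")
        if self.K1 > self.F + _EPS * max(1.0, self.F):
            raise ValueError("K1 must not exceed F (extraction fraction <= 1)")
        if self.vb > 1.0 + _EPS:
            raise ValueError("derived blood volume F*Tc/60 exceeds 1")

    @property
    def E(self) -> float:
        """Extraction fraction K1/F (0 when F = 0)."""
        return 0.0 if self.F == 0 else min(self.K1 / self.F, 1.0)

    @property
    def vb(self) -> float:
        """Derived blood volume fraction F*Tc/60."""
        return self.F * self.Tc / SEC_PER_MIN

    @property
    def n_free(self) -> int:
        return 5


KineticParams = Union[S1TCParams, AATHParams]


def _check_nonneg_time(t: np.ndarray):
    if np.any(t < 0):
        raise ValueError("time must be non-negative")


def s1tc_irf(t, p: S1TCParams):
    """S1TC impulse response: vb at t=0, K1*exp(-k2*t/60) for t>0.

    The point value vb at t=0 expresses instantaneous vascular mixing; in the
    forward model this appears as the additive blood term vb*Ca(t-td).
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg_time(t)
    out = np.where(t == 0.0, p.vb, p.K1 * np.exp(-p.k2 * t / SEC_PER_MIN))
    return out if out.ndim else float(out)


def aath_irf(t, p: AATHParams):
    """AATH impulse response: F during the vascular phase (0 <= t < Tc),
    K1*exp(-k2*(t-Tc)/60) in the tissue phase (t >= Tc).

    Right-continuous at t = Tc with value K1.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg_time(t)
    out = np.where(t < p.Tc, p.F,
                   p.K1 * np.exp(-p.k2 * np.maximum(t - p.Tc, 0.0) / SEC_PER_MIN))
    return out if out.ndim else float(out)


def extraction_fraction(F: float, K1: float) -> float:
    """Extraction fraction E = K1/F from the identity K1 = F*E."""
    if F <= 0:
        raise ValueError("F must be positive")
    if K1 < 0 or K1 > F + _EPS * F:
        raise ValueError("K1 must lie in [0, F]")
    return min(K1 / F, 1.0)


def vascular_transit_time(vb: float, F: float) -> float:
    """Mean vascular transit time Tc = vb/F, converted to seconds
    (F is per minute): Tc = 60*vb/F."""
    if F <= 0:
        raise ValueError("F must be positive")
    if vb < 0:
        raise ValueError("vb must be non-negative")
    return SEC_PER_MIN * vb / F


def _model_kind_of(params: KineticParams) -> str:
    if isinstance(params, AATHParams):
        return "aath"
    if isinstance(params, S1TCParams):
        return "s1tc"
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def forward_tac(model_kind: str, params: KineticParams, aif: ArterialInput,
                schedule: FrameSchedule, fine_dt: float = FINE_DT,
                label: str = "") -> TimeActivityCurve:
    """Frame-averaged tissue curve Q(t) = Ca(t-td) (x) R(t).

    The continuous curve is computed on a uniform fine grid (trapezoidal
    integration, linear interpolation for the continuous delay) and averaged
    over each frame interval.  Ca(t) = 0 for t < 0.
    """
    kind = model_kind.lower()
    if kind != _model_kind_of(params):
        raise ValueError(f"model_kind {model_kind!r} does not match "
                         f"{type(params).__name__}")
    if aif.duration + _EPS < schedule.ends[-1]:
        raise ValueError("arterial input too short for the requested schedule")
    t, ca = resample_uniform(aif.times, aif.values, fine_dt)
    starts, ends = schedule.starts, schedule.ends
    if kind == "aath":
        b1, b2 = aath_frame_regressors(t, ca, starts, ends,
                                       params.k2, params.Tc, params.td)
        vals = params.F * b1 + params.K1 * b2
    else:
        b1, b2 = s1tc_frame_regressors(t, ca, starts, ends,
                                       params.k2, params.td)
        vals = params.vb * b1 + params.K1 * b2
    return TimeActivityCurve(schedule, vals, label)
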
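"""Synthetic-data engine: regional presets, TAC noise, phantoms,
practical-identifiability analysis.

The ten regional presets carry the cohort-mean early FDG kinetics (blood
flow, transport rate, blood volume, vascular transit time) of the healthy-
participant study conditions; the clearance rate k2, which is not part of
that summary, is derived as K1 divided by a per-tissue-class distribution
volume (see ``DISTRIBUTION_VOLUMES``).

TAC noise follows the standard PET approximation: zero-mean Gaussian with
per-frame SD proportional to sqrt(activity / frame duration).  The noise
scale can be given directly or calibrated so that the peak-frame
signal-to-noise ratio hits a target (default 25, typical of kernel-smoothed
high-temporal-resolution regional curves).

Practical identifiability repeats simulate-then-fit many times per region
and summarizes the percent error of each kinetic parameter (mean = bias,
SD = variability).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AATHParams,
    ArterialInput,
    FrameSchedule,
    KineticParams,
    S1TCParams,
    TimeActivityCurve,
    forward_tac,
)
from .estimation import GridConfig, build_basis, fit_tac
from .input_functions import input_source_for_region

__all__ = ["RegionPreset", "region_presets", "NoiseConfig", "noise_sigma",
           "simulate_tac", "IdentifiabilityReport", "identifiability_analysis",
           "simulate_phantom", "default_phantom_labels", "REGION_LABELS",
           "DISTRIBUTION_VOLUMES"]

# cohort-mean early FDG kinetics: (label, F, K1, vb, Tc)
# F, K1 in mL/min/cm^3; vb in mL/cm^3; Tc in s.  Lungs K1 is the cohort median.
_REGION_TABLE = [
    ("cortical_gm",     0.507, 0.136, 0.036, 4.4),
    ("white_matter",    0.165, 0.066, 0.018, 6.9),
    ("subcortical_gm",  0.461, 0.143, 0.033, 4.6),
    ("brain_stem",      0.339, 0.125, 0.030, 5.6),
    ("cerebellum",      0.447, 0.145, 0.037, 5.1),
    ("spleen",          1.676, 1.204, 0.166, 6.5),
    ("renal_cortex",    1.938, 0.657, 0.318, 10.1),
    ("skeletal_muscle", 0.039, 0.034, 0.017, 29.1),
    ("bone_marrow",     0.136, 0.130, 0.053, 24.6),
    ("lungs",           2.031, 0.072, 0.143, 4.4),
]

REGION_LABELS = tuple(r[0] for r in _REGION_TABLE)

#: per-tissue-class distribution volume vd (mL/cm^3) used to derive k2 = K1/vd.
#: 0.3 by default; larger for the highly perfused spleen and renal cortex so
#: the derived clearance rates stay within the default search grid.
DISTRIBUTION_VOLUMES = {
    "spleen": 0.6,
    "renal_cortex": 0.4,
}
_DEFAULT_VD = 0.3


@dataclass(frozen=True)
class RegionPreset:
    """Simulation preset for one tissue region."""

    label: str
    F: float
    K1: float
    vb: float
    Tc: float
    k2: float
    input_source: str

    def to_aath_params(self, td: float = 0.0) -> AATHParams:
        return AATHParams(F=self.F, K1=self.K1, k2=self.k2, Tc=self.Tc, td=td)

    def to_s1tc_params(self, td: float = 0.0) -> S1TCParams:
        return S1TCParams(vb=self.vb, K1=self.K1, k2=self.k2, td=td)


def region_presets(distribution_volumes: dict[str, float] | None = None
                   ) -> list[RegionPreset]:
    """The ten regional presets with derived k2 = K1/vd."""
    vd_map = dict(DISTRIBUTION_VOLUMES)
    if distribution_volumes:
        vd_map.update(distribution_volumes)
    out = []
    for label, F, K1, vb, Tc in _REGION_TABLE:
        vd = vd_map.get(label, _DEFAULT_VD)
        out.append(RegionPreset(label=label, F=F, K1=K1, vb=vb, Tc=Tc,
                                k2=K1 / vd,
                                input_source=input_source_for_region(label)))
    return out


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian TAC noise with per-frame SD = scale*sqrt(max(Q, floor)/dt).

    Exactly one of ``scale`` (kBq^0.5 mL^-0.5 s^0.5) or ``peak_snr`` must be
    set; with ``peak_snr`` the scale is calibrated per curve so the
    peak-frame SNR equals the target.  ``seed`` makes every draw
    reproducible; ``clip_negative`` optionally truncates at zero (off by
    default, as reconstruction noise can go negative).
    """

    scale: Optional[float] = None
    peak_snr: Optional[float] = None
    seed: Optional[int] = None
    floor: float = 1e-6
    clip_negative: bool = False

    def __post_init__(self):
        if (self.scale is None) == (self.peak_snr is None):
            raise ValueError("set exactly one of scale or peak_snr")
        if self.scale is not None and self.scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.peak_snr is not None and self.peak_snr <= 0:
            raise ValueError("peak SNR must be positive")
        if self.floor <= 0:
            raise ValueError("floor must be positive")

    def resolve_scale(self, noiseless: TimeActivityCurve) -> float:
        """Noise scale, calibrating to the peak-frame SNR if requested."""
        if self.scale is not None:
            return self.scale
        i = int(np.argmax(noiseless.values))
        q = max(float(noiseless.values[i]), self.floor)
        dt = float(noiseless.schedule.durations[i])
        return float(noiseless.values[i]) * np.sqrt(dt / q) / self.peak_snr


def noise_sigma(values: np.ndarray, durations: np.ndarray, scale: float,
                floor: float = 1e-6) -> np.ndarray:
    """Per-frame noise SD under the activity-over-duration variance law."""
    return scale * np.sqrt(np.maximum(values, floor) / durations)


def _forward(params: KineticParams, aif, schedule, label=""):
    kind = "aath" if isinstance(params, AATHParams) else "s1tc"
    return forward_tac(kind, params, aif, schedule, label=label)


def simulate_tac(params: KineticParams, aif: ArterialInput,
                 schedule: FrameSchedule, noise: NoiseConfig,
                 rng: np.random.Generator | None = None,
                 label: str = "") -> TimeActivityCurve:
    """Forward TAC plus seeded Gaussian noise under the variance law."""
    clean = _forward(params, aif, schedule, label)
    scale = noise.resolve_scale(clean)
    if scale == 0.0:
        return clean
    sigma = noise_sigma(clean.values, schedule.durations, scale, noise.floor)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    vals = clean.values + rng.normal(size=sigma.size) * sigma
    if noise.clip_negative:
        vals = np.maximum(vals, 0.0)
    return clean.with_values(vals)


_REPORT_PARAMS = ("F", "K1", "k2", "Tc", "vb")


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Per-region, per-parameter percent-error summary of replicate fits.

    ``table`` has columns region, parameter, mean_percent_error,
    sd_percent_error, n_reps.
    """

    table: pd.DataFrame
    n_reps: int

    def mean_error(self, parameter: str = "F") -> pd.Series:
        sub = self.table[self.table.parameter == parameter]
        return sub.set_index("region")["mean_percent_error"]

    def sd_error(self, parameter: str = "F") -> pd.Series:
        sub = self.table[self.table.parameter == parameter]
        return sub.set_index("region")["sd_percent_error"]

    def max_abs_mean_error(self, parameter: str = "F",
                           exclude: Sequence[str] = ()) -> float:
        s = self.mean_error(parameter).drop(list(exclude), errors="ignore")
        return float(s.abs().max())

    def max_sd_error(self, parameter: str = "F",
                     exclude: Sequence[str] = ()) -> float:
        s = self.sd_error(parameter).drop(list(exclude), errors="ignore")
        return float(s.max())


def identifiability_analysis(presets: Iterable[RegionPreset],
                             aif: ArterialInput, schedule: FrameSchedule,
                             noise: NoiseConfig, n_reps: int = 100,
                             grid: GridConfig | None = None,
                             td: float = 0.0) -> IdentifiabilityReport:
    """Simulate ``n_reps`` noisy TACs per region at preset truth, fit the
    AATH model, and summarize the percent error of F, K1, k2, Tc and vb."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    grid = grid or GridConfig.default()
    presets = list(presets)
    basis = build_basis(aif, schedule, grid, "aath")
    children = np.random.SeedSequence(noise.seed).spawn(len(presets))
    rows = []
    for preset, child in zip(presets, children):
        truth = preset.to_aath_params(td=td)
        clean = _forward(truth, aif, schedule, preset.label)
        scale = noise.resolve_scale(clean)
        sigma = noise_sigma(clean.values, schedule.durations, scale, noise.floor)
        rng = np.random.default_rng(child)
        truth_vals = {"F": truth.F, "K1": truth.K1, "k2": truth.k2,
                      "Tc": truth.Tc, "vb": truth.vb}
        errors = {p: [] for p in _REPORT_PARAMS}
        for _ in range(n_reps):
            noisy = clean.with_values(
                clean.values + rng.normal(size=sigma.size) * sigma)
            fit = fit_tac(noisy, basis)
            est = {"F": fit.params.F, "K1": fit.params.K1, "k2": fit.params.k2,
                   "Tc": fit.params.Tc, "vb": fit.params.vb}
            for p in _REPORT_PARAMS:
                tv = truth_vals[p]
                errors[p].append(100.0 * (est[p] - tv) / tv if tv != 0 else np.nan)
        for p in _REPORT_PARAMS:
            e = np.asarray(errors[p])
            rows.append(dict(region=preset.label, parameter=p,
                             mean_percent_error=float(np.nanmean(e)),
                             sd_percent_error=float(np.nanstd(e, ddof=1))
                             if n_reps > 1 else 0.0,
                             n_reps=n_reps))
    return IdentifiabilityReport(pd.DataFrame(rows), n_reps)


def default_phantom_labels(shape: tuple[int, int, int] = (24, 24, 24),
                           n_regions: int = 10) -> np.ndarray:
    """Cuboid label map: ``n_regions`` blocks (labels 1..n) laid out on a
    2 x 5 grid inside the volume, background 0 elsewhere."""
    if n_regions < 1 or n_regions > 10:
        raise ValueError("n_regions must be in 1..10")
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)
    xs = [(int(round(2 / 24 * nx)), int(round(10 / 24 * nx))),
          (int(round(14 / 24 * nx)), int(round(22 / 24 * nx)))]
    ys = [(int(round((2 + 4 * j) / 24 * ny)), int(round((6 + 4 * j) / 24 * ny)))
          for j in range(5)]
    z0, z1 = int(round(6 / 24 * nz)), int(round(18 / 24 * nz))
    lab = 1
    for x0, x1 in xs:
        for y0, y1 in ys:
            if lab > n_regions:
                break
            labels[x0:x1, y0:y1, z0:z1] = lab
            lab += 1
    return labels


def simulate_phantom(label_map: np.ndarray, presets: Sequence[RegionPreset],
                     aif: ArterialInput, schedule: FrameSchedule,
                     noise: NoiseConfig | None = None,
                     background: str = "zero", background_scale: float = 1.0,
                     voxel_size_mm: float = 4.0, td: float = 0.0):
    """Digital 4D phantom: label value L > 0 gets the forward TAC of
    ``presets[L-1]`` (independent per-voxel noise); background voxels are a
    scaled blood-pool curve (``background='blood'``) or zero.

    Returns a :class:`flowpet.imaging.DynamicImage` whose analysis mask
    covers the labeled (non-background) voxels.
    """
    from .imaging import DynamicImage

    label_map = np.asarray(label_map)
    if label_map.ndim != 3:
        raise ValueError("label map must be 3-D")
    labels = np.unique(label_map)
    if labels.min() < 0 or labels.max() > len(presets):
        raise ValueError("label values must map to presets (0 = background)")
    if background not in ("zero", "blood"):
        raise ValueError("background must be 'zero' or 'blood'")
    nf = schedule.n_frames
    data = np.zeros(label_map.shape + (nf,))
    rng = np.random.default_rng(noise.seed if noise is not None else None)

    def _fill(mask, clean_vals):
        nvox = int(mask.sum())
        if nvox == 0:
            return
        if noise is None:
            data[mask] = clean_vals
            return
        scale = noise.resolve_scale(TimeActivityCurve(schedule, clean_vals))
        if scale == 0.0:
            data[mask] = clean_vals
            return
        sigma = noise_sigma(clean_vals, schedule.durations, scale, noise.floor)
        vals = clean_vals + rng.normal(size=(nvox, nf)) * sigma
        if noise.clip_negative:
            vals = np.maximum(vals, 0.0)
        data[mask] = vals

    for lab in labels:
        mask = label_map == lab
        if lab == 0:
            if background == "zero":
                continue
            bg = forward_tac("s1tc",
                             S1TCParams(vb=1.0, K1=0.0, k2=0.0, td=td),
                             aif, schedule)
            _fill(mask, background_scale * bg.values)
        else:
            clean = _forward(presets[int(lab) - 1].to_aath_params(td=td),
                             aif, schedule)
            _fill(mask, clean.values)

    return DynamicImage(data=data, schedule=schedule,
                        voxel_size_mm=voxel_size_mm, mask=label_map > 0)
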
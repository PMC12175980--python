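"""Basis-function weighted least-squares fitting of the S1TC and AATH models.

Both forward models are linear in two coefficients once the nonlinear
parameters are fixed: AATH in (F, K1) given (k2, Tc, td), S1TC in (vb, K1)
given (k2, td).  Fitting therefore reduces to an exhaustive search over a
grid of nonlinear-parameter nodes, solving a tiny 2-coefficient weighted
linear least-squares problem at each node, with physical constraints
(non-negativity, extraction fraction K1/F <= 1, blood volume <= 1) enforced
by examining the active-constraint edges of the convex quadratic.

The regressors are precomputed once per arterial input: for every required
time shift the running integral of the AIF (vascular phase) and its
exponential convolutions (tissue phase, one per k2 node) are frame-averaged.
This makes repeated fits against a shared basis — replicate simulations,
voxelwise parametric imaging — cost only two small matrix-vector products
and a vectorized sweep over the grid.

The search is exhaustive and deterministic; ties in the weighted residual
sum of squares are broken toward smaller td, then smaller Tc, then smaller
k2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from ._kinetics import (
    FINE_DT,
    SEC_PER_MIN,
    cumtrapz0,
    exp_decay_conv,
    frame_average,
    resample_uniform,
    shift_right,
)
from .core import (
    AATHParams,
    ArterialInput,
    FrameSchedule,
    KineticParams,
    S1TCParams,
    TimeActivityCurve,
)

__all__ = ["GridConfig", "FitResult", "BasisSet", "build_basis", "fit_tac",
           "fit_weights", "WEIGHT_SCHEMES"]

WEIGHT_SCHEMES = ("uniform", "frame_duration", "inverse_variance")

_EPS = 1e-9


def _sorted_positive(a, name, allow_zero=False) -> np.ndarray:
    a = np.ascontiguousarray(np.asarray(a, dtype=float))
    if a.ndim != 1 or a.size == 0:
        raise ValueError(f"{name} grid must be a non-empty 1-D array")
    if np.any(np.diff(a) <= 0):
        raise ValueError(f"{name} grid must be strictly ascending")
    lo = 0.0 if allow_zero else np.nextafter(0.0, 1.0)
    if a[0] < lo:
        raise ValueError(f"{name} grid values out of range")
    return a


@dataclass(frozen=True)
class GridConfig:
    """Search grids for the nonlinear parameters.

    k2 in 1/min (geometric spacing recommended), Tc and td in seconds
    (linear spacing).  The defaults span the regional transit times and
    clearance rates seen in early FDG kinetics with margin.
    """

    k2: np.ndarray
    tc: np.ndarray
    td: np.ndarray
    weighting: str = "frame_duration"
    nonneg: bool = True

    def __post_init__(self):
        object.__setattr__(self, "k2", _sorted_positive(self.k2, "k2",
                                                        allow_zero=True))
        object.__setattr__(self, "tc", _sorted_positive(self.tc, "Tc", allow_zero=True))
        object.__setattr__(self, "td", _sorted_positive(self.td, "td", allow_zero=True))
        if self.weighting not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weighting scheme {self.weighting!r}")

    @classmethod
    def default(cls) -> "GridConfig":
        return cls(
            k2=np.geomspace(0.01, 3.0, 50),
            tc=np.arange(0.0, 40.0 + 1e-9, 0.5),
            td=np.arange(0.0, 30.0 + 1e-9, 0.5),
        )


@dataclass
class FitResult:
    """Outcome of a single-TAC model fit."""

    model_kind: str
    params: KineticParams
    rss: float
    fitted: TimeActivityCurve
    grid_indices: dict
    n_frames: int
    n_params: int
    weights: np.ndarray = field(repr=False, default=None)

    def aic(self, small_sample: bool = False) -> float:
        from .model_selection import aic as _aic
        return _aic(self.rss, self.n_frames, self.n_params,
                    small_sample=small_sample)


def fit_weights(tac: TimeActivityCurve, scheme: str) -> np.ndarray:
    """Per-frame weights: 'uniform' -> 1; 'frame_duration' -> frame length
    (equalizes information between 1 s and 2 s frames); 'inverse_variance'
    -> duration / max(value, floor) with a positive floor."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    d = tac.schedule.durations
    if scheme == "uniform":
        return np.ones(tac.schedule.n_frames)
    if scheme == "frame_duration":
        return d.copy()
    floor = max(1e-6, 1e-3 * float(np.max(np.abs(tac.values), initial=0.0)))
    return d / np.maximum(tac.values, floor)


class BasisSet:
    """Precomputed frame-averaged regressors over a nonlinear-parameter grid.

    Normal-equation cross products are cached per weight vector, so repeated
    fits with the same weighting (the default frame-duration scheme is
    TAC-independent) reuse all heavy computation.
    """

    def __init__(self, aif: ArterialInput, schedule: FrameSchedule,
                 grid: GridConfig, model_kind: str, fine_dt: float = FINE_DT):
        model_kind = model_kind.lower()
        if model_kind not in ("aath", "s1tc"):
            raise ValueError("model_kind must be 'aath' or 's1tc'")
        if aif.duration + _EPS < schedule.ends[-1]:
            raise ValueError("arterial input too short for the requested schedule")
        self.model_kind = model_kind
        self.grid = grid
        self.schedule = schedule
        t, ca = resample_uniform(aif.times, aif.values, fine_dt)
        self._t, self._ca = t, ca
        starts, ends = schedule.starts, schedule.ends
        dt = fine_dt
        k2g, tcg, tdg = grid.k2, grid.tc, grid.td
        I = cumtrapz0(ca, dt)

        if model_kind == "aath":
            sums = (tdg[:, None] + tcg[None, :]).ravel()
            shift_vals = np.unique(np.concatenate([tdg, sums]))
            Jfa = np.stack([frame_average(t, shift_right(t, I, d), starts, ends)
                            for d in shift_vals])
            Cfa = np.empty((k2g.size, shift_vals.size, starts.size))
            for i, k2 in enumerate(k2g):
                C = exp_decay_conv(ca, dt, k2)
                for j, d in enumerate(shift_vals):
                    Cfa[i, j] = frame_average(t, shift_right(t, C, d), starts, ends)
            Cfa /= SEC_PER_MIN
            td_idx = np.searchsorted(shift_vals, tdg)
            self._sum_idx = np.searchsorted(shift_vals, sums)      # (npair,)
            self._B1 = (Jfa[np.repeat(td_idx, tcg.size)]
                        - Jfa[self._sum_idx]) / SEC_PER_MIN         # (npair, nf)
            self._Cfa = Cfa                                         # (nk2, ns, nf)
            self._tc_pair = np.tile(tcg, tdg.size)
            self._td_pair = np.repeat(tdg, tcg.size)
            with np.errstate(divide="ignore"):
                self._fcap_pair = np.where(
                    self._tc_pair > 0, SEC_PER_MIN / np.maximum(self._tc_pair, 1e-300),
                    np.inf)
        else:
            shift_vals = tdg
            self._B1 = np.stack([frame_average(t, shift_right(t, ca, d), starts, ends)
                                 for d in shift_vals])              # (ntd, nf)
            Cfa = np.empty((k2g.size, shift_vals.size, starts.size))
            for i, k2 in enumerate(k2g):
                C = exp_decay_conv(ca, dt, k2)
                for j, d in enumerate(shift_vals):
                    Cfa[i, j] = frame_average(t, shift_right(t, C, d), starts, ends)
            self._Cfa = Cfa / SEC_PER_MIN
            self._sum_idx = np.arange(shift_vals.size)
            self._td_pair = tdg
        self._normal_cache: dict = {}

    # -- public helpers -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames

    def regressors(self, i_k2: int, i_tc: int | None, i_td: int):
        """Frame-averaged regressor pair at one grid node (testing hook).

        For AATH returns (vascular, tissue) carrying coefficients (F, K1);
        for S1TC (blood, tissue) carrying (vb, K1); ``i_tc`` is ignored for
        S1TC.
        """
        if self.model_kind == "aath":
            p = i_td * self.grid.tc.size + i_tc
            return self._B1[p].copy(), self._Cfa[i_k2, self._sum_idx[p]].copy()
        return self._B1[i_td].copy(), self._Cfa[i_k2, i_td].copy()

    # -- normal equations ------------------------------------------------

    def _normal(self, w: np.ndarray):
        key = w.tobytes()
        cached = self._normal_cache.get(key)
        if cached is not None:
            return cached
        B1, Cfa, sum_idx = self._B1, self._Cfa, self._sum_idx
        B1w = B1 * w
        a11 = np.einsum("pf,pf->p", B1w, B1)
        Cw = Cfa * w
        a22_sh = np.einsum("ksf,ksf->ks", Cw, Cfa)
        nk2 = Cfa.shape[0]
        a12 = np.empty((B1.shape[0], nk2))
        for i in range(nk2):
            a12[:, i] = np.einsum("pf,pf->p", B1w, Cfa[i][sum_idx])
        a22p = a22_sh[:, sum_idx].T
        cached = dict(B1w=B1w, Cw=Cw, a11=a11, a12=a12, a22p=a22p)
        if len(self._normal_cache) > 4:   # bound the cache for per-TAC weights
            self._normal_cache.clear()
        self._normal_cache[key] = cached
        return cached

    # -- fitting ----------------------------------------------------------

    def fit(self, tac: TimeActivityCurve,
            weights: Union[str, np.ndarray, None] = None) -> FitResult:
        if tac.schedule.n_frames != self.n_frames or not np.allclose(
                tac.schedule.starts, self.schedule.starts, atol=1e-9):
            raise ValueError("TAC schedule does not match the basis schedule")
        y = tac.values
        if not np.all(np.isfinite(y)):
            raise ValueError("TAC contains non-finite values")
        if weights is None:
            weights = self.grid.weighting
        if isinstance(weights, str):
            w = fit_weights(tac, weights)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != y.shape or np.any(w < 0):
                raise ValueError("weight vector must be non-negative and match the TAC")
        if not np.any(w > 0):
            raise ValueError("all weights are zero")

        nm = self._normal(w)
        if self.model_kind == "aath":
            return self._fit_aath(tac, y, w, nm)
        return self._fit_s1tc(tac, y, w, nm)

    def _fit_aath(self, tac, y, w, nm) -> FitResult:
        sy2 = float(w @ (y * y))
        b1 = nm["B1w"] @ y                                   # (npair,)
        b2_sh = np.einsum("ksf,f->ks", nm["Cw"], y)
        B2v = b2_sh[:, self._sum_idx].T                      # (npair, nk2)
        B1v = b1[:, None]
        A11 = nm["a11"][:, None]
        A12, A22 = nm["a12"], nm["a22p"]
        Fcap = self._fcap_pair[:, None]

        scale = float(np.max(A11) * np.max(A22)) + 1e-300
        tiny = 1e-13 * scale

        def rssq(F, K):
            return (sy2 - 2.0 * (F * B1v + K * B2v)
                    + F * F * A11 + 2.0 * F * K * A12 + K * K * A22)

        with np.errstate(divide="ignore", invalid="ignore"):
            det = A11 * A22 - A12 * A12
            F0 = (A22 * B1v - A12 * B2v) / det
            K0 = (A11 * B2v - A12 * B1v) / det
            ok0 = ((det > tiny) & np.isfinite(F0) & np.isfinite(K0)
                   & (F0 >= 0) & (K0 >= 0) & (K0 <= F0) & (F0 <= Fcap))
            r0 = np.where(ok0, rssq(np.where(ok0, F0, 0.0),
                                    np.where(ok0, K0, 0.0)), np.inf)
            # edge K1 = 0
            F1 = np.where(A11 > 1e-13 * np.max(A11) + 1e-300, B1v / A11, 0.0)
            F1 = np.clip(np.nan_to_num(F1, nan=0.0, posinf=0.0, neginf=0.0),
                         0.0, Fcap)
            r1 = rssq(F1, np.zeros(1))
            # edge K1 = F (extraction fraction 1)
            S = A11 + 2.0 * A12 + A22
            T1 = np.where(S > 1e-13 * np.max(S) + 1e-300, (B1v + B2v) / S, 0.0)
            T1 = np.clip(np.nan_to_num(T1, nan=0.0, posinf=0.0, neginf=0.0),
                         0.0, Fcap)
            r2 = rssq(T1, T1)
            # edge F at the blood-volume cap (finite caps only)
            finite = np.broadcast_to(np.isfinite(Fcap), A22.shape)
            Fc = np.where(np.isfinite(Fcap), Fcap, 0.0)
            K3 = np.where(A22 > 1e-13 * np.max(A22) + 1e-300,
                          (B2v - Fc * A12) / A22, 0.0)
            K3 = np.clip(np.nan_to_num(K3, nan=0.0, posinf=0.0, neginf=0.0),
                         0.0, Fc)
            r3 = np.where(finite, rssq(Fc, K3), np.inf)

        R = np.stack([r0, r1, r2, r3])
        Rmin = R.min(axis=0)
        flat = int(np.argmin(Rmin))            # first min: smaller td, Tc, k2
        nk2 = self.grid.k2.size
        p, ik2 = divmod(flat, nk2)
        which = int(np.argmin(R[:, p, ik2]))
        if which == 0:
            F, K1 = float(F0[p, ik2]), float(K0[p, ik2])
        elif which == 1:
            F, K1 = float(F1[p, ik2]), 0.0
        elif which == 2:
            F = K1 = float(T1[p, ik2])
        else:
            F, K1 = float(Fc[p, 0]), float(K3[p, ik2])
        F = max(F, 0.0)
        K1 = min(max(K1, 0.0), F)
        rss = max(float(Rmin[p, ik2]), 0.0)
        tc = float(self._tc_pair[p])
        td = float(self._td_pair[p])
        k2 = float(self.grid.k2[ik2])
        fitted = F * self._B1[p] + K1 * self._Cfa[ik2, self._sum_idx[p]]
        params = AATHParams(F=F, K1=K1, k2=k2, Tc=tc, td=td)
        itd, itc = divmod(p, self.grid.tc.size)
        return FitResult("aath", params, rss,
                         TimeActivityCurve(self.schedule, fitted, tac.label),
                         {"k2": ik2, "tc": itc, "td": itd},
                         self.n_frames, params.n_free, w)

    def _fit_s1tc(self, tac, y, w, nm) -> FitResult:
        sy2 = float(w @ (y * y))
        b1 = nm["B1w"] @ y                                   # (ntd,)
        B2v = np.einsum("ksf,f->ks", nm["Cw"], y).T          # (ntd, nk2)
        B1v = b1[:, None]
        A11 = nm["a11"][:, None]
        A12 = nm["a12"]
        A22 = nm["a22p"]

        scale = float(np.max(A11) * np.max(A22)) + 1e-300
        tiny = 1e-13 * scale

        def rssq(V, K):
            return (sy2 - 2.0 * (V * B1v + K * B2v)
                    + V * V * A11 + 2.0 * V * K * A12 + K * K * A22)

        with np.errstate(divide="ignore", invalid="ignore"):
            det = A11 * A22 - A12 * A12
            V0 = (A22 * B1v - A12 * B2v) / det
            K0 = (A11 * B2v - A12 * B1v) / det
            ok0 = ((det > tiny) & np.isfinite(V0) & np.isfinite(K0)
                   & (V0 >= 0) & (V0 <= 1.0) & (K0 >= 0))
            r0 = np.where(ok0, rssq(np.where(ok0, V0, 0.0),
                                    np.where(ok0, K0, 0.0)), np.inf)
            V1 = np.where(A11 > 1e-13 * np.max(A11) + 1e-300, B1v / A11, 0.0)
            V1 = np.clip(np.nan_to_num(V1, nan=0.0, posinf=0.0, neginf=0.0), 0.0, 1.0)
            r1 = rssq(V1, np.zeros(1))
            K2c = np.where(A22 > 1e-13 * np.max(A22) + 1e-300, B2v / A22, 0.0)
            K2c = np.maximum(np.nan_to_num(K2c, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
            r2 = rssq(np.zeros(1), K2c)
            K3c = np.where(A22 > 1e-13 * np.max(A22) + 1e-300,
                           (B2v - A12) / A22, 0.0)
            K3c = np.maximum(np.nan_to_num(K3c, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
            r3 = rssq(np.ones(1), K3c)

        R = np.stack([r0, r1, r2, r3])
        Rmin = R.min(axis=0)
        flat = int(np.argmin(Rmin))            # first min: smaller td, then k2
        nk2 = self.grid.k2.size
        itd, ik2 = divmod(flat, nk2)
        which = int(np.argmin(R[:, itd, ik2]))
        if which == 0:
            vb, K1 = float(V0[itd, ik2]), float(K0[itd, ik2])
        elif which == 1:
            vb, K1 = float(V1[itd, ik2]), 0.0
        elif which == 2:
            vb, K1 = 0.0, float(K2c[itd, ik2])
        else:
            vb, K1 = 1.0, float(K3c[itd, ik2])
        vb = min(max(vb, 0.0), 1.0)
        K1 = max(K1, 0.0)
        rss = max(float(Rmin[itd, ik2]), 0.0)
        k2 = float(self.grid.k2[ik2])
        td = float(self._td_pair[itd])
        fitted = vb * self._B1[itd] + K1 * self._Cfa[ik2, itd]
        params = S1TCParams(vb=vb, K1=K1, k2=k2, td=td)
        return FitResult("s1tc", params, rss,
                         TimeActivityCurve(self.schedule, fitted, tac.label),
                         {"k2": ik2, "td": itd},
                         self.n_frames, params.n_free, w)


def build_basis(aif: ArterialInput, schedule: FrameSchedule, grid: GridConfig,
                model_kind: str, fine_dt: float = FINE_DT) -> BasisSet:
    """Precompute the frame-averaged basis table for one AIF/schedule/grid."""
    return BasisSet(aif, schedule, grid, model_kind, fine_dt=fine_dt)


def fit_tac(tac: TimeActivityCurve, basis: BasisSet,
            weights: Union[str, np.ndarray, None] = None) -> FitResult:
    """Grid-search weighted least squares against a precomputed basis."""
    return basis.fit(tac, weights=weights)
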
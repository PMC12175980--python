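"""Voxelwise parametric imaging and kernel-method smoothing.

Parametric maps are produced by fitting every masked voxel's time-activity
curve against a single shared basis, so a voxel's map values are identical to
a regional fit of that voxel's TAC.

The kernel method is a neighbor-graph smoother analogous to nonlocal means:
composite (time-averaged) frames provide a per-voxel feature vector, each
voxel is connected to its k most feature-similar neighbors inside a local
spatial window (default 49 neighbors in a 9 x 9 x 9 box), and smoothing
replaces a voxel's value with a row-normalized Gaussian-weighted neighbor
average.  Because similarity is measured in composite-intensity space, edges
between tissues with distinct intensities are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from .core import ArterialInput, FrameSchedule, TimeActivityCurve
from .estimation import GridConfig, build_basis, fit_tac, fit_weights

__all__ = ["DynamicImage", "ParametricMaps", "KernelOperator",
           "composite_frames", "build_kernel", "apply_kernel", "fit_voxelwise"]

MAP_NAMES = ("F", "K1", "k2", "Tc", "td", "vb", "E", "rss")


@dataclass
class DynamicImage:
    """4D dynamic image (x, y, z, frame) in kBq/mL with its frame schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: float = 4.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image data must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis length must equal the schedule length")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match the image grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size_mm
        return a

    def voxel_tac(self, index: tuple[int, int, int],
                  label: str = "") -> TimeActivityCurve:
        return TimeActivityCurve(self.schedule, self.data[index], label)


@dataclass
class ParametricMaps:
    """3D kinetic-parameter maps sharing the source image geometry.

    Voxels outside the analysis mask hold NaN.
    """

    maps: dict
    model_kind: str
    mask: np.ndarray
    voxel_size_mm: float = 4.0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def keys(self):
        return self.maps.keys()


def composite_frames(img: DynamicImage,
                     intervals: Sequence[tuple[float, float]]) -> list[np.ndarray]:
    """Duration-weighted mean volume over each (start_s, end_s) interval."""
    s = img.schedule
    out = []
    for a, b in intervals:
        overlap = np.clip(np.minimum(s.ends, b) - np.maximum(s.starts, a),
                          0.0, None)
        total = overlap.sum()
        if total <= 0:
            raise ValueError(f"interval ({a}, {b}) overlaps no frames")
        out.append(img.data @ (overlap / total))
    return out


@dataclass
class KernelOperator:
    """Sparse row-stochastic neighbor-weight operator over masked voxels."""

    matrix: sparse.csr_matrix = field(repr=False)
    mask: np.ndarray = field(repr=False)
    k: int
    window_radius: int

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]


def build_kernel(composites: Sequence[np.ndarray], mask: np.ndarray,
                 k: int = 49, window_radius: int = 4) -> KernelOperator:
    """Build the kernel smoothing operator from composite-frame features.

    Per masked voxel the feature vector is the z-scored composite intensity;
    its neighbors are the ``k`` masked voxels with smallest Euclidean feature
    distance inside the ``(2*window_radius+1)^3`` spatial window (the voxel
    itself always included; fewer are used where the window holds fewer
    masked voxels).  Weights are Gaussian in feature distance with a
    per-voxel bandwidth equal to the median neighbor distance, degenerating
    to uniform weights when all distances vanish, then row-normalized.
    """
    if len(composites) == 0:
        raise ValueError("at least one composite volume is required")
    mask = np.asarray(mask).astype(bool)
    shape = mask.shape
    if any(c.shape != shape for c in composites):
        raise ValueError("composite shapes must match the mask")
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > (2 * window_radius + 1) ** 3:
        raise ValueError("k exceeds the window volume")

    feats = np.empty(shape + (len(composites),))
    for j, comp in enumerate(composites):
        v = comp[mask]
        sd = v.std()
        feats[..., j] = (comp - v.mean()) / sd if sd > 0 else 0.0

    index_vol = -np.ones(shape, dtype=np.int64)
    coords = np.argwhere(mask)
    index_vol[mask] = np.arange(coords.shape[0])

    r = window_radius
    rows, cols, vals = [], [], []
    for vox_id, (x, y, z) in enumerate(coords):
        sl = (slice(max(x - r, 0), x + r + 1),
              slice(max(y - r, 0), y + r + 1),
              slice(max(z - r, 0), z + r + 1))
        cand_idx = index_vol[sl][mask[sl]]
        fwin = feats[sl][mask[sl]]
        d2 = ((fwin - feats[x, y, z]) ** 2).sum(axis=1)
        self_pos = int(np.nonzero(cand_idx == vox_id)[0][0])
        d2[self_pos] = -1.0                      # self always kept
        k_eff = min(k, d2.size)
        sel = np.argpartition(d2, k_eff - 1)[:k_eff]
        d2sel = np.maximum(d2[sel], 0.0)
        h = np.median(np.sqrt(d2sel))
        if h > 0:
            wts = np.exp(-d2sel / (2.0 * h * h))
        else:
            wts = np.ones(k_eff)
        wts /= wts.sum()
        rows.extend([vox_id] * k_eff)
        cols.extend(cand_idx[sel].tolist())
        vals.extend(wts.tolist())

    n = coords.shape[0]
    mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return KernelOperator(matrix=mat, mask=mask, k=k, window_radius=window_radius)


def apply_kernel(op: KernelOperator, img):
    """Smooth a 3D map or a DynamicImage with the kernel operator.

    Masked voxels become weighted neighbor averages (frame-wise for 4D
    input); voxels outside the mask pass through unchanged.
    """
    if isinstance(img, DynamicImage):
        if img.shape != op.mask.shape:
            raise ValueError("image geometry does not match the operator")
        out = img.data.copy()
        out[op.mask] = op.matrix @ img.data[op.mask]
        return DynamicImage(out, img.schedule, img.voxel_size_mm, img.mask)
    arr = np.asarray(img, dtype=float)
    if arr.shape != op.mask.shape:
        raise ValueError("map geometry does not match the operator")
    out = arr.copy()
    out[op.mask] = op.matrix @ arr[op.mask]
    return out


DEFAULT_COMPOSITE_INTERVALS = ((0.0, 30.0), (30.0, 60.0), (60.0, 120.0))


def fit_voxelwise(img: DynamicImage, aif: ArterialInput,
                  grid: GridConfig | None = None, model_kind: str = "aath",
                  smooth: bool = False,
                  composite_intervals=DEFAULT_COMPOSITE_INTERVALS,
                  k: int = 49, window_radius: int = 4) -> ParametricMaps:
    """Voxelwise kinetic modeling of a dynamic image.

    Optionally smooths the dynamics with the kernel method (operator built
    from composite frames of the input image) before fitting every masked
    voxel against one shared precomputed basis.  Deterministic.
    """
    if img.mask is None or not img.mask.any():
        raise ValueError("dynamic image needs a non-empty analysis mask")
    grid = grid or GridConfig.default()
    work = img
    if smooth:
        comps = composite_frames(img, composite_intervals)
        op = build_kernel(comps, img.mask, k=k, window_radius=window_radius)
        work = apply_kernel(op, img)
    basis = build_basis(aif, img.schedule, grid, model_kind)
    maps = {name: np.full(img.shape, np.nan) for name in MAP_NAMES}
    # frame-duration weights are TAC-independent: resolve once
    proto = TimeActivityCurve(img.schedule, np.zeros(img.schedule.n_frames))
    shared_w = (fit_weights(proto, grid.weighting)
                if grid.weighting != "inverse_variance" else None)
    for x, y, z in np.argwhere(img.mask):
        tac = TimeActivityCurve(img.schedule, work.data[x, y, z])
        fit = fit_tac(tac, basis, weights=shared_w)
        p = fit.params
        maps["K1"][x, y, z] = p.K1
        maps["k2"][x, y, z] = p.k2
        maps["td"][x, y, z] = p.td
        maps["vb"][x, y, z] = p.vb
        maps["rss"][x, y, z] = fit.rss
        if model_kind == "aath":
            maps["F"][x, y, z] = p.F
            maps["Tc"][x, y, z] = p.Tc
            maps["E"][x, y, z] = p.E
    return ParametricMaps(maps=maps, model_kind=model_kind, mask=img.mask,
                          voxel_size_mm=img.voxel_size_mm)
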
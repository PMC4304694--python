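"""Density-map container and map algebra.

A :class:`DensityMap` is a 3D scalar grid on orthogonal axes with a per-axis
voxel size and a world-space origin (the position of the first voxel center),
everything in Angstrom.  The module provides the map statistics used for
Z-scoring (histogram-based, discarding the modal bin so that the huge flat
solvent background of EM boxes does not crush the standard deviation),
trilinear interpolation, model-based masking, spherical segmentation,
B-factor sharpening/blurring, radial amplitude scaling and map combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DensityMap",
    "MapStatistics",
    "SphereRegion",
    "SEGMENT_RADIUS_PROTEIN",
    "SEGMENT_RADIUS_RNA",
    "read_mrc",
    "write_mrc",
    "robust_map_stats",
    "interpolate",
    "trilinear",
    "trilinear_gradient",
    "z_weighted_score",
    "mask_by_model",
    "segment_sphere",
    "sharpen_map",
    "lowpass_map",
    "scale_to_reference",
    "average_maps",
    "composite_maps",
    "sfreq_grid",
    "radial_amplitude",
]

#: Segmentation sphere radii that work well for protein domains and RNA motifs.
SEGMENT_RADIUS_PROTEIN = 34.0
SEGMENT_RADIUS_RNA = 17.0


class DensityMap:
    """3D scalar grid with voxel spacing and world origin (A)."""

    def __init__(self, values: np.ndarray, voxel_size, origin=(0.0, 0.0, 0.0),
                 label: str = ""):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or min(values.shape) < 2:
            raise ValueError("map values must be a 3D grid, each axis >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("map contains non-finite values")
        voxel = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
        if np.any(voxel <= 0):
            raise ValueError("voxel size must be positive")
        self.values = values
        self.voxel_size = voxel
        self.origin = np.asarray(origin, dtype=float).copy()
        self.label = label

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent(self) -> np.ndarray:
        """Physical box edge lengths (A)."""
        return np.array(self.shape) * self.voxel_size

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def world_to_voxel(self, positions: np.ndarray) -> np.ndarray:
        return (np.asarray(positions, dtype=float) - self.origin) / self.voxel_size

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.voxel_size.copy(),
                          self.origin.copy(), self.label)

    def same_grid(self, other: "DensityMap") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size, other.voxel_size)
                and np.allclose(self.origin, other.origin))


@dataclass
class MapStatistics:
    """Mean/sd with the modal histogram bin discarded, plus plain mean/sd."""

    mean: float
    sd: float
    n_used: int
    n_discarded: int
    bin_width: float
    raw_mean: float
    raw_sd: float


@dataclass
class SphereRegion:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O (mode 2, orthogonal cells)
# ---------------------------------------------------------------------------

def read_mrc(path: str) -> DensityMap:
    """Read an MRC2014/CCP4 mode-2 map; axis order normalized to x-fast."""
    m = gemmi.read_ccp4_map(str(path))
    mode = m.header_i32(4)
    if mode != 2:
        raise ValueError(f"unsupported MRC mode {mode}; only mode 2 "
                         "(32-bit float) is supported")
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError("non-orthogonal cell angles are not supported")
    nstart = [m.header_i32(5), m.header_i32(6), m.header_i32(7)]
    origin_words = [m.header_float(50), m.header_float(51), m.header_float(52)]
    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, dtype=float)
    voxel = np.array([cell.a / m.header_i32(8),
                      cell.b / m.header_i32(9),
                      cell.c / m.header_i32(10)])
    if any(abs(o) > 1e-6 for o in origin_words):
        origin = np.array(origin_words, dtype=float)
    else:
        origin = np.array(nstart, dtype=float) * voxel
    return DensityMap(values, voxel, origin)


def write_mrc(dmap: DensityMap, path: str) -> None:
    """Write a mode-2 CCP4/MRC map; origin stored in the MRC2014 origin words."""
    nx, ny, nz = dmap.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    ext = dmap.extent
    grid.set_unit_cell(gemmi.UnitCell(ext[0], ext[1], ext[2], 90, 90, 90))
    np.asarray(grid)[:] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for i, o in enumerate(dmap.origin):
        m.set_header_float(50 + i, float(o))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# statistics and scoring
# ---------------------------------------------------------------------------

def robust_map_stats(dmap: DensityMap, n_bins: int = 10000) -> MapStatistics:
    """Histogram-based mean/variance with the modal bin discarded.

    EM reconstructions sit in boxes padded with (near-)zero solvent, which
    drags the plain mean and sd toward the background.  The density values are
    histogrammed into finely sampled bins, the peak bin is located and its
    voxels are discarded before the mean and sd are computed.
    """
    v = dmap.values.ravel()
    lo, hi = float(v.min()), float(v.max())
    raw_mean, raw_sd = float(v.mean()), float(v.std())
    if hi - lo <= 0:
        raise ValueError("degenerate map: all voxels identical")
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    peak = int(np.argmax(counts))
    if peak == n_bins - 1:  # last bin is closed on the right
        in_peak = (v >= edges[peak]) & (v <= edges[peak + 1])
    else:
        in_peak = (v >= edges[peak]) & (v < edges[peak + 1])
    kept = v[~in_peak]
    if kept.size == 0:
        raise ValueError("degenerate map: all voxels fall in one bin")
    return MapStatistics(mean=float(kept.mean()), sd=float(kept.std()),
                         n_used=int(kept.size), n_discarded=int(in_peak.sum()),
                         bin_width=float(edges[1] - edges[0]),
                         raw_mean=raw_mean, raw_sd=raw_sd)


def trilinear(dmap: DensityMap, positions: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation at world positions.

    Returns (values, inside).  Positions outside the grid bounding box give 0
    with ``inside`` False -- jiggled poses are allowed to leave the box, which
    is padded with near-zero solvent anyway.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    f = dmap.world_to_voxel(pos)
    shape = np.array(dmap.shape)
    inside = np.all((f >= 0) & (f <= shape - 1), axis=1)
    out = np.zeros(len(f))
    if inside.any():
        fi = f[inside]
        i0 = np.floor(fi).astype(int)
        i0 = np.minimum(i0, shape - 2)
        d = fi - i0
        v = dmap.values
        x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
        dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
        c = 0.0
        for ox in (0, 1):
            wx = dx if ox else 1 - dx
            for oy in (0, 1):
                wy = dy if oy else 1 - dy
                for oz in (0, 1):
                    wz = dz if oz else 1 - dz
                    c = c + v[x0 + ox, y0 + oy, z0 + oz] * wx * wy * wz
        out[inside] = c
    return out, inside


def trilinear_gradient(dmap: DensityMap, positions: np.ndarray) -> np.ndarray:
    """Gradient (d density / d world position) of the trilinear interpolant."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    f = dmap.world_to_voxel(pos)
    shape = np.array(dmap.shape)
    inside = np.all((f >= 0) & (f <= shape - 1), axis=1)
    grad = np.zeros((len(f), 3))
    if inside.any():
        fi = f[inside]
        i0 = np.minimum(np.floor(fi).astype(int), shape - 2)
        d = fi - i0
        v = dmap.values
        x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
        dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
        g = np.zeros((inside.sum(), 3))
        for ox in (0, 1):
            wx, dwx = (dx, 1.0) if ox else (1 - dx, -1.0)
            for oy in (0, 1):
                wy, dwy = (dy, 1.0) if oy else (1 - dy, -1.0)
                for oz in (0, 1):
                    wz, dwz = (dz, 1.0) if oz else (1 - dz, -1.0)
                    val = v[x0 + ox, y0 + oy, z0 + oz]
                    g[:, 0] += val * dwx * wy * wz
                    g[:, 1] += val * wx * dwy * wz
                    g[:, 2] += val * wx * wy * dwz
        grad[inside] = g / dmap.voxel_size
    return grad


def interpolate(dmap: DensityMap, position) -> float | np.ndarray:
    """Density at one world position (or an (n,3) array of them)."""
    vals, _ = trilinear(dmap, position)
    pos = np.asarray(position, dtype=float)
    return float(vals[0]) if pos.ndim == 1 else vals


def z_weighted_score(dmap: DensityMap, stats: MapStatistics, model,
                     weight_mode: str = "atomic_number") -> float:
    """Z-weighted sum of interpolated map density at the atom positions.

    score = sum_a w_a * (rho(x_a) - mean) / sd with w_a the atomic number
    (default) or 1.  Out-of-box atoms contribute (0 - mean)/sd.
    """
    if stats.sd <= 0:
        raise ValueError("map stats have zero standard deviation")
    coords = model.coords() if hasattr(model, "coords") else np.asarray(model)
    vals, _ = trilinear(dmap, coords)
    if weight_mode == "atomic_number":
        if hasattr(model, "atomic_numbers"):
            w = model.atomic_numbers()
        else:
            w = np.ones(len(coords))
    elif weight_mode == "unit":
        w = np.ones(len(coords))
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return float(np.sum(w * (vals - stats.mean) / stats.sd))


# ---------------------------------------------------------------------------
# masking and segmentation
# ---------------------------------------------------------------------------

def _voxel_center_grid(dmap: DensityMap) -> np.ndarray:
    axes = [dmap.voxel_centers_axis(i) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def model_distance_grid(dmap: DensityMap, model) -> np.ndarray:
    """Per-voxel distance (A) from the voxel center to the nearest atom."""
    coords = model.coords() if hasattr(model, "coords") else np.asarray(model)
    centers = _voxel_center_grid(dmap).reshape(-1, 3)
    dist, _ = cKDTree(coords).query(centers, k=1)
    return dist.reshape(dmap.shape)


def mask_by_model(dmap: DensityMap, model, radius: float,
                  soft_edge: float = 0.0) -> DensityMap:
    """Zero all density farther than radius (+ cosine soft edge) from the model."""
    if radius <= 0:
        raise ValueError("mask radius must be positive")
    dist = model_distance_grid(dmap, model)
    weight = np.ones(dmap.shape)
    if soft_edge > 0:
        edge = (dist > radius) & (dist < radius + soft_edge)
        weight[edge] = 0.5 * (1 + np.cos(np.pi * (dist[edge] - radius) / soft_edge))
        weight[dist >= radius + soft_edge] = 0.0
    else:
        weight[dist > radius] = 0.0
    out = dmap.copy()
    out.values = dmap.values * weight
    return out


def segment_sphere(dmap: DensityMap, region: SphereRegion) -> DensityMap:
    """Crop the minimal sub-grid holding a sphere; density outside it is zeroed.

    The returned map's origin is updated so world coordinates are preserved:
    interpolating the segment at a point inside the sphere gives the same
    value as interpolating the parent map.
    """
    lo_w = region.center - region.radius
    hi_w = region.center + region.radius
    lo = np.floor(dmap.world_to_voxel(lo_w)).astype(int)
    hi = np.ceil(dmap.world_to_voxel(hi_w)).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, dmap.shape)
    if np.any(hi - lo < 2):
        raise ValueError("sphere does not intersect the map grid")
    sub = dmap.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
    origin = dmap.origin + lo * dmap.voxel_size
    seg = DensityMap(sub, dmap.voxel_size, origin, label=dmap.label)
    dist2 = np.sum((_voxel_center_grid(seg) - region.center) ** 2, axis=-1)
    seg.values[dist2 > region.radius ** 2] = 0.0
    return seg


# ---------------------------------------------------------------------------
# Fourier-space operations
# ---------------------------------------------------------------------------

def sfreq_grid(shape, voxel_size) -> np.ndarray:
    """|s| = 1/d (A^-1) on the FFT grid of a map."""
    voxel = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    fx = np.fft.fftfreq(shape[0], d=voxel[0])
    fy = np.fft.fftfreq(shape[1], d=voxel[1])
    fz = np.fft.fftfreq(shape[2], d=voxel[2])
    gx, gy, gz = np.meshgrid(fx, fy, fz, indexing="ij")
    return np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)


def sharpen_map(dmap: DensityMap, B: float) -> DensityMap:
    """Multiply Fourier coefficients by exp(-B s^2 / 4), s = 1/d.

    With this (crystallographic temperature-factor) sign convention a
    negative B sharpens and a positive B blurs.  The zero-frequency term is
    untouched.
    """
    if not np.isfinite(B):
        raise ValueError("B factor must be finite")
    s = sfreq_grid(dmap.shape, dmap.voxel_size)
    F = np.fft.fftn(dmap.values) * np.exp(-B * s ** 2 / 4.0)
    out = dmap.copy()
    out.values = np.real(np.fft.ifftn(F))
    return out


def lowpass_map(dmap: DensityMap, d_min: float) -> DensityMap:
    """Zero all Fourier coefficients finer than d_min (A)."""
    s = sfreq_grid(dmap.shape, dmap.voxel_size)
    F = np.fft.fftn(dmap.values)
    F[s > 1.0 / d_min] = 0.0
    out = dmap.copy()
    out.values = np.real(np.fft.ifftn(F))
    return out


def _shell_index(s: np.ndarray, n_shells: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width shells in s covering (0, s_max]; returns (index, edges)."""
    s_max = float(s.max())
    edges = np.linspace(0.0, s_max, n_shells + 1)
    idx = np.clip(np.searchsorted(edges, s, side="left") - 1, 0, n_shells - 1)
    return idx, edges


def radial_amplitude(dmap: DensityMap, n_shells: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Shell-averaged |F| profile; returns (s_centers, amplitude)."""
    if n_shells is None:
        n_shells = default_n_shells(dmap.shape)
    F = np.fft.fftn(dmap.values)
    s = sfreq_grid(dmap.shape, dmap.voxel_size)
    idx, edges = _shell_index(s, n_shells)
    amp = np.zeros(n_shells)
    for i in range(n_shells):
        sel = idx == i
        if sel.any():
            amp[i] = np.mean(np.abs(F[sel]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, amp


def default_n_shells(shape) -> int:
    return min(max(min(shape) // 2, 4), 50)


def _piecewise_linear(x: np.ndarray, xs: np.ndarray,
                      ys: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation beyond the anchor range."""
    out = np.interp(x, xs, ys)
    if len(xs) >= 2:
        lo = x < xs[0]
        if lo.any():
            m = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out[lo] = ys[0] + m * (x[lo] - xs[0])
        hi = x > xs[-1]
        if hi.any():
            m = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out[hi] = ys[-1] + m * (x[hi] - xs[-1])
    return out


def scale_to_reference(dmap: DensityMap, reference,
                       n_shells: int | None = None,
                       max_scale: float = 1e3) -> DensityMap:
    """Radial amplitude scaling onto a reference.

    ``reference`` is either a DensityMap on the same grid or a radial
    amplitude curve given as (s_values, amplitudes).  Two stages: first a
    smooth radial scale, piecewise linear in (s^2, log amplitude ratio)
    between per-shell anchors with linear extrapolation — a B-factor-like
    difference exp(-B s^2/4) is log-linear in s^2 and is therefore inverted
    exactly — then a per-shell constant correction so the output's
    shell-averaged |F| equals the reference's.  Shells where the reference
    amplitude vanishes while the map's does not get a capped scale and a
    warning.
    """
    if n_shells is None:
        n_shells = default_n_shells(dmap.shape)
    F = np.fft.fftn(dmap.values)
    s = sfreq_grid(dmap.shape, dmap.voxel_size)
    idx, edges = _shell_index(s, n_shells)
    centers = 0.5 * (edges[:-1] + edges[1:])
    absF = np.abs(F)
    floor = 1e-12 * max(float(absF.max()), 1e-300)
    xs, ys = [], []
    if isinstance(reference, DensityMap):
        if not dmap.same_grid(reference):
            raise ValueError("reference map must share the grid geometry")
        absG = np.abs(np.fft.fftn(reference.values))
        g_floor = 1e-12 * max(float(absG.max()), 1e-300)
        ref_amp = np.zeros(n_shells)
        for i in range(n_shells):
            shell = idx == i
            if shell.any():
                ref_amp[i] = np.mean(absG[shell])
            sel = shell & (absF > floor) & (absG > g_floor)
            if sel.any():
                xs.append(float(np.mean(s[sel] ** 2)))
                ys.append(float(np.mean(np.log(absG[sel]) -
                                        np.log(absF[sel]))))
    else:
        s_ref, a_ref = (np.asarray(x, dtype=float) for x in reference)
        ref_amp = np.interp(centers, s_ref, a_ref)
        for i in range(n_shells):
            shell = idx == i
            if not shell.any():
                continue
            own = np.mean(absF[shell])
            if own > floor and ref_amp[i] > 0:
                xs.append(float(centers[i] ** 2))
                ys.append(float(np.log(ref_amp[i] / own)))
    if xs:
        order = np.argsort(xs)
        smooth = np.exp(_piecewise_linear(
            s ** 2, np.asarray(xs)[order], np.asarray(ys)[order]))
        smooth = np.clip(smooth, 1.0 / max_scale, max_scale)
    else:
        smooth = np.ones_like(s)
    G1 = F * smooth
    abs1 = np.abs(G1)
    shell_scale = np.ones(n_shells)
    for i in range(n_shells):
        sel = idx == i
        if not sel.any():
            continue
        own = np.mean(abs1[sel])
        if own <= 0:
            continue
        if ref_amp[i] <= 0:
            warnings.warn(f"reference amplitude zero in shell {i}; scale capped")
            shell_scale[i] = 1.0 / max_scale
        else:
            shell_scale[i] = min(ref_amp[i] / own, max_scale)
    out = dmap.copy()
    out.values = np.real(np.fft.ifftn(G1 * shell_scale[idx]))
    return out


# ---------------------------------------------------------------------------
# map combination
# ---------------------------------------------------------------------------

def average_maps(maps: list[DensityMap], weights=None) -> DensityMap:
    """Voxelwise (weighted) mean of maps on identical grids."""
    if not maps:
        raise ValueError("no maps given")
    for m in maps[1:]:
        if not maps[0].same_grid(m):
            raise ValueError("maps do not share grid geometry")
    if weights is None:
        weights = np.ones(len(maps))
    weights = np.asarray(weights, dtype=float)
    acc = sum(w * m.values for w, m in zip(weights, maps))
    out = maps[0].copy()
    out.values = acc / weights.sum()
    return out


def composite_maps(maps: list[DensityMap], masks: list[DensityMap]) -> DensityMap:
    """Combine maps with averaging only where the masks overlap.

    out = sum_i m_i * mask_i / sum_i mask_i where the mask sum is positive,
    else 0.  With binary disjoint masks each region is copied verbatim.
    """
    if len(maps) != len(masks) or not maps:
        raise ValueError("need equally many maps and masks")
    for m in list(maps[1:]) + list(masks):
        if not maps[0].same_grid(m):
            raise ValueError("maps/masks do not share grid geometry")
    num = sum(m.values * k.values for m, k in zip(maps, masks))
    den = sum(k.values for k in masks)
    out = maps[0].copy()
    out.values = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out
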
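"""Fourier-shell correlation metrics and half-map cross-validation.

FSC between two maps (or between a model's calculated structure factors and
a map) is computed per resolution shell as Re(sum F_a conj(F_b)) /
sqrt(sum |F_a|^2 sum |F_b|^2), using complex coefficients so the metric
carries phase information, unlike amplitude-only R factors.  Shells are
equal-width in s = 1/d and Friedel mates are counted once (hemisphere of
reciprocal space).  FSC_average = sum N_i FSC_i / sum N_i condenses a curve
into one number that is invariant under any per-shell-constant positive
reweighting of the coefficients — the property that makes it preferable to
weighted R factors for cross-run comparison.

Half-map cross-validation shakes a model, refines it against one half map
only, and compares FSC_work (vs the refinement half) with FSC_test (vs the
free half); large per-shell gaps, or a sharp FSC_work drop at the resolution
cutoff, indicate overfitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .maps import DensityMap, default_n_shells, scale_to_reference, sfreq_grid
from .model import AtomicModel
from .scattering import ELECTRON_TABLE, ScatteringTable
from .synth import calc_structure_factors, map_structure_factors, shake_model

__all__ = [
    "FSCCurve", "ValidationReport", "WeightSpec", "ResolutionEstimate",
    "fsc_between_maps", "fsc_model_map", "fsc_average", "weighted_r_factor",
    "resolution_at_threshold", "cross_validate", "curve_to_text",
    "curve_to_json", "curve_from_json",
]


@dataclass
class FSCCurve:
    """Per-shell FSC: list of (d_max, d_min [A], fsc, n_coeffs).

    Shells are contiguous and ordered coarse to fine; each holds at least
    one coefficient and a finite fsc value.
    """

    shells: list  # of (d_max, d_min, fsc, n)

    def __post_init__(self) -> None:
        if not self.shells:
            raise ValueError("FSC curve must contain at least one shell")
        prev_dmin = None
        for d_max, d_min, fsc, n in self.shells:
            if not (d_min < d_max):
                raise ValueError(f"shell [{d_max}, {d_min}] not ordered")
            if prev_dmin is not None and abs(d_max - prev_dmin) > 1e-9 * d_max:
                raise ValueError("shells not contiguous coarse->fine")
            if n < 1:
                raise ValueError("shell with no coefficients")
            if not np.isfinite(fsc):
                raise ValueError("non-finite FSC value")
            prev_dmin = d_min

    @property
    def fsc(self) -> np.ndarray:
        return np.array([sh[2] for sh in self.shells])

    @property
    def n_coeffs(self) -> np.ndarray:
        return np.array([sh[3] for sh in self.shells])

    def s_mid(self) -> np.ndarray:
        """Shell midpoints in s = 1/d."""
        return np.array([0.5 * (1.0 / d_max + 1.0 / d_min)
                         for d_max, d_min, _, _ in self.shells])

    def same_shells(self, other: "FSCCurve") -> bool:
        if len(self.shells) != len(other.shells):
            return False
        def close(x, y):
            if np.isinf(x) or np.isinf(y):
                return x == y
            return abs(x - y) < 1e-9

        return all(close(a[0], b[0]) and close(a[1], b[1])
                   for a, b in zip(self.shells, other.shells))


@dataclass
class WeightSpec:
    """Per-coefficient weights w_h >= 0; ``None`` means unit weights."""

    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if not np.all(np.isfinite(w)):
                raise ValueError("weights must be finite")
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            self.weights = w

    def resolve(self, n: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(n)
        if self.weights.size != n:
            raise ValueError(
                f"weight count {self.weights.size} != coefficient count {n}")
        return self.weights


@dataclass
class ResolutionEstimate:
    """Resolution estimate from an FSC curve.

    ``crossed`` is False when the curve never drops below the threshold; the
    estimate is then the finest shell edge (a lower bound on resolution).
    """

    d: float
    crossed: bool
    threshold: float


@dataclass
class ValidationReport:
    """Half-map cross-validation result.

    ``max_gap``/``mean_gap`` are computed over shells no finer than the
    refinement cutoff ``d_cut`` (including the shell containing the cutoff).
    """

    fsc_work: FSCCurve
    fsc_test: FSCCurve
    max_gap: float
    mean_gap: float
    d_cut: float
    shake_rms: float = 0.0

    def __post_init__(self) -> None:
        if not self.fsc_work.same_shells(self.fsc_test):
            raise ValueError("work/test curves must share shell boundaries")


def _hemisphere_mask(shape) -> np.ndarray:
    """True for one member of each Friedel pair (and not for F(000))."""
    nx, ny, nz = shape
    ix = np.arange(nx)[:, None, None]
    iy = np.arange(ny)[None, :, None]
    iz = np.arange(nz)[None, None, :]
    # lexicographic comparison of the index triple with its Friedel mate
    # (-h mod N); self-conjugate coefficients (key == ckey) count once, and
    # pairs inside Nyquist planes are handled exactly
    key = (ix * ny + iy) * nz + iz
    ckey = ((((-ix) % nx) * ny + ((-iy) % ny)) * nz + ((-iz) % nz))
    mask = key <= ckey
    mask = np.broadcast_to(mask, shape).copy()
    mask[0, 0, 0] = False
    return mask


def _shell_curve(fa: np.ndarray, fb: np.ndarray, s: np.ndarray,
                 keep: np.ndarray, s_max: float, n_shells: int) -> FSCCurve:
    """Bin two coefficient sets into equal-width-in-s shells and correlate."""
    edges = np.linspace(0.0, s_max, n_shells + 1)
    sel = keep & (s > 0) & (s <= s_max)
    idx = np.minimum((s[sel] / s_max * n_shells).astype(int), n_shells - 1)
    a, b = fa[sel], fb[sel]
    shells = []
    for i in range(n_shells):
        m = idx == i
        n = int(np.count_nonzero(m))
        if n == 0:
            warnings.warn(f"empty FSC shell {i} dropped")
            continue
        cross = np.sum(a[m] * np.conj(b[m])).real
        denom = np.sqrt(np.sum(np.abs(a[m]) ** 2) * np.sum(np.abs(b[m]) ** 2))
        fsc = 0.0 if denom == 0 else float(cross / denom)
        s_lo = max(edges[i], 1e-12)
        shells.append((1.0 / s_lo if edges[i] > 0 else np.inf,
                       1.0 / edges[i + 1], fsc, n))
    return FSCCurve(_finite_coarse_edge(shells))


def _finite_coarse_edge(shells: list) -> list:
    """Replace an infinite coarsest d_max with a large finite sentinel."""
    if shells and not np.isfinite(shells[0][0]):
        d_max, d_min, fsc, n = shells[0]
        shells[0] = (1e6, d_min, fsc, n)
    return shells


def fsc_between_maps(a: DensityMap, b: DensityMap,
                     n_shells: int | None = None) -> FSCCurve:
    """FSC curve between two maps on identical grids.

    Per shell: FSC = Re(sum F_a conj(F_b)) / sqrt(sum|F_a|^2 sum|F_b|^2),
    shells equal-width in s up to the grid Nyquist frequency.
    """
    if not a.same_grid(b):
        raise ValueError("maps must share grid geometry (shape, voxel, origin)")
    if n_shells is None:
        n_shells = default_n_shells(a.shape)
    fa = np.fft.fftn(a.values)
    fb = np.fft.fftn(b.values)
    s = sfreq_grid(a.shape, a.voxel_size)
    s_max = 1.0 / (2.0 * float(np.max(a.voxel_size)))
    keep = _hemisphere_mask(a.shape)
    return _shell_curve(fa, fb, s, keep, s_max, n_shells)


def fsc_model_map(model: AtomicModel, density: DensityMap, d_min: float,
                  table: ScatteringTable = ELECTRON_TABLE,
                  n_shells: int | None = None) -> FSCCurve:
    """FSC between a model's calculated structure factors and a map's FFT,
    over shells spanning (0, 1/d_min]."""
    sf_calc = calc_structure_factors(model, density, d_min, table=table)
    sf_obs = map_structure_factors(density, d_min)
    if n_shells is None:
        n_shells = default_n_shells(density.shape)
    s = sf_calc.s_grid()
    keep = _hemisphere_mask(density.shape)
    return _shell_curve(sf_obs.coeffs, sf_calc.coeffs, s, keep,
                        1.0 / d_min, n_shells)


def fsc_average(curve: FSCCurve) -> float:
    """FSC_average = sum N_i FSC_i / sum N_i.

    Independent of any per-shell-constant positive reweighting of the
    underlying coefficients, because each shell's FSC is scale-invariant and
    the N_i are counts.
    """
    n = curve.n_coeffs.astype(float)
    return float(np.sum(n * curve.fsc) / np.sum(n))


def weighted_r_factor(f_obs, f_calc, w: WeightSpec | None = None) -> float:
    """R_w = sum w |F_o - F_c| / sum w |F_o| over matching amplitude sets."""
    fo = np.abs(np.asarray(f_obs, dtype=float).ravel())
    fc = np.abs(np.asarray(f_calc, dtype=float).ravel())
    if fo.shape != fc.shape:
        raise ValueError("f_obs and f_calc must have matching coefficients")
    wv = (w or WeightSpec()).resolve(fo.size)
    denom = float(np.sum(wv * fo))
    if denom == 0.0:
        raise ValueError("sum of w |F_obs| is zero; R factor undefined")
    return float(np.sum(wv * np.abs(fo - fc)) / denom)


def resolution_at_threshold(curve: FSCCurve,
                            threshold: float = 0.143) -> ResolutionEstimate:
    """Resolution at the first downward crossing of ``threshold``.

    Linear interpolation in s between shell midpoints; if the curve never
    drops below the threshold the finest shell edge is returned with
    ``crossed=False``.
    """
    s_mid = curve.s_mid()
    fsc = curve.fsc
    if fsc[0] < threshold:
        return ResolutionEstimate(d=float(curve.shells[0][0]
                                          if np.isfinite(curve.shells[0][0])
                                          else 1.0 / s_mid[0]),
                                  crossed=True, threshold=threshold)
    for i in range(len(fsc) - 1):
        if fsc[i] >= threshold and fsc[i + 1] < threshold:
            frac = (fsc[i] - threshold) / (fsc[i] - fsc[i + 1])
            s_cross = s_mid[i] + frac * (s_mid[i + 1] - s_mid[i])
            return ResolutionEstimate(d=float(1.0 / s_cross), crossed=True,
                                      threshold=threshold)
    return ResolutionEstimate(d=float(curve.shells[-1][1]), crossed=False,
                              threshold=threshold)


def _gap_stats(work: FSCCurve, test: FSCCurve, d_cut: float
               ) -> tuple[float, float]:
    gaps = []
    for (d_max, d_min, fw, _), (_, _, ft, _) in zip(work.shells, test.shells):
        if d_max >= d_cut:  # shell coarser than, or containing, the cutoff
            gaps.append(abs(fw - ft))
    if not gaps:
        raise ValueError("no shells at or coarser than the resolution cutoff")
    return float(np.max(gaps)), float(np.mean(gaps))


def cross_validate(model: AtomicModel, half1: DensityMap, half2: DensityMap,
                   refine_params=None, shake_rms: float = 0.5,
                   seed: int = 0, rset=None) -> ValidationReport:
    """Shake, refine against half map 1 only, and report FSC_work/FSC_test.

    The half maps are first brought onto a common amplitude scale
    (half2 scaled to half1).  ``refine_params`` is a refine.RefineParams;
    its d_min is the refinement cutoff reported as d_cut.  ``rset``
    optionally overrides the default restraints (the shaken model's own
    geometry plus helical hydrogen bonds), e.g. to probe overfitting with
    deliberately weakened restraints.
    """
    from .refine import RefineParams, refine  # deferred: refine imports fsc

    if not half1.same_grid(half2):
        raise ValueError("half maps must share grid geometry")
    params = refine_params if refine_params is not None else RefineParams()
    half2s = scale_to_reference(half2, half1)
    shaken = shake_model(model, shake_rms, seed=seed) if shake_rms > 0 \
        else model.copy()
    result = refine(shaken, half1, params, rset=rset)
    n_shells = default_n_shells(half1.shape)
    # evaluate the curves out to the grid Nyquist, past the refinement
    # cutoff: the behavior of FSC_work in the never-refined shells beyond
    # d_cut is itself diagnostic (a sharp drop there flags overfitting)
    d_eval = 2.0 * float(np.max(half1.voxel_size))
    work = fsc_model_map(result.model, half1, d_eval, n_shells=n_shells)
    test = fsc_model_map(result.model, half2s, d_eval, n_shells=n_shells)
    max_gap, mean_gap = _gap_stats(work, test, params.d_min)
    return ValidationReport(fsc_work=work, fsc_test=test, max_gap=max_gap,
                            mean_gap=mean_gap, d_cut=params.d_min,
                            shake_rms=shake_rms)


def curve_to_text(curve: FSCCurve) -> str:
    """Two-column text: s = 1/d at shell midpoint, FSC."""
    lines = ["# 1/d(A^-1)  FSC"]
    for s, f in zip(curve.s_mid(), curve.fsc):
        lines.append(f"{s:.6f}  {f:.6f}")
    return "\n".join(lines) + "\n"


def curve_to_json(curve: FSCCurve) -> str:
    return json.dumps({"shells": [
        {"d_max": sh[0], "d_min": sh[1], "fsc": sh[2], "n": sh[3]}
        for sh in curve.shells]}, indent=2)


def curve_from_json(text: str) -> FSCCurve:
    data = json.loads(text)
    return FSCCurve([(sh["d_max"], sh["d_min"], sh["fsc"], sh["n"])
                     for sh in data["shells"]])
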
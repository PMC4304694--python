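"""Synthetic density generation and idealized model building.

This module emulates the upstream single-particle reconstruction pipeline at
the level this toolkit needs: a model is turned into band-limited density
through five-Gaussian scattering factors (density sampling + FFT, with an
anti-aliasing blur applied in real space and removed in reciprocal space),
optionally truncated at a nominal resolution, and independent white Gaussian
noise realizations turn one signal into a half-map pair.  Idealized
poly-alanine helices and A/B-form nucleic-acid duplexes provide ground-truth
models, and shake/bend perturbations create controlled starting points for
fitting, morphing and refinement experiments.

CTF effects, projection geometry and beam-induced motion are upstream of the
toolkit and are not simulated; noise is white in real space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .maps import DensityMap, sfreq_grid
from .model import (Atom, AtomicModel, Residue, RTOperator, _axis_angle_matrix,
                    apply_rt)
from .scattering import ELECTRON_TABLE, ScatteringTable
from . import bases

__all__ = [
    "SFGrid", "NoiseSpec", "calc_structure_factors", "map_structure_factors",
    "sf_to_map", "simulate_map", "simulate_half_maps", "build_ideal_helix",
    "build_ideal_duplex", "build_helix_bundle", "shake_model", "bend_model",
    "DUPLEX_PARAMS",
]

#: Helical rise (A) and twist (deg) per duplex form; implementation defaults.
DUPLEX_PARAMS = {"A": (2.81, 32.7), "B": (3.38, 36.0)}


@dataclass
class NoiseSpec:
    """White Gaussian voxel noise: standard deviation and RNG seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


class SFGrid:
    """Complex structure factors on the reciprocal grid of a real-space map.

    ``coeffs`` follows the numpy fftn layout; the world-space origin of the
    source grid is folded into the phases, so coefficients transform under
    model translation by the plain shift theorem.
    """

    def __init__(self, coeffs: np.ndarray, voxel_size, origin, d_min: float):
        self.coeffs = np.asarray(coeffs, dtype=complex)
        self.voxel_size = np.broadcast_to(
            np.asarray(voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(origin, dtype=float).copy()
        self.d_min = float(d_min)

    @property
    def shape(self):
        return self.coeffs.shape

    def s_grid(self) -> np.ndarray:
        return sfreq_grid(self.shape, self.voxel_size)

    def resolution_mask(self) -> np.ndarray:
        """True where the coefficient is inside the d_min sphere (excl. F(0))."""
        s = self.s_grid()
        return (s > 0) & (s <= 1.0 / self.d_min)

    def amplitudes(self) -> np.ndarray:
        return np.abs(self.coeffs)

    def copy(self) -> "SFGrid":
        return SFGrid(self.coeffs.copy(), self.voxel_size, self.origin,
                      self.d_min)


def _grid_geometry(grid) -> tuple[tuple[int, int, int], np.ndarray, np.ndarray]:
    if isinstance(grid, DensityMap):
        return grid.shape, grid.voxel_size, grid.origin
    shape, voxel, origin = grid
    return (tuple(int(n) for n in shape),
            np.broadcast_to(np.asarray(voxel, dtype=float), (3,)).copy(),
            np.asarray(origin, dtype=float))


def _origin_phase(shape, voxel, origin) -> np.ndarray:
    fx = np.fft.fftfreq(shape[0], d=voxel[0])
    fy = np.fft.fftfreq(shape[1], d=voxel[1])
    fz = np.fft.fftfreq(shape[2], d=voxel[2])
    ph = (np.exp(-2j * np.pi * fx * origin[0])[:, None, None]
          * np.exp(-2j * np.pi * fy * origin[1])[None, :, None]
          * np.exp(-2j * np.pi * fz * origin[2])[None, None, :])
    return ph


def _sample_density(model: AtomicModel, shape, voxel, origin,
                    table: ScatteringTable, extra_b: float,
                    tail_log: float = 21.0) -> np.ndarray:
    """Sum-of-Gaussians atom density sampled at voxel centers.

    Each scattering term a exp(-b s^2/4) corresponds to the real-space
    Gaussian a (4 pi / b')^{3/2} exp(-4 pi^2 r^2 / b') with b' = b + B_atom
    + extra_b.  Atoms outside the grid raise.
    """
    rho = np.zeros(shape)
    lengths = np.array(shape) * voxel
    axes = [origin[i] + np.arange(shape[i]) * voxel[i] for i in range(3)]
    for atom in model.atoms():
        try:
            a_coef, b_coef = table.coefficients[atom.element]
        except KeyError:
            warnings.warn(f"element {atom.element!r} not in scattering table; "
                          "using carbon")
            a_coef, b_coef = table.coefficients["C"]
        pos = atom.position
        fidx = (pos - origin) / voxel
        if np.any(fidx < 0) or np.any(fidx > np.array(shape) - 1):
            raise ValueError(f"atom at {pos} lies outside the map box")
        bp = np.array(b_coef) + atom.b_factor + extra_b
        # nearest-image wrapped axis distances keep the FFT's periodic
        # convention exact (no truncation discontinuity at box edges)
        dax = [np.mod(axes[i] - pos[i] + lengths[i] / 2, lengths[i])
               - lengths[i] / 2 for i in range(3)]
        for a_i, b_i in zip(a_coef, bp):
            k = 4 * np.pi ** 2 / b_i
            amp = atom.occupancy * a_i * (4 * np.pi / b_i) ** 1.5
            sel = [k * d ** 2 < tail_log for d in dax]
            # two-image periodic sum: with large blur the Gaussian tail can
            # reach past half the box, where the next image contributes too
            gx, gy, gz = (np.exp(-k * d[s] ** 2)
                          + np.exp(-k * (L - np.abs(d[s])) ** 2)
                          for d, s, L in zip(dax, sel, lengths))
            rho[np.ix_(*[np.flatnonzero(s) for s in sel])] += (
                amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :])
    return rho


def _sample_density_grad(model: AtomicModel, shape, voxel, origin,
                         table: ScatteringTable, extra_b: float,
                         tail_log: float, field: np.ndarray) -> np.ndarray:
    """Adjoint of _sample_density: d(sum_v field_v rho_v)/d(atom positions).

    ``field`` is a real array on the sampling grid (e.g. dE/drho); the return
    value is an (n_atoms, 3) gradient array.  Mirrors _sample_density's
    two-image periodic Gaussian kernel exactly.
    """
    lengths = np.array(shape) * voxel
    axes = [origin[i] + np.arange(shape[i]) * voxel[i] for i in range(3)]
    grads = np.zeros((sum(1 for _ in model.atoms()), 3))
    for ai, atom in enumerate(model.atoms()):
        try:
            a_coef, b_coef = table.coefficients[atom.element]
        except KeyError:
            a_coef, b_coef = table.coefficients["C"]
        pos = atom.position
        bp = np.array(b_coef) + atom.b_factor + extra_b
        dax = [np.mod(axes[i] - pos[i] + lengths[i] / 2, lengths[i])
               - lengths[i] / 2 for i in range(3)]
        for a_i, b_i in zip(a_coef, bp):
            k = 4 * np.pi ** 2 / b_i
            amp = atom.occupancy * a_i * (4 * np.pi / b_i) ** 1.5
            sel = [k * d ** 2 < tail_log for d in dax]
            ds = [d[s] for d, s in zip(dax, sel)]
            g = []
            dg = []  # d(gaussian)/d(atom coordinate); note d(d)/d(pos) = -1
            for d, L in zip(ds, lengths):
                e1 = np.exp(-k * d ** 2)
                e2 = np.exp(-k * (L - np.abs(d)) ** 2)
                g.append(e1 + e2)
                dg.append(2.0 * k * d * e1
                          - 2.0 * k * (L - np.abs(d)) * np.sign(d) * e2)
            sub = field[np.ix_(*[np.flatnonzero(s) for s in sel])]
            gx, gy, gz = g
            dgx, dgy, dgz = dg
            grads[ai, 0] += amp * np.einsum("ijk,i,j,k->", sub, dgx, gy, gz)
            grads[ai, 1] += amp * np.einsum("ijk,i,j,k->", sub, gx, dgy, gz)
            grads[ai, 2] += amp * np.einsum("ijk,i,j,k->", sub, gx, gy, dgz)
    return grads


def _anti_alias_blur(voxel: float, d_min: float) -> float:
    """Blur B (A^2) making sampling ghosts < ~1e-9 inside the d_min sphere.

    The nearest alias of a coefficient at s_max = 1/d_min sits at
    1/voxel - s_max; a Gaussian blur of width B suppresses it by
    exp(-B (s_ghost^2 - s_max^2)/4).  At d_min close to the Nyquist limit the
    ghost cannot be separated and the blur is clamped.
    """
    s_max = 1.0 / d_min
    s_ghost = 1.0 / voxel - s_max
    gap = s_ghost ** 2 - s_max ** 2
    cap = 400.0 * voxel ** 2
    if gap <= 0.01:
        return cap
    return min(cap, 4.0 * math.log(1e9) / gap)


def calc_structure_factors(model: AtomicModel, grid, d_min: float,
                           table: ScatteringTable = ELECTRON_TABLE) -> SFGrid:
    """Structure factors F(h) of a model on a map's reciprocal grid.

    F(h) = sum_a occ_a f_a(s) exp(-B_a s^2/4) exp(-2 pi i s . x_a), evaluated
    by Gaussian density sampling + FFT; coefficients beyond d_min are zeroed.
    ``grid`` is a DensityMap or a (shape, voxel_size, origin) triple.
    """
    shape, voxel, origin = _grid_geometry(grid)
    if d_min < 2.0 * float(np.max(voxel)):
        raise ValueError(
            f"d_min {d_min} A is finer than the Nyquist limit "
            f"{2.0 * float(np.max(voxel))} A of the grid")
    extra_b = _anti_alias_blur(float(np.max(voxel)), d_min)
    # tail cutoff tightened so truncation error stays below the unblur gain
    tail_log = 21.0 + extra_b / (4.0 * d_min ** 2)
    rho = _sample_density(model, shape, voxel, origin, table, extra_b,
                          tail_log)
    dv = float(np.prod(voxel))
    s = sfreq_grid(shape, voxel)
    F = np.fft.fftn(rho) * dv * _origin_phase(shape, voxel, origin)
    F *= np.exp(extra_b * s ** 2 / 4.0)  # undo the anti-aliasing blur
    F[s > 1.0 / d_min] = 0.0
    return SFGrid(F, voxel, origin, d_min)


def map_structure_factors(dmap: DensityMap, d_min: float | None = None) -> SFGrid:
    """FFT of a map in the same coefficient convention as calc_structure_factors."""
    voxel = dmap.voxel_size
    if d_min is None:
        d_min = 2.0 * float(np.max(voxel))
    dv = float(np.prod(voxel))
    s = sfreq_grid(dmap.shape, voxel)
    F = np.fft.fftn(dmap.values) * dv * _origin_phase(dmap.shape, voxel,
                                                      dmap.origin)
    F[s > 1.0 / d_min] = 0.0
    return SFGrid(F, voxel, dmap.origin, d_min)


def sf_to_map(sf: SFGrid) -> DensityMap:
    """Inverse of map_structure_factors."""
    dv = float(np.prod(sf.voxel_size))
    F = sf.coeffs / _origin_phase(sf.shape, sf.voxel_size, sf.origin)
    values = np.real(np.fft.ifftn(F)) / dv
    return DensityMap(values, sf.voxel_size, sf.origin)


def simulate_map(model: AtomicModel, box, voxel: float, resolution: float,
                 noise: NoiseSpec | None = None, origin=(0.0, 0.0, 0.0),
                 table: ScatteringTable = ELECTRON_TABLE) -> DensityMap:
    """Band-limited model density plus optional white Gaussian noise.

    ``box`` is the edge length (A), scalar or per-axis triple; the grid is
    box/voxel voxels per axis.  Deterministic given the noise seed.
    """
    if resolution < 2.0 * voxel:
        raise ValueError("resolution must be >= 2 * voxel (Nyquist)")
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,))
    shape = tuple(int(round(b / voxel)) for b in box)
    sf = calc_structure_factors(model, (shape, voxel, origin), resolution,
                                table)
    dmap = sf_to_map(sf)
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        dmap.values = dmap.values + rng.normal(0.0, noise.sigma, shape)
    return dmap


def simulate_half_maps(model: AtomicModel, box, voxel: float,
                       resolution: float, noise: NoiseSpec,
                       seed_pair: tuple[int, int],
                       origin=(0.0, 0.0, 0.0),
                       table: ScatteringTable = ELECTRON_TABLE
                       ) -> tuple[DensityMap, DensityMap]:
    """Half-map pair: identical signal, independent noise realizations."""
    s1, s2 = seed_pair
    if s1 == s2:
        raise ValueError("half-map noise seeds must differ (independence)")
    clean = simulate_map(model, box, voxel, resolution, None, origin, table)
    halves = []
    for seed in (s1, s2):
        h = clean.copy()
        if noise.sigma > 0:
            rng = np.random.default_rng(seed)
            h.values = h.values + rng.normal(0.0, noise.sigma, clean.shape)
        halves.append(h)
    return halves[0], halves[1]


# ---------------------------------------------------------------------------
# idealized model generators
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
                angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d from a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(angle),
                   bond * math.sin(angle) * math.cos(torsion),
                   bond * math.sin(angle) * math.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_ideal_helix(n_res: int, phi: float = -57.0, psi: float = -47.0
                      ) -> AtomicModel:
    """Poly-Ala alpha-helix with uniform backbone dihedrals.

    phi = -57, psi = -47 degrees give the canonical ~1.5 A rise per residue
    and 3.8 A consecutive C-alpha spacing.
    """
    if n_res < 1:
        raise ValueError("need at least one residue")
    residues = []
    prev = None
    for i in range(n_res):
        if prev is None:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([1.458, 0.0, 0.0])
            c = _place_atom(np.array([0.0, 1.0, 0.0]), n, ca,
                            1.525, 111.2, 33.0)
        else:
            pn, pca, pc = prev
            n = _place_atom(pn, pca, pc, 1.329, 116.2, psi)
            ca = _place_atom(pca, pc, n, 1.458, 121.7, 180.0)
            c = _place_atom(pc, n, ca, 1.525, 111.2, phi)
        o = _place_atom(n, ca, c, 1.231, 120.8, psi + 180.0)
        cb = _place_atom(c, n, ca, 1.521, 110.4, -122.0)
        residues.append(Residue("ALA", i + 1, [
            Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c),
            Atom("O", "O", o), Atom("CB", "C", cb)]))
        prev = (n, ca, c)
    return AtomicModel([("A", residues)])


def helix_axis(model: AtomicModel) -> np.ndarray:
    """Unit vector along the helix (principal axis of the C-alpha trace),
    oriented from N- to C-terminus."""
    ca = np.array([r.find_atom("CA").position for _, r in model.residues()
                   if r.find_atom("CA") is not None])
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if (ca[-1] - ca[0]) @ axis < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def build_ideal_duplex(sequence: str, form: str = "A", kind: str = "RNA"
                       ) -> AtomicModel:
    """Idealized double helix with canonical Watson-Crick pairing.

    The given strand runs 5'->3' as chain A; the reverse-complement strand is
    chain B.  Base pairs are stacked by the per-form helical rise/twist, with
    the pair center on the helix axis (no x-displacement or inclination --
    an idealization that keeps the generator consistent with the base-pair
    and stacking detectors).
    """
    form = form.upper()
    kind = kind.upper()
    if form not in DUPLEX_PARAMS:
        raise ValueError(f"unknown duplex form {form!r}")
    if kind not in ("RNA", "DNA"):
        raise ValueError(f"kind must be RNA or DNA, got {kind!r}")
    alphabet = "ACGU" if kind == "RNA" else "ACGT"
    sequence = sequence.upper()
    for ch in sequence:
        if ch not in alphabet:
            raise ValueError(f"invalid {kind} base {ch!r} in sequence")
    rise, twist = DUPLEX_PARAMS[form]
    res_a, res_b = [], []
    for i, base in enumerate(sequence):
        comp = bases.WC_COMPLEMENT[base]
        if kind == "DNA" and base == "A":
            comp = "T"
        c1 = bases.base_coords_2d(base)
        c2 = {k: np.array([v[0], -v[1]])
              for k, v in bases.base_coords_2d(comp).items()}
        op = RTOperator(_axis_angle_matrix(np.array([0.0, 0.0, 1.0]),
                                           math.radians(twist * i)),
                        np.array([0.0, 0.0, rise * i]))

        def placed(coords2d):
            return {k: apply_rt(op, np.array([v[0], v[1], 0.0]))
                    for k, v in coords2d.items()}

        name_a = base if kind == "RNA" else "D" + base
        name_c = comp if kind == "RNA" else "D" + comp
        atoms_a = _build_res_atoms(placed(c1))
        atoms_b = _build_res_atoms(placed(c2))
        res_a.append(Residue(name_a, i + 1, atoms_a))
        res_b.append(Residue(name_c, len(sequence) - i, atoms_b))
    res_b.reverse()
    return AtomicModel([("A", res_a), ("B", res_b)])


def _build_res_atoms(coords3d: dict[str, np.ndarray]) -> list[Atom]:
    atoms = []
    c1 = coords3d["C1'"]
    # phosphate: radial extension of the glycosidic atom in the pair plane
    axis_pt = np.array([0.0, 0.0, c1[2]])
    radial = c1 - axis_pt
    nr = np.linalg.norm(radial)
    p = axis_pt + radial * (7.5 / nr) if nr > 1e-6 else c1 + np.array([7.5, 0, 0])
    atoms.append(Atom("P", "P", p + np.array([0.0, 0.0, 1.0])))
    for name, pos in coords3d.items():
        atoms.append(Atom(name, name[0], np.asarray(pos, dtype=float)))
    return atoms


def build_helix_bundle(n_helices: int = 3, n_res: int = 20,
                       spacing: float = 10.0) -> AtomicModel:
    """Small antiparallel helix bundle; a convenient single-domain fixture."""
    chains = []
    base = build_ideal_helix(n_res)
    axis = helix_axis(base)
    # rotate so the helix axis lies along z
    target = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, target)
    sv = np.linalg.norm(v)
    if sv > 1e-9:
        R = _axis_angle_matrix(v / sv, math.asin(min(1.0, sv))
                               if axis @ target >= 0
                               else math.pi - math.asin(min(1.0, sv)))
    else:
        R = np.eye(3)
    aligned = base.transformed(RTOperator(R, np.zeros(3)))
    aligned.set_coords(aligned.coords() - aligned.centroid())
    residues_all = []
    seq = 1
    for k in range(n_helices):
        ang = 2 * math.pi * k / n_helices
        offset = np.array([spacing * math.cos(ang), spacing * math.sin(ang), 0])
        flip = RTOperator(_axis_angle_matrix(np.array([1.0, 0.0, 0.0]),
                                             math.pi * (k % 2)), np.zeros(3))
        h = aligned.transformed(flip)
        h.set_coords(h.coords() + offset)
        for _, r in h.residues():
            r2 = r.copy()
            r2.seq_id = seq
            seq += 1
            residues_all.append(r2)
    return AtomicModel([("A", residues_all)])


# ---------------------------------------------------------------------------
# model perturbation
# ---------------------------------------------------------------------------

def shake_model(model: AtomicModel, rms: float, seed: int = 0) -> AtomicModel:
    """I.i.d. Gaussian atom displacements with expected coordinate RMSD = rms."""
    if rms < 0:
        raise ValueError("rms must be >= 0")
    out = model.copy()
    if rms == 0:
        return out
    rng = np.random.default_rng(seed)
    coords = out.coords()
    coords = coords + rng.normal(0.0, rms / math.sqrt(3.0), coords.shape)
    out.set_coords(coords)
    return out


def bend_model(model: AtomicModel, hinge_seq_id: int, axis, angle: float,
               chain_id: str | None = None) -> AtomicModel:
    """Rigidly rotate all residues after the hinge about an axis through the
    hinge residue's C-alpha (or first atom)."""
    out = model.copy()
    cid = chain_id if chain_id is not None else out.chains[0][0]
    residues = dict(out.chains)[cid]
    idx = [i for i, r in enumerate(residues) if r.seq_id == hinge_seq_id]
    if not idx:
        raise ValueError(f"hinge residue {hinge_seq_id} not found")
    i = idx[0]
    if i == 0 or i == len(residues) - 1:
        raise ValueError("hinge residue must not be a chain terminus")
    hinge = residues[i]
    pivot_atom = hinge.find_atom("CA") or hinge.atoms[0]
    pivot = pivot_atom.position
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = _axis_angle_matrix(axis, math.radians(angle))
    for r in residues[i + 1:]:
        for a in r.atoms:
            a.position = R @ (a.position - pivot) + pivot
    return out
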
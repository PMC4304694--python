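"""Restrained coordinate refinement against density.

The refinement target has two components: a geometry (prior knowledge)
term built from covalent ideal-geometry restraints plus the external
restraints of :mod:`emfit.restraints` (distance terms robustly weighted by
the Geman-McClure function), and a density term, either reciprocal-space
(L2 misfit of complex structure factors, so phase information is retained;
the default, because for a noiseless simulated map its global minimum is
exactly the generating coordinates) or real-space (negative Z-weighted
interpolated density, the rigid-body docking score; useful for cheap local
tidying but not stationary at the truth, since a sum of pointwise density
values keeps rewarding motion toward blurred density ridges).  Their
relative contribution is a single scalar weight.

Refinement is first-order gradient descent with a per-cycle cap on the
largest atom shift and backtracking (steps that raise the total score are
rejected), not a second-order maximum-likelihood engine: the scientific
content validated here is the target construction -- restraints, weights,
per-cycle multi-target selection, symmetry-mate clash handling and masked
region refinement -- not the optimizer.

Multi-target restraints (G:U base pairs) are resolved once per cycle: the
alternative geometry agreeing best with the current coordinates becomes the
active target, jointly for all restraints of the same base pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry_tables as geom
from .maps import (DensityMap, MapStatistics, mask_by_model, robust_map_stats,
                   sfreq_grid, trilinear, trilinear_gradient)
from .model import AtomicModel, SymmetryGroup, residue_kind
from .restraints import RestraintSet, TorsionRestraint, atom_index_map, \
    geman_mcclure, generate_hbond_restraints, generate_jelly_restraints
from .scattering import ELECTRON_TABLE
from .synth import (_anti_alias_blur, _origin_phase, _sample_density,
                    _sample_density_grad, map_structure_factors)

__all__ = ["RefineParams", "RefineResult", "CycleRecord", "geometry_energy",
           "select_multi_targets", "density_energy", "refine_coords",
           "refine_masked_region", "refine"]


@dataclass
class RefineParams:
    """Knobs of the two-component refinement target."""

    n_cycles: int = 20
    data_weight: float = 1.0
    gm_scale: float = 0.5         # Geman-McClure scale c (A)
    max_shift: float = 0.5        # per-cycle cap on the largest atom move (A)
    d_min: float = 4.0            # resolution cutoff (reciprocal mode, FSC)
    mode: str = "reciprocal"      # "reciprocal" | "real"
    symmetry: SymmetryGroup | None = None
    nb_dist: float = 2.2          # nonbonded repulsion onset (A)
    inner_steps: int = 4          # descent steps per cycle (shared shift cap)
    nb_weight: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.data_weight < 0:
            raise ValueError("data_weight must be >= 0")
        if self.mode not in ("real", "reciprocal"):
            raise ValueError(f"unknown refinement mode {self.mode!r}")


@dataclass
class CycleRecord:
    """One refinement cycle: scores, active multi-targets and step size."""

    total: float
    data: float
    geometry: float
    selected_targets: dict
    max_shift: float


@dataclass
class RefineResult:
    """Final model plus the per-cycle trajectory."""

    model: AtomicModel
    cycles: list  # of CycleRecord

    @property
    def final_scores(self) -> CycleRecord:
        return self.cycles[-1]


# ---------------------------------------------------------------------------
# covalent connectivity from the internal ideal-geometry table
# ---------------------------------------------------------------------------

def _covalent_terms(model: AtomicModel, index: dict):
    """(bond list, angle list) of covalent terms resolvable in the model.

    bonds: (i, j, ideal, sigma); angles: (i, j, k, ideal_deg, sigma_deg)
    with j the vertex.
    """
    bonds, angles = [], []

    def idx(cid, res, name):
        return index.get((cid, res.seq_id, name))

    for cid, residues in model.chains:
        for n, res in enumerate(residues):
            kind = residue_kind(res.name)
            if kind == "protein":
                table_b, table_a = geom.PROTEIN_BONDS, geom.PROTEIN_ANGLES
                link_b, link_a = geom.PROTEIN_LINK_BOND, \
                    geom.PROTEIN_LINK_ANGLES
            elif kind in ("rna", "dna"):
                table_b, table_a = geom.NUCLEIC_BONDS, {}
                link_b, link_a = geom.NUCLEIC_LINK_BOND, {}
            else:
                continue
            for (a, b), ideal in table_b.items():
                i, j = idx(cid, res, a), idx(cid, res, b)
                if i is not None and j is not None:
                    bonds.append((i, j, ideal, geom.BOND_SIGMA))
            for (a, b, c), ideal in table_a.items():
                i, j, k = idx(cid, res, a), idx(cid, res, b), idx(cid, res, c)
                if i is not None and j is not None and k is not None:
                    angles.append((i, j, k, ideal, geom.ANGLE_SIGMA_DEG))
            nxt = residues[n + 1] if n + 1 < len(residues) else None
            if nxt is not None and nxt.seq_id == res.seq_id + 1 \
                    and residue_kind(nxt.name) == kind:
                (a, b), ideal = link_b
                i, j = idx(cid, res, a), idx(cid, nxt, b)
                if i is not None and j is not None:
                    bonds.append((i, j, ideal, geom.BOND_SIGMA))
                for key, ideal_a in link_a.items():
                    trip = [idx(cid, res if off == 0 else nxt, name)
                            for name, off in key]
                    if all(t is not None for t in trip):
                        angles.append((*trip, ideal_a, geom.ANGLE_SIGMA_DEG))
    return bonds, angles


def covalent_pairs(model: AtomicModel) -> set:
    """Atom index pairs joined by a covalent term (for nonbonded exclusion)."""
    index = atom_index_map(model)
    bonds, angles = _covalent_terms(model, index)
    pairs = {tuple(sorted((i, j))) for i, j, _, _ in bonds}
    for i, j, k, _, _ in angles:
        pairs.add(tuple(sorted((i, k))))
        pairs.add(tuple(sorted((i, j))))
        pairs.add(tuple(sorted((j, k))))
    return pairs


# ---------------------------------------------------------------------------
# geometry energy
# ---------------------------------------------------------------------------

def _resolve(index: dict, ref, what: str) -> int:
    try:
        return index[tuple(ref)]
    except KeyError:
        raise ValueError(f"restraint references missing atom {ref!r} "
                         f"({what})") from None


def _torsion_value_grad(p: np.ndarray):
    """Dihedral angle (rad) of 4 points and its analytic gradient (4, 3)."""
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    m = np.cross(n1, b2 / nb2)
    phi = np.arctan2(np.dot(m, n2), np.dot(n1, n2))
    g = np.zeros((4, 3))
    g[0] = nb2 / np.dot(n1, n1) * n1
    g[3] = -nb2 / np.dot(n2, n2) * n2
    f1 = np.dot(b1, b2) / np.dot(b2, b2)
    f3 = np.dot(b3, b2) / np.dot(b2, b2)
    g[1] = -(1.0 + f1) * g[0] + f3 * g[3]
    g[2] = -(1.0 + f3) * g[3] + f1 * g[0]
    return phi, g


def _plane_normal(xyz: np.ndarray) -> np.ndarray:
    c = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - c)
    return vt[2]


def _plane_energy(coords: np.ndarray, idx_a, idx_b, sigma_deg: float):
    na = _plane_normal(coords[idx_a])
    nb = _plane_normal(coords[idx_b])
    ang = np.degrees(np.arccos(np.clip(abs(float(np.dot(na, nb))), 0.0, 1.0)))
    return (ang / sigma_deg) ** 2


def geometry_energy(model: AtomicModel, rset: RestraintSet,
                    gm_scale: float = 0.5,
                    coords: np.ndarray | None = None
                    ) -> tuple[float, np.ndarray]:
    """Geometry score and its per-atom gradient.

    Terms: covalent bonds/angles from the internal ideal-geometry table
    (harmonic, ((x - x0)/sigma)^2); external distance restraints through the
    Geman-McClure function, rho(d - d_target, c) / sigma^2; torsion
    restraints (harmonic in the wrapped angle difference); parallel-plane
    restraints (harmonic in the inter-normal angle; gradient for this term
    by central differences over its few atoms, all other gradients
    analytic).  Multi-target restraints use their first target here; run
    select_multi_targets beforehand to pick per-cycle alternatives.
    """
    if gm_scale <= 0:
        raise ValueError("gm_scale must be > 0")
    if coords is None:
        coords = model.coords()
    index = atom_index_map(model)
    grad = np.zeros_like(coords)
    energy = 0.0

    bonds, angles = _covalent_terms(model, index)
    for i, j, ideal, sigma in bonds:
        v = coords[i] - coords[j]
        d = np.linalg.norm(v)
        dev = (d - ideal) / sigma
        energy += dev ** 2
        g = 2.0 * dev / sigma * v / d
        grad[i] += g
        grad[j] -= g
    for i, j, k, ideal, sigma in angles:
        u, v = coords[i] - coords[j], coords[k] - coords[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        theta = np.degrees(np.arccos(cosang))
        dev = (theta - ideal) / sigma
        energy += dev ** 2
        sin = np.sqrt(max(1.0 - cosang ** 2, 1e-12))
        pref = 2.0 * dev / sigma * np.degrees(-1.0 / sin)
        dci = (v / (nu * nv)) - cosang * u / nu ** 2
        dck = (u / (nu * nv)) - cosang * v / nv ** 2
        grad[i] += pref * dci
        grad[k] += pref * dck
        grad[j] -= pref * (dci + dck)

    for r in rset.distance:
        i = _resolve(index, r.atom_a, f"{r.kind} restraint")
        j = _resolve(index, r.atom_b, f"{r.kind} restraint")
        target, sigma = r.targets[0]
        v = coords[i] - coords[j]
        d = np.linalg.norm(v)
        val, dval = geman_mcclure(d - target, gm_scale)
        energy += val / sigma ** 2
        g = (dval / sigma ** 2) * v / d
        grad[i] += g
        grad[j] -= g

    for r in rset.torsion:
        ids = [_resolve(index, a, "torsion restraint") for a in r.atoms]
        phi, gphi = _torsion_value_grad(coords[list(ids)])
        target, sigma = r.targets[0]
        diff = np.degrees(phi) - target
        diff = (diff + 180.0) % 360.0 - 180.0
        energy += (diff / sigma) ** 2
        pref = 2.0 * diff / sigma ** 2 * np.degrees(1.0)
        for a, k in enumerate(ids):
            grad[k] += pref * gphi[a]

    h = 1e-5
    for r in rset.plane:
        idx_a = [_resolve(index, a, "plane restraint")
                 for a in r.plane_a_atoms]
        idx_b = [_resolve(index, a, "plane restraint")
                 for a in r.plane_b_atoms]
        energy += _plane_energy(coords, idx_a, idx_b, r.sigma_deg)
        for k in set(idx_a) | set(idx_b):
            for ax in range(3):
                cp = coords.copy()
                cp[k, ax] += h
                ep = _plane_energy(cp, idx_a, idx_b, r.sigma_deg)
                cp[k, ax] -= 2 * h
                em = _plane_energy(cp, idx_a, idx_b, r.sigma_deg)
                grad[k, ax] += (ep - em) / (2 * h)
    return float(energy), grad


# ---------------------------------------------------------------------------
# multi-target selection
# ---------------------------------------------------------------------------

def select_multi_targets(model: AtomicModel, rset: RestraintSet
                         ) -> tuple[RestraintSet, dict]:
    """Resolve alternative targets against the current coordinates.

    Restraints sharing a residue pair (one base pair) are selected jointly:
    the alternative with the least total squared distance deviation wins and
    is applied to that pair's distance and torsion restraints alike.
    Returns (single-target restraint set, {group: chosen index}).
    """
    index = atom_index_map(model)
    coords = model.coords()

    def group_key(a, b):
        return tuple(sorted(((a[0], a[1]), (b[0], b[1]))))

    groups: dict = {}
    for r in rset.distance:
        if len(r.targets) > 1:
            groups.setdefault(group_key(r.atom_a, r.atom_b), []).append(r)
    chosen = {}
    for key, members in groups.items():
        n_alt = len(members[0].targets)
        if any(len(m.targets) != n_alt for m in members):
            raise ValueError(f"inconsistent alternative count in group {key}")
        dev = np.zeros(n_alt)
        for m in members:
            i = _resolve(index, m.atom_a, "multi-target restraint")
            j = _resolve(index, m.atom_b, "multi-target restraint")
            d = np.linalg.norm(coords[i] - coords[j])
            for k in range(n_alt):
                dev[k] += (d - m.targets[k][0]) ** 2
        chosen[key] = int(np.argmin(dev))

    def pick_dist(r):
        if len(r.targets) == 1:
            return r
        k = chosen[group_key(r.atom_a, r.atom_b)]
        return type(r)(r.atom_a, r.atom_b, [r.targets[k]], r.kind)

    def pick_tors(r):
        if len(r.targets) == 1:
            return r
        key = group_key(r.atoms[0], r.atoms[-1])
        k = chosen.get(key, 0)
        return TorsionRestraint(r.atoms, [r.targets[k]])

    out = RestraintSet([pick_dist(r) for r in rset.distance],
                       [pick_tors(r) for r in rset.torsion],
                       list(rset.plane), dict(rset.provenance))
    return out, chosen


# ---------------------------------------------------------------------------
# density energy
# ---------------------------------------------------------------------------

def density_energy(model: AtomicModel, dmap: DensityMap, mode: str = "real",
                   weight: float = 1.0, d_min: float = 4.0,
                   stats: MapStatistics | None = None,
                   coords: np.ndarray | None = None,
                   f_obs: np.ndarray | None = None,
                   symmetry: SymmetryGroup | None = None
                   ) -> tuple[float, np.ndarray]:
    """Density score and per-atom gradient.

    real mode: -weight * Z-weighted score (atomic-number weights), gradient
    back-propagated through the trilinear interpolant.  reciprocal mode:
    weight * sum |F_obs - F_calc|^2 over coefficients to d_min, gradient by
    the adjoint of the Gaussian-sampling structure-factor pipeline.  When a
    symmetry group is given, F_calc sums the model over all its operators,
    so refining one copy against a map of the whole assembly is unbiased
    (a monomer-only F_calc would be dragged toward the unmodelled mates).
    """
    if coords is None:
        coords = model.coords()
    n = len(coords)
    if weight == 0.0:
        return 0.0, np.zeros((n, 3))
    w_atom = model.atomic_numbers()
    if mode == "real":
        if stats is None:
            stats = robust_map_stats(dmap)
        if stats.sd <= 0:
            raise ValueError("degenerate map statistics (sd = 0)")
        vals, _ = trilinear(dmap, coords)
        energy = -weight * float(np.sum(w_atom * (vals - stats.mean)
                                        / stats.sd))
        g = trilinear_gradient(dmap, coords)
        grad = -weight * (w_atom / stats.sd)[:, None] * g
        return energy, grad
    if mode != "reciprocal":
        raise ValueError(f"unknown density mode {mode!r}")

    shape, voxel, origin = dmap.shape, dmap.voxel_size, dmap.origin
    if f_obs is None:
        f_obs = map_structure_factors(dmap, d_min).coeffs
    extra_b = _anti_alias_blur(float(np.max(voxel)), d_min)
    tail_log = 21.0 + extra_b / (4.0 * d_min ** 2)
    ops = [op for op in symmetry.operators] if symmetry is not None \
        else [None]
    work = model.copy()
    rho = None
    for op in ops:
        xyz = coords if op is None \
            else coords @ op.rotation.T + op.translation
        work.set_coords(xyz)
        part = _sample_density(work, shape, voxel, origin, ELECTRON_TABLE,
                               extra_b, tail_log)
        rho = part if rho is None else rho + part
    dv = float(np.prod(voxel))
    s = sfreq_grid(shape, voxel)
    transfer = dv * _origin_phase(shape, voxel, origin) \
        * np.exp(extra_b * s ** 2 / 4.0)
    transfer[s > 1.0 / d_min] = 0.0
    f_calc = np.fft.fftn(rho) * transfer
    resid = f_calc - f_obs
    energy = weight * float(np.sum(np.abs(resid) ** 2))
    # dE/drho = 2 w N^3 Re[ifftn(resid * conj(transfer))]
    field = 2.0 * weight * np.prod(shape) \
        * np.real(np.fft.ifftn(resid * np.conj(transfer)))
    grad = np.zeros((n, 3))
    for op in ops:
        xyz = coords if op is None \
            else coords @ op.rotation.T + op.translation
        work.set_coords(xyz)
        g_img = _sample_density_grad(work, shape, voxel, origin,
                                     ELECTRON_TABLE, extra_b, tail_log,
                                     field)
        grad += g_img if op is None else g_img @ op.rotation
    return energy, grad


# ---------------------------------------------------------------------------
# nonbonded repulsion
# ---------------------------------------------------------------------------

def _residue_of_atoms(model: AtomicModel) -> np.ndarray:
    """Per-atom (chain index, residue position) id for exclusion rules."""
    out = []
    for ci, (_, residues) in enumerate(model.chains):
        for ri, res in enumerate(residues):
            out.extend([(ci, ri)] * len(res.atoms))
    return np.array(out)


def _nonbonded_energy(coords: np.ndarray, res_id: np.ndarray,
                      excluded: set, r0: float, k: float,
                      symmetry: SymmetryGroup | None
                      ) -> tuple[float, np.ndarray]:
    """Soft quartic repulsion k ((r0 - r)/r0)^4 below r0, intra-model pairs
    (minus covalent/adjacent exclusions) plus symmetry-mate pairs."""
    from scipy.spatial import cKDTree

    energy = 0.0
    grad = np.zeros_like(coords)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(r0):
        ci, ri = res_id[i]
        cj, rj = res_id[j]
        if ci == cj and abs(ri - rj) <= 1:
            continue
        if tuple(sorted((i, j))) in excluded:
            continue
        v = coords[i] - coords[j]
        r = np.linalg.norm(v)
        if r >= r0 or r == 0:
            continue
        energy += k * ((r0 - r) / r0) ** 4
        g = -4.0 * k * (r0 - r) ** 3 / r0 ** 4 * v / r
        grad[i] += g
        grad[j] -= g
    if symmetry is not None:
        for op in symmetry.operators:
            if op.is_identity(1e-6):
                continue
            imaged = coords @ op.rotation.T + op.translation
            itree = cKDTree(imaged)
            for i, js in enumerate(tree.query_ball_tree(itree, r0)):
                for j in js:
                    v = coords[i] - imaged[j]
                    r = np.linalg.norm(v)
                    if r >= r0 or r == 0:
                        continue
                    energy += k * ((r0 - r) / r0) ** 4
                    g = -4.0 * k * (r0 - r) ** 3 / r0 ** 4 * v / r
                    grad[i] += g
                    grad[j] -= op.rotation.T @ g
    return energy, grad


# ---------------------------------------------------------------------------
# the refinement loop
# ---------------------------------------------------------------------------

def _diag_stiffness(model: AtomicModel, rset: RestraintSet,
                    index: dict) -> np.ndarray:
    """Per-atom curvature estimate used to precondition descent steps.

    Harmonic distance terms contribute 2/sigma^2 to each end atom; covalent
    angle terms a small-angle Cartesian equivalent.  The restraint energy is
    dominated by very stiff terms (sigma ~ 0.02 A) while the density pull is
    soft, so raw steepest descent is catastrophically ill-conditioned;
    dividing the gradient per atom by this positive diagonal lets stiff and
    soft degrees of freedom advance at comparable rates while remaining a
    descent direction (backtracking still enforces monotonicity).
    """
    n = model.n_atoms
    p = np.full(n, 1.0)
    bonds, angles = _covalent_terms(model, index)
    for i, j, _, sigma in bonds:
        p[i] += 2.0 / sigma ** 2
        p[j] += 2.0 / sigma ** 2
    deg = np.degrees(1.0)
    for i, j, k, _, sigma in angles:
        c = 2.0 * deg ** 2 / (sigma ** 2 * 1.5 ** 2)
        p[i] += c
        p[j] += 2.0 * c
        p[k] += c
    for r in rset.distance:
        sigma = r.targets[0][1]
        i = _resolve(index, r.atom_a, f"{r.kind} restraint")
        j = _resolve(index, r.atom_b, f"{r.kind} restraint")
        p[i] += 2.0 / sigma ** 2
        p[j] += 2.0 / sigma ** 2
    return p

def refine_coords(model: AtomicModel, dmap: DensityMap,
                  rset: RestraintSet, params: RefineParams | None = None
                  ) -> RefineResult:
    """Gradient-descent refinement of atomic coordinates.

    Per cycle: resolve multi-target restraints, evaluate the total score
    (geometry + weighted density + nonbonded repulsion), take a steepest-
    descent step capped at params.max_shift for the largest atom, and
    backtrack (halve the step) until the score decreases; a cycle that finds
    no decreasing step leaves the coordinates unchanged.
    """
    params = params or RefineParams()
    work = model.copy()
    stats = robust_map_stats(dmap) if params.mode == "real" else None
    f_obs = None
    if params.mode == "reciprocal":
        f_obs = map_structure_factors(dmap, params.d_min).coeffs
    res_id = _residue_of_atoms(work)
    excluded = covalent_pairs(work)

    # automatic weighting (REFMAC-style "weight auto"): the raw data-term
    # gradient scales with map size and contents, so a fixed weight would
    # make the two-component target either all-data or all-geometry.  The
    # data gradient is scaled to the geometry-gradient RMS at the starting
    # point; params.data_weight multiplies that balanced scale (w = 1
    # balanced, w >> 1 data-dominated).
    data_scale = 1.0
    if params.data_weight != 0.0:
        start_active, _ = select_multi_targets(work, rset)
        _, g_geo0 = geometry_energy(work, start_active, params.gm_scale)
        _, g_dat0 = density_energy(work, dmap, params.mode, 1.0,
                                   params.d_min, stats=stats, f_obs=f_obs,
                                   symmetry=params.symmetry)
        rms_g = float(np.sqrt(np.mean(g_geo0 ** 2)))
        rms_d = float(np.sqrt(np.mean(g_dat0 ** 2)))
        if rms_d > 1e-12 and rms_g > 1e-12:
            data_scale = rms_g / rms_d

    def total(coords, active):
        e_geo, g_geo = geometry_energy(work, active, params.gm_scale, coords)
        e_dat, g_dat = density_energy(work, dmap, params.mode,
                                      params.data_weight * data_scale,
                                      params.d_min,
                                      stats=stats, coords=coords,
                                      f_obs=f_obs,
                                      symmetry=params.symmetry)
        e_nb, g_nb = _nonbonded_energy(coords, res_id, excluded,
                                       params.nb_dist, params.nb_weight,
                                       params.symmetry)
        return (e_geo + e_dat + e_nb, e_dat, e_geo + e_nb,
                g_geo + g_dat + g_nb)

    index = atom_index_map(work)
    precond = _diag_stiffness(work, rset, index)
    coords = work.coords()
    cycles = []
    alpha_prev = 1.0
    for _ in range(params.n_cycles):
        work.set_coords(coords)
        # jelly-body semantics: targets follow the current geometry, damping
        # deformation within a cycle without anchoring to the start point
        refreshed = []
        for r in rset.distance:
            if r.kind == "jelly":
                i, j = index[tuple(r.atom_a)], index[tuple(r.atom_b)]
                d = float(np.linalg.norm(coords[i] - coords[j]))
                r = type(r)(r.atom_a, r.atom_b,
                            [(d, r.targets[0][1])], "jelly")
            refreshed.append(r)
        cycle_set = RestraintSet(refreshed, list(rset.torsion),
                                 list(rset.plane), dict(rset.provenance))
        active, chosen = select_multi_targets(work, cycle_set)
        e_tot, e_dat, e_geo, grad = total(coords, active)
        start = coords
        shift = 0.0
        # several preconditioned descent steps per cycle against this
        # cycle's active targets; the whole-cycle shift stays below
        # max_shift
        for _ in range(params.inner_steps):
            direction = grad / precond[:, None]
            dmax = float(np.max(np.linalg.norm(direction, axis=1)))
            budget = params.max_shift - shift
            if dmax <= 0 or budget <= 1e-6:
                break
            # adaptive step carried across steps and cycles: soft collective
            # modes (whose curvature the per-atom diagonal overestimates)
            # need step factors orders of magnitude above the stiff-mode
            # scale; the budget/dmax cap bounds the physical move anyway
            alpha = min(2.0 * alpha_prev, budget / dmax)
            accepted = False
            for _ in range(12):
                trial = coords - alpha * direction
                move = float(np.max(np.linalg.norm(trial - start, axis=1)))
                if move <= params.max_shift + 1e-9:
                    e_trial, e_dat_t, e_geo_t, g_trial = total(trial, active)
                    if e_trial < e_tot:
                        coords, grad = trial, g_trial
                        e_tot, e_dat, e_geo = e_trial, e_dat_t, e_geo_t
                        shift = move
                        alpha_prev = alpha
                        accepted = True
                        break
                alpha *= 0.5
            if not accepted:
                break
        cycles.append(CycleRecord(e_tot, e_dat, e_geo, dict(chosen), shift))
    work.set_coords(coords)
    return RefineResult(work, cycles)


def refine(model: AtomicModel, dmap: DensityMap,
           params: RefineParams | None = None,
           rset: RestraintSet | None = None) -> RefineResult:
    """Convenience entry point: default restraints are the model's own
    geometry (jelly) plus helical hydrogen bonds."""
    params = params or RefineParams()
    if rset is None:
        rset = generate_jelly_restraints(model).merged(
            generate_hbond_restraints(model))
    return refine_coords(model, dmap, rset, params)


def refine_masked_region(model: AtomicModel, dmap: DensityMap,
                         mask_radius: float,
                         rset: RestraintSet | None = None,
                         params: RefineParams | None = None) -> RefineResult:
    """Reciprocal-space refinement against the map region explained by the
    model: density farther than mask_radius from any atom is zeroed before
    structure factors are computed, so components of a larger reconstruction
    can be refined in isolation."""
    params = params or RefineParams(mode="reciprocal")
    if params.mode != "reciprocal":
        raise ValueError("masked-region refinement uses reciprocal mode")
    masked = mask_by_model(dmap, model, mask_radius)
    if rset is None:
        rset = generate_jelly_restraints(model).merged(
            generate_hbond_restraints(model))
    return refine_coords(model, masked, rset, params)
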
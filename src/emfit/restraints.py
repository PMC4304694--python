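"""External restraint generation for macromolecular refinement.

Covers the restraint families used when refining against medium-resolution
EM maps, where the data alone cannot hold the local geometry together:

* reference restraints -- local interatomic distances copied from a homolog
  or known structure (targets below a 4.2 A threshold);
* jelly restraints -- the model's own current geometry as targets, giving
  slowly deforming ("jelly body") behavior;
* hydrogen-bond and helical-fragment restraints from generic secondary
  structure patterns;
* nucleic-acid base-pair restraints, including dual-target G:U restraints
  that carry both the wobble and the reverse-wobble geometry (the
  refinement engine picks whichever target the current coordinates favor);
* parallel-plane restraints preserving stacking between bases and planar
  side chains;
* the Geman-McClure robust function, which caps the influence of restraint
  outliers.

Atoms are referenced as (chain_id, seq_id, atom_name) triples, resolved
against a model only when energies are evaluated, so restraint sets can be
serialized (JSON, or REFMAC-style ``exte`` text for distances) and reused.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import bases
from .model import AtomicModel, residue_kind, superpose
from .synth import build_ideal_helix

__all__ = [
    "DistanceRestraint", "TorsionRestraint", "BasePair",
    "ParallelPlaneRestraint", "RestraintSet", "generate_reference_restraints",
    "generate_jelly_restraints", "generate_hbond_restraints",
    "generate_helix_fragment_restraints", "detect_base_pairs",
    "generate_base_pair_restraints", "detect_stacking", "geman_mcclure",
    "write_exte", "read_exte", "restraint_set_to_json",
    "restraint_set_from_json", "atom_index_map",
]

#: Restrained atom subsets ("default" mode): main chain + C-beta for protein,
#: backbone + glycosidic nitrogen for nucleic acids.
PROTEIN_RESTRAINED = ("N", "CA", "C", "O", "CB")
NUCLEIC_RESTRAINED = ("P", "O5'", "C5'", "C4'", "C3'", "O3'", "O4'", "C1'",
                      "N1", "N9")

_KINDS = ("reference", "hbond", "helix_fragment", "jelly", "basepair")


@dataclass
class DistanceRestraint:
    """A distance restraint between two atoms with one or more targets.

    Multi-target lists (alternative geometries) are only meaningful for
    base-pair restraints; other kinds must carry exactly one target.
    """

    atom_a: tuple  # (chain_id, seq_id, atom_name)
    atom_b: tuple
    targets: list  # of (d_target A, sigma A)
    kind: str = "reference"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if not self.targets:
            raise ValueError("restraint needs at least one target")
        for d, sigma in self.targets:
            if d <= 0 or sigma <= 0:
                raise ValueError("targets need d > 0 and sigma > 0")
        if len(self.targets) > 1 and self.kind != "basepair":
            raise ValueError("multi-target restraints only for kind=basepair")

    def pair_key(self) -> tuple:
        return tuple(sorted((tuple(self.atom_a), tuple(self.atom_b))))


@dataclass
class TorsionRestraint:
    """A torsion restraint over four atoms, possibly with alternative
    targets (base-pair configurations)."""

    atoms: tuple  # of four (chain_id, seq_id, atom_name)
    targets: list  # of (angle_deg, sigma_deg)

    def __post_init__(self) -> None:
        if len(self.atoms) != 4:
            raise ValueError("torsion restraint needs four atoms")
        if not self.targets:
            raise ValueError("torsion restraint needs at least one target")
        for ang, sigma in self.targets:
            if not (-180.0 < ang <= 180.0):
                raise ValueError("target angle must lie in (-180, 180]")
            if sigma <= 0:
                raise ValueError("sigma must be > 0")


_PAIR_CLASS_NBONDS = {"WC_GC": 3, "WC_AU": 2,
                      "GU_wobble": 2, "GU_reverse_wobble": 2}


@dataclass
class BasePair:
    """A detected base pair: residue references, class and hydrogen bonds."""

    residue_a: tuple  # (chain_id, seq_id, residue_name)
    residue_b: tuple
    pair_class: str
    hbonds: list  # of (atom_a_name, atom_b_name, distance)

    def __post_init__(self) -> None:
        if self.pair_class not in _PAIR_CLASS_NBONDS:
            raise ValueError(f"unknown pair class {self.pair_class!r}")
        if len(self.hbonds) != _PAIR_CLASS_NBONDS[self.pair_class]:
            raise ValueError(
                f"{self.pair_class} expects "
                f"{_PAIR_CLASS_NBONDS[self.pair_class]} hydrogen bonds")


@dataclass
class ParallelPlaneRestraint:
    """Keep two predefined planar groups parallel (target inter-normal
    angle 0) with their centroids at stacking distance."""

    plane_a_atoms: list  # of (chain_id, seq_id, atom_name)
    plane_b_atoms: list
    sigma_deg: float = 5.0
    centroid_bounds: tuple = (2.5, 4.5)

    def __post_init__(self) -> None:
        if len(self.plane_a_atoms) < 3 or len(self.plane_b_atoms) < 3:
            raise ValueError("plane restraint needs >= 3 atoms per plane")
        if self.sigma_deg <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class RestraintSet:
    """Aggregate of distance, torsion and plane restraints."""

    distance: list = field(default_factory=list)
    torsion: list = field(default_factory=list)
    plane: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.distance:
            key = (r.kind, r.pair_key())
            if key in seen:
                raise ValueError(f"duplicate restraint pair {key}")
            seen.add(key)

    def merged(self, other: "RestraintSet") -> "RestraintSet":
        return RestraintSet(self.distance + other.distance,
                            self.torsion + other.torsion,
                            self.plane + other.plane,
                            {**self.provenance, **other.provenance})

    def __len__(self) -> int:
        return len(self.distance) + len(self.torsion) + len(self.plane)


# ---------------------------------------------------------------------------
# atom reference resolution
# ---------------------------------------------------------------------------

def atom_index_map(model: AtomicModel) -> dict:
    """(chain_id, seq_id, atom_name) -> flat atom index (model.coords order)."""
    out = {}
    k = 0
    for chain_id, residues in model.chains:
        for res in residues:
            for atom in res.atoms:
                out[(chain_id, res.seq_id, atom.name)] = k
                k += 1
    return out


def _restrained_atoms(res, mode: str) -> list:
    if mode == "all":
        return [a for a in res.atoms if a.element != "H"]
    kind = residue_kind(res.name)
    allow = PROTEIN_RESTRAINED if kind == "protein" else NUCLEIC_RESTRAINED
    return [a for a in res.atoms if a.name in allow]


# ---------------------------------------------------------------------------
# reference / jelly restraints
# ---------------------------------------------------------------------------

def generate_reference_restraints(target: AtomicModel,
                                  reference: AtomicModel,
                                  correspondence: dict | None = None,
                                  d_max: float = 4.2,
                                  min_seq_sep: int = 2,
                                  sigma: float = 0.1,
                                  atom_mode: str = "default",
                                  kind: str = "reference") -> RestraintSet:
    """Local interatomic distance restraints copied from a reference model.

    ``correspondence`` maps (chain_id, seq_id) in the target to the same in
    the reference; by default residues with identical numbering correspond.
    For every pair of restrained atoms whose reference distance is below
    d_max and whose sequence separation is at least min_seq_sep (pairs on
    different chains always qualify), one restraint is emitted with the
    reference distance as target.
    """
    ref_res = {(cid, res.seq_id): res
               for cid, residues in reference.chains for res in residues}
    if correspondence is None:
        correspondence = {key: key for cid, residues in target.chains
                          for res in residues
                          if (key := (cid, res.seq_id)) in ref_res}
    if not correspondence:
        raise ValueError("empty target/reference residue correspondence")

    # collect corresponded atoms: (target ref triple, chain, seq, ref coords)
    entries = []
    for cid, residues in target.chains:
        for res in residues:
            key = (cid, res.seq_id)
            if key not in correspondence:
                continue
            rres = ref_res.get(correspondence[key])
            if rres is None:
                continue
            for atom in _restrained_atoms(res, atom_mode):
                ratom = rres.find_atom(atom.name)
                if ratom is None:
                    continue
                entries.append(((cid, res.seq_id, atom.name), cid, res.seq_id,
                                ratom.position))
    restraints = []
    seen = set()
    for i in range(len(entries)):
        ref_i, ci, si, xi = entries[i]
        for j in range(i + 1, len(entries)):
            ref_j, cj, sj, xj = entries[j]
            if ci == cj and abs(si - sj) < min_seq_sep:
                continue
            d = float(np.linalg.norm(xi - xj))
            if d >= d_max or d <= 0:
                continue
            key = tuple(sorted((ref_i, ref_j)))
            if key in seen:
                continue
            seen.add(key)
            restraints.append(DistanceRestraint(ref_i, ref_j,
                                                [(d, sigma)], kind))
    return RestraintSet(distance=restraints,
                        provenance={"generator": kind, "d_max": d_max,
                                    "min_seq_sep": min_seq_sep})


def generate_jelly_restraints(model: AtomicModel, d_max: float = 4.2,
                              sigma: float = 0.02) -> RestraintSet:
    """The model's own current geometry as restraint targets."""
    return generate_reference_restraints(model, model, d_max=d_max,
                                         sigma=sigma, kind="jelly")


# ---------------------------------------------------------------------------
# secondary-structure restraints
# ---------------------------------------------------------------------------

def generate_hbond_restraints(model: AtomicModel, max_dist: float = 3.5,
                              target: float = 2.9,
                              sigma: float = 0.2) -> RestraintSet:
    """Alpha-helical O(i)..N(i+4) hydrogen-bond restraints.

    Pairs currently closer than max_dist are restrained to the ideal
    hydrogen-bond length; an empty set is returned when nothing qualifies.
    """
    restraints = []
    for chain_id, residues in model.chains:
        prot = [r for r in residues if residue_kind(r.name) == "protein"]
        by_seq = {r.seq_id: r for r in prot}
        for r in prot:
            partner = by_seq.get(r.seq_id + 4)
            if partner is None:
                continue
            o, n = r.find_atom("O"), partner.find_atom("N")
            if o is None or n is None:
                continue
            if np.linalg.norm(o.position - n.position) < max_dist:
                restraints.append(DistanceRestraint(
                    (chain_id, r.seq_id, "O"),
                    (chain_id, partner.seq_id, "N"),
                    [(target, sigma)], "hbond"))
    return RestraintSet(distance=restraints,
                        provenance={"generator": "hbond"})


def generate_helix_fragment_restraints(model: AtomicModel, window: int = 9,
                                       rmsd_max: float = 1.5,
                                       d_max: float = 4.2,
                                       min_seq_sep: int = 2,
                                       sigma: float = 0.1) -> RestraintSet:
    """Idealized alpha-helix fragment restraints.

    A window slides over each chain; where the backbone superposes onto an
    ideal helix with RMSD below rmsd_max (tolerant detection -- strict
    helical conformation is not required), the ideal fragment's internal
    backbone distances below d_max become targets.
    """
    backbone = ("N", "CA", "C", "O")
    ideal = build_ideal_helix(window)
    ideal_res = ideal.chains[0][1]
    ideal_xyz = {}
    for k, res in enumerate(ideal_res):
        for name in backbone:
            atom = res.find_atom(name)
            if atom is not None:
                ideal_xyz[(k, name)] = atom.position
    restraints = []
    seen = set()
    for chain_id, residues in model.chains:
        prot = [r for r in residues if residue_kind(r.name) == "protein"]
        for start in range(0, len(prot) - window + 1):
            frag = prot[start:start + window]
            if any(frag[k + 1].seq_id != frag[k].seq_id + 1
                   for k in range(window - 1)):
                continue
            pairs = [((k, name), res)
                     for k, res in enumerate(frag) for name in backbone
                     if res.find_atom(name) is not None
                     and (k, name) in ideal_xyz]
            if len(pairs) < 6:
                continue
            mdl = np.array([res.find_atom(name).position
                            for (k, name), res in pairs])
            idl = np.array([ideal_xyz[key] for key, _ in pairs])
            _, rmsd = superpose(mdl, idl)
            if rmsd >= rmsd_max:
                continue
            for i in range(len(pairs)):
                (ki, ni), res_i = pairs[i]
                for j in range(i + 1, len(pairs)):
                    (kj, nj), res_j = pairs[j]
                    if abs(frag[ki].seq_id - frag[kj].seq_id) < min_seq_sep:
                        continue
                    d = float(np.linalg.norm(ideal_xyz[(ki, ni)]
                                             - ideal_xyz[(kj, nj)]))
                    if d >= d_max:
                        continue
                    ra = (chain_id, res_i.seq_id, ni)
                    rb = (chain_id, res_j.seq_id, nj)
                    key = tuple(sorted((ra, rb)))
                    if key in seen:
                        continue
                    seen.add(key)
                    restraints.append(DistanceRestraint(
                        ra, rb, [(d, sigma)], "helix_fragment"))
    return RestraintSet(distance=restraints,
                        provenance={"generator": "helix_fragment"})


# ---------------------------------------------------------------------------
# base pairs
# ---------------------------------------------------------------------------

def _base_letter(name: str) -> str | None:
    n = name.strip().upper()
    if n in ("A", "G", "C", "U", "T"):
        return n
    if n in ("DA", "DG", "DC", "DT", "DU"):
        return n[1]
    return None

def _ring_normal(res) -> np.ndarray | None:
    """Plane normal oriented by the ring-traversal order of the base's
    predefined plane atoms (consistent chirality reference)."""
    letter = _base_letter(res.name)
    if letter is None:
        return None
    names = bases.BASE_PLANE_ATOMS[letter]
    pts = [res.find_atom(n) for n in names]
    pts = [a.position for a in pts if a is not None]
    if len(pts) < 3:
        return None
    pts = np.array(pts)
    c = pts.mean(axis=0)
    normal = np.zeros(3)
    for k in range(len(pts)):
        normal += np.cross(pts[k] - c, pts[(k + 1) % len(pts)] - c)
    norm = np.linalg.norm(normal)
    if norm == 0:
        return None
    # purine and pyrimidine plane-atom lists traverse their rings in
    # opposite senses in the standard frame; the parity makes every
    # unflipped template report the same normal direction, so normal
    # anti-parallelism is exactly the cis (WC-like) chirality signature
    parity = -1.0 if letter in ("C", "U", "T") else 1.0
    return parity * normal / norm


_PATTERN_BASES = {"WC_GC": ("G", "C"), "WC_AU": ("A", "U"),
                  "GU_wobble": ("G", "U"), "GU_reverse_wobble": ("G", "U")}


def detect_base_pairs(model: AtomicModel, dist_tol: float = 0.5,
                      max_plane_angle: float = 35.0,
                      contact_range: tuple = (2.4, 3.5)) -> list[BasePair]:
    """Detect Watson-Crick and G:U base pairs from coordinates.

    Candidates are base pairs with at least one N/O--N/O contact inside
    contact_range; a candidate is accepted when all hydrogen bonds of a
    shipped pattern are within dist_tol of their targets, the base planes
    are within max_plane_angle of parallel, and the ring-normal chirality
    matches the configuration (normals anti-parallel for cis / WC-like
    pairs, parallel for the reverse wobble).  Each residue joins at most
    one pair (lowest total deviation wins).
    """
    from scipy.spatial import cKDTree

    entries = []  # (chain_id, res, letter)
    for chain_id, residues in model.chains:
        for res in residues:
            letter = _base_letter(res.name)
            if letter is not None:
                entries.append((chain_id, res, letter))
    if len(entries) < 2:
        return []
    # contact screen on base N/O atoms
    pts, owner = [], []
    for k, (_, res, letter) in enumerate(entries):
        for atom in res.atoms:
            if atom.element in ("N", "O") and atom.name in \
                    bases.BASE_TEMPLATES[letter]:
                pts.append(atom.position)
                owner.append(k)
    if not pts:
        return []
    tree = cKDTree(np.array(pts))
    owner = np.array(owner)
    cand = set()
    for i, j in tree.query_pairs(contact_range[1]):
        if owner[i] != owner[j]:
            d = np.linalg.norm(pts[i] - pts[j])
            if d >= contact_range[0]:
                cand.add(tuple(sorted((owner[i], owner[j]))))

    scored = []
    for ka, kb in sorted(cand):
        for first, second in ((ka, kb), (kb, ka)):
            ca, ra, la = entries[first]
            cb, rb, lb = entries[second]
            for cls, (need_a, need_b) in _PATTERN_BASES.items():
                if (la, lb) != (need_a, need_b) and not (
                        cls == "WC_AU" and (la, lb) == ("A", "T")):
                    continue
                pattern = bases.HBOND_PATTERNS[cls]
                dev, hbonds, ok = 0.0, [], True
                for an, bn, target in pattern:
                    aa, ab = ra.find_atom(an), rb.find_atom(bn)
                    if aa is None or ab is None:
                        ok = False
                        break
                    d = float(np.linalg.norm(aa.position - ab.position))
                    if abs(d - target) > dist_tol:
                        ok = False
                        break
                    dev += abs(d - target)
                    hbonds.append((an, bn, d))
                if not ok:
                    continue
                na, nb = _ring_normal(ra), _ring_normal(rb)
                if na is None or nb is None:
                    continue
                dot = float(np.dot(na, nb))
                angle = np.degrees(np.arccos(np.clip(abs(dot), 0, 1)))
                if angle > max_plane_angle:
                    continue
                want_anti = cls != "GU_reverse_wobble"
                if (dot < 0) != want_anti:
                    continue
                scored.append((dev, first, second, cls, hbonds))
    scored.sort(key=lambda t: t[0])
    used, pairs = set(), []
    for dev, first, second, cls, hbonds in scored:
        if first in used or second in used:
            continue
        used.update((first, second))
        ca, ra, _ = entries[first]
        cb, rb, _ = entries[second]
        pairs.append(BasePair((ca, ra.seq_id, ra.name),
                              (cb, rb.seq_id, rb.name), cls, hbonds))
    return pairs


def _template_torsion(cls: str) -> float:
    """Glycosidic C1'-N...N-C1' torsion of the ideal (planar) pair
    geometry for a configuration; 0 or 180 by construction."""
    if cls.startswith("WC"):
        a, b = bases.wc_pair_coords("G" if cls == "WC_GC" else "A")
        base_b = "C" if cls == "WC_GC" else "U"
    else:
        a, b = bases.gu_pair_coords(cls)
        base_b = "U"
    base_a = "G" if cls != "WC_AU" else "A"
    p1 = np.append(a["C1'"], 0.0)
    p2 = np.append(a[bases.glycosidic_atom(base_a)], 0.0)
    p3 = np.append(b[bases.glycosidic_atom(base_b)], 0.0)
    p4 = np.append(b["C1'"], 0.0)
    return _torsion_deg(p1, p2, p3, p4)


def _torsion_deg(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / (np.linalg.norm(b2) or 1.0))
    ang = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    return 180.0 if ang <= -180.0 + 1e-9 else float(ang)


def generate_base_pair_restraints(pairs: list[BasePair],
                                  sigma: float = 0.15,
                                  torsion_sigma: float = 10.0
                                  ) -> RestraintSet:
    """Distance (and glycosidic-torsion) restraints from detected pairs.

    Watson-Crick pairs give single-target restraints per hydrogen bond.
    G:U pairs give restraints on the union of wobble/reverse-wobble atom
    pairs, each carrying BOTH configurations' distances as alternative
    targets; the refinement engine selects per cycle.
    """
    gu_targets = bases.gu_target_distances()
    dist, tors = [], []
    for pair in pairs:
        ca, sa, na = pair.residue_a
        cb, sb, nb = pair.residue_b
        if pair.pair_class.startswith("WC"):
            for an, bn, _ in pair.hbonds:
                target = next(t for a2, b2, t in
                              bases.HBOND_PATTERNS[pair.pair_class]
                              if (a2, b2) == (an, bn))
                dist.append(DistanceRestraint((ca, sa, an), (cb, sb, bn),
                                              [(target, sigma)], "basepair"))
            tors.append(TorsionRestraint(
                ((ca, sa, "C1'"), (ca, sa, bases.glycosidic_atom(na)),
                 (cb, sb, bases.glycosidic_atom(nb)), (cb, sb, "C1'")),
                [(_template_torsion(pair.pair_class), torsion_sigma)]))
        else:  # G:U -- dual targets, configuration chosen during refinement
            for an, bn in bases.GU_ATOM_PAIRS:
                targets = [(gu_targets["GU_wobble"][(an, bn)], sigma),
                           (gu_targets["GU_reverse_wobble"][(an, bn)], sigma)]
                dist.append(DistanceRestraint((ca, sa, an), (cb, sb, bn),
                                              targets, "basepair"))
            tors.append(TorsionRestraint(
                ((ca, sa, "C1'"), (ca, sa, "N9"),
                 (cb, sb, "N1"), (cb, sb, "C1'")),
                [(_template_torsion("GU_wobble"), torsion_sigma),
                 (_template_torsion("GU_reverse_wobble"), torsion_sigma)]))
    return RestraintSet(distance=dist, torsion=tors,
                        provenance={"generator": "basepair"})


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

def _plane_group(chain_id: str, res) -> tuple | None:
    letter = _base_letter(res.name)
    if letter is not None:
        names = bases.BASE_PLANE_ATOMS[letter]
    elif res.name.strip().upper() in bases.PROTEIN_PLANE_ATOMS:
        names = bases.PROTEIN_PLANE_ATOMS[res.name.strip().upper()]
    else:
        return None
    atoms = [(n, res.find_atom(n)) for n in names]
    atoms = [(n, a) for n, a in atoms if a is not None]
    if len(atoms) < 3:
        warnings.warn(f"planar group of {res.name} {res.seq_id} has fewer "
                      "than 3 resolved atoms; skipped")
        return None
    refs = [(chain_id, res.seq_id, n) for n, _ in atoms]
    xyz = np.array([a.position for _, a in atoms])
    centroid = xyz.mean(axis=0)
    # orthogonal least-squares plane: normal = smallest singular direction
    _, _, vt = np.linalg.svd(xyz - centroid)
    return refs, centroid, vt[2]


def detect_stacking(model: AtomicModel, max_normal_angle: float = 30.0,
                    max_centroid_angle: float = 45.0,
                    centroid_range: tuple = (2.5, 4.5)
                    ) -> list[ParallelPlaneRestraint]:
    """Detect stacked planar groups and emit parallel-plane restraints.

    Acceptance: inter-normal angle below max_normal_angle, angle between
    each normal and the centroid-centroid vector below max_centroid_angle,
    and centroid distance inside centroid_range.  The centroid-angle test
    is what separates true stacking from side-by-side coplanar groups.
    """
    groups = []
    for chain_id, residues in model.chains:
        for res in residues:
            g = _plane_group(chain_id, res)
            if g is not None:
                groups.append(g)
    out = []
    for i in range(len(groups)):
        refs_i, ci, ni = groups[i]
        for j in range(i + 1, len(groups)):
            refs_j, cj, nj = groups[j]
            v = cj - ci
            dist = np.linalg.norm(v)
            if not (centroid_range[0] <= dist <= centroid_range[1]):
                continue
            v = v / dist

            def fold(cosang: float) -> float:
                return np.degrees(np.arccos(np.clip(abs(cosang), 0.0, 1.0)))

            if fold(np.dot(ni, nj)) > max_normal_angle:
                continue
            if fold(np.dot(ni, v)) > max_centroid_angle:
                continue
            if fold(np.dot(nj, v)) > max_centroid_angle:
                continue
            out.append(ParallelPlaneRestraint(refs_i, refs_j,
                                              centroid_bounds=centroid_range))
    return out


# ---------------------------------------------------------------------------
# robust function
# ---------------------------------------------------------------------------

def geman_mcclure(delta, c: float):
    """Geman-McClure robust function rho(D) = D^2 / (1 + (D/c)^2).

    Returns (value, derivative).  Bounded by c^2; the derivative vanishes
    for large |D|, so gross outliers exert no force.
    """
    if c <= 0:
        raise ValueError("Geman-McClure scale c must be > 0")
    d = np.asarray(delta, dtype=float)
    denom = 1.0 + (d / c) ** 2
    value = d ** 2 / denom
    deriv = 2.0 * d / denom ** 2
    if np.isscalar(delta):
        return float(value), float(deriv)
    return value, deriv


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_exte(rset: RestraintSet) -> str:
    """REFMAC-style external distance restraint text.

    One line per target; alternative targets of a multi-target restraint
    appear on adjacent lines sharing an ``alt group`` tag.
    """
    lines = []
    group = 0
    for r in rset.distance:
        (ca, sa, na), (cb, sb, nb) = r.atom_a, r.atom_b
        base = (f"exte dist first chain {ca} resi {sa} atom {na} "
                f"second chain {cb} resi {sb} atom {nb}")
        if len(r.targets) == 1:
            d, sig = r.targets[0]
            lines.append(f"{base} value {d:.3f} sigma {sig:.3f} type 1")
        else:
            group += 1
            for d, sig in r.targets:
                lines.append(f"{base} value {d:.3f} sigma {sig:.3f} type 1 "
                             f"alt group {group}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_exte(text: str, kind: str = "reference") -> RestraintSet:
    """Parse the ``exte dist`` dialect written by write_exte."""
    pending: dict = {}
    order: list = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        try:
            if tok[0] != "exte" or tok[1] != "dist":
                raise ValueError("not an 'exte dist' record")
            def grab(key, off=1):
                return tok[tok.index(key) + off]
            ca, sa, na = grab("first", 2), int(grab("first", 4)), \
                grab("first", 6)
            cb, sb, nb = grab("second", 2), int(grab("second", 4)), \
                grab("second", 6)
            d = float(grab("value"))
            sig = float(grab("sigma"))
            alt = grab("group") if "alt" in tok else None
        except (ValueError, IndexError) as exc:
            raise ValueError(f"unparseable exte line {ln}: {raw!r}") from exc
        key = ((ca, sa, na), (cb, sb, nb), alt)
        if key not in pending:
            pending[key] = []
            order.append(key)
        pending[key].append((d, sig))
    restraints = []
    for key in order:
        (a, b, alt) = key
        targets = pending[key]
        this_kind = "basepair" if (alt is not None or len(targets) > 1) \
            else kind
        restraints.append(DistanceRestraint(a, b, targets, this_kind))
    return RestraintSet(distance=restraints,
                        provenance={"generator": "exte_import"})


def restraint_set_to_json(rset: RestraintSet) -> str:
    return json.dumps({
        "provenance": rset.provenance,
        "distance": [{"atom_a": list(r.atom_a), "atom_b": list(r.atom_b),
                      "targets": [list(t) for t in r.targets],
                      "kind": r.kind} for r in rset.distance],
        "torsion": [{"atoms": [list(a) for a in r.atoms],
                     "targets": [list(t) for t in r.targets]}
                    for r in rset.torsion],
        "plane": [{"plane_a_atoms": [list(a) for a in r.plane_a_atoms],
                   "plane_b_atoms": [list(a) for a in r.plane_b_atoms],
                   "sigma_deg": r.sigma_deg,
                   "centroid_bounds": list(r.centroid_bounds)}
                  for r in rset.plane],
    }, indent=2)


def restraint_set_from_json(text: str) -> RestraintSet:
    data = json.loads(text)

    def ref(x):
        return (x[0], int(x[1]), x[2])

    return RestraintSet(
        distance=[DistanceRestraint(ref(r["atom_a"]), ref(r["atom_b"]),
                                    [tuple(t) for t in r["targets"]],
                                    r["kind"]) for r in data["distance"]],
        torsion=[TorsionRestraint(tuple(ref(a) for a in r["atoms"]),
                                  [tuple(t) for t in r["targets"]])
                 for r in data["torsion"]],
        plane=[ParallelPlaneRestraint([ref(a) for a in r["plane_a_atoms"]],
                                      [ref(a) for a in r["plane_b_atoms"]],
                                      r["sigma_deg"],
                                      tuple(r["centroid_bounds"]))
               for r in data["plane"]],
        provenance=data.get("provenance", {}))
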
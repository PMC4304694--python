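"""Atomic model container, PDB I/O, rigid-body operators and point-group symmetry.

The model is a plain hierarchy (chains -> residues -> atoms) with Cartesian
coordinates in Angstrom.  It is deliberately minimal: one position per atom
(the highest-occupancy alternate conformer is kept on reading), isotropic
B factors, no hydrogens required.  Maps carry their own origin, so no
fractional coordinates appear anywhere in the toolkit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "AtomicModel",
    "RTOperator",
    "SymmetryGroup",
    "ATOMIC_NUMBERS",
    "read_pdb",
    "write_pdb",
    "apply_rt",
    "angles_to_rt",
    "rt_to_euler",
    "expand_symmetry",
    "superpose",
]

#: Atomic numbers for the elements the toolkit ships scattering factors for,
#: plus a few common hetero elements.  Used as the default Z weight in map
#: scoring.
ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "MG": 12, "P": 15, "S": 16,
    "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "NI": 28, "ZN": 30,
}

_PROTEIN_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "MSE", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL",
}
_RNA_RES = {"A", "C", "G", "U", "I"}
_DNA_RES = {"DA", "DC", "DG", "DT", "DU", "DI"}


@dataclass
class Atom:
    """One atom: name, element symbol, Cartesian position (A), occupancy, B (A^2)."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        self.element = self.element.strip().upper()

    @property
    def atomic_number(self) -> int:
        """Atomic number, or 6 (carbon) for elements not in the table."""
        return ATOMIC_NUMBERS.get(self.element, 6)

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.occupancy, self.b_factor)


def residue_kind(name: str) -> str:
    name = name.strip().upper()
    if name in _PROTEIN_RES:
        return "protein"
    if name in _RNA_RES:
        return "rna"
    if name in _DNA_RES:
        return "dna"
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_amino_acid():
            return "protein"
        if info.is_nucleic_acid():
            return "dna" if name.startswith("D") else "rna"
    return "other"


@dataclass
class Residue:
    """A residue: 3-letter (protein) or 1-2 letter (nucleotide) name plus atoms."""

    name: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    kind: str = ""

    def __post_init__(self) -> None:
        if not self.kind:
            self.kind = residue_kind(self.name)
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.name} {self.seq_id}: duplicate atom names")

    def find_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, [a.copy() for a in self.atoms],
                       self.insertion_code, self.kind)


class AtomicModel:
    """Ordered chains of residues; iteration order is deterministic."""

    def __init__(self, chains: Sequence[tuple[str, Sequence[Residue]]] = ()):
        self.chains: list[tuple[str, list[Residue]]] = [
            (cid, list(residues)) for cid, residues in chains]
        seen = set()
        for cid, residues in self.chains:
            for r in residues:
                key = (cid, r.seq_id, r.insertion_code)
                if key in seen:
                    raise ValueError(f"duplicate residue id {key}")
                seen.add(key)

    # -- iteration helpers -------------------------------------------------
    def residues(self) -> Iterator[tuple[str, Residue]]:
        for cid, residues in self.chains:
            for r in residues:
                yield cid, r

    def atoms(self) -> Iterator[Atom]:
        for _, r in self.residues():
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    @property
    def n_residues(self) -> int:
        return sum(1 for _ in self.residues())

    def coords(self) -> np.ndarray:
        """All atom positions as an (n, 3) array, in iteration order."""
        n = self.n_atoms
        out = np.empty((n, 3))
        for i, a in enumerate(self.atoms()):
            out[i] = a.position
        return out

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for i, a in enumerate(self.atoms()):
            a.position = coords[i].copy()

    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.atomic_number for a in self.atoms()], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def copy(self) -> "AtomicModel":
        return AtomicModel([(cid, [r.copy() for r in residues])
                            for cid, residues in self.chains])

    def transformed(self, op: "RTOperator") -> "AtomicModel":
        m = self.copy()
        m.set_coords(apply_rt(op, m.coords()))
        return m

    def rmsd_to(self, other: "AtomicModel") -> float:
        a, b = self.coords(), other.coords()
        if a.shape != b.shape:
            raise ValueError("models have different atom counts")
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


class RTOperator:
    """Proper rotation plus translation, y = R x + t."""

    def __init__(self, rotation: np.ndarray, translation: np.ndarray,
                 tol: float = 1e-8):
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=max(tol, 1e-8)):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is improper (det -1)")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RTOperator":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RTOperator") -> "RTOperator":
        """self after other: (self o other)(x) = self(other(x))."""
        return RTOperator(self.rotation @ other.rotation,
                          self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RTOperator":
        Rinv = self.rotation.T
        return RTOperator(Rinv, -Rinv @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    def is_identity(self, tol: float = 1e-8) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=tol)
                and np.allclose(self.translation, 0.0, atol=tol))

    def __repr__(self) -> str:
        return f"RTOperator(angle={self.rotation_angle_deg():.2f} deg, t={self.translation})"


class SymmetryGroup:
    """A finite set of rigid-body operators containing the identity."""

    def __init__(self, operators: Sequence[RTOperator]):
        ops = list(operators)
        if not ops:
            raise ValueError("symmetry group must contain at least the identity")
        if not any(op.is_identity(1e-6) for op in ops):
            ops = [RTOperator.identity()] + ops
        self.operators = ops

    def __len__(self) -> int:
        return len(self.operators)

    @classmethod
    def cyclic(cls, n: int, axis: Sequence[float] = (0, 0, 1)) -> "SymmetryGroup":
        """C_n point group about an axis through the origin."""
        axis = np.asarray(axis, dtype=float)
        axis /= np.linalg.norm(axis)
        ops = []
        for k in range(n):
            ops.append(RTOperator(_axis_angle_matrix(axis, 2 * math.pi * k / n),
                                  np.zeros(3)))
        return cls(ops)


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


# ---------------------------------------------------------------------------
# rigid-body algebra
# ---------------------------------------------------------------------------

def apply_rt(op: RTOperator, coords: np.ndarray) -> np.ndarray:
    """Apply y = R x + t to an (n, 3) array (or a single 3-vector)."""
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 1
    out = op.apply(coords)
    return out[0] if single else out


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def angles_to_rt(convention: str, angles: Sequence[float],
                 translation: Sequence[float] = (0.0, 0.0, 0.0)) -> RTOperator:
    """Build an operator from named angles (degrees).

    ``euler``: intrinsic z-y-z Euler angles (alpha, beta, gamma);
    R = Rz(alpha) Ry(beta) Rz(gamma), so euler (90, 0, 0) maps x to y.

    ``polar``: rotation axis at spherical angles (omega from +z, phi about z)
    with spin kappa about that axis.
    """
    a1, a2, a3 = (math.radians(float(x)) for x in angles)
    if not all(math.isfinite(math.degrees(x)) for x in (a1, a2, a3)):
        raise ValueError("angles must be finite")
    if convention == "euler":
        R = _rot_z(a1) @ _rot_y(a2) @ _rot_z(a3)
    elif convention == "polar":
        axis = np.array([math.sin(a1) * math.cos(a2),
                         math.sin(a1) * math.sin(a2),
                         math.cos(a1)])
        R = _axis_angle_matrix(axis, a3)
    else:
        raise ValueError(f"unknown angle convention {convention!r}; "
                         "expected 'euler' or 'polar'")
    return RTOperator(R, np.asarray(translation, dtype=float))


def rt_to_euler(op: RTOperator) -> tuple[float, float, float]:
    """Inverse of angles_to_rt('euler', ...): z-y-z angles in degrees."""
    R = op.rotation
    beta = math.acos(min(1.0, max(-1.0, R[2, 2])))
    if abs(math.sin(beta)) > 1e-10:
        alpha = math.atan2(R[1, 2], R[0, 2])
        gamma = math.atan2(R[2, 1], -R[2, 0])
    else:  # gimbal: fold everything into alpha
        alpha = math.atan2(R[1, 0], R[0, 0]) if R[2, 2] > 0 else \
            -math.atan2(R[1, 0], R[0, 0])
        gamma = 0.0
    return math.degrees(alpha), math.degrees(beta), math.degrees(gamma)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return quaternion_to_matrix(q)


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def matrix_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) with w >= 0 for a proper rotation."""
    t = np.trace(R)
    if t > 0:
        w = math.sqrt(1.0 + t) / 2.0
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1e-12, 1.0 + R[i, i] - R[j, j] - R[k, k])) * 2
        vals = [0.0, 0.0, 0.0]
        vals[i] = s / 4
        vals[j] = (R[j, i] + R[i, j]) / s
        vals[k] = (R[k, i] + R[i, k]) / s
        w = (R[k, j] - R[j, k]) / s
        x, y, z = vals
    q = np.array([w, x, y, z])
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str) -> AtomicModel:
    """Read ATOM/HETATM records of a PDB file into an AtomicModel.

    Alternate conformers are collapsed to the highest-occupancy one (first on
    tie).  Unparseable records raise an error naming the offending line.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        return AtomicModel()
    st.setup_entities()
    chains = []
    for chain in st[0]:
        residues = []
        for res in chain:
            atoms: dict[str, Atom] = {}
            for at in res:
                elem = at.element.name.upper() if at.element else ""
                if not elem:
                    elem = at.name.strip()[:1]
                new = Atom(at.name, elem,
                           np.array([at.pos.x, at.pos.y, at.pos.z]),
                           at.occ, at.b_iso)
                prev = atoms.get(at.name)
                if prev is None or new.occupancy > prev.occupancy:
                    atoms[at.name] = new
            icode = res.seqid.icode.strip()
            residues.append(Residue(res.name, res.seqid.num,
                                    list(atoms.values()), icode))
        if residues:
            chains.append((chain.name, residues))
    return AtomicModel(chains)


def write_pdb(model: AtomicModel, path: str) -> None:
    """Write fixed-column PDB (coordinates to 3 decimals)."""
    lines = ["REMARK   generated by emfit"]
    serial = 0
    for cid, residues in model.chains:
        for res in residues:
            record = "ATOM  " if res.kind != "other" else "HETATM"
            for a in res.atoms:
                serial += 1
                x, y, z = a.position
                if max(abs(x), abs(y), abs(z)) >= 10000:
                    raise ValueError(
                        f"coordinate {a.position} exceeds PDB field width")
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"{record}{serial % 100000:5d} {name:<4s} {res.name:>3s} "
                    f"{cid[:1]:1s}{res.seq_id:4d}{res.insertion_code or ' ':>1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
                    f"{a.b_factor:6.2f}          {a.element:>2s}")
        if residues:
            lines.append(f"TER   {serial % 100000:5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# symmetry expansion and superposition
# ---------------------------------------------------------------------------

def expand_symmetry(model: AtomicModel, group: SymmetryGroup,
                    contact_cutoff: float) -> list[tuple[Atom, RTOperator]]:
    """Symmetry-mate atoms that come within contact_cutoff of the model.

    Returns (atom, operator) pairs for every atom of every non-identity image
    that has at least one atom within the cutoff of the input model; identity
    is never reported.
    """
    if len(group.operators) == 0:
        raise ValueError("empty symmetry group")
    base = model.coords()
    out: list[tuple[Atom, RTOperator]] = []
    atoms = list(model.atoms())
    for op in group.operators:
        if op.is_identity(1e-6):
            continue
        imaged = apply_rt(op, base)
        # image is in contact if any image atom is near any model atom
        d2 = np.min(
            np.sum((imaged[:, None, :] - base[None, :, :]) ** 2, axis=2))
        if d2 <= contact_cutoff ** 2:
            for a, pos in zip(atoms, imaged):
                img = a.copy()
                img.position = pos
                out.append((img, op))
    return out


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[RTOperator, float]:
    """Least-squares rigid superposition of b onto a (Kabsch).

    Returns the operator T with T(b) ~= a and the post-fit RMSD.  Accepts
    AtomicModel arguments too, pairing atoms in iteration order.
    """
    if isinstance(coords_a, AtomicModel):
        coords_a = coords_a.coords()
    if isinstance(coords_b, AtomicModel):
        coords_b = coords_b.coords()
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("superposition needs >=3 paired atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    A, B = a - ca, b - cb
    H = B.T @ A
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("superposition points are (nearly) collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    op = RTOperator(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((op.apply(b) - a) ** 2, axis=1))))
    return op, rmsd
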
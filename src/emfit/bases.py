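"""Idealized nucleic-acid base geometry and pairing patterns.

Each base is shipped as a planar 2D template in the standard base-pair
reference frame (x toward the major-groove edge, y toward the sugar of
strand I, all z = 0).  The Watson-Crick partner of a base is obtained by
flipping the complementary template about the x axis, which directly yields
hydrogen-bond donor-acceptor distances of 2.86-3.02 A.  Wobble and reverse
wobble G:U configurations are constructed by a rigid in-plane placement of
the U template against the fixed G template so that the configuration's two
hydrogen bonds hit their target length.

These templates are implementation defaults chosen to be self-consistent
with the detection thresholds used elsewhere in the toolkit; they are not a
statistical survey.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BASE_TEMPLATES", "WC_COMPLEMENT", "HBOND_PATTERNS", "BASE_PLANE_ATOMS",
    "PROTEIN_PLANE_ATOMS", "base_coords_2d", "wc_pair_coords",
    "gu_pair_coords", "glycosidic_atom", "GU_ATOM_PAIRS", "gu_target_distances",
]

# (x, y) coordinates in the standard pair frame; z = 0.
BASE_TEMPLATES: dict[str, dict[str, tuple[float, float]]] = {
    "A": {"C1'": (-2.479, 5.346), "N9": (-1.291, 4.498), "C8": (0.024, 4.897),
          "N7": (0.877, 3.902), "C5": (0.071, 2.771), "C6": (0.369, 1.398),
          "N6": (1.611, 0.909), "N1": (-0.668, 0.532), "C2": (-1.912, 1.023),
          "N3": (-2.320, 2.290), "C4": (-1.267, 3.124)},
    "G": {"C1'": (-2.477, 5.399), "N9": (-1.289, 4.551), "C8": (0.023, 4.962),
          "N7": (0.870, 3.969), "C5": (0.071, 2.833), "C6": (0.424, 1.460),
          "O6": (1.554, 0.955), "N1": (-0.700, 0.641), "C2": (-1.999, 1.087),
          "N2": (-2.949, 0.139), "N3": (-2.342, 2.364), "C4": (-1.265, 3.177)},
    "C": {"C1'": (-2.477, 5.402), "N1": (-1.285, 4.542), "C2": (-1.472, 3.158),
          "O2": (-2.628, 2.709), "N3": (-0.391, 2.344), "C4": (0.837, 2.868),
          "N4": (1.875, 2.027), "C5": (1.056, 4.275), "C6": (-0.023, 5.068)},
    "U": {"C1'": (-2.481, 5.354), "N1": (-1.284, 4.500), "C2": (-1.462, 3.131),
          "O2": (-2.563, 2.608), "N3": (-0.302, 2.397), "C4": (0.989, 2.884),
          "O4": (1.935, 2.094), "C5": (1.089, 4.311), "C6": (-0.024, 5.053)},
}
BASE_TEMPLATES["T"] = dict(BASE_TEMPLATES["U"], C7=(2.466, 4.961))

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}

#: Hydrogen-bond atom pairs (first base, second base) and target lengths (A)
#: for each supported pair class.  WC G:C has three bonds, the others two.
HBOND_PATTERNS: dict[str, list[tuple[str, str, float]]] = {
    "WC_GC": [("O6", "N4", 3.00), ("N1", "N3", 3.00), ("N2", "O2", 2.87)],
    "WC_AU": [("N6", "O4", 3.02), ("N1", "N3", 2.95)],
    "GU_wobble": [("O6", "N3", 2.80), ("N1", "O2", 2.80)],
    "GU_reverse_wobble": [("O6", "N3", 2.80), ("N1", "O4", 2.80)],
}

#: The atom pairs carrying multi-target G:U restraints (union of both
#: configurations' hydrogen bonds).
GU_ATOM_PAIRS = [("O6", "N3"), ("N1", "O2"), ("N1", "O4")]

#: Predefined planar atom groups (ring systems) per residue name.
BASE_PLANE_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"],
}
for _d, _r in [("DA", "A"), ("DG", "G"), ("DC", "C"), ("DT", "T")]:
    BASE_PLANE_ATOMS[_d] = BASE_PLANE_ATOMS[_r]

#: Planar side-chain groups of aromatic / guanidinium amino acids.
PROTEIN_PLANE_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "ARG": ["CZ", "NH1", "NH2", "NE"],
}


def glycosidic_atom(base: str) -> str:
    """N9 for purines, N1 for pyrimidines."""
    return "N9" if base.upper().lstrip("D") in ("A", "G") else "N1"


def base_coords_2d(base: str) -> dict[str, np.ndarray]:
    base = base.upper().lstrip("D")
    if base not in BASE_TEMPLATES:
        raise ValueError(f"unknown base {base!r}")
    return {k: np.array(v, dtype=float) for k, v in BASE_TEMPLATES[base].items()}


def _flip_y(coords: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.array([v[0], -v[1]]) for k, v in coords.items()}


def wc_pair_coords(base: str) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """2D coordinates of (base, WC partner) in the shared pair frame."""
    base = base.upper().lstrip("D")
    partner = WC_COMPLEMENT[base]
    return base_coords_2d(base), _flip_y(base_coords_2d(partner))


def _fit_two_points(src: np.ndarray, dst: np.ndarray, mirror: bool
                    ) -> tuple[np.ndarray, np.ndarray]:
    """2D rigid transform (optionally with reflection) mapping src[0:2] onto
    dst[0:2] in the least-squares sense; returns (R 2x2, t)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    A, B = src - cs, dst - cd
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.linalg.det(Vt.T @ U.T)
    want = -1.0 if mirror else 1.0
    # det(R) = want: flip the smallest singular direction when needed
    D = np.diag([1.0, want * (1.0 if d >= 0 else -1.0)])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return R, t


def gu_pair_coords(configuration: str
                   ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """2D coordinates of (G, U) in wobble or reverse-wobble configuration.

    The G template stays in its standard-frame position; U is rigidly placed
    in-plane so that the configuration's two hydrogen bonds reach 2.8 A,
    pointing away from the G ring.  A paired base faces its partner, i.e. it
    is flipped relative to the strand-I template, so the WC-like wobble uses
    the mirrored in-plane placement; the reverse wobble flips the base back
    over (ring-traversal normals parallel instead of anti-parallel).
    """
    if configuration not in ("GU_wobble", "GU_reverse_wobble"):
        raise ValueError(f"unknown G:U configuration {configuration!r}")
    g = base_coords_2d("G")
    u = base_coords_2d("U")
    ring = np.array([v for k, v in g.items() if k != "C1'"])
    centroid = ring.mean(axis=0)
    mid = 0.5 * (g["O6"] + g["N1"])
    direction = mid - centroid
    direction /= np.linalg.norm(direction)
    (ga, ua, d1), (gb, ub, d2) = HBOND_PATTERNS[configuration]
    dst = np.array([g[ga] + d1 * direction, g[gb] + d2 * direction])
    mirror = configuration == "GU_wobble"
    src = np.array([u[ua], u[ub]])
    R, t = _fit_two_points(src, dst, mirror=mirror)
    placed = {k: R @ v + t for k, v in u.items()}
    return g, placed


def gu_target_distances() -> dict[str, dict[tuple[str, str], float]]:
    """Distances of the three multi-target G:U atom pairs in each ideal
    configuration, measured on the constructed geometries."""
    out: dict[str, dict[tuple[str, str], float]] = {}
    for config in ("GU_wobble", "GU_reverse_wobble"):
        g, u = gu_pair_coords(config)
        out[config] = {(a, b): float(np.linalg.norm(g[a] - u[b]))
                       for a, b in GU_ATOM_PAIRS}
    return out
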
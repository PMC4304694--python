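"""Minimal internal ideal-geometry table for covalent restraint terms.

Bond lengths (A) and bond angles (deg) for the standard polymer backbone,
matching the values used by the idealized model generators so that ideal
fixtures sit exactly at the covalent-energy minimum.  This is deliberately
not a full chemical dictionary: side chains beyond C-beta, hydrogens and
ligands are out of scope; their geometry is expected to be held by external
(reference/jelly) restraints.
"""

from __future__ import annotations

__all__ = ["PROTEIN_BONDS", "PROTEIN_LINK_BOND", "PROTEIN_ANGLES",
           "PROTEIN_LINK_ANGLES", "NUCLEIC_BONDS", "NUCLEIC_LINK_BOND",
           "BOND_SIGMA", "ANGLE_SIGMA_DEG"]

#: Default uncertainties for covalent terms.
BOND_SIGMA = 0.02      # A
ANGLE_SIGMA_DEG = 3.0  # degrees

#: Intra-residue protein bonds: (atom_a, atom_b) -> ideal length (A).
PROTEIN_BONDS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.521,
}

#: Peptide link bond: C(i) - N(i+1).
PROTEIN_LINK_BOND = (("C", "N"), 1.329)

#: Intra-residue protein angles: (a, b, c) -> ideal angle (deg), vertex b.
PROTEIN_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "O"): 120.8,
    ("N", "CA", "CB"): 110.4,
}

#: Link angles spanning the peptide bond: (atoms, residue offsets) -> deg.
#: Offsets say which residue (0 = current, 1 = next) each atom belongs to.
PROTEIN_LINK_ANGLES = {
    (("CA", 0), ("C", 0), ("N", 1)): 116.2,
    (("C", 0), ("N", 1), ("CA", 1)): 121.7,
}

#: Intra-residue nucleic-acid backbone bonds (applied only when both atoms
#: are present in the residue).
NUCLEIC_BONDS = {
    ("P", "O5'"): 1.593,
    ("O5'", "C5'"): 1.440,
    ("C5'", "C4'"): 1.510,
    ("C4'", "C3'"): 1.524,
    ("C3'", "O3'"): 1.423,
    ("C4'", "O4'"): 1.453,
    ("O4'", "C1'"): 1.414,
}

#: Phosphodiester link bond: O3'(i) - P(i+1).
NUCLEIC_LINK_BOND = (("O3'", "P"), 1.607)
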
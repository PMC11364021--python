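"""United-atom chemistry tables for protein SAXS calculations.

Heavy atoms are treated as united-atom groups (heavy atom plus its bonded
hydrogens).  Each group carries a displaced-solvent volume, from which the
group radius and the Gaussian-sphere dummy form factor are derived, and an
implicit-hydrogen count.  The volume set is the classic displaced-solvent
table of Fraser, MacRae & Suzuki as adopted by dummy-atom SAXS codes; it is
a documented default of this package, overridable via configuration, and not
a reproduction of any one program's internal table.
"""

from __future__ import annotations

import math

# electrons per element
ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15}

# group -> (heavy element, implicit H count, displaced-solvent volume [A^3])
GROUP_TABLE: dict[str, tuple[str, int, float]] = {
    "C":   ("C", 0, 16.44),
    "CH":  ("C", 1, 21.59),
    "CH2": ("C", 2, 26.74),
    "CH3": ("C", 3, 31.89),
    "N":   ("N", 0, 2.49),
    "NH":  ("N", 1, 7.64),
    "NH2": ("N", 2, 12.79),
    "NH3": ("N", 3, 17.94),
    "O":   ("O", 0, 9.13),
    "OH":  ("O", 1, 14.28),
    "S":   ("S", 0, 19.86),
    "SH":  ("S", 1, 25.10),
    "P":   ("P", 0, 5.73),
}


def group_radius(group: str) -> float:
    """Radius [A] of the sphere with the group's displaced-solvent volume."""
    _, _, vol = GROUP_TABLE[group]
    return (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)


def group_electrons(group: str) -> int:
    elem, n_h, _ = GROUP_TABLE[group]
    return ELECTRONS[elem] + n_h


# 4-Gaussian Cromer-Mann coefficients (a1..a4, b1..b4, c), International
# Tables for Crystallography Vol. C; argument is s = q/(4*pi) = sin(theta)/lambda.
CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
    "P": ([6.43450, 4.17910, 1.78000, 1.49080],
          [1.90670, 27.1570, 0.526000, 68.1645], 1.11490),
}

# Backbone united-atom assignment shared by all amino acids; per-residue
# overrides and side chains below.  PRO backbone N has no hydrogen, GLY CA
# carries two.
_BACKBONE = {"N": "NH", "CA": "CH", "C": "C", "O": "O", "OXT": "O"}

_SIDECHAINS: dict[str, dict[str, str]] = {
    "ALA": {"CB": "CH3"},
    "ARG": {"CB": "CH2", "CG": "CH2", "CD": "CH2", "NE": "NH", "CZ": "C",
            "NH1": "NH2", "NH2": "NH2"},
    "ASN": {"CB": "CH2", "CG": "C", "OD1": "O", "ND2": "NH2"},
    "ASP": {"CB": "CH2", "CG": "C", "OD1": "O", "OD2": "O"},
    "CYS": {"CB": "CH2", "SG": "SH"},
    "GLN": {"CB": "CH2", "CG": "CH2", "CD": "C", "OE1": "O", "NE2": "NH2"},
    "GLU": {"CB": "CH2", "CG": "CH2", "CD": "C", "OE1": "O", "OE2": "O"},
    "GLY": {},
    "HIS": {"CB": "CH2", "CG": "C", "ND1": "NH", "CD2": "CH", "CE1": "CH",
            "NE2": "N"},
    "ILE": {"CB": "CH", "CG1": "CH2", "CG2": "CH3", "CD1": "CH3"},
    "LEU": {"CB": "CH2", "CG": "CH", "CD1": "CH3", "CD2": "CH3"},
    "LYS": {"CB": "CH2", "CG": "CH2", "CD": "CH2", "CE": "CH2", "NZ": "NH3"},
    "MET": {"CB": "CH2", "CG": "CH2", "SD": "S", "CE": "CH3"},
    "PHE": {"CB": "CH2", "CG": "C", "CD1": "CH", "CD2": "CH", "CE1": "CH",
            "CE2": "CH", "CZ": "CH"},
    "PRO": {"CB": "CH2", "CG": "CH2", "CD": "CH2"},
    "SER": {"CB": "CH2", "OG": "OH"},
    "THR": {"CB": "CH", "OG1": "OH", "CG2": "CH3"},
    "TRP": {"CB": "CH2", "CG": "C", "CD1": "CH", "CD2": "C", "NE1": "NH",
            "CE2": "C", "CE3": "CH", "CZ2": "CH", "CZ3": "CH", "CH2": "CH"},
    "TYR": {"CB": "CH2", "CG": "C", "CD1": "CH", "CD2": "CH", "CE1": "CH",
            "CE2": "CH", "CZ": "C", "OH": "OH"},
    "VAL": {"CB": "CH", "CG1": "CH3", "CG2": "CH3"},
}

_ELEMENT_FALLBACK_GROUP = {"C": "C", "N": "N", "O": "O", "S": "S", "P": "P"}


def assign_group(res_name: str, atom_name: str, element: str) -> str | None:
    """United-atom group for a heavy atom, or None if unknown.

    Unknown residue/atom names fall back to the bare-element group where the
    element is in the table (callers log a warning).
    """
    res = res_name.upper()
    atom = atom_name.upper()
    if res in _SIDECHAINS:
        if atom in _BACKBONE:
            if res == "PRO" and atom == "N":
                return "N"
            if res == "GLY" and atom == "CA":
                return "CH2"
            return _BACKBONE[atom]
        side = _SIDECHAINS[res].get(atom)
        if side is not None:
            return side
    return _ELEMENT_FALLBACK_GROUP.get(element.upper())
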
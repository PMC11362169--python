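"""Analytic peptide-backbone construction from internal coordinates.

Chains are extended atom-by-atom with the standard internal-to-Cartesian
(NeRF) construction: each new atom is placed from the previous three by a
bond length, a bond angle, and a torsion.  Geometry uses idealised
Engh–Huber-like bond lengths and angles; only backbone N, CA, C, O atoms
are generated, which is all the dihedral and superposition machinery
needs.  The construction is exact, so torsions measured on a built chain
reproduce the requested φ/ψ to machine precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structure import ATOM_COLUMNS, StructureModel

__all__ = ["place_atom", "build_backbone", "AA_THREE"]

# idealised backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0  # trans peptide bond

AA_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom ``d`` given atoms ``a, b, c`` such that ``|c−d| = bond``,
    ∠(b,c,d) = ``angle_deg`` and the torsion a-b-c-d equals ``torsion_deg``."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi, psi, sequence: str | None = None, chain: str = "A",
                   label: str = "built") -> StructureModel:
    """Build an N-residue backbone with the given per-residue φ/ψ (degrees).

    ``phi[0]`` and ``psi[-1]`` are not geometrically constrained by the
    chain (terminal torsions); ``psi[-1]`` is still used to orient the last
    carbonyl oxygen.  Residue numbering is 1-based sequential.
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be 1-D arrays of equal length")
    n_res = len(phi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must match number of residues")

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))

    # first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    th = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])

    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi[i])

    rows = []
    for i in range(n_res):
        resname = AA_THREE.get(sequence[i].upper())
        if resname is None:
            raise ValueError(f"unknown residue code {sequence[i]!r}")
        resnum = i + 1
        O = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
        for name, xyz in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O)):
            rows.append((chain, resnum, resname, name, name[0],
                         xyz[0], xyz[1], xyz[2]))
    return StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS), label=label)
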
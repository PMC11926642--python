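"""Ideal-geometry peptide construction.

Builds all-heavy-atom models of polypeptides from backbone dihedral angles
and idealised internal coordinates (bond lengths, bond angles, side-chain
torsions all-trans).  The geometry is deliberately simple — rings are closed
only approximately and no steric relaxation is performed — but it is accurate
enough for hydrogen-bond based secondary-structure assignment, solvent
accessibility and contact counting, which is all the synthetic structures
are used for.

Canonical dihedral recipes:

* alpha helix      phi = -57,  psi = -47
* beta strand      phi = -139, psi = 135
* type II' turn    (60, -120), (-80, 0) — used to close beta hairpins
* coil             phi/psi sampled from a broad extended/PPII-like region
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

# ideal backbone internal coordinates (Engh & Huber style averages)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)
TURN_II_PRIME = ((60.0, -120.0), (-80.0, 0.0))

# Side-chain templates: atom -> (a, b, c, bond, angle, dihedral) places the
# atom at distance `bond` from c, angle atom-c-b, dihedral atom-c-b-a.
# Backbone references N, CA, C belong to the same residue.  All-trans chains;
# sp3 angles ~110-114 deg, sp2 rings walked with in-plane dihedrals.
SIDE_CHAIN_TEMPLATES: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "G": [],
    "A": [],
    "S": [("OG", "N", "CA", "CB", 1.417, 110.8, 180.0)],
    "C": [("SG", "N", "CA", "CB", 1.808, 113.8, 180.0)],
    "T": [
        ("OG1", "N", "CA", "CB", 1.433, 109.6, 180.0),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, -60.0),
    ],
    "V": [
        ("CG1", "N", "CA", "CB", 1.527, 110.5, 180.0),
        ("CG2", "N", "CA", "CB", 1.527, 110.5, -60.0),
    ],
    "L": [
        ("CG", "N", "CA", "CB", 1.530, 116.3, 180.0),
        ("CD1", "CA", "CB", "CG", 1.524, 110.7, 180.0),
        ("CD2", "CA", "CB", "CG", 1.525, 110.4, 60.0),
    ],
    "I": [
        ("CG1", "N", "CA", "CB", 1.530, 110.4, 180.0),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, -60.0),
        ("CD1", "CA", "CB", "CG1", 1.513, 113.8, 180.0),
    ],
    "M": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("SD", "CA", "CB", "CG", 1.803, 112.7, 180.0),
        ("CE", "CB", "CG", "SD", 1.791, 100.9, 180.0),
    ],
    "P": [
        ("CG", "N", "CA", "CB", 1.495, 104.5, 30.0),
        ("CD", "CA", "CB", "CG", 1.507, 106.1, -35.0),
    ],
    "F": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, 180.0),
        ("CD1", "CA", "CB", "CG", 1.384, 120.8, 90.0),
        ("CD2", "CA", "CB", "CG", 1.384, 120.8, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.382, 121.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 121.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.372, 120.0, 0.0),
    ],
    "Y": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, 180.0),
        ("CD1", "CA", "CB", "CG", 1.384, 120.8, 90.0),
        ("CD2", "CA", "CB", "CG", 1.384, 120.8, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.382, 121.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 121.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.372, 120.0, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0),
    ],
    "W": [
        ("CG", "N", "CA", "CB", 1.498, 113.6, 180.0),
        ("CD1", "CA", "CB", "CG", 1.365, 126.9, 90.0),
        ("CD2", "CA", "CB", "CG", 1.433, 126.7, -90.0),
        ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
        ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
        ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
        ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
        ("CH2", "CD2", "CE3", "CZ3", 1.400, 121.1, 0.0),
    ],
    "D": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, 180.0),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, 90.0),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, -90.0),
    ],
    "N": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, 180.0),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, 90.0),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, -90.0),
    ],
    "E": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, 90.0),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, -90.0),
    ],
    "Q": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, 90.0),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, -90.0),
    ],
    "K": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, 180.0),
        ("CE", "CB", "CG", "CD", 1.508, 111.9, 180.0),
        ("NZ", "CG", "CD", "CE", 1.489, 111.7, 180.0),
    ],
    "R": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, 180.0),
        ("NE", "CB", "CG", "CD", 1.461, 112.0, 180.0),
        ("CZ", "CG", "CD", "NE", 1.329, 124.2, 180.0),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
    ],
    "H": [
        ("CG", "N", "CA", "CB", 1.497, 113.8, 180.0),
        ("ND1", "CA", "CB", "CG", 1.378, 122.7, 90.0),
        ("CD2", "CA", "CB", "CG", 1.354, 131.2, -90.0),
        ("CE1", "CB", "CG", "ND1", 1.321, 109.3, 180.0),
        ("NE2", "CB", "CG", "CD2", 1.374, 107.2, 180.0),
    ],
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given positions a-b-c, |c-D|, angle(D,c,b), dihedral(D,c,b,a)."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("collinear reference atoms in place_atom")
    n = n / norm
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi: Sequence[float], psi: Sequence[float],
                   omega: Sequence[float] | None = None) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O coordinates for the given dihedral lists.

    phi[0] is unused (no preceding carbonyl); the carbonyl O of the last
    residue is placed trans to its own psi.
    """
    n = len(phi)
    if n == 0:
        raise ValueError("empty dihedral list")
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = [180.0] * n
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega[i])
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi[i])
    for i in range(n):
        if i < n - 1:
            O[i] = place_atom(N[i + 1], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def attach_side_chain(aa: str, N: np.ndarray, CA: np.ndarray, C: np.ndarray
                      ) -> list[tuple[str, np.ndarray]]:
    """Heavy-atom side chain of residue type `aa` given its backbone frame."""
    atoms: dict[str, np.ndarray] = {"N": N, "CA": CA, "C": C}
    out: list[tuple[str, np.ndarray]] = []
    if aa != "G":
        # L-configuration beta carbon off the N-CA-C frame
        cb = place_atom(atoms["N"], atoms["C"], atoms["CA"], 1.530, 110.5, 122.5)
        atoms["CB"] = cb
        out.append(("CB", cb))
    for name, a, b, c, bond, angle, dihedral in SIDE_CHAIN_TEMPLATES[aa]:
        pos = place_atom(atoms[a], atoms[b], atoms[c], bond, angle, dihedral)
        atoms[name] = pos
        out.append((name, pos))
    return out


def segment_dihedrals(plan: Sequence[tuple[str, int]],
                      rng: np.random.Generator | None = None
                      ) -> tuple[list[float], list[float]]:
    """Expand a segment plan [(type, length), ...] into phi/psi lists.

    Types: ``helix``, ``strand``, ``coil``.  A coil segment of length 2-4
    that sits between two strand segments is rendered as a type II' turn
    (plus extended filler), so consecutive strands pair into an antiparallel
    hairpin that hydrogen-bond based assignment recognises as sheet.
    Coil dihedrals are sampled from a broad extended region; pass ``rng``
    for reproducibility (defaults to a fixed seed).
    """
    if not plan:
        raise ValueError("empty segment plan")
    if rng is None:
        rng = np.random.default_rng(0)
    phi: list[float] = []
    psi: list[float] = []
    types = [t for t, _ in plan]
    for k, (seg_type, length) in enumerate(plan):
        if length < 1:
            raise ValueError(f"segment length must be >= 1, got {length}")
        if seg_type == "helix":
            phi += [HELIX_PHI_PSI[0]] * length
            psi += [HELIX_PHI_PSI[1]] * length
        elif seg_type == "strand":
            phi += [STRAND_PHI_PSI[0]] * length
            psi += [STRAND_PHI_PSI[1]] * length
        elif seg_type == "coil":
            is_hairpin_turn = (
                2 <= length <= 4
                and 0 < k < len(types) - 1
                and types[k - 1] == "strand"
                and types[k + 1] == "strand"
            )
            if is_hairpin_turn:
                # embed the two-residue turn mid-loop; pad with strand-like
                # residues so longer loops still reverse the chain cleanly
                before = (length - 2) // 2
                pattern = [STRAND_PHI_PSI] * before + list(TURN_II_PRIME)
                pattern += [STRAND_PHI_PSI] * (length - len(pattern))
                for p, s in pattern:
                    phi.append(p)
                    psi.append(s)
            else:
                phi += list(rng.uniform(-150, -70, size=length))
                psi += list(rng.uniform(100, 170, size=length))
        else:
            raise ValueError(f"unknown segment type: {seg_type!r}")
    return phi, psi
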
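"""Per-residue geometric features of a protein chain.

Implements the three structural primitives the immunogen analysis rests on:

* hydrogen-bond based secondary structure (Kabsch-Sander electrostatic
  model, collapsed to helix/sheet/coil),
* relative solvent accessibility by Shrake-Rupley sphere sampling,
  normalised by theoretical per-residue maxima, with burial at RSA < 7%,
* residue-residue contact counts at an 8 A any-heavy-atom cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    BURIED_RSA_THRESHOLD,
    CONTACT_DISTANCE,
    MAX_ASA,
    VDW_RADII,
)
from .io_formats import ProteinStructure

HELIX, SHEET, COIL = "helix", "sheet", "coil"

#: Kabsch-Sander coupling constant: q1*q2*332 kcal/mol with partial charges
#: 0.42 and 0.20 on the C=O and N-H dipoles.
_KS_COUPLING = 0.084 * 332.0
_HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_NH_BOND_LENGTH = 1.01       # amide H placed geometrically (models lack hydrogens)
_CA_SEARCH_RADIUS = 9.0      # CA-CA prefilter for hydrogen-bond candidates


@dataclass
class ResidueFeatureProfile:
    """Everything the immunogen analysis needs to know about one residue."""

    residue_index: int
    amino_acid: str
    ss3: str
    rsa: float
    buried: bool
    contacts: int
    disorder: float | None = None
    is_tm: bool = False
    in_disulfide: bool = False
    is_ptm: bool = False


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def _backbone_arrays(structure: ProteinStructure):
    n = len(structure)
    out = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for i, res in enumerate(structure.residues):
        for name in ("N", "CA", "C", "O"):
            pos = res.atom(name)
            if pos is not None:
                out[name][i] = pos
    return out


def _hydrogen_bond_set(structure: ProteinStructure) -> set[tuple[int, int]]:
    """Pairs (donor i, acceptor j): backbone NH(i) bonded to C=O(j).

    Energy per the Kabsch-Sander electrostatic model; a bond is accepted
    below -0.5 kcal/mol.  The amide hydrogen is placed 1.01 A from N
    opposite the preceding carbonyl; residue 1 and prolines donate nothing.
    Residues missing a backbone O are excluded from the search.
    """
    bb = _backbone_arrays(structure)
    N, CA, C, O = bb["N"], bb["CA"], bb["C"], bb["O"]
    n = len(structure)
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if structure.residues[i].amino_acid == "P":
            continue
        if np.isnan(N[i]).any() or np.isnan(C[i - 1]).any() or np.isnan(O[i - 1]).any():
            continue
        d = C[i - 1] - O[i - 1]
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            continue
        H[i] = N[i] + _NH_BOND_LENGTH * d / norm

    ok_ca = ~np.isnan(CA).any(axis=1)
    idx = np.flatnonzero(ok_ca)
    if len(idx) < 2:
        return set()
    tree = cKDTree(CA[idx])
    bonds: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(_CA_SEARCH_RADIUS):
        i0, j0 = idx[a], idx[b]
        for i, j in ((i0, j0), (j0, i0)):  # i donor, j acceptor
            if abs(i - j) < 2:
                continue
            if np.isnan(H[i]).any() or np.isnan(O[j]).any() or np.isnan(C[j]).any():
                continue
            r_on = np.linalg.norm(N[i] - O[j])
            r_ch = np.linalg.norm(H[i] - C[j])
            r_oh = np.linalg.norm(H[i] - O[j])
            r_cn = np.linalg.norm(N[i] - C[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing atoms: not a bond
                continue
            energy = _KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HBOND_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def assign_secondary_structure(structure: ProteinStructure,
                               collapse: bool = True) -> list[str]:
    """Per-residue secondary structure from backbone hydrogen bonds.

    Returns 3-state labels (``helix``/``sheet``/``coil``) by default, or the
    underlying states ``H G I E C`` with ``collapse=False``.  The standard
    collapse is used: H, G, I -> helix; E (bridges/ladders) -> sheet;
    everything else -> coil.  Turn and bend states are not distinguished
    from blank, since the 3-state scheme does not need them.
    """
    n = len(structure)
    if n < 3:
        if n:
            warnings.warn(f"{structure.protein_id}: chain of {n} residues; all coil",
                          stacklevel=2)
        return [COIL] * n if collapse else ["C"] * n
    for res in structure.residues:
        if res.atom("O") is None:
            warnings.warn(
                f"{structure.protein_id}: residue {res.index} lacks O; "
                "excluded from hydrogen-bond search", stacklevel=2)

    hb = _hydrogen_bond_set(structure)

    def bond(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and (i, j) in hb

    # n-turns: NH(i+k) -> O(i)
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in turn:
        for i in range(n - k):
            turn[k][i] = bond(i + k, i)

    states = np.array(["C"] * n, dtype="U1")

    # alpha helix: two consecutive 4-turns
    for i in range(1, n - 4):
        if turn[4][i - 1] and turn[4][i]:
            states[i:i + 4] = "H"

    # beta bridges (parallel or antiparallel), sequence separation >= 3
    is_bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (bond(i + 1, j) and bond(j, i - 1)) or \
                       (bond(j + 1, i) and bond(i, j - 1))
            antiparallel = (bond(i, j) and bond(j, i)) or \
                           (bond(i + 1, j - 1) and bond(j + 1, i - 1))
            if parallel or antiparallel:
                is_bridge[i] = is_bridge[j] = True
    states[is_bridge & (states == "C")] = "E"

    # 3-10 and pi helices where nothing stronger claimed the residues
    for k, sym in ((3, "G"), (5, "I")):
        for i in range(1, n - k):
            if turn[k][i - 1] and turn[k][i]:
                span = slice(i, i + k)
                if np.all(states[span] == "C"):
                    states[span] = sym

    if not collapse:
        return list(states)
    collapse_map = {"H": HELIX, "G": HELIX, "I": HELIX, "E": SHEET, "C": COIL}
    return [collapse_map[s] for s in states]


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(structure: ProteinStructure, n_points: int = 960,
                 probe_radius: float = 1.4,
                 radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Each heavy atom is sampled with `n_points` sphere points at its van der
    Waals radius plus the probe radius; a point is accessible if it lies
    outside every neighbouring atom's expanded sphere.
    """
    if radii is None:
        radii = VDW_RADII
    coords, owner = structure.all_atoms()
    elements = [name[0] for res in structure.residues for name in res.atom_names]
    if len(coords) == 0:
        raise ValueError(f"{structure.protein_id}: structure has no atoms")
    try:
        r = np.array([radii[e] for e in elements]) + probe_radius
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc}") from exc

    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = r.max()
    atom_sasa = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + r[i] * sphere
        neighbours = tree.query_ball_point(coords[i], r[i] + max_r)
        neighbours = [j for j in neighbours if j != i]
        accessible = np.ones(n_points, dtype=bool)
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            accessible = ~(d2 < (r[nb] ** 2)[None, :]).any(axis=1)
        atom_sasa[i] = accessible.mean() * 4.0 * np.pi * r[i] ** 2

    n_res = len(structure)
    out = np.zeros(n_res)
    np.add.at(out, owner, atom_sasa)
    return out


def compute_rsa(structure: ProteinStructure, n_points: int = 960,
                probe_radius: float = 1.4,
                max_asa: dict[str, float] | None = None) -> np.ndarray:
    """Relative solvent accessibility: SASA over the residue-type maximum.

    Values are not clipped at 1; an RSA slightly above 1 simply means the
    residue is more exposed than in the reference tripeptide.
    """
    if max_asa is None:
        max_asa = MAX_ASA
    sasa = compute_sasa(structure, n_points=n_points, probe_radius=probe_radius)
    ref = np.empty(len(structure))
    for i, res in enumerate(structure.residues):
        if res.amino_acid not in max_asa:
            raise ValueError(f"no reference maximum ASA for {res.amino_acid!r}")
        ref[i] = max_asa[res.amino_acid]
    return sasa / ref


def flag_buried(rsa: float | np.ndarray) -> bool | np.ndarray:
    """Buried iff RSA is strictly below 7% of the reference maximum."""
    arr = np.asarray(rsa, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative RSA")
    out = arr < BURIED_RSA_THRESHOLD
    return bool(out) if np.isscalar(rsa) or arr.ndim == 0 else out


#: Conformer grid for the reference-maximum search: backbone (phi, psi)
#: pairs spanning the extended basin, and chi1 rotamers.
_REF_BACKBONE_GRID = [(-180, 180), (-139, 135), (-120, 140), (-90, 150),
                      (-60, 150), (-150, 100), (-100, 100)]
_REF_CHI1_GRID = [-90.0, -60.0, 60.0, 90.0, 180.0]


def reference_max_asa(n_points: int = 3840,
                      radii: dict[str, float] | None = None) -> dict[str, float]:
    """Theoretical maximum ASA per residue type, self-consistent with this
    package's geometry and radii.

    Follows the construction behind published maximum-ASA scales: for each
    residue type X, Gly-X-Gly tripeptides are built over a grid of extended
    backbone conformations and chi1 rotamers, and the largest central-residue
    SASA is taken.  The shipped ``constants.MAX_ASA`` table was frozen from
    this function at its defaults, so RSA values are calibrated to the same
    radius set that produces the numerator.
    """
    from .io_formats import ProteinStructure, Residue
    from .peptide_builder import SIDE_CHAIN_TEMPLATES, attach_side_chain, build_backbone

    out: dict[str, float] = {}
    for aa in sorted(MAX_ASA):
        best = 0.0
        chis = _REF_CHI1_GRID if SIDE_CHAIN_TEMPLATES[aa] or aa == "A" else [180.0]
        chis = chis if aa not in ("G", "A") else [180.0]
        for flank in _REF_BACKBONE_GRID:
            for centre in _REF_BACKBONE_GRID:
                phi = [flank[0], centre[0], flank[0]]
                psi = [flank[1], centre[1], flank[1]]
                bb = build_backbone(phi, psi)
                for chi1 in chis:
                    template = SIDE_CHAIN_TEMPLATES[aa]
                    patched = [t[:6] + (chi1,) if k == 0 else t
                               for k, t in enumerate(template)]
                    residues = []
                    for i, res_aa in enumerate("G" + aa + "G"):
                        names = ["N", "CA", "C", "O"]
                        coords = [bb["N"][i], bb["CA"][i], bb["C"][i], bb["O"][i]]
                        if i == 1:
                            saved = SIDE_CHAIN_TEMPLATES[aa]
                            SIDE_CHAIN_TEMPLATES[aa] = patched
                            try:
                                side = attach_side_chain(res_aa, *coords[:3])
                            finally:
                                SIDE_CHAIN_TEMPLATES[aa] = saved
                        else:
                            side = attach_side_chain(res_aa, *coords[:3])
                        for nm, pos in side:
                            names.append(nm)
                            coords.append(pos)
                        residues.append(Residue(i + 1, res_aa, names, np.array(coords)))
                    st = ProteinStructure("ref", residues)
                    sasa = compute_sasa(st, n_points=n_points, radii=radii)
                    best = max(best, float(sasa[1]))
        out[aa] = best
    return out


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_profile(structure: ProteinStructure,
                    threshold: float = CONTACT_DISTANCE,
                    min_separation: int = 1) -> np.ndarray:
    """Number of residues within `threshold` A (any heavy atom pair, <=).

    `min_separation` is the smallest |i - j| counted; the default 1 counts
    sequence neighbours as contacts (no separation exclusion).
    """
    coords, owner = structure.all_atoms()
    n = len(structure)
    counts = np.zeros(n, dtype=int)
    if len(coords) == 0:
        return counts
    tree = cKDTree(coords)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    if len(pairs):
        ri = owner[pairs[:, 0]]
        rj = owner[pairs[:, 1]]
        keep = np.abs(ri - rj) >= min_separation
        contact_pairs = {(min(a, b), max(a, b)) for a, b in zip(ri[keep], rj[keep])}
        for a, b in contact_pairs:
            counts[a] += 1
            counts[b] += 1
    return counts


# ---------------------------------------------------------------------------
# segments and the assembled feature table
# ---------------------------------------------------------------------------

def ss_segments(labels: list[str], window: tuple[int, int] | None = None) -> int:
    """Number of maximal same-label runs intersecting `window` (1-based incl.)."""
    if window is None:
        window = (1, len(labels))
    start, end = window
    if not (1 <= start <= end <= len(labels)):
        raise ValueError(f"invalid window {start}..{end} for {len(labels)} labels")
    sub = labels[start - 1:end]
    return 1 + sum(a != b for a, b in zip(sub, sub[1:]))


def build_feature_table(structure: ProteinStructure,
                        disorder=None, annotations=None,
                        n_points: int = 960) -> pd.DataFrame:
    """Assemble the per-residue feature table for one protein.

    Secondary structure, RSA/burial and contacts are computed from the
    structure; disorder and TM/disulfide/PTM flags are merged in when a
    DisorderTrack / ProteinAnnotations is given.  Row order follows the
    chain; columns match io_formats.PROFILE_COLUMNS.
    """
    ss3 = assign_secondary_structure(structure)
    rsa = compute_rsa(structure, n_points=n_points)
    buried = flag_buried(rsa)
    contacts = contact_profile(structure)
    n = len(structure)
    indices = [r.index for r in structure.residues]

    dis = np.full(n, np.nan)
    if disorder is not None:
        for i, idx in enumerate(indices):
            if 1 <= idx <= len(disorder.scores):
                dis[i] = disorder.scores[idx - 1]

    is_tm = np.zeros(n, dtype=bool)
    in_ss = np.zeros(n, dtype=bool)
    is_ptm = np.zeros(n, dtype=bool)
    if annotations is not None:
        tm_set = {k for s, e in annotations.tm_ranges for k in range(s, e + 1)}
        ss_set = {k for pair in annotations.disulfide_pairs for k in pair}
        ptm_set = set(annotations.ptm_sites)
        for i, idx in enumerate(indices):
            is_tm[i] = idx in tm_set
            in_ss[i] = idx in ss_set
            is_ptm[i] = idx in ptm_set

    return pd.DataFrame({
        "protein_id": structure.protein_id,
        "residue_index": indices,
        "aa": list(structure.sequence),
        "ss3": ss3,
        "rsa": rsa,
        "buried": buried,
        "contacts": contacts,
        "disorder": dis,
        "is_tm": is_tm,
        "in_disulfide": in_ss,
        "is_ptm": is_ptm,
    })
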
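"""Independent reference implementations used only to check the package.

Each oracle is written from first principles, without reusing the package's
code paths: Monte-Carlo solvent accessibility, all-pairs contact counting,
an elemental-composition mass table, exhaustive enumeration for the
Mann-Whitney distribution and the outcome truth table, and the textbook
chi-squared formula.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2 as chi2_dist

# --- solvent accessibility -------------------------------------------------

_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


def mc_sasa(structure, n_points: int = 10000, probe: float = 1.4,
            seed: int = 0) -> np.ndarray:
    """Per-residue SASA by Monte-Carlo sphere sampling (uniform random
    directions), independent of the deterministic point construction."""
    rng = np.random.default_rng(seed)
    coords = []
    radii = []
    owner = []
    for i, res in enumerate(structure.residues):
        for name, xyz in zip(res.atom_names, res.coords):
            coords.append(xyz)
            radii.append(_VDW[name[0]] + probe)
            owner.append(i)
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    owner = np.asarray(owner)
    out = np.zeros(len(structure.residues))
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + radii[i] * v
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) > radii[i] + radii[j]:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            free &= d2 >= radii[j] ** 2
        out[owner[i]] += free.mean() * 4.0 * np.pi * radii[i] ** 2
    return out


# --- contacts ---------------------------------------------------------------

def brute_force_contacts(structure, threshold: float = 8.0,
                         min_separation: int = 1) -> np.ndarray:
    """O(n^2 a^2) residue contact counts from the literal definition."""
    n = len(structure.residues)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if j - i < min_separation:
                continue
            ci = structure.residues[i].coords
            cj = structure.residues[j].coords
            d = np.sqrt(((ci[:, None, :] - cj[None, :, :]) ** 2).sum(axis=2))
            if d.min() <= threshold:
                counts[i] += 1
                counts[j] += 1
    return counts


# --- peptide mass from elemental composition --------------------------------

_ATOMIC = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
_RESIDUE_FORMULA = {
    "A": "C3H5NO", "R": "C6H12N4O", "N": "C4H6N2O2", "D": "C4H5NO3",
    "C": "C3H5NOS", "E": "C5H7NO3", "Q": "C5H8N2O2", "G": "C2H3NO",
    "H": "C6H7N3O", "I": "C6H11NO", "L": "C6H11NO", "K": "C6H12N2O",
    "M": "C5H9NOS", "F": "C9H9NO", "P": "C5H7NO", "S": "C3H5NO2",
    "T": "C4H7NO2", "W": "C11H10N2O", "Y": "C9H9NO2", "V": "C5H9NO",
}


def _formula_mass(formula: str) -> float:
    import re
    total = 0.0
    for element, count in re.findall(r"([A-Z])(\d*)", formula):
        total += _ATOMIC[element] * (int(count) if count else 1)
    return total


def elemental_peptide_mass_kda(sequence: str) -> float:
    """Average peptide mass from residue elemental formulas plus water."""
    water = 2 * _ATOMIC["H"] + _ATOMIC["O"]
    return (sum(_formula_mass(_RESIDUE_FORMULA[c]) for c in sequence) + water) / 1000.0


# --- antibody outcome rule --------------------------------------------------

def outcome_rule_oracle(wb: str, ihc: str, icc: str) -> str:
    """Independently coded success rule: all tested pass (>=2 tested) is
    successful, all tested fail (>=2 tested) is unsuccessful."""
    verdicts = []
    for o in (wb, ihc, icc):
        if o == "untested":
            continue
        verdicts.append(o in ("approved", "supported", "enhanced"))
    if len(verdicts) >= 2 and all(verdicts):
        return "successful"
    if len(verdicts) >= 2 and not any(verdicts):
        return "unsuccessful"
    return "unclassified"


# --- Mann-Whitney exact distribution ----------------------------------------

def exact_mannwhitney_p(x, y) -> float:
    """Two-sided exact p by enumerating all assignments of pooled ranks."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)

    observed = u_of(x, y)
    mean_u = n * m / 2.0
    count = 0
    total = comb(n + m, n)
    idx = range(n + m)
    for chosen in combinations(idx, n):
        chosen = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen]
        if abs(u_of(xs, ys) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


# --- chi-squared ------------------------------------------------------------

def textbook_chi2(table) -> tuple[float, float]:
    """Pearson statistic from expected counts; p from the chi2 survival fn."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    stat = ((obs - exp) ** 2 / exp).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(stat), float(chi2_dist.sf(stat, df))
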
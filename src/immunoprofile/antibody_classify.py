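"""Validation-outcome classification and western-blot specificity.

An antibody is tested in up to three technologies (WB, IHC, ICC); each
tested technology either passes (``approved``/``supported``/``enhanced``)
or fails (``uncertain``).  The antibody is *successful* when every tested
technology passes and at least two were tested, *unsuccessful* when every
tested technology fails and at least two were tested, and *unclassified*
otherwise (mixed results, or fewer than two technologies tested).

WB specificity compares observed band sizes against the molecular weight
predicted from the full protein sequence: a band within +-20% of the
prediction is in-range; no bands at all is ``no_binding``; any out-of-range
band makes the blot ``unspecific``; otherwise it is ``specific``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .constants import AVERAGE_RESIDUE_MASS, WATER_MASS, WB_BAND_TOLERANCE
from .io_formats import OUTCOME_VOCABULARY, AntibodyRecord

_MASS_BY_CODE = np.full(128, np.nan)
for _aa, _m in AVERAGE_RESIDUE_MASS.items():
    _MASS_BY_CODE[ord(_aa)] = _m

SUCCESSFUL, UNSUCCESSFUL, UNCLASSIFIED = "successful", "unsuccessful", "unclassified"
PASS_OUTCOMES = frozenset({"approved", "supported", "enhanced"})


@dataclass
class AntibodyLabel:
    label: str
    n_tested: int
    wb_specificity: str  # specific | unspecific | no_binding | untested
    predicted_kda: float | None = None


def classify_outcome(outcome_wb: str, outcome_ihc: str, outcome_icc: str) -> str:
    """Success label from the three per-technology outcomes."""
    outcomes = (outcome_wb, outcome_ihc, outcome_icc)
    for o in outcomes:
        if o not in OUTCOME_VOCABULARY:
            raise ValueError(f"unknown outcome {o!r}")
    tested = [o for o in outcomes if o != "untested"]
    n_pass = sum(o in PASS_OUTCOMES for o in tested)
    if len(tested) >= 2 and n_pass == len(tested):
        return SUCCESSFUL
    if len(tested) >= 2 and n_pass == 0:
        return UNSUCCESSFUL
    return UNCLASSIFIED


@lru_cache(maxsize=512)
def predicted_mass(sequence: str) -> float:
    """Average molecular weight of a protein sequence in kDa.

    Average (not monoisotopic) residue masses plus one water.
    """
    if not sequence:
        raise ValueError("empty sequence")
    codes = np.frombuffer(sequence.encode("ascii", "replace"), dtype=np.uint8)
    masses = _MASS_BY_CODE[codes]
    if np.isnan(masses).any():
        bad = sorted({c for c in sequence if c not in AVERAGE_RESIDUE_MASS})
        raise ValueError(f"non-standard residues {bad} in sequence")
    return (float(masses.sum()) + WATER_MASS) / 1000.0


def classify_wb(bands, predicted_kda: float, single_band_strict: bool = False) -> str:
    """WB specificity from observed band sizes (kDa) and the predicted size.

    A band b is in-range iff |b - predicted| <= 0.2 * predicted (inclusive).
    ``no_binding``: no bands; ``unspecific``: any out-of-range band (an
    in-range band may also be present); ``specific`` otherwise.  With
    ``single_band_strict`` several in-range bands also count as unspecific.
    """
    if predicted_kda <= 0:
        raise ValueError("predicted mass must be positive")
    bands = list(bands)
    if any(b < 0 for b in bands):
        raise ValueError("negative band size")
    if not bands:
        return "no_binding"
    tol = WB_BAND_TOLERANCE * predicted_kda
    out_of_range = sum(abs(b - predicted_kda) > tol for b in bands)
    if out_of_range:
        return "unspecific"
    if single_band_strict and len(bands) > 1:
        return "unspecific"
    return "specific"


def label_record(record: AntibodyRecord, protein_sequence: str | None = None
                 ) -> AntibodyLabel:
    """Full label for one antibody record.

    WB specificity needs the target protein's sequence for the mass
    prediction; without it (or with WB untested) it is ``untested``.
    """
    label = classify_outcome(record.outcome_wb, record.outcome_ihc, record.outcome_icc)
    n_tested = sum(o != "untested"
                   for o in (record.outcome_wb, record.outcome_ihc, record.outcome_icc))
    if record.outcome_wb == "untested" or protein_sequence is None:
        return AntibodyLabel(label, n_tested, "untested")
    kda = predicted_mass(protein_sequence)
    return AntibodyLabel(label, n_tested, classify_wb(record.wb_bands or [], kda), kda)
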
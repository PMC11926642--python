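"""Locating an immunogen in its protein and classifying the window.

An immunogen is profiled by five rule-based classifications plus three
structural aggregates, all computed over the window's residues only:

* position: ``terminus`` if the window overlaps the first or last 25
  residues of the protein, else ``center``;
* disorder: ``high`` if every residue scores >= 0.8, ``low`` if every
  residue scores <= 0.2, else ``medium`` (``unavailable`` without scores);
* majority secondary structure with a fixed coil > helix > sheet tie-break;
* transmembrane relation: ``overlap`` / ``vicinity`` (TM protein, no
  overlap) / ``no_tm``;
* disulfide and PTM presence inside the window;
* number of secondary-structure segments, buried-residue count, and the
  mean per-residue contact count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DISORDER_HIGH, DISORDER_LOW, TERMINUS_LENGTH
from .io_formats import ProteinAnnotations
from .structure_features import ss_segments

TERMINUS, CENTER = "terminus", "center"
SS_TIE_ORDER = ("coil", "helix", "sheet")


@dataclass(frozen=True)
class ImmunogenWindow:
    """A located immunogen: 1-based inclusive span plus its sequence."""

    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid window {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("window span does not match sequence length")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ImmunogenProfile:
    """Aggregated classification of one immunogen window."""

    window: ImmunogenWindow
    position_class: str
    disorder_class: str
    majority_ss: str
    n_ss_segments: int
    n_buried: int
    mean_contacts: float
    tm_class: str
    has_disulfide: bool
    has_ptm: bool

    @property
    def length(self) -> int:
        return self.window.length


def locate_immunogen(protein_id: str, protein_sequence: str,
                     immunogen_sequence: str, strict: bool = False
                     ) -> ImmunogenWindow:
    """Exact-substring placement of an immunogen in its protein.

    Returns the first occurrence; multiple occurrences trigger a warning
    (or an error in strict mode), no occurrence is an error.
    """
    pos = protein_sequence.find(immunogen_sequence)
    if pos < 0:
        raise ValueError(f"{protein_id}: immunogen not found in protein sequence")
    second = protein_sequence.find(immunogen_sequence, pos + 1)
    if second >= 0:
        msg = f"{protein_id}: immunogen occurs more than once; using first at {pos + 1}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return ImmunogenWindow(protein_id, pos + 1, pos + len(immunogen_sequence),
                           immunogen_sequence)


def classify_position(start: int, end: int, protein_length: int) -> str:
    """``terminus`` iff the window lies at least partly within the first or
    last 25 residues of the protein; otherwise ``center``."""
    if protein_length < end:
        raise ValueError(f"window end {end} beyond protein length {protein_length}")
    if start <= TERMINUS_LENGTH or end >= protein_length - (TERMINUS_LENGTH - 1):
        return TERMINUS
    return CENTER


def classify_disorder(scores) -> str:
    """``high`` iff all scores >= 0.8; ``low`` iff all <= 0.2; else ``medium``.

    `scores` may contain NaN (missing prediction), which makes the window
    ``unavailable``; such windows are excluded from disorder-grouped
    analyses downstream.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0 or np.isnan(arr).any():
        return "unavailable"
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("disorder scores outside [0, 1]")
    if arr.min() >= DISORDER_HIGH:
        return "high"
    if arr.max() <= DISORDER_LOW:
        return "low"
    return "medium"


def majority_ss(labels) -> str:
    """The most prevalent 3-state class in the window; ties break
    coil > helix > sheet (coil is the modal class in this data)."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty window")
    counts = {c: 0 for c in SS_TIE_ORDER}
    for lab in labels:
        counts[lab] += 1
    return max(SS_TIE_ORDER, key=lambda c: (counts[c], -SS_TIE_ORDER.index(c)))


def functional_overlap(start: int, end: int, annotations: ProteinAnnotations
                       ) -> tuple[str, bool, bool]:
    """(tm_class, has_disulfide, has_ptm) for a window.

    ``overlap``: a window residue lies in a TM range; ``vicinity``: the
    protein has TM ranges but none intersect the window (no distance cap);
    ``no_tm``: the protein has no TM annotation.  Disulfide presence
    requires an annotated half-cystine inside the window.
    """
    if annotations.tm_ranges:
        tm_class = "vicinity"
        for s, e in annotations.tm_ranges:
            if s <= end and e >= start:
                tm_class = "overlap"
                break
    else:
        tm_class = "no_tm"
    has_ss = any(start <= k <= end for pair in annotations.disulfide_pairs for k in pair)
    has_ptm = any(start <= k <= end for k in annotations.ptm_sites)
    return tm_class, has_ss, has_ptm


def build_profile(window: ImmunogenWindow, ss3_labels, buried_flags,
                  contact_counts, disorder_scores,
                  annotations: ProteinAnnotations) -> ImmunogenProfile:
    """Assemble the full profile of one window from per-residue tracks.

    All tracks are full-protein, index 1 = first residue; aggregates use
    window residues only.
    """
    protein_length = len(annotations.sequence)
    for name, track in (("ss3", ss3_labels), ("buried", buried_flags),
                        ("contacts", contact_counts)):
        if len(track) != protein_length:
            raise ValueError(
                f"{window.protein_id}: {name} track has {len(track)} entries "
                f"for a {protein_length}-residue protein")
    sl = slice(window.start - 1, window.end)
    if disorder_scores is None:
        window_disorder = np.full(window.length, np.nan)
    else:
        if len(disorder_scores) != protein_length:
            raise ValueError(f"{window.protein_id}: disorder track length mismatch")
        window_disorder = np.asarray(disorder_scores, dtype=float)[sl]
    tm_class, has_ss, has_ptm = functional_overlap(window.start, window.end, annotations)
    buried_arr = np.asarray(buried_flags[sl], dtype=bool)
    contacts_arr = np.asarray(contact_counts[sl], dtype=float)
    labels = ss3_labels if isinstance(ss3_labels, list) else list(ss3_labels)
    return ImmunogenProfile(
        window=window,
        position_class=classify_position(window.start, window.end, protein_length),
        disorder_class=classify_disorder(window_disorder),
        majority_ss=majority_ss(labels[sl]),
        n_ss_segments=ss_segments(labels, (window.start, window.end)),
        n_buried=int(buried_arr.sum()),
        mean_contacts=float(contacts_arr.mean()),
        tm_class=tm_class,
        has_disulfide=has_ss,
        has_ptm=has_ptm,
    )
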
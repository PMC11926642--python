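"""Glue: from records + per-protein tracks to the analysis-ready table.

Every grouped analysis consumes one flat DataFrame with a row per antibody
record carrying its success label, WB specificity and immunogen profile.
This module builds that table, either from a simulated cohort (using the
generator's tracks, or recomputing the geometric features from the built
structures) or from externally supplied tracks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .antibody_classify import label_record
from .immunogen_profile import build_profile, locate_immunogen
from .io_formats import AntibodyRecord, DisorderTrack, ProteinAnnotations
from .structure_features import build_feature_table


def profile_record(record: AntibodyRecord, annotations: ProteinAnnotations,
                   ss3, buried, contacts, disorder) -> dict:
    """One output row: success label + window profile for a single record."""
    window = locate_immunogen(record.protein_id, annotations.sequence,
                              record.immunogen_sequence)
    label = label_record(record, annotations.sequence)
    profile = build_profile(window, ss3, buried, contacts, disorder, annotations)
    return {
        "antibody_id": record.antibody_id,
        "protein_id": record.protein_id,
        "label": label.label,
        "n_tested": label.n_tested,
        "wb_specificity": label.wb_specificity,
        "predicted_kda": label.predicted_kda,
        "protein_length": len(annotations.sequence),
        "immunogen_length": window.length,
        "start": window.start,
        "end": window.end,
        "position_class": profile.position_class,
        "disorder_class": profile.disorder_class,
        "majority_ss": profile.majority_ss,
        "n_ss_segments": profile.n_ss_segments,
        "n_buried": profile.n_buried,
        "mean_contacts": profile.mean_contacts,
        "tm_class": profile.tm_class,
        "has_disulfide": profile.has_disulfide,
        "has_ptm": profile.has_ptm,
    }


def profile_table(records, annotations_by_protein, tracks_by_protein) -> pd.DataFrame:
    """Analysis table from records plus per-protein feature tracks.

    `tracks_by_protein` maps protein_id to a dict with keys ``ss3``,
    ``buried``, ``contacts`` and optionally ``disorder``.
    """
    rows = []
    for record in records:
        ann = annotations_by_protein[record.protein_id]
        tr = tracks_by_protein[record.protein_id]
        rows.append(profile_record(record, ann, tr["ss3"], tr["buried"],
                                   tr["contacts"], tr.get("disorder")))
    return pd.DataFrame(rows)


def cohort_table(cohort, use_structures: bool = False,
                 n_points: int = 240) -> pd.DataFrame:
    """Analysis table for a simulated cohort.

    With ``use_structures`` the geometric features (secondary structure,
    burial, contacts) are recomputed from the built ideal structures through
    the same code path real PDB input takes; otherwise the generator's
    tracks are used directly.  ``n_points`` is the SASA sphere resolution
    used in the structure path.
    """
    annotations = {p.protein_id: p.annotations for p in cohort.proteins}
    tracks = {}
    for p in cohort.proteins:
        if use_structures:
            if p.structure is None:
                raise ValueError(f"{p.protein_id}: cohort was generated without "
                                 "structures")
            feats = build_feature_table(
                p.structure, DisorderTrack(p.protein_id, p.disorder),
                p.annotations, n_points=n_points)
            tracks[p.protein_id] = {
                "ss3": feats["ss3"].tolist(),
                "buried": feats["buried"].to_numpy(),
                "contacts": feats["contacts"].to_numpy(),
                "disorder": p.disorder,
            }
        else:
            tracks[p.protein_id] = {
                "ss3": p.ss3,
                "buried": p.buried,
                "contacts": p.contacts,
                "disorder": p.disorder,
            }
    return profile_table(cohort.records, annotations, tracks)


def odds_ratio(table: pd.DataFrame, column: str, level_a, level_b) -> float:
    """Empirical success odds ratio between two levels of a grouping column.

    Computed from the classified records only; returns nan when a cell is
    empty.
    """
    df = table[table["label"].isin(["successful", "unsuccessful"])]
    out = []
    for level in (level_a, level_b):
        sub = df[df[column] == level]
        s = int((sub["label"] == "successful").sum())
        f = int((sub["label"] == "unsuccessful").sum())
        if s == 0 or f == 0:
            return float("nan")
        out.append(s / f)
    return out[0] / out[1]
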
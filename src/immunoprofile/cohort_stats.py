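"""Dataset filters, grouped success rates and the statistical tests.

Works on a flat per-record DataFrame (one row per antibody/immunogen) that
carries at least: ``label`` (successful/unsuccessful/unclassified),
``immunogen_length``, ``protein_length`` and whatever grouping columns the
analysis asks for (``position_class``, ``disorder_class``, ``majority_ss``,
``tm_class``, ``has_disulfide``, ``has_ptm``).  Group differences in
success are tested with Pearson's chi-squared (no continuity correction);
continuous structural aggregates are compared with two-sided Mann-Whitney U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .antibody_classify import SUCCESSFUL, UNSUCCESSFUL
from .constants import (
    AMINO_ACIDS,
    MAX_IMMUNOGEN_LENGTH,
    MAX_PROTEIN_LENGTH,
    MIN_PROTEIN_LENGTH,
)

logger = logging.getLogger(__name__)

#: Immunogen-length bin edges: printed endpoints <30 and >=110, interior
#: bins of width 20; right-open bins over the observed 19..202 range.
DEFAULT_LENGTH_BIN_EDGES = (19, 30, 50, 70, 90, 110, 203)

GROUPINGS = ("position_class", "disorder_class", "majority_ss", "tm_class",
             "has_disulfide", "has_ptm", "length_bin")


@dataclass
class CohortRow:
    group_label: str
    n_total: int
    n_success: int

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_total if self.n_total else float("nan")


@dataclass
class CohortTable:
    """Success counts per group plus the test over the full contingency table."""

    grouping_variable: str
    rows: list[CohortRow] = field(default_factory=list)
    test_name: str | None = None
    statistic: float | None = None
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "grouping_variable": self.grouping_variable,
            "rows": [
                {"group": r.group_label, "n_total": r.n_total,
                 "n_success": r.n_success, "success_rate": round(r.success_rate, 4)}
                for r in self.rows
            ],
            "test": None if self.test_name is None else {
                "name": self.test_name,
                "statistic": self.statistic,
                "p_value": self.p_value,
            },
        }

    def rate(self, group_label: str) -> float:
        for r in self.rows:
            if r.group_label == group_label:
                return r.success_rate
        raise KeyError(group_label)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_filters(records: pd.DataFrame,
                  max_immunogen_length: int = MAX_IMMUNOGEN_LENGTH,
                  min_protein_length: int = MIN_PROTEIN_LENGTH,
                  max_protein_length: int = MAX_PROTEIN_LENGTH
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inclusion filters of the grouped analyses.

    Keeps classified records (successful/unsuccessful) whose immunogen is at
    most 50 residues and whose protein is 100..2000 residues long.  Returns
    the filtered frame and exclusion counts by reason (a record is counted
    once, under the first reason that removes it).
    """
    reasons = {"unclassified_label": 0, "immunogen_too_long": 0,
               "protein_length_out_of_range": 0}
    keep = np.ones(len(records), dtype=bool)
    classified = records["label"].isin([SUCCESSFUL, UNSUCCESSFUL]).to_numpy()
    reasons["unclassified_label"] = int((~classified).sum())
    keep &= classified
    too_long = (records["immunogen_length"] > max_immunogen_length).to_numpy()
    reasons["immunogen_too_long"] = int((too_long & keep).sum())
    keep &= ~too_long
    bad_protein = ((records["protein_length"] < min_protein_length)
                   | (records["protein_length"] > max_protein_length)).to_numpy()
    reasons["protein_length_out_of_range"] = int((bad_protein & keep).sum())
    keep &= ~bad_protein
    logger.info("apply_filters: kept %d of %d records (%s)", keep.sum(),
                len(records), reasons)
    return records.loc[keep].copy(), reasons


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def chi_squared(table) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction; p from the
    chi-squared distribution with (r-1)(c-1) df."""
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("cells must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(sample_x, sample_y, exact_threshold: int = 20
                 ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, normal
    approximation with tie correction otherwise.  Returns (U of x, p)."""
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= exact_threshold and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# grouped success rates
# ---------------------------------------------------------------------------

def _success_mask(df: pd.DataFrame) -> np.ndarray:
    unknown = set(df["label"]) - {SUCCESSFUL, UNSUCCESSFUL}
    if unknown:
        raise ValueError(f"grouped analysis needs classified records; got {unknown}")
    return (df["label"] == SUCCESSFUL).to_numpy()


def success_rate_by_group(records: pd.DataFrame, grouping: str,
                          group_order=None) -> CohortTable:
    """Success rate per level of `grouping` plus a chi-squared test on the
    group x outcome contingency table.

    Records must already be filtered to successful/unsuccessful.  Groups
    with no records are dropped with a warning; the test is skipped (with
    rates still reported) when fewer than two groups remain.
    """
    if grouping not in records.columns:
        raise ValueError(f"no column {grouping!r} in records")
    success = _success_mask(records)
    values = records[grouping]
    if group_order is None:
        group_order = sorted(values.unique(), key=str)
    table = CohortTable(grouping_variable=grouping)
    counts = []
    for g in group_order:
        mask = (values == g).to_numpy()
        n, k = int(mask.sum()), int(success[mask].sum())
        if n == 0:
            logger.warning("group %r=%r empty; dropped", grouping, g)
            continue
        table.rows.append(CohortRow(str(g), n, k))
        counts.append((k, n - k))
    arr = np.array(counts)
    if len(counts) >= 2 and not np.any(arr.sum(axis=0) == 0):
        stat, p = chi_squared(arr)
        table.test_name, table.statistic, table.p_value = "chi_squared", stat, p
    return table


def disorder_by_position(records: pd.DataFrame) -> dict[str, CohortTable]:
    """Disorder-grouped success rates for all records and within each
    position class (three tests, no multiplicity adjustment)."""
    usable = records[records["disorder_class"] != "unavailable"]
    n_dropped = len(records) - len(usable)
    if n_dropped:
        logger.info("disorder grouping: %d windows without scores excluded", n_dropped)
    order = ["low", "medium", "high"]
    out = {"all": success_rate_by_group(usable, "disorder_class", order)}
    for pos in ("terminus", "center"):
        sub = usable[usable["position_class"] == pos]
        out[pos] = success_rate_by_group(sub, "disorder_class", order)
    return out


def length_bin_label(length: int, edges=DEFAULT_LENGTH_BIN_EDGES) -> str:
    """Human-readable label of the right-open bin containing `length`."""
    if not edges[0] <= length < edges[-1]:
        raise ValueError(f"immunogen length {length} outside bins "
                         f"{edges[0]}..{edges[-1] - 1}")
    for lo, hi in zip(edges, edges[1:]):
        if lo <= length < hi:
            if lo == edges[0]:
                return f"<{hi}"
            if hi == edges[-1]:
                return f">={lo}"
            return f"{lo}-{hi - 1}"
    raise AssertionError("unreachable")


def length_bin_analysis(records: pd.DataFrame,
                        edges=DEFAULT_LENGTH_BIN_EDGES) -> CohortTable:
    """Success rate per immunogen-length bin (run on the pre-length-filter
    cohort: the length effect is assessed before the <=50 cut is applied).

    The returned table's rows follow ascending length bins; the test is a
    chi-squared over the bins x outcome table.
    """
    df = records.copy()
    df["length_bin"] = [length_bin_label(v, edges) for v in df["immunogen_length"]]
    order = []
    for lo, hi in zip(edges, edges[1:]):
        order.append(length_bin_label(lo, edges))
    return success_rate_by_group(df, "length_bin", order)


def wb_specificity_by_length(records: pd.DataFrame,
                             edges=DEFAULT_LENGTH_BIN_EDGES) -> pd.DataFrame:
    """Fraction of specific / unspecific / no_binding WB outcomes per
    length bin, over records with a WB result."""
    df = records[records["wb_specificity"] != "untested"].copy()
    if df.empty:
        raise ValueError("no WB-tested records")
    df["length_bin"] = [length_bin_label(v, edges) for v in df["immunogen_length"]]
    out = []
    for lo in edges[:-1]:
        lab = length_bin_label(lo, edges)
        sub = df[df["length_bin"] == lab]
        if len(sub) == 0:
            continue
        frac = sub["wb_specificity"].value_counts(normalize=True)
        out.append({
            "length_bin": lab, "n": len(sub),
            "specific": float(frac.get("specific", 0.0)),
            "unspecific": float(frac.get("unspecific", 0.0)),
            "no_binding": float(frac.get("no_binding", 0.0)),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# coverage and composition
# ---------------------------------------------------------------------------

def coverage_summary(records: pd.DataFrame, proteome: pd.DataFrame) -> dict:
    """Antibody coverage of a proteome table.

    `proteome` has one row per protein with columns ``protein_id``,
    ``protein_length`` and optionally ``localization``; `records` one row
    per antibody with ``protein_id`` and the three outcome columns.
    """
    known = set(proteome["protein_id"])
    unknown = set(records["protein_id"]) - known
    if unknown:
        raise ValueError(f"records reference unknown proteins: {sorted(unknown)[:5]}")
    per_protein = records.groupby("protein_id").size()
    n = len(proteome)
    n_one = int((per_protein == 1).sum())
    n_multi = int((per_protein >= 2).sum())
    covered = set(per_protein.index)

    tech = {}
    for t in ("wb", "ihc", "icc"):
        col = records[f"outcome_{t}"]
        tested = col != "untested"
        passed = col.isin(["approved", "supported", "enhanced"])
        tech[t] = {
            "tested_fraction": float(tested.mean()),
            "success_fraction_given_tested":
                float(passed[tested].mean()) if tested.any() else float("nan"),
        }

    out = {
        "n_proteins": n,
        "n_antibodies": len(records),
        "covered_fraction": len(covered) / n,
        "single_antibody_fraction": n_one / n,
        "multi_antibody_fraction": n_multi / n,
        "technologies": tech,
        "length_distribution": {
            "covered_median": float(
                proteome.loc[proteome["protein_id"].isin(covered),
                             "protein_length"].median()) if covered else float("nan"),
            "uncovered_median": float(
                proteome.loc[~proteome["protein_id"].isin(covered),
                             "protein_length"].median())
            if len(covered) < n else float("nan"),
        },
    }
    if "localization" in proteome.columns:
        comp = {}
        for which, mask in (("covered", proteome["protein_id"].isin(covered)),
                            ("uncovered", ~proteome["protein_id"].isin(covered))):
            sub = proteome.loc[mask, "localization"].value_counts(normalize=True)
            comp[which] = {str(k): float(v) for k, v in sub.items()}
        out["localization_composition"] = comp
    return out


def aa_composition(sequences) -> np.ndarray:
    """20-vector of amino-acid frequencies (order constants.AMINO_ACIDS)."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("empty sequence set")
    counts = np.zeros(20)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for seq in sequences:
        for c in seq:
            counts[index[c]] += 1
    if counts.sum() == 0:
        raise ValueError("no residues in sequence set")
    return counts / counts.sum()


def compare_aa_composition(sequences_a, sequences_b) -> tuple[float, float]:
    """Chi-squared comparison of pooled residue counts between two sets."""
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((2, 20))
    for row, seqs in enumerate((list(sequences_a), list(sequences_b))):
        for seq in seqs:
            for c in seq:
                counts[row, index[c]] += 1
    keep = counts.sum(axis=0) > 0
    return chi_squared(counts[:, keep])
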
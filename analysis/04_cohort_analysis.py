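#!/usr/bin/env python
"""Grouped success-rate analysis of the profiled cohort.

Merges labels and immunogen profiles, applies the inclusion filters
(immunogen <= 50 residues, protein 100..2000 residues, classified label),
and compares success rates across immunogen length bins, position,
disorder-by-position, majority secondary structure and functional
annotations, each with its chi-squared test.  Writes the tables and two
summary figures.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from immunoprofile.cohort_stats import (
    apply_filters,
    disorder_by_position,
    length_bin_analysis,
    mann_whitney,
    success_rate_by_group,
    wb_specificity_by_length,
)
from immunoprofile.io_formats import write_cohort_report

BASE = Path(__file__).resolve().parent.parent / "results"


def bar_figure(tables, path):
    fig, axes = plt.subplots(1, len(tables), figsize=(3.2 * len(tables), 3.2),
                             constrained_layout=True)
    for ax, table in zip(axes, tables):
        labels = [r.group_label for r in table.rows]
        rates = [100 * r.success_rate for r in table.rows]
        ax.bar(labels, rates, color="#4878a8")
        ax.set_title(table.grouping_variable, fontsize=9)
        ax.set_ylabel("success rate (%)")
        ax.set_ylim(0, 100)
        ax.tick_params(axis="x", rotation=45, labelsize=8)
        if table.p_value is not None:
            ax.text(0.02, 0.95, f"p = {table.p_value:.3g}",
                    transform=ax.transAxes, fontsize=8, va="top")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def main():
    profiles = pd.read_csv(BASE / "immunogen_profiles.tsv", sep="\t")
    labels = pd.read_csv(BASE / "antibody_labels.tsv", sep="\t")
    table = profiles.merge(labels[["antibody_id", "wb_specificity"]],
                           on="antibody_id", suffixes=("", "_y"))

    # the length effect is assessed before the <=50 cut
    classified = table[table["label"].isin(["successful", "unsuccessful"])]
    length_table = length_bin_analysis(classified)
    wb_by_length = wb_specificity_by_length(classified)

    kept, reasons = apply_filters(table)
    print(f"kept {len(kept)} of {len(table)} records; exclusions: {reasons}")

    position = success_rate_by_group(kept, "position_class")
    disorder = disorder_by_position(kept)
    ss = success_rate_by_group(kept, "majority_ss",
                               ["coil", "helix", "sheet"])
    tm = success_rate_by_group(kept, "tm_class",
                               ["no_tm", "vicinity", "overlap"])
    disulfide = success_rate_by_group(kept, "has_disulfide")
    ptm = success_rate_by_group(kept, "has_ptm")

    all_tables = [length_table, position, disorder["all"],
                  disorder["terminus"], disorder["center"], ss, tm,
                  disulfide, ptm]
    write_cohort_report(all_tables, BASE / "cohort_report")
    wb_by_length.to_csv(BASE / "wb_specificity_by_length.tsv", sep="\t",
                        index=False, float_format="%.4f")

    figures = BASE / "figures"
    figures.mkdir(exist_ok=True)
    bar_figure([length_table, position, ss], figures / "success_rates_structure.png")
    bar_figure([disorder["terminus"], tm, ptm],
               figures / "success_rates_disorder_functional.png")

    print("\nsuccess rate by immunogen length bin:")
    for row in length_table.rows:
        print(f"  {row.group_label:>7s}: {100 * row.success_rate:5.2f}% "
              f"(n={row.n_total})")
    print(f"\nposition (terminus {100 * position.rate('terminus'):.2f}% vs "
          f"center {100 * position.rate('center'):.2f}%, "
          f"p={position.p_value:.3f})")
    terminus = disorder["terminus"]
    print(f"terminus disorder low->high: "
          f"{100 * terminus.rate('low'):.2f}% -> {100 * terminus.rate('high'):.2f}% "
          f"(p={terminus.p_value:.3g})")
    print(f"majority SS coil {100 * ss.rate('coil'):.2f}% vs sheet "
          f"{100 * ss.rate('sheet'):.2f}% (p={ss.p_value:.3g})")
    print(f"TM overlap {100 * tm.rate('overlap'):.2f}% vs no TM "
          f"{100 * tm.rate('no_tm'):.2f}% (p={tm.p_value:.3g})")
    print(f"PTM-containing {100 * ptm.rate('True'):.2f}% vs without "
          f"{100 * ptm.rate('False'):.2f}% (p={ptm.p_value:.3g})")

    # structural aggregates: terminus vs center (Mann-Whitney)
    for feature in ("n_ss_segments", "n_buried", "mean_contacts"):
        x = kept.loc[kept["position_class"] == "center", feature]
        y = kept.loc[kept["position_class"] == "terminus", feature]
        _, p = mann_whitney(x, y)
        print(f"{feature}: center median {x.median():.2f} vs terminus "
              f"{y.median():.2f} (Mann-Whitney p={p:.3g})")


if __name__ == "__main__":
    main()
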
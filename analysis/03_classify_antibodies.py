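#!/usr/bin/env python
"""Label every antibody from its validation outcomes.

Applies the success rule (all tested technologies pass, at least two
tested) and the western-blot specificity rule (+-20% of the predicted
molecular weight) to the cohort records, and writes one label row per
antibody.
"""

from pathlib import Path

import pandas as pd

from immunoprofile.antibody_classify import label_record
from immunoprofile.io_formats import read_antibody_table, read_fasta

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    data = BASE / "data"
    records = read_antibody_table(data / "records.tsv")
    sequences = read_fasta(data / "sequences.fasta")

    rows = []
    for record in records:
        label = label_record(record, sequences[record.protein_id])
        rows.append({
            "antibody_id": record.antibody_id,
            "label": label.label,
            "n_tested": label.n_tested,
            "wb_specificity": label.wb_specificity,
            "predicted_kda": None if label.predicted_kda is None
            else round(label.predicted_kda, 2),
        })
    table = pd.DataFrame(rows)
    out = BASE / "antibody_labels.tsv"
    table.to_csv(out, sep="\t", index=False)

    print(f"labelled {len(table)} antibodies -> {out}")
    print("  labels:", table["label"].value_counts().to_dict())
    tested_wb = table[table["wb_specificity"] != "untested"]
    print(f"  WB specificity over {len(tested_wb)} WB-tested antibodies:",
          tested_wb["wb_specificity"].value_counts().to_dict())


if __name__ == "__main__":
    main()
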
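#!/usr/bin/env python
"""Estimate global and class-specific PB substitution matrices.

Reads the simulated dataset from scratch/, applies the <40% identity filter,
counts substitutions in the conserved core (C-alpha within 3 A), normalizes
by family size, converts to log-odds, and compares each class matrix to the
global one row by row (flagging rows with correlation < 0.95 and their
1.5*IQR outlier cells).

Run analysis/01_simulate_families.py first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pbscope import io
from pbscope.pb_core import PB_LABELS
from pbscope.substitution import (
    build_matrix,
    class_matrices,
    compare_rows,
    filter_dataset,
    outlier_substitutions,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    pairs = io.read_alignment_dataset(ROOT / "scratch" / "two_class")
    kept = filter_dataset(pairs, 40.0)
    print(f"{len(kept)} of {len(pairs)} pairs pass the identity filter")

    global_mat = build_matrix(kept, scop_class="global", id="global")
    per_class = class_matrices(kept)

    mat_dir = ROOT / "results" / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    io.write_matrix(global_mat, mat_dir / "global.mat")
    for cls, m in per_class.items():
        io.write_matrix(m, mat_dir / f"{cls.replace('/', '_')}.mat")

    corr_rows, outlier_rows = [], []
    for cls, m in per_class.items():
        corr, diff = compare_rows(m, global_mat)
        for lab, c in zip(PB_LABELS, corr):
            corr_rows.append({"class": cls, "pb": lab, "row_corr": round(float(c), 4)})
            if c < 0.95:
                mask = outlier_substitutions(np.abs(diff[PB_LABELS.index(lab)]))
                for j in np.flatnonzero(mask):
                    outlier_rows.append({
                        "class": cls, "pb_row": lab, "pb_col": PB_LABELS[j],
                        "score_diff": round(float(diff[PB_LABELS.index(lab), j]), 3),
                    })
    # direct class-vs-class comparison: the global matrix averages the two
    # classes, so it shows only half the planted contrast
    classes = sorted(per_class)
    if len(classes) == 2:
        corr, diff = compare_rows(per_class[classes[0]], per_class[classes[1]])
        for lab, c in zip(PB_LABELS, corr):
            corr_rows.append({"class": f"{classes[0]} vs {classes[1]}",
                              "pb": lab, "row_corr": round(float(c), 4)})
            if c < 0.95:
                mask = outlier_substitutions(np.abs(diff[PB_LABELS.index(lab)]))
                for j in np.flatnonzero(mask):
                    outlier_rows.append({
                        "class": f"{classes[0]} vs {classes[1]}",
                        "pb_row": lab, "pb_col": PB_LABELS[j],
                        "score_diff": round(float(diff[PB_LABELS.index(lab), j]), 3),
                    })

    pd.DataFrame(corr_rows).to_csv(ROOT / "results" / "class_row_correlations.tsv",
                                   sep="\t", index=False)
    out = pd.DataFrame(outlier_rows)
    out.to_csv(ROOT / "results" / "class_outlier_substitutions.tsv",
               sep="\t", index=False)
    flagged = sorted({(r["class"], r["pb_row"]) for r in outlier_rows})
    print(f"rows with correlation < 0.95: {flagged}")
    print(f"matrices -> {mat_dir}")


if __name__ == "__main__":
    main()
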
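#!/usr/bin/env python
"""Cluster PBs by the similarity of their substitution patterns.

For the global and each class-specific matrix, computes correlation
distances (1 - Pearson r between score rows), runs complete-linkage
agglomeration and writes the dendrograms as Newick files.  Also clusters the
prototypes by plain conformational similarity (pairwise RMSDA) for contrast:
the two trees differ, which is the point - substitution preference is not
just conformational closeness.

Run analysis/02_build_substitution_matrices.py first.
"""

from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from pbscope import io
from pbscope.pb_core import circular_difference, default_prototype_table
from pbscope.substitution import PBDendrogram, cluster_pbs

ROOT = Path(__file__).resolve().parent.parent


def rmsda_dendrogram() -> PBDendrogram:
    table = default_prototype_table()
    diffs = circular_difference(table.angles[:, None, :], table.angles[None, :, :])
    d = np.sqrt(np.mean(diffs**2, axis=2))
    link = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return PBDendrogram(labels=list(table.labels), linkage=link)


def main() -> None:
    out_dir = ROOT / "results" / "dendrograms"
    out_dir.mkdir(parents=True, exist_ok=True)
    for mat_file in sorted((ROOT / "results" / "matrices").glob("*.mat")):
        dend = cluster_pbs(io.read_matrix(mat_file))
        target = out_dir / (mat_file.stem + ".nwk")
        target.write_text(dend.to_newick() + "\n")
        print(f"{mat_file.stem}: {dend.to_newick()}")
    (out_dir / "rmsda.nwk").write_text(rmsda_dendrogram().to_newick() + "\n")
    print(f"conformation (RMSDA): {rmsda_dendrogram().to_newick()}")


if __name__ == "__main__":
    main()
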
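#!/usr/bin/env python
"""Fuse the two expression views into one patient similarity network.

Builds per-view locally scaled affinity kernels and runs the cross-diffusion
fusion; reports how sharply the fused network separates the planted subtypes
compared with each single view (mean within-subtype over between-subtype
affinity), and writes the fused matrix to results/fused.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import fusemod as fm
from fusemod.snf import default_neighborhood

DATA = Path("results/data")


def block_contrast(M: pd.DataFrame, labels: pd.Series) -> float:
    same = labels.to_numpy()[:, None] == labels.to_numpy()[None, :]
    np.fill_diagonal(same, False)
    diff = ~same
    np.fill_diagonal(diff, False)
    return float(M.to_numpy()[same].mean() / M.to_numpy()[diff].mean())


def main() -> None:
    views = [
        fm.read_feature_matrix(DATA / "mrna.tsv"),
        fm.read_feature_matrix(DATA / "mirna.tsv"),
    ]
    bundle = fm.align_cohort(views)
    truth = json.loads((DATA / "ground_truth.json").read_text())
    labels = pd.Series(truth["true_labels"]).loc[bundle.patients]

    fused = fm.fuse_feature_views(bundle.views)
    fused.matrix.to_csv("results/fused.tsv", sep="\t", index_label="patient_id")

    k = default_neighborhood(len(bundle.patients))
    contrasts = []
    for name, X in zip(("mRNA", "miRNA"), bundle.views):
        D = fm.euclidean_distances(X)
        P = fm.full_kernel(fm.scaled_affinity(D, mu=0.5, k=k))
        c = block_contrast(P, labels)
        contrasts.append(c)
        print(f"{name} view alone: within/between affinity contrast {c:.2f}")
    c_fused = block_contrast(fused.matrix, labels)
    print(f"fused network:    within/between affinity contrast {c_fused:.2f}")
    print(f"fusion {'sharpened' if c_fused > max(contrasts) else 'did not sharpen'} "
          f"the subtype block structure "
          f"({fused.iterations_run} iterations, last rel. change {fused.max_rel_change:.1e})")


if __name__ == "__main__":
    main()
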
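"""Copy-number alteration scoring per subtype.

Gene-level GISTIC codes are binarized — only homozygous deletions (-2) and
high-level amplifications (+2) count as alterations.  Within a subtype the
per-gene score weights each alteration inversely by its sample's total
alteration load (column-wise normalization), so an alteration in a quiet
genome carries more evidence than one in a heavily altered genome:

    C_i  = sum_j x_ij / (sum over genes of x_.j),   p0_i = C_i / sum_i C_i.

Genes whose normalized score p0 meets the threshold (default 2e-4,
inclusive) form the subtype's altered gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AlteredGeneSet",
    "binarize_copy_number",
    "gene_alteration_scores",
    "filter_altered_genes",
]


@dataclass
class AlteredGeneSet:
    genes: frozenset
    threshold: float

    def sorted(self) -> list[str]:
        return sorted(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def binarize_copy_number(calls: pd.DataFrame) -> pd.DataFrame:
    """Genes x samples GISTIC codes -> binary alteration matrix (|code| == 2)."""
    codes = np.asarray(calls, dtype=float)
    bad = (codes != np.round(codes)) | (np.abs(codes) > 2) | ~np.isfinite(codes)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"copy-number code out of range at gene {calls.index[r]!r}, "
            f"sample {calls.columns[c]!r}: {calls.iat[r, c]!r}"
        )
    x = (np.abs(codes) == 2).astype(np.int8)
    return pd.DataFrame(x, index=calls.index, columns=calls.columns)


def gene_alteration_scores(x: pd.DataFrame, subtype_samples: list[str]) -> pd.DataFrame:
    """Per-gene alteration scores restricted to one subtype's samples.

    Returns a DataFrame indexed by gene with columns ``C`` (load-weighted
    alteration count) and ``p0`` (normalized score summing to 1).  Samples
    with zero alterations contribute nothing.
    """
    samples = list(subtype_samples)
    if not samples:
        raise ValueError("subtype sample set is empty")
    sub = x.loc[:, samples].astype(float)
    if not sub.isin([0.0, 1.0]).to_numpy().all():
        raise ValueError("alteration matrix must be binary")
    col_sums = sub.sum(axis=0)
    if col_sums.sum() == 0:
        raise ValueError("no alterations in subtype")
    nonzero = col_sums[col_sums > 0].index
    C = (sub.loc[:, nonzero] / col_sums[nonzero]).sum(axis=1)
    p0 = C / C.sum()
    return pd.DataFrame({"C": C, "p0": p0})


def filter_altered_genes(scores: pd.DataFrame, tau: float = 2e-4) -> AlteredGeneSet:
    """Genes with p0 >= tau (boundary inclusive)."""
    if tau < 0:
        raise ValueError(f"threshold must be nonnegative, got {tau}")
    keep = scores.index[scores["p0"] >= tau]
    return AlteredGeneSet(genes=frozenset(keep), threshold=tau)
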
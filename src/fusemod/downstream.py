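"""Downstream subtype comparisons: differential miRNA analysis with a fold
change filter, evidence-filtered miRNA->target lookup, and per-gene
copy-number-versus-expression ANOVA annotation.

The two-subtype comparison uses the two-sample Wilcoxon rank-sum test
(exact when the combined sample is small and tie-free, otherwise the
tie-corrected normal approximation) together with a linear-scale fold
change mean(subtype 2)/mean(subtype 1).  Up-regulated features must pass
both strict cutoffs (defaults p < 0.01 and fold change > 1.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, mannwhitneyu

from .subtypes import SubtypeAssignment

__all__ = [
    "AnovaAnnotation",
    "differential_features",
    "filter_upregulated",
    "mirnas_targeting",
    "intersect_candidates",
    "cna_expression_anova",
    "load_rb1_target_table",
]


@dataclass
class AnovaAnnotation:
    gene: str
    F: float
    p_value: float


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for tie-free combined n <= 20."""
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(np.clip(res.pvalue, 5e-324, 1.0))


def differential_features(
    expr: pd.DataFrame,
    labels: pd.Series | SubtypeAssignment,
    log2_scale: bool = False,
) -> pd.DataFrame:
    """Per-feature rank-sum p and fold change between exactly two subtypes.

    ``expr`` is patients x features.  Fold change is mean(subtype 2) /
    mean(subtype 1) on the linear scale; with ``log2_scale`` the input means
    are treated as log2 and the fold change is 2**(mean2 - mean1).
    """
    if isinstance(labels, SubtypeAssignment):
        labels = labels.labels
    common = expr.index.intersection(labels.index)
    expr = expr.loc[common]
    labels = labels.loc[common]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"pairwise only: expected exactly 2 subtypes, got {len(groups)}")
    g1 = expr.loc[labels == groups[0]]
    g2 = expr.loc[labels == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each subtype needs >= 2 patients")
    rows = []
    for feat in expr.columns:
        a = g1[feat].to_numpy(dtype=float)
        b = g2[feat].to_numpy(dtype=float)
        p = _ranksum_p(a, b)
        m1, m2 = a.mean(), b.mean()
        if log2_scale:
            fc = float(2.0 ** (m2 - m1))
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                fc = float(m2 / m1) if m1 != 0 else np.inf
        rows.append(
            {
                "feature": feat,
                "p_value": p,
                "fold_change": fc,
                "direction": "up" if fc > 1 else ("down" if fc < 1 else "flat"),
            }
        )
    return pd.DataFrame(rows)


def filter_upregulated(
    results: pd.DataFrame, p_cut: float = 0.01, fc_cut: float = 1.2
) -> pd.DataFrame:
    """Features passing both strict cutoffs: p < p_cut and fold change > fc_cut."""
    if results.empty:
        return results
    keep = (results["p_value"] < p_cut) & (results["fold_change"] > fc_cut)
    return results[keep].reset_index(drop=True)


def mirnas_targeting(gene: str, table: pd.DataFrame, tier: str = "strong") -> set:
    """Unique miRNAs with a (miRNA, gene, tier) row in the evidence table."""
    if table.empty:
        return set()
    required = {"mirna", "target", "evidence"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"target table missing column(s): {sorted(missing)}")
    hit = table[(table["target"] == gene) & (table["evidence"] == tier)]
    return set(hit["mirna"])


def intersect_candidates(upregulated: set, targeting: set) -> set:
    """Candidate regulators: up-regulated miRNAs that also target the gene."""
    return set(upregulated) & set(targeting)


def cna_expression_anova(
    expr_values: pd.Series | np.ndarray,
    cn_category: pd.Series | np.ndarray,
    gene: str = "",
) -> AnovaAnnotation:
    """One-way fixed-effects ANOVA of expression across copy-number classes."""
    values = np.asarray(expr_values, dtype=float)
    cats = np.asarray(cn_category)
    if values.shape != cats.shape:
        raise ValueError("expression and copy-number vectors differ in length")
    groups = []
    for c in np.unique(cats):
        g = values[cats == c]
        if len(g) < 2:
            raise ValueError(f"copy-number class {c!r} has fewer than 2 patients")
        groups.append(g)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 copy-number classes")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(values) == 0:
        raise ValueError("zero variance within and between groups")
    F, p = f_oneway(*groups)
    if not np.isfinite(F):
        raise ValueError("ANOVA degenerate: no within-group variance")
    return AnovaAnnotation(gene=gene, F=float(max(F, 0.0)), p_value=float(np.clip(p, 5e-324, 1.0)))


def load_rb1_target_table() -> pd.DataFrame:
    """Bundled fixture: experimentally supported strong-evidence miRNA->RB1
    interactions (curated MiRTarbase subset used by the worked example)."""
    with resources.files("fusemod.data").joinpath("rb1_strong_targets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
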
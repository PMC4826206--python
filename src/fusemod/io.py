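"""Readers, writers and cohort alignment for the pipeline's file formats.

Formats are deliberately plain: tab-separated matrices (first header token
ignored), SIF or two-column edge lists for interaction networks, a clinical
TSV with ``patient_id``/``os_time``/``os_event`` columns, and GISTIC-style
gene-level integer copy-number calls in {-2..2}.  Feature matrices are held
internally as :class:`pandas.DataFrame` with patients in rows, regardless of
the file orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_clinical",
    "write_clinical",
    "read_copy_number",
    "write_copy_number",
    "read_network_sif",
    "write_network_sif",
    "align_cohort",
    "AlignedCohort",
]


def _check_unique(values: pd.Index, what: str) -> None:
    dup = values[values.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate {what} identifier(s): {sorted(set(dup))}")


def _read_table(path: str | Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = pd.Index([c.strip() for c in header[1:]])  # pandas mangles dupes to "X.1"
    _check_unique(cols, "column")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def _to_numeric(df: pd.DataFrame, path: str | Path, *, drop_missing: bool = False) -> pd.DataFrame:
    """Convert a string-typed table to floats, locating any offending cell."""
    raw = df.replace({"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan})
    out = raw.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    missing_cols = out.columns[out.isna().any(axis=0)]
    if len(missing_cols):
        if not drop_missing:
            r, c = np.argwhere(out.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at row {out.index[r]!r}, column {out.columns[c]!r} "
                "(use drop_missing=True to pre-filter features with missing values)"
            )
        log.info("%s: dropping %d feature(s) with missing values", path, len(missing_cols))
        out = out.drop(columns=missing_cols)
        if out.shape[1] == 0:
            raise ValueError(f"{path}: all features dropped for missing values")
    return out.astype(float)


def read_feature_matrix(
    path: str | Path,
    orientation: str = "features-in-rows",
    *,
    drop_missing: bool = False,
) -> pd.DataFrame:
    """Read one omics view; returns patients x features.

    ``orientation`` names what the *file* rows are.  Missing cells (``NA`` or
    empty) are rejected unless ``drop_missing`` is set, in which case any
    feature containing a missing value is dropped and the count logged.
    """
    if orientation not in ("features-in-rows", "patients-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "features-in-rows":
        _check_unique(df.index, "feature")
        _check_unique(df.columns, "patient")
        df = df.T
    else:
        _check_unique(df.index, "patient")
        _check_unique(df.columns, "feature")
    out = _to_numeric(df, path, drop_missing=drop_missing)
    out.index.name = "patient_id"
    return out


def write_feature_matrix(
    X: pd.DataFrame, path: str | Path, orientation: str = "features-in-rows", label: str = "feature"
) -> None:
    if orientation == "features-in-rows":
        X.T.to_csv(path, sep="\t", index_label=label)
    elif orientation == "patients-in-rows":
        X.to_csv(path, sep="\t", index_label="patient_id")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV -> DataFrame indexed by patient with os_time / os_event."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical column(s): {sorted(missing)}")
    _check_unique(pd.Index(df["patient_id"]), "patient")
    df = df.set_index("patient_id")[["os_time", "os_event"]].astype(float)
    if (df["os_time"] < 0).any():
        bad = df.index[df["os_time"] < 0][0]
        raise ValueError(f"{path}: negative os_time for patient {bad!r}")
    if not df["os_event"].isin([0.0, 1.0]).all():
        bad = df.index[~df["os_event"].isin([0.0, 1.0])][0]
        raise ValueError(f"{path}: os_event must be 0 or 1 (patient {bad!r})")
    df["os_event"] = df["os_event"].astype(int)
    return df


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index_label="patient_id")


def read_copy_number(path: str | Path) -> pd.DataFrame:
    """GISTIC-style gene-level calls, genes x samples, integer codes -2..2."""
    df = _read_table(path)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    out = _to_numeric(df, path)
    codes = out.to_numpy()
    bad = (codes != np.round(codes)) | (np.abs(codes) > 2)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: copy-number code out of range at gene {out.index[r]!r}, "
            f"sample {out.columns[c]!r}: {codes[r, c]!r}"
        )
    return out.astype(int)


def write_copy_number(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index_label="gene")


def read_network_sif(path: str | Path) -> nx.Graph:
    """Parse a SIF file (``A <relation> B [C ...]``) or 2-column edge list.

    Returns a simple undirected graph; self-loops and duplicate edges are
    dropped with a logged count.
    """
    G = nx.Graph()
    self_loops = duplicates = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 node tokens, got {line!r}")
            source = tokens[0]
            targets = [tokens[1]] if len(tokens) == 2 else tokens[2:]
            for t in targets:
                if t == source:
                    self_loops += 1
                    G.add_node(source)
                elif G.has_edge(source, t):
                    duplicates += 1
                else:
                    G.add_edge(source, t)
    if self_loops or duplicates:
        log.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)", path, self_loops, duplicates
        )
    return G


def write_network_sif(G: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in G.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in sorted(n for n in G.nodes() if G.degree(n) == 0):
            fh.write(f"{node}\n")


@dataclass
class AlignedCohort:
    """All inputs restricted to a common, lexicographically ordered patient set."""

    views: list[pd.DataFrame]
    clinical: pd.DataFrame | None = None
    alterations: pd.DataFrame | None = None
    patients: list[str] = field(default_factory=list)


def align_cohort(
    views: list[pd.DataFrame],
    clinical: pd.DataFrame | None = None,
    alterations: pd.DataFrame | None = None,
) -> AlignedCohort:
    """Intersect patient identifiers across all inputs; canonical order is
    lexicographic so every downstream result is independent of file order.

    ``alterations`` is genes x samples (patients in columns).
    """
    if not views:
        raise ValueError("need at least one feature view")
    common: set[str] = set(views[0].index)
    for v in views[1:]:
        common &= set(v.index)
    if clinical is not None:
        common &= set(clinical.index)
    if alterations is not None:
        common &= set(alterations.columns)
    if not common:
        raise ValueError("empty patient intersection across inputs")
    order = sorted(common)
    log.info("aligned cohort: %d patient(s) in common", len(order))
    return AlignedCohort(
        views=[v.loc[order] for v in views],
        clinical=None if clinical is None else clinical.loc[order],
        alterations=None if alterations is None else alterations.loc[:, order],
        patients=order,
    )
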
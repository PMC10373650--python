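"""Tabular input/output with strict validation.

All pipeline inputs are plain tab-separated text: an expression matrix
(genes as rows, samples as columns), an interaction network given either as
a directed two-column edge list or as a STRING-style scored edge list
(protein1, protein2, combined_score), a sample-to-stage annotation table,
and a survival table (sample, time, event).  Everything numeric downstream
works on validated in-memory objects; no other module touches files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("smfe")

__all__ = [
    "ExpressionMatrix",
    "StageAnnotation",
    "SurvivalRecord",
    "read_expression",
    "read_scored_edges",
    "read_directed_edges",
    "read_stage_annotation",
    "read_survival",
    "write_scores",
    "read_scores",
    "write_local_scores",
    "write_biomarkers",
    "read_biomarkers",
]


class ExpressionMatrix:
    """A genes x samples matrix of nonnegative expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene identifier, columns by sample identifier.
        Units (FPKM, TPM, counts, ...) are unconstrained; values must be
        finite and >= 0.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("expression matrix needs at least 1 gene and 1 sample")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        values = data.to_numpy(dtype=float)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"invalid expression value {values[i, j]!r} at "
                f"gene {data.index[i]!r}, sample {data.columns[j]!r} "
                "(values must be finite and >= 0)"
            )
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample(self, sample_id: str) -> pd.Series:
        """Expression vector of one sample (indexed by gene)."""
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.data[sample_id]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass(frozen=True)
class StageAnnotation:
    """Assignment of one sample to an ordered disease stage."""

    sample_id: str
    stage_label: str
    stage_order: int


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time on study and event indicator.

    ``event`` is 1 for death/progression, 0 for censoring.  Time units
    (days or months) are metadata carried in the run config; no conversion
    is performed here.
    """

    sample_id: str
    time: float
    event: int

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"survival time must be finite and >= 0, got {self.time!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 (censored) or 1 (death), got {self.event!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The first column holds gene identifiers and the header row sample
    identifiers; pass ``transpose=True`` for the samples-as-rows layout.
    Duplicate gene rows are collapsed by their mean (common after gene-symbol
    mapping); duplicate sample columns are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        kind = "gene" if transpose else "sample"
        raise ValueError(f"{path}: duplicate {kind} columns in header: {dupes[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "%s: %d duplicate gene rows collapsed by mean", path, n_dup
        )
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df)


def read_scored_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a STRING-style scored edge list (node_a, node_b, combined_score).

    Scores are returned on the [0, 1] scale.  STRING distributes
    ``combined_score`` as an integer in 0-1000; if any observed score
    exceeds 1 the whole column is divided by 1000 (logged).
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        logger.warning("%s: empty edge list", path)
        return []
    # tolerate a header row of column names
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:]
        if df.empty:
            logger.warning("%s: empty edge list (header only)", path)
            return []
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (node_a, node_b, score)")
    try:
        scores = df.iloc[:, 2].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric score column: {exc}") from exc
    if not np.isfinite(scores).all():
        raise ValueError(f"{path}: non-finite score in edge list")
    if scores.max() > 1.0:
        logger.info("%s: scores exceed 1, assuming STRING 0-1000 scale (dividing by 1000)", path)
        scores = scores / 1000.0
    a = df.iloc[:, 0].astype(str).to_numpy()
    b = df.iloc[:, 1].astype(str).to_numpy()
    return [(x, y, float(s)) for x, y, s in zip(a, b, scores)]


def read_directed_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (source, target) directed edge list."""
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        logger.warning("%s: empty edge list", path)
        return []
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (source, target)")
    return [(str(s), str(t)) for s, t in zip(df.iloc[:, 0], df.iloc[:, 1])]


def read_stage_annotation(path: str | Path) -> list[StageAnnotation]:
    """Read a sample-to-stage table.

    Two or three tab-separated columns: sample_id, stage_label and an
    optional integer stage_order.  Without an explicit order column, stages
    are ranked by first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no stage annotations")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >= 2 columns (sample_id, stage_label)")
    samples = df.iloc[:, 0].astype(str)
    if samples.duplicated().any():
        dupes = samples[samples.duplicated()].unique().tolist()
        raise ValueError(f"{path}: sample annotated more than once: {dupes[:5]}")
    labels = df.iloc[:, 1].astype(str)
    if df.shape[1] >= 3:
        orders = df.iloc[:, 2].astype(int)
        label_order = dict(zip(labels, orders))
        if len({label_order[l] for l in labels.unique()}) != labels.nunique():
            raise ValueError(f"{path}: stage_order is not a total order over labels")
    else:
        label_order = {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
    return [
        StageAnnotation(s, l, int(label_order[l]))
        for s, l in zip(samples, labels)
    ]


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival table: sample_id, time, event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: no records in survival table")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (sample_id, time, event)")
    records = []
    for _, row in df.iterrows():
        sample = str(row.iloc[0])
        time = float(row.iloc[1])
        event_raw = row.iloc[2]
        event = int(event_raw)
        if event != float(event_raw) or event not in (0, 1):
            raise ValueError(
                f"{path}: event for sample {sample!r} must be 0 or 1, got {event_raw!r}"
            )
        records.append(SurvivalRecord(sample, time, event))
    return records


# ---------------------------------------------------------------------------
# writers (write -> read is the identity on the data model)
# ---------------------------------------------------------------------------

def write_scores(scores: Iterable, path: str | Path) -> None:
    """Write per-sample global sMFE and signaling genes as TSV."""
    rows = [
        {
            "sample_id": s.sample_id,
            "global_smfe": repr(float(s.global_score)),
            "signaling_genes": ",".join(s.signaling_genes),
        }
        for s in scores
    ]
    pd.DataFrame(rows, columns=["sample_id", "global_smfe", "signaling_genes"]).to_csv(
        path, sep="\t", index=False
    )


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_scores`.

    Returns a DataFrame indexed by sample with a float ``global_smfe``
    column and ``signaling_genes`` as tuples of gene IDs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no score records")
    out = pd.DataFrame(index=df["sample_id"].astype(str))
    out["global_smfe"] = df["global_smfe"].astype(float).to_numpy()
    out["signaling_genes"] = [
        tuple(s.split(",")) if isinstance(s, str) and s else ()
        for s in df["signaling_genes"]
    ]
    return out


def write_local_scores(scores: Iterable, path: str | Path) -> None:
    """Write the full gene x sample matrix of local sMFE values as TSV."""
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to write")
    df = pd.DataFrame({s.sample_id: pd.Series(s.local_scores) for s in scores})
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_biomarkers(results: Iterable, path: str | Path) -> None:
    """Write biomarker classification results as TSV."""
    rows = [
        {
            "gene": r.gene,
            "n_long": r.n_long,
            "m_short": r.m_short,
            "enrichment": repr(float(r.enrichment)),
            "logrank_p": repr(float(r.logrank_p)),
            "direction_stat": repr(float(r.direction_stat)),
            "class": r.biomarker_class,
        }
        for r in results
    ]
    cols = ["gene", "n_long", "m_short", "enrichment", "logrank_p", "direction_stat", "class"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_biomarkers(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_biomarkers`."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")
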
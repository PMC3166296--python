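"""Reading, validation and pre-filtering of multi-tissue, multi-age expression data.

The central container is :class:`ExpressionDataset`: a genes x samples value
table (probes before duplicate collapse, genes after) together with per-sample
annotations (tissue, age, optional sex/replicate/dataset) and an optional
parallel table of Present/Absent/Marginal detection calls.

Files are plain tab-delimited text.  Missing values are written as a sentinel
token (``"NA"`` by default) and represented internally as ``NaN`` in a float
table -- the mask is always explicit, never a magic number.  The loader never
transforms values; a ``scale`` flag (``"log2"``, ``"linear"`` or ``"zscore"``)
travels with the dataset and downstream fold-change logic interprets it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_TOKEN",
    "SCALES",
    "ExpressionDataset",
    "load_expression",
    "write_expression",
    "filter_missing_probes",
    "collapse_duplicate_probes",
]

log = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
SCALES = ("log2", "linear", "zscore")

#: annotation columns; sample_id and the first two are required
ANNOTATION_COLUMNS = ("sample_id", "tissue", "age", "sex", "replicate", "dataset")
DETECTION_CALLS = frozenset({"P", "A", "M"})


@dataclass(eq=False)
class ExpressionDataset:
    """Expression values plus sample metadata.

    Parameters
    ----------
    values
        Float DataFrame, rows indexed by probe/gene identifier, columns by
        sample id.  ``NaN`` marks a missing measurement.
    samples
        DataFrame indexed by sample id with at least ``tissue`` and ``age``
        columns; ``sex``, ``replicate`` and ``dataset`` are optional.
    scale
        One of ``"log2"``, ``"linear"``, ``"zscore"``.
    detection
        Optional DataFrame of the same shape as ``values`` with cells in
        {P, A, M} (MAS5-style detection calls).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if list(self.values.columns) != list(self.samples.index):
            missing = set(self.values.columns) - set(self.samples.index)
            if missing:
                raise ValueError(
                    f"samples present in the matrix but not annotated: {sorted(missing)}"
                )
            # same sample set, enforce matrix column order
            self.samples = self.samples.loc[list(self.values.columns)]
        for col in ("tissue", "age"):
            if col not in self.samples.columns:
                raise ValueError(f"annotation column {col!r} is required")
        if self.detection is not None:
            if self.detection.shape != self.values.shape:
                raise ValueError("detection table shape differs from value table")
            bad = set(np.unique(self.detection.values.astype(str))) - DETECTION_CALLS
            if bad:
                raise ValueError(f"invalid detection calls: {sorted(bad)}")
        self.values = self.values.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        """Number of missing (masked) cells in the value table."""
        return int(self.values.isna().to_numpy().sum())

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.samples["tissue"]:
            seen.setdefault(t, None)
        return list(seen)

    def age_ladder(self, tissue: str | None = None) -> list[float]:
        """Sorted unique ages, overall or within one tissue."""
        sub = self.samples if tissue is None else self.samples[self.samples["tissue"] == tissue]
        return sorted(set(sub["age"].astype(float)))

    def condition_samples(self, tissue: str, age: float) -> list[str]:
        """Sample ids measured in ``tissue`` at ``age`` (the replicate group)."""
        mask = (self.samples["tissue"] == tissue) & (
            self.samples["age"].astype(float) == float(age)
        )
        return list(self.samples.index[mask])

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        det = self.detection.loc[genes] if self.detection is not None else None
        return replace(self, values=self.values.loc[genes], detection=det)


def load_expression(
    matrix_path: str | Path,
    annotation_path: str | Path,
    scale: str,
    detection_path: str | Path | None = None,
    missing: str = MISSING_TOKEN,
) -> ExpressionDataset:
    """Load an expression matrix and its sample annotations from TSV files.

    The matrix has a probe/gene-identifier first column and a header row of
    sample ids; the annotation file maps every sample id to tissue and age
    (plus optional sex/replicate/dataset).  Cells equal to ``missing`` become
    masked values; any other non-numeric cell is an error.
    """
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"duplicate sample ids in matrix header: {dups}")
    raw = pd.read_csv(
        matrix_path, sep="\t", index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    values = raw.replace(missing, np.nan)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(
            f"non-numeric cell that is not the missing marker {missing!r}: {exc}"
        ) from exc

    ann = pd.read_csv(
        annotation_path, sep="\t", dtype=str, keep_default_na=False, na_values=[""],
    )
    if "sample_id" not in ann.columns:
        raise ValueError("annotation file must have a sample_id column")
    ann = ann.set_index("sample_id")
    if "age" in ann.columns:
        ann["age"] = ann["age"].astype(float)
    if "replicate" in ann.columns:
        ann["replicate"] = pd.to_numeric(ann["replicate"], errors="coerce").astype("Int64")

    detection = None
    if detection_path is not None:
        detection = pd.read_csv(
            detection_path, sep="\t", index_col=0, dtype=str,
            keep_default_na=False, na_values=[],
        )
        detection = detection.loc[values.index, values.columns]

    return ExpressionDataset(values=values, samples=ann, scale=scale, detection=detection)


def write_expression(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    annotation_path: str | Path,
    detection_path: str | Path | None = None,
    missing: str = MISSING_TOKEN,
) -> None:
    """Write a dataset back to the TSV conventions of :func:`load_expression`.

    Values round-trip at full ``repr`` precision.
    """
    out = ds.values.map(lambda v: missing if pd.isna(v) else repr(float(v)))
    out.index.name = ds.values.index.name or "probe_id"
    out.to_csv(matrix_path, sep="\t")
    ann = ds.samples.reset_index()
    ann = ann.rename(columns={ann.columns[0]: "sample_id"})
    ann.to_csv(annotation_path, sep="\t", index=False)
    if detection_path is not None and ds.detection is not None:
        det = ds.detection.copy()
        det.index.name = out.index.name
        det.to_csv(detection_path, sep="\t")


def filter_missing_probes(
    ds: ExpressionDataset, max_missing_fraction: float = 0.80
) -> ExpressionDataset:
    """Drop probes whose missing fraction strictly exceeds ``max_missing_fraction``.

    The cut is strict: a probe missing in exactly 80% of samples survives the
    default threshold.  Probe order is preserved; an empty result is allowed.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = ds.values.isna().mean(axis=1)
    keep = list(ds.values.index[frac <= max_missing_fraction])
    removed = ds.n_genes - len(keep)
    if removed:
        log.info("filter_missing_probes removed %d of %d probes", removed, ds.n_genes)
    return ds.subset_genes(keep)


def collapse_duplicate_probes(
    ds: ExpressionDataset, gene_map: Mapping[str, str]
) -> ExpressionDataset:
    """Collapse probes mapping to the same gene, keeping the best-covered probe.

    For each gene the retained probe is the one with the maximum number of
    samples with presented expression: detection calls of ``P`` when a
    detection table is attached, non-missing values otherwise.  Ties break to
    the lowest input row index.  The result is indexed by gene identifier.
    """
    probes = list(ds.values.index)
    unmapped = [p for p in probes if p not in gene_map]
    if unmapped:
        raise ValueError(f"gene_map does not cover probes: {unmapped[:5]}")
    if ds.detection is not None:
        presented = (ds.detection == "P").sum(axis=1)
    else:
        presented = ds.values.notna().sum(axis=1)

    best: dict[str, tuple[int, int]] = {}  # gene -> (row index, presented count)
    order: list[str] = []
    for row, probe in enumerate(probes):
        gene = gene_map[probe]
        n = int(presented.iloc[row])
        if gene not in best:
            best[gene] = (row, n)
            order.append(gene)
        elif n > best[gene][1]:
            best[gene] = (row, n)

    rows = [best[g][0] for g in order]
    values = ds.values.iloc[rows].copy()
    values.index = pd.Index(order, name="gene_id")
    detection = None
    if ds.detection is not None:
        detection = ds.detection.iloc[rows].copy()
        detection.index = values.index
    return replace(ds, values=values, detection=detection)
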
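"""Shared helpers: small in-memory datasets and TSV round-trip paths."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sastagea import ExpressionDataset


def build_dataset(
    values: dict[str, list[float]],
    annotations: list[dict],
    genes: list[str] | None = None,
    scale: str = "log2",
    detection: dict[str, list[str]] | None = None,
) -> ExpressionDataset:
    """Assemble an ExpressionDataset from plain dicts (columns = samples)."""
    n = len(next(iter(values.values())))
    idx = pd.Index(genes or [f"g{i}" for i in range(n)], name="gene_id")
    vals = pd.DataFrame(values, index=idx, dtype=float)
    samples = pd.DataFrame(annotations).set_index("sample_id")
    det = pd.DataFrame(detection, index=idx) if detection is not None else None
    return ExpressionDataset(values=vals, samples=samples, scale=scale, detection=det)


def two_tissue_annotations(ages=(4, 10, 18, 24), tissues=("A", "H")):
    return [
        {"sample_id": f"{t}_{int(a)}M", "tissue": t, "age": float(a), "replicate": 1}
        for t in tissues
        for a in ages
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
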
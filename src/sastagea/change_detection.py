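"""Directional change calling per tissue and age phase.

An *age phase* is the comparison window between two ages of one tissue
(normally consecutive on the age ladder), e.g. 10 months vs 4 months, labelled
``"10Mv4M"``.  For each phase a change criterion assigns every gene to the
*up* set, the *down* set, or neither; the resulting directional gene sets
(:class:`PhaseChangeSet`) are the nodes of the association networks and carry
names like ``"A_10Mv4M_up"`` (tissue code, phase label, direction).

Three criteria are supported, matching the heterogeneous array designs the
method is applied to:

``fold_change``
    |fold-change| >= a threshold (default 2), i.e. |log2 difference| >= 1 on
    log2-scale data.  Replicates are aggregated by arithmetic mean on the
    stored scale before the ratio is taken.
``z_test``
    One-sided two-sample Z test on replicated measurements with unpooled
    (Welch-style) per-group sample variances and a standard-normal reference.
``mas5_composite``
    Externally supplied change p-values (< 0.0025 for increase, 1 - p < 0.0025
    for decrease) AND |fold-change| >= 2 AND all compared samples detected
    Present.  The probe-level change algorithm itself is never computed here;
    its outputs are consumed as input columns.

A fourth mode, :func:`detect_consensus`, intersects same-direction fold-change
calls from two datasets measuring the same process.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression_io import ExpressionDataset

__all__ = [
    "AgePhase",
    "ChangeCriterion",
    "PhaseChangeSet",
    "consecutive_phases",
    "detect_fold_change",
    "detect_z_test",
    "detect_mas5_composite",
    "detect_consensus",
    "build_change_sets",
]

log = logging.getLogger(__name__)

CRITERION_KINDS = ("fold_change", "z_test", "mas5_composite", "consensus")
DIRECTIONS = ("up", "down")


def _fmt_age(age: float) -> str:
    f = float(age)
    return str(int(f)) if f.is_integer() else f"{f:g}"


@dataclass(frozen=True)
class AgePhase:
    """A temporal comparison window within one tissue."""

    tissue: str
    age_from: float
    age_to: float
    unit: str = "M"

    def __post_init__(self) -> None:
        # age_from > age_to is tolerated so the direction-antisymmetry property
        # (swapping endpoints swaps up and down) can be exercised directly
        if self.age_from == self.age_to:
            raise ValueError("age_from and age_to must differ")

    @property
    def label(self) -> str:
        """Phase label, later age first: ``"10Mv4M"`` for 4 -> 10 months."""
        return f"{_fmt_age(self.age_to)}{self.unit}v{_fmt_age(self.age_from)}{self.unit}"

    @property
    def window(self) -> tuple[float, float]:
        return (float(self.age_from), float(self.age_to))

    def reversed(self) -> "AgePhase":
        """Swapped-endpoint phase (used by the direction-antisymmetry property)."""
        return AgePhase(
            tissue=self.tissue, age_from=self.age_to, age_to=self.age_from, unit=self.unit
        )


@dataclass
class ChangeCriterion:
    """Parameters of a change-detection rule; exactly one ``kind`` per run."""

    kind: str = "fold_change"
    fc_threshold: float = 2.0
    z_alpha: float = 0.01
    change_p_threshold: float = 0.0025
    require_presence: bool = True

    def __post_init__(self) -> None:
        if self.kind not in CRITERION_KINDS:
            raise ValueError(f"kind must be one of {CRITERION_KINDS}")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.z_alpha < 1:
            raise ValueError("z_alpha must be in (0, 1)")
        if not 0 < self.change_p_threshold < 1:
            raise ValueError("change_p_threshold must be in (0, 1)")


@dataclass(frozen=True)
class PhaseChangeSet:
    """The genes changed in one direction, in one tissue, over one phase."""

    phase: AgePhase
    direction: str
    genes: frozenset
    tissue_code: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")

    @property
    def code(self) -> str:
        return self.tissue_code if self.tissue_code is not None else self.phase.tissue

    @property
    def node_name(self) -> str:
        return f"{self.code}_{self.phase.label}_{self.direction}"

    def __len__(self) -> int:
        return len(self.genes)


def consecutive_phases(
    ds: ExpressionDataset, tissue: str, unit: str = "M", include_endpoint: bool = False
) -> list[AgePhase]:
    """Consecutive-age phases of one tissue on the dataset's age ladder.

    With ``include_endpoint`` the first-to-last contrast (e.g. 24 vs 4 months)
    is appended; the networks themselves use consecutive phases only.
    """
    ladder = ds.age_ladder(tissue)
    if len(ladder) < 2:
        return []
    phases = [
        AgePhase(tissue=tissue, age_from=a, age_to=b, unit=unit)
        for a, b in zip(ladder[:-1], ladder[1:])
    ]
    if include_endpoint and len(ladder) > 2:
        phases.append(AgePhase(tissue=tissue, age_from=ladder[0], age_to=ladder[-1], unit=unit))
    return phases


def _condition_mean(ds: ExpressionDataset, tissue: str, age: float) -> pd.Series:
    cols = ds.condition_samples(tissue, age)
    if not cols:
        raise ValueError(f"no samples for tissue {tissue!r} at age {age}")
    return ds.values[cols].mean(axis=1)  # skipna: NaN only if all replicates missing


def _log2_delta(ds: ExpressionDataset, phase: AgePhase) -> pd.Series:
    """Per-gene log2 expression difference age_to - age_from; NaN = unusable."""
    if ds.scale == "zscore":
        raise ValueError("fold-change thresholds are undefined for z-scored data")
    m_from = _condition_mean(ds, phase.tissue, phase.age_from)
    m_to = _condition_mean(ds, phase.tissue, phase.age_to)
    if ds.scale == "log2":
        return m_to - m_from
    # linear scale: ratio; non-positive signals cannot form a fold-change
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m_to.where(m_to > 0) / m_from.where(m_from > 0)
        return np.log2(ratio)


def _make_sets(
    phase: AgePhase, up: Iterable[str], down: Iterable[str], tissue_code: str | None
) -> tuple[PhaseChangeSet, PhaseChangeSet]:
    return (
        PhaseChangeSet(phase=phase, direction="up", genes=frozenset(up), tissue_code=tissue_code),
        PhaseChangeSet(phase=phase, direction="down", genes=frozenset(down), tissue_code=tissue_code),
    )


def detect_fold_change(
    ds: ExpressionDataset,
    phase: AgePhase,
    criterion: ChangeCriterion | None = None,
    tissue_code: str | None = None,
) -> tuple[PhaseChangeSet, PhaseChangeSet]:
    """Call genes whose |fold-change| across the phase meets the threshold.

    The threshold is inclusive ("at least 2"): on log2 data a difference of
    exactly +1.0 is called up at the default threshold.  Genes with a missing
    aggregated value at either age are in neither set.
    """
    criterion = criterion or ChangeCriterion(kind="fold_change")
    delta = _log2_delta(ds, phase)
    thr = math.log2(criterion.fc_threshold)
    up = delta.index[delta >= thr]
    down = delta.index[delta <= -thr]
    return _make_sets(phase, up, down, tissue_code)


def detect_z_test(
    ds: ExpressionDataset,
    phase: AgePhase,
    criterion: ChangeCriterion | None = None,
    tissue_code: str | None = None,
) -> tuple[PhaseChangeSet, PhaseChangeSet]:
    """One-sided two-sample Z test between the two replicate groups of a phase.

    z = (mean_to - mean_from) / sqrt(s2_to/n_to + s2_from/n_from) with per-gene,
    per-group sample variances (n-1 denominator) and standard-normal tails.
    Genes with fewer than two non-missing replicates in either group are
    skipped (counted and logged), as are genes with zero spread in both groups
    and equal means, where z is undefined.  Zero spread with unequal means is
    an infinitely confident call.
    """
    criterion = criterion or ChangeCriterion(kind="z_test")
    g_from = ds.values[ds.condition_samples(phase.tissue, phase.age_from)]
    g_to = ds.values[ds.condition_samples(phase.tissue, phase.age_to)]

    n_from = g_from.notna().sum(axis=1)
    n_to = g_to.notna().sum(axis=1)
    usable = (n_from >= 2) & (n_to >= 2)
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.warning(
            "detect_z_test %s/%s: %d genes skipped (<2 replicates in a group)",
            phase.tissue, phase.label, n_skipped,
        )

    m_from = g_from.mean(axis=1)
    m_to = g_to.mean(axis=1)
    v_from = g_from.var(axis=1, ddof=1)
    v_to = g_to.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(v_to / n_to + v_from / n_from)
        diff = m_to - m_from
        z = diff / se

    degenerate = usable & (se == 0) & (diff == 0)
    if int(degenerate.sum()):
        log.warning(
            "detect_z_test %s/%s: %d genes skipped (zero variance, equal means)",
            phase.tissue, phase.label, int(degenerate.sum()),
        )
    z = z.where(~((se == 0) & (diff != 0)), np.sign(diff) * np.inf)
    valid = usable & ~degenerate & z.notna()

    p_up = pd.Series(norm.sf(z), index=z.index)
    p_down = pd.Series(norm.cdf(z), index=z.index)
    up = z.index[valid & (p_up < criterion.z_alpha)]
    down = z.index[valid & (p_down < criterion.z_alpha)]
    return _make_sets(phase, up, down, tissue_code)


def detect_mas5_composite(
    ds: ExpressionDataset,
    phase: AgePhase,
    criterion: ChangeCriterion,
    change_p: pd.Series,
    detection: pd.DataFrame | None = None,
    tissue_code: str | None = None,
) -> tuple[PhaseChangeSet, PhaseChangeSet]:
    """Composite MAS5-style criterion: change p-value, fold-change and presence.

    ``change_p`` is the per-gene change p-value of this comparison, supplied
    externally (small = increase, near 1 = decrease).  A gene is up when
    change_p < threshold, |fold-change| >= fc_threshold in the up direction,
    and every sample of both compared conditions is detected Present; down
    symmetrically with 1 - change_p.  Without a detection table the presence
    filter is skipped with a logged warning.
    """
    if change_p is None:
        raise ValueError("mas5_composite requires a change_p table")
    change_p = change_p.reindex(ds.values.index)
    delta = _log2_delta(ds, phase)
    thr = math.log2(criterion.fc_threshold)

    detection = detection if detection is not None else ds.detection
    if detection is None:
        if criterion.require_presence:
            log.warning(
                "no detection calls available; presence filter skipped for %s/%s",
                phase.tissue, phase.label,
            )
        present = pd.Series(True, index=ds.values.index)
    else:
        cols = ds.condition_samples(phase.tissue, phase.age_from) + ds.condition_samples(
            phase.tissue, phase.age_to
        )
        present = (detection[cols] == "P").all(axis=1)
        if not criterion.require_presence:
            present = pd.Series(True, index=ds.values.index)

    p_thr = criterion.change_p_threshold
    up = ds.values.index[(change_p < p_thr) & (delta >= thr) & present]
    down = ds.values.index[((1.0 - change_p) < p_thr) & (delta <= -thr) & present]
    return _make_sets(phase, up, down, tissue_code)


def detect_consensus(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    phase: AgePhase,
    criterion: ChangeCriterion | None = None,
    tissue_code: str | None = None,
) -> tuple[PhaseChangeSet, PhaseChangeSet]:
    """Fold-change calls required in the same direction in both datasets.

    Used when two independent array series measure the same aging process: a
    gene is called only if it passes the fold-change rule with the same sign
    in both.  Mismatched gene universes are restricted to the intersection
    (logged); direction conflicts are called in neither set.
    """
    criterion = criterion or ChangeCriterion(kind="consensus")
    fc = ChangeCriterion(kind="fold_change", fc_threshold=criterion.fc_threshold)
    shared = [g for g in ds_a.genes if g in set(ds_b.genes)]
    lost = (len(ds_a.genes) - len(shared)) + (len(ds_b.genes) - len(shared))
    if lost:
        log.warning("consensus: %d probes outside the shared gene universe dropped", lost)
    up_a, down_a = detect_fold_change(ds_a.subset_genes(shared), phase, fc)
    up_b, down_b = detect_fold_change(ds_b.subset_genes(shared), phase, fc)
    return _make_sets(
        phase, up_a.genes & up_b.genes, down_a.genes & down_b.genes, tissue_code
    )


def build_change_sets(
    ds: ExpressionDataset,
    criterion: ChangeCriterion,
    tissue_codes: Mapping[str, str] | None = None,
    unit: str = "M",
    include_endpoint: bool = False,
    change_p: Mapping[tuple[str, float, float], pd.Series] | None = None,
) -> list[PhaseChangeSet]:
    """Directional change sets for every tissue and consecutive phase.

    Returns 2 x |tissues| x |phases| sets (some possibly empty), one up and
    one down per tissue-phase, named by the ``<code>_<to><unit>v<from><unit>_<dir>``
    convention.  ``tissue_codes`` maps tissue labels to short node codes
    (identity by default).  For the ``mas5_composite`` criterion, ``change_p``
    maps (tissue, age_from, age_to) to that comparison's change p-values.
    """
    tissue_codes = dict(tissue_codes or {})
    out: list[PhaseChangeSet] = []
    for tissue in ds.tissues:
        code = tissue_codes.get(tissue, tissue)
        for phase in consecutive_phases(ds, tissue, unit=unit, include_endpoint=include_endpoint):
            if criterion.kind == "fold_change":
                up, down = detect_fold_change(ds, phase, criterion, tissue_code=code)
            elif criterion.kind == "z_test":
                up, down = detect_z_test(ds, phase, criterion, tissue_code=code)
            elif criterion.kind == "mas5_composite":
                if change_p is None:
                    raise ValueError("mas5_composite requires change_p tables")
                key = (tissue, float(phase.age_from), float(phase.age_to))
                up, down = detect_mas5_composite(
                    ds, phase, criterion, change_p[key], tissue_code=code
                )
            else:
                raise ValueError(
                    "build_change_sets supports fold_change, z_test and mas5_composite; "
                    "use detect_consensus for two-dataset designs"
                )
            out.extend([up, down])
    return out
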
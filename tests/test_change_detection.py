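"""Directional change calling: fold-change, Z test, composite and consensus."""

import math

import numpy as np
import pandas as pd
import pytest

from sastagea import (
    AgePhase,
    ChangeCriterion,
    build_change_sets,
    consecutive_phases,
    detect_consensus,
    detect_fold_change,
    detect_mas5_composite,
    detect_z_test,
    make_worked_example_fixture,
)

from conftest import build_dataset, two_tissue_annotations


def _phase(tissue, a, b):
    return AgePhase(tissue=tissue, age_from=a, age_to=b)


class TestAgePhase:
    def test_label_convention(self):
        assert _phase("A", 4, 10).label == "10Mv4M"
        assert AgePhase("MU", 1, 6).label == "6Mv1M"

    def test_node_name_convention(self):
        up, _ = detect_fold_change(make_worked_example_fixture(), _phase("A", 4, 10))
        assert up.node_name == "A_10Mv4M_up"

    def test_equal_endpoints_rejected(self):
        with pytest.raises(ValueError):
            AgePhase("A", 4, 4)


class TestFoldChange:
    def test_worked_example_adrenal_called_only_in_first_phase(self):
        """The printed adrenal series rises >= 2-fold only from 4 to 10 months."""
        ds = make_worked_example_fixture()
        called = {
            ph.label: detect_fold_change(ds, ph)[0].genes
            for ph in consecutive_phases(ds, "A")
        }
        assert called == {"10Mv4M": {"Slc24a2"}, "18Mv10M": frozenset(), "24Mv18M": frozenset()}

    def test_worked_example_hypothalamus_called_only_in_second_phase(self):
        ds = make_worked_example_fixture()
        called = {
            ph.label: detect_fold_change(ds, ph)[0].genes
            for ph in consecutive_phases(ds, "H")
        }
        assert called == {"10Mv4M": frozenset(), "18Mv10M": {"Slc24a2"}, "24Mv18M": frozenset()}

    def test_endpoint_contrast_hides_the_asynchrony(self):
        """Both tissues look 'up' young-vs-old, though their phases differ."""
        ds = make_worked_example_fixture()
        for t in ("A", "H"):
            ph = consecutive_phases(ds, t, include_endpoint=True)[-1]
            assert ph.label == "24Mv4M"
            assert detect_fold_change(ds, ph)[0].genes == {"Slc24a2"}

    def test_constant_series_never_called(self):
        ds = build_dataset(
            {f"A_{a}M": [3.3, 8.0] for a in (4, 10, 18, 24)},
            [{"sample_id": f"A_{a}M", "tissue": "A", "age": float(a)} for a in (4, 10, 18, 24)],
        )
        for ph in consecutive_phases(ds, "A"):
            up, down = detect_fold_change(ds, ph)
            assert not up.genes and not down.genes

    def test_boundary_log2_delta_of_one_is_called(self):
        """'At least two'-fold is inclusive: log2 difference exactly 1 counts."""
        ds = build_dataset(
            {"A_4M": [5.0, 5.0, 5.0], "A_10M": [6.0, 6.0 - 1e-9, 4.0]},
            [{"sample_id": "A_4M", "tissue": "A", "age": 4.0},
             {"sample_id": "A_10M", "tissue": "A", "age": 10.0}],
            genes=["exact", "justunder", "downer"],
        )
        up, down = detect_fold_change(ds, _phase("A", 4, 10))
        assert up.genes == {"exact"}
        assert down.genes == {"downer"}

    def test_missing_value_excludes_gene(self):
        ds = build_dataset(
            {"A_4M": [np.nan, 1.0], "A_10M": [9.0, 9.0]},
            [{"sample_id": "A_4M", "tissue": "A", "age": 4.0},
             {"sample_id": "A_10M", "tissue": "A", "age": 10.0}],
            genes=["gapped", "ok"],
        )
        up, _ = detect_fold_change(ds, _phase("A", 4, 10))
        assert up.genes == {"ok"}

    def test_linear_scale_uses_ratio(self):
        ds = build_dataset(
            {"A_4M": [100.0, 100.0], "A_10M": [200.0, 150.0]},
            [{"sample_id": "A_4M", "tissue": "A", "age": 4.0},
             {"sample_id": "A_10M", "tissue": "A", "age": 10.0}],
            genes=["doubled", "mild"], scale="linear",
        )
        up, _ = detect_fold_change(ds, _phase("A", 4, 10))
        assert up.genes == {"doubled"}

    def test_zscore_scale_rejects_fold_change(self):
        ds = build_dataset(
            {"A_4M": [0.0], "A_10M": [2.0]},
            [{"sample_id": "A_4M", "tissue": "A", "age": 4.0},
             {"sample_id": "A_10M", "tissue": "A", "age": 10.0}],
            scale="zscore",
        )
        with pytest.raises(ValueError, match="z-scored"):
            detect_fold_change(ds, _phase("A", 4, 10))

    def test_unknown_tissue_is_error(self):
        with pytest.raises(ValueError, match="no samples"):
            detect_fold_change(make_worked_example_fixture(), _phase("X", 4, 10))

    def test_direction_antisymmetry(self, rng):
        """Swapping the phase endpoints swaps the up and down sets exactly."""
        vals = rng.normal(8, 2, (300, 2))
        ds = build_dataset(
            {"A_4M": vals[:, 0], "A_10M": vals[:, 1]},
            [{"sample_id": "A_4M", "tissue": "A", "age": 4.0},
             {"sample_id": "A_10M", "tissue": "A", "age": 10.0}],
        )
        fwd_up, fwd_down = detect_fold_change(ds, _phase("A", 4, 10))
        rev_up, rev_down = detect_fold_change(ds, _phase("A", 4, 10).reversed())
        assert fwd_up.genes == rev_down.genes and fwd_down.genes == rev_up.genes
        assert fwd_up.genes  # non-degenerate draw


def _replicated_ds(rows_from, rows_to, genes=None):
    """Two replicate groups as genes x replicates arrays."""
    rows_from = np.atleast_2d(rows_from)
    rows_to = np.atleast_2d(rows_to)
    cols = {}
    ann = []
    for r in range(rows_from.shape[1]):
        sid = f"A_4M_r{r + 1}"
        cols[sid] = rows_from[:, r]
        ann.append({"sample_id": sid, "tissue": "A", "age": 4.0, "replicate": r + 1})
    for r in range(rows_to.shape[1]):
        sid = f"A_10M_r{r + 1}"
        cols[sid] = rows_to[:, r]
        ann.append({"sample_id": sid, "tissue": "A", "age": 10.0, "replicate": r + 1})
    return build_dataset(cols, ann, genes=genes, scale="zscore")


class TestZTest:
    def test_identical_groups_not_called(self):
        ds = _replicated_ds([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        up, down = detect_z_test(ds, _phase("A", 4, 10))
        assert not up.genes and not down.genes

    def test_huge_shift_tiny_variance_called_up(self):
        f = 1.0 + 1e-3 * np.arange(5)
        ds = _replicated_ds([f], [f + 10.0])
        up, down = detect_z_test(ds, _phase("A", 4, 10))
        assert up.genes == {"g0"} and not down.genes

    def test_p_value_matches_independent_normal_tail(self):
        """Frozen oracle: z computed by hand, tail from erfc, for one triple."""
        g_from = np.array([0.0, 0.1, -0.1])
        g_to = np.array([1.0, 1.1, 0.9])
        m1, m2 = g_from.mean(), g_to.mean()
        v1, v2 = g_from.var(ddof=1), g_to.var(ddof=1)
        z = (m2 - m1) / math.sqrt(v1 / 3 + v2 / 3)
        p = 0.5 * math.erfc(z / math.sqrt(2))  # = 1.02e-34 at z = 12.247
        assert z == pytest.approx(12.2474487, rel=1e-6)
        ds = _replicated_ds([g_from], [g_to])
        up, down = detect_z_test(ds, _phase("A", 4, 10), ChangeCriterion(kind="z_test", z_alpha=0.01))
        assert up.genes == {"g0"}
        # the same gene stops being called once alpha drops below the oracle p
        tight = ChangeCriterion(kind="z_test", z_alpha=max(p / 10, 1e-300))
        up2, _ = detect_z_test(ds, _phase("A", 4, 10), tight)
        assert not up2.genes

    def test_short_replicate_groups_skipped(self):
        ds = _replicated_ds(
            np.array([[1.0, np.nan, np.nan], [1.0, 1.2, 0.8]]),
            np.array([[9.0, 9.1, 8.9], [9.0, 9.1, 8.9]]),
            genes=["short", "ok"],
        )
        up, _ = detect_z_test(ds, _phase("A", 4, 10))
        assert up.genes == {"ok"}

    def test_zero_variance_equal_means_skipped(self):
        ds = _replicated_ds([[2.0, 2.0, 2.0]], [[2.0, 2.0, 2.0]])
        up, down = detect_z_test(ds, _phase("A", 4, 10))
        assert not up.genes and not down.genes

    def test_zero_variance_unequal_means_is_certain_call(self):
        ds = _replicated_ds([[2.0, 2.0, 2.0]], [[5.0, 5.0, 5.0]])
        up, down = detect_z_test(ds, _phase("A", 4, 10))
        assert up.genes == {"g0"} and not down.genes

    def test_antisymmetry(self, rng):
        vals = rng.normal(0, 1, (200, 10))
        ds = _replicated_ds(vals[:, :5], vals[:, 5:] + rng.normal(0, 2, (200, 1)))
        crit = ChangeCriterion(kind="z_test", z_alpha=0.05)
        fwd_up, fwd_down = detect_z_test(ds, _phase("A", 4, 10), crit)
        rev_up, rev_down = detect_z_test(ds, _phase("A", 4, 10).reversed(), crit)
        assert fwd_up.genes == rev_down.genes and fwd_down.genes == rev_up.genes

    def test_null_rate_matches_sampling_distribution(self, rng):
        """With estimated variances at n=5 the true per-tail level follows the
        t distribution with 8 df (~0.0242 at nominal 0.01), approaching the
        nominal level as replication grows."""
        from scipy.stats import t as t_dist
        from scipy.stats import norm

        n_genes = 20_000
        for n, tol_mult in ((5, 1.0), (50, 1.0)):
            a = rng.normal(0, 1, (n_genes, n))
            b = rng.normal(0, 1, (n_genes, n))
            ds = _replicated_ds(a, b)
            up, down = detect_z_test(ds, _phase("A", 4, 10))
            expected = t_dist.sf(norm.isf(0.01), 2 * n - 2)
            sd = math.sqrt(expected * (1 - expected) / n_genes)
            for called in (up, down):
                assert abs(len(called.genes) / n_genes - expected) < 4 * sd


class TestMas5Composite:
    def _ds(self, delta, genes=("g0",)):
        return build_dataset(
            {"A_4M": [8.0] * len(genes), "A_10M": [8.0 + d for d in delta]},
            [{"sample_id": "A_4M", "tissue": "A", "age": 4.0},
             {"sample_id": "A_10M", "tissue": "A", "age": 10.0}],
            genes=list(genes),
        )

    def test_all_three_filters_pass_up(self):
        ds = self._ds([1.5])
        det = pd.DataFrame({"A_4M": ["P"], "A_10M": ["P"]}, index=ds.values.index)
        crit = ChangeCriterion(kind="mas5_composite")
        up, down = detect_mas5_composite(
            ds, _phase("A", 4, 10), crit, pd.Series([0.001], index=ds.values.index), det
        )
        assert up.genes == {"g0"} and not down.genes

    def test_absent_call_blocks(self):
        ds = self._ds([1.5])
        det = pd.DataFrame({"A_4M": ["P"], "A_10M": ["A"]}, index=ds.values.index)
        crit = ChangeCriterion(kind="mas5_composite")
        up, _ = detect_mas5_composite(
            ds, _phase("A", 4, 10), crit, pd.Series([0.001], index=ds.values.index), det
        )
        assert not up.genes

    def test_decrease_rule_uses_one_minus_p(self):
        ds = self._ds([-1.5])
        det = pd.DataFrame({"A_4M": ["P"], "A_10M": ["P"]}, index=ds.values.index)
        crit = ChangeCriterion(kind="mas5_composite")
        up, down = detect_mas5_composite(
            ds, _phase("A", 4, 10), crit, pd.Series([0.9990], index=ds.values.index), det
        )
        assert down.genes == {"g0"} and not up.genes

    def test_fold_change_filter_still_required(self):
        ds = self._ds([0.5])  # significant change p but under 2-fold
        det = pd.DataFrame({"A_4M": ["P"], "A_10M": ["P"]}, index=ds.values.index)
        crit = ChangeCriterion(kind="mas5_composite")
        up, _ = detect_mas5_composite(
            ds, _phase("A", 4, 10), crit, pd.Series([0.0001], index=ds.values.index), det
        )
        assert not up.genes

    def test_missing_change_p_is_error(self):
        ds = self._ds([1.5])
        with pytest.raises(ValueError, match="change_p"):
            detect_mas5_composite(
                ds, _phase("A", 4, 10), ChangeCriterion(kind="mas5_composite"), None
            )

    def test_no_detection_table_skips_presence_filter_with_warning(self, caplog):
        ds = self._ds([1.5])
        crit = ChangeCriterion(kind="mas5_composite")
        with caplog.at_level("WARNING"):
            up, _ = detect_mas5_composite(
                ds, _phase("A", 4, 10), crit, pd.Series([0.001], index=ds.values.index)
            )
        assert up.genes == {"g0"}
        assert any("presence filter skipped" in r.message for r in caplog.records)


class TestConsensus:
    def _pair(self, delta_a, delta_b, genes):
        mk = lambda d: build_dataset(
            {"A_4M": [8.0] * len(genes), "A_10M": [8.0 + x for x in d]},
            [{"sample_id": "A_4M", "tissue": "A", "age": 4.0},
             {"sample_id": "A_10M", "tissue": "A", "age": 10.0}],
            genes=list(genes),
        )
        return mk(delta_a), mk(delta_b)

    def test_same_direction_in_both_is_called(self):
        a, b = self._pair([1.2], [1.1], ["g0"])
        up, _ = detect_consensus(a, b, _phase("A", 4, 10))
        assert up.genes == {"g0"}

    def test_one_dataset_unchanged_blocks(self):
        a, b = self._pair([1.2], [0.0], ["g0"])
        up, down = detect_consensus(a, b, _phase("A", 4, 10))
        assert not up.genes and not down.genes

    def test_direction_conflict_blocks_both(self):
        a, b = self._pair([1.2], [-1.2], ["g0"])
        up, down = detect_consensus(a, b, _phase("A", 4, 10))
        assert not up.genes and not down.genes

    def test_consensus_with_itself_equals_fold_change(self, rng):
        vals = rng.normal(8, 1.2, (200, 2))
        ds = build_dataset(
            {"A_4M": vals[:, 0], "A_10M": vals[:, 1]},
            [{"sample_id": "A_4M", "tissue": "A", "age": 4.0},
             {"sample_id": "A_10M", "tissue": "A", "age": 10.0}],
        )
        cons = detect_consensus(ds, ds, _phase("A", 4, 10))
        solo = detect_fold_change(ds, _phase("A", 4, 10))
        assert cons[0].genes == solo[0].genes and cons[1].genes == solo[1].genes

    def test_mismatched_universes_restricted_to_intersection(self):
        a, b = self._pair([1.2, 1.2], [1.1], ["g0", "extra"])
        b_genes_only = b  # b lacks "extra"
        a2, _ = self._pair([1.2, 1.2], [1.1], ["g0", "extra"])
        up, _ = detect_consensus(a2, b_genes_only.subset_genes(["g0"]), _phase("A", 4, 10))
        assert up.genes == {"g0"}


class TestBuildChangeSets:
    def _design(self, n_tissues, ages=(4, 10, 18, 24)):
        tissues = [f"T{i}" for i in range(n_tissues)]
        ann = [
            {"sample_id": f"{t}_{a}M", "tissue": t, "age": float(a)}
            for t in tissues for a in ages
        ]
        cols = {r["sample_id"]: [8.0, 8.0] for r in ann}
        return build_dataset(cols, ann)

    @pytest.mark.parametrize("n_tissues,expected", [(7, 42), (16, 96)])
    def test_set_count_is_two_per_tissue_phase(self, n_tissues, expected):
        sets = build_change_sets(self._design(n_tissues), ChangeCriterion())
        assert len(sets) == expected
        assert len({s.node_name for s in sets}) == expected

    def test_up_and_down_disjoint_per_node(self, rng):
        vals = rng.normal(8, 1.5, (100, 8))
        ann = two_tissue_annotations()
        ds = build_dataset({r["sample_id"]: vals[:, i] for i, r in enumerate(ann)}, ann)
        sets = build_change_sets(ds, ChangeCriterion())
        by_key = {}
        for s in sets:
            by_key.setdefault((s.code, s.phase.label), []).append(s)
        for (code, label), pair in by_key.items():
            assert len(pair) == 2
            assert not (pair[0].genes & pair[1].genes)

    def test_empty_dataset_gives_empty_list(self):
        ds = self._design(1)
        empty = ds.subset_genes([])
        sets = build_change_sets(empty, ChangeCriterion())
        assert all(len(s.genes) == 0 for s in sets)
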
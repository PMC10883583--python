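"""Prevalence, variation of information, threshold selection and
cancer-specific calls."""

import numpy as np
import pandas as pd
import pytest

from sefingerprint.activity_matrix import SampleSheet
from sefingerprint.specificity import (
    SpecificityCall,
    call_cancer_specific,
    call_cell_specific,
    cluster_cells,
    compute_prevalence,
    select_from_curve,
    select_threshold,
    summarize_cancer_specific_se,
    variation_of_information,
)
from sefingerprint.genome_intervals import CEtoSEMap


def vi_oracle(a, b):
    """Independent VI via sklearn mutual information and scipy entropy."""
    from scipy.stats import entropy
    from sklearn.metrics import mutual_info_score

    _, ca = np.unique(a, return_counts=True)
    _, cb = np.unique(b, return_counts=True)
    return entropy(ca) + entropy(cb) - 2 * mutual_info_score(a, b)


class TestPrevalence:
    def test_arithmetic(self):
        states = pd.DataFrame(
            [[True] * 12 + [False] * 48, [True] * 60, [False] * 60],
            index=["a", "b", "c"], columns=[f"c{i}" for i in range(60)])
        prof = compute_prevalence(states)
        assert prof.loc["a", "active_prevalence"] == pytest.approx(0.2)
        assert prof.loc["b", "active_prevalence"] == 1.0
        assert prof.loc["c", "active_prevalence"] == 0.0

    def test_prevalences_sum_to_one(self):
        rng = np.random.default_rng(0)
        states = pd.DataFrame(rng.random((50, 30)) < 0.4)
        prof = compute_prevalence(states)
        np.testing.assert_allclose(
            prof["active_prevalence"] + prof["inactive_prevalence"], 1.0)


class TestVariationOfInformation:
    def test_identical_partitions_zero(self):
        assert variation_of_information([1, 1, 2, 2], [7, 7, 8, 8]) == 0.0

    def test_crossed_partitions_two_ln_two(self):
        vi = variation_of_information(list("aabb"), list("abab"))
        assert vi == pytest.approx(2 * np.log(2))

    def test_single_cluster_gives_entropy_of_other(self):
        a = [1, 1, 2, 3]
        vi = variation_of_information(a, [0, 0, 0, 0])
        _, counts = np.unique(a, return_counts=True)
        p = counts / counts.sum()
        assert vi == pytest.approx(float(-(p * np.log(p)).sum()))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_entropy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        a = rng.integers(0, 5, n)
        b = rng.integers(0, 4, n)
        assert variation_of_information(a, b) == pytest.approx(
            vi_oracle(a, b), abs=1e-10)
        assert variation_of_information(a, b) == pytest.approx(
            variation_of_information(b, a))

    def test_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            a, b, c = (rng.integers(0, 4, 30) for _ in range(3))
            ab = variation_of_information(a, b)
            bc = variation_of_information(b, c)
            ac = variation_of_information(a, c)
            assert ac <= ab + bc + 1e-12

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            variation_of_information([1, 2], [1, 2, 3])


class TestClusterCells:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        block = np.repeat([0, 1], 6)
        values = np.where(block[None, :] == 1, 9.0, 3.0) \
            + rng.normal(0, 0.3, (40, 12))
        part = cluster_cells(pd.DataFrame(values), k=2)
        assert variation_of_information(part, block) == 0.0

    def test_k_one_and_k_n(self):
        df = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        assert len(np.unique(cluster_cells(df, 1))) == 1
        assert len(np.unique(cluster_cells(df, 4))) == 4

    def test_zero_features_single_cluster(self):
        df = pd.DataFrame(np.empty((0, 5)))
        assert len(np.unique(cluster_cells(df, 3))) == 1


class TestSelectFromCurve:
    def test_linear_slope_minus_one_selects_last_grid_point(self):
        grid = np.arange(0, 0.51, 0.01)
        vi = 1.0 - np.linspace(0, 1, len(grid))  # scaled slope exactly -1
        scan = select_from_curve(grid, vi)
        assert scan.selected == pytest.approx(0.5)
        assert not scan.fallback_used

    def test_flat_curve_falls_back_to_corner_rule(self):
        grid = np.arange(0, 0.51, 0.01)
        scan = select_from_curve(grid, np.ones(len(grid)))
        assert scan.fallback_used
        assert scan.selected == pytest.approx(0.0)

    def test_step_drop_selects_just_after_step(self):
        grid = np.arange(0, 0.51, 0.01)
        vi = np.where(grid < 0.2, 1.0, 0.0)
        scan = select_from_curve(grid, vi)
        assert 0.15 < scan.selected < 0.35
        assert not scan.fallback_used


def planted_panel(seed=0, n_cancers=10, cells_per_cancer=3, n_background=400,
                  n_specific=60, minority=4):
    """States with planted low-prevalence CEs and 0.5-prevalence background,
    plus activities that mirror the states."""
    rng = np.random.default_rng(seed)
    cells = [f"ca{c}_cell{i}" for c in range(n_cancers)
             for i in range(cells_per_cancer)]
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": cells, "cell_line": cells,
        "cancer_type": [c.split("_")[0] for c in cells]}))
    n_cells = len(cells)
    rows, planted = [], []
    for i in range(n_specific):
        cancer = i % n_cancers
        row = np.zeros(n_cells, bool)
        own = [cancer * cells_per_cancer + k for k in range(cells_per_cancer)]
        row[own] = True
        extra_pool = [j for j in range(n_cells)
                      if j // cells_per_cancer != cancer]
        row[rng.choice(extra_pool, minority - cells_per_cancer,
                       replace=False)] = True
        rows.append(row)
        planted.append((f"ce{i}", f"ca{cancer}"))
    for i in range(n_background):
        rows.append(rng.random(n_cells) < 0.5)
    states = pd.DataFrame(rows, index=[f"ce{i}" for i in range(len(rows))],
                          columns=cells)
    activities = pd.DataFrame(
        np.where(states.to_numpy(), 9.0, 5.0) + rng.normal(
            0, 1.0, states.shape),
        index=states.index, columns=cells)
    return sheet, states, activities, dict(planted)


class TestSelectThreshold:
    def test_planted_structure_recovery(self):
        sheet, states, activities, planted = planted_panel(seed=1)
        prof = compute_prevalence(states)
        labels = [sheet.cell_to_cancer()[c] for c in states.columns]
        scan = select_threshold(prof, activities, labels)
        minority_prev = 4 / 30
        assert minority_prev < scan.selected < 0.5
        calls = call_cell_specific(prof, states, scan.selected)
        called = {c.ce_id for c in calls if c.mode == "specific_active"}
        tp = len(called & set(planted))
        prec = tp / len(called)
        rec = tp / len(planted)
        f1 = 2 * prec * rec / (prec + rec)
        assert f1 >= 0.9

    def test_scan_table_schema(self):
        sheet, states, activities, _ = planted_panel(seed=2, n_background=50,
                                                     n_specific=20)
        prof = compute_prevalence(states)
        labels = [sheet.cell_to_cancer()[c] for c in states.columns]
        scan = select_threshold(prof, activities, labels)
        assert list(scan.table.columns[:3]) == ["cutoff", "n_selected", "vi"]
        assert len(scan.table) == 51
        assert (scan.table["vi"] >= 0).all()
        assert scan.table["n_selected"].is_monotonic_increasing


class TestCallCellSpecific:
    def _profiles_states(self):
        cells = [f"c{i}" for i in range(60)]
        rows = {
            "low": [True] * 12 + [False] * 48,      # active prev 0.20
            "edge": [True] * 13 + [False] * 47,     # active prev ~0.2167
            "high": [True] * 57 + [False] * 3,      # inactive prev 0.05
            "uniform": [True] * 60,                  # prevalence 0/1
        }
        states = pd.DataFrame.from_dict(rows, orient="index", columns=cells)
        return compute_prevalence(states), states

    def test_strict_threshold_and_minority_cells(self):
        prof, states = self._profiles_states()
        calls = call_cell_specific(prof, states, 0.21)
        by_ce = {(c.ce_id, c.mode): c for c in calls}
        assert ("low", "specific_active") in by_ce
        assert len(by_ce[("low", "specific_active")].cells) == 12
        assert ("edge", "specific_active") not in by_ce  # 0.2167 !< 0.21
        assert ("high", "specific_inactive") in by_ce
        assert len(by_ce[("high", "specific_inactive")].cells) == 3
        assert not any(c.ce_id == "uniform" for c in calls)

    def test_active_and_inactive_calls_disjoint_below_half(self):
        rng = np.random.default_rng(11)
        states = pd.DataFrame(rng.random((100, 20)) < rng.uniform(
            0, 1, (100, 1)), columns=[f"c{i}" for i in range(20)])
        prof = compute_prevalence(states)
        calls = call_cell_specific(prof, states, 0.5)
        seen = {}
        for c in calls:
            assert seen.setdefault(c.ce_id, c.mode) == c.mode
        assert all(c.cells for c in calls)

    def test_monotone_in_threshold(self):
        prof, states = self._profiles_states()
        low = {(c.ce_id, c.mode) for c in call_cell_specific(prof, states, 0.1)}
        high = {(c.ce_id, c.mode)
                for c in call_cell_specific(prof, states, 0.3)}
        assert low <= high

    def test_empty_cell_set_rejected_by_type(self):
        with pytest.raises(ValueError):
            SpecificityCall("ce", "specific_active", ())


class TestCallCancerSpecific:
    def _sheet(self):
        return SampleSheet(pd.DataFrame({
            "sample_id": ["A", "B", "D", "Y1"],
            "cell_line": ["A", "B", "D", "Y1"],
            "cancer_type": ["X", "X", "X", "Y"]}))

    def test_two_cell_line_rule(self):
        calls = [SpecificityCall("ce1", "specific_active", ("A", "B", "C"))]
        out = call_cancer_specific(calls, self._sheet())
        assert out["cancer_type"].tolist() == ["X"]

    def test_single_cell_line_cancer_rule(self):
        calls = [SpecificityCall("ce1", "specific_active", ("Y1",))]
        out = call_cancer_specific(calls, self._sheet())
        assert out["cancer_type"].tolist() == ["Y"]

    def test_one_of_many_lines_not_attached(self):
        calls = [SpecificityCall("ce1", "specific_active", ("A",))]
        out = call_cancer_specific(calls, self._sheet())
        assert out.empty


class TestSummarizeSe:
    def _map(self):
        return CEtoSEMap(mapping={"ce1": "se1", "ce2": "se1", "ce3": "se2",
                                  "ce4": "se2"})

    def test_both_category_listed_per_cancer(self):
        table = pd.DataFrame([
            {"ce_id": "ce1", "mode": "specific_active", "cancer_type": "X",
             "cells": "a,b"},
            {"ce_id": "ce2", "mode": "specific_inactive", "cancer_type": "Y",
             "cells": "c,d"},
        ])
        out = summarize_cancer_specific_se(table, self._map())
        assert set(out["cancer_type"]) == {"X", "Y"}
        assert (out["category"] == "both").all()

    def test_active_only_deduplicated_per_cancer(self):
        table = pd.DataFrame([
            {"ce_id": "ce3", "mode": "specific_active", "cancer_type": "X",
             "cells": "a,b"},
            {"ce_id": "ce4", "mode": "specific_active", "cancer_type": "X",
             "cells": "a,b"},
        ])
        out = summarize_cancer_specific_se(table, self._map())
        assert len(out) == 1
        assert out.iloc[0]["category"] == "active_only"
        assert out.iloc[0]["specific_active_ces"] == "ce3,ce4"

    def test_none_rows_for_untouched_ses(self):
        table = pd.DataFrame(columns=["ce_id", "mode", "cancer_type",
                                      "cells"])
        out = summarize_cancer_specific_se(table, self._map(),
                                           all_se_ids=["se1", "se2"])
        assert (out["category"] == "none").all() and len(out) == 2
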
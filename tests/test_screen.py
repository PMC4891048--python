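"""Outlier exclusion, activity discretization and the Spearman screen."""

import numpy as np
import pandas as pd
import pytest

import drugsig as ds
from drugsig.grouplasso import SignatureSet
from drugsig.screen import (
    ScreenConfig,
    detect_outliers,
    discretize_activity,
    exclude_silent,
    run_resistance_screen,
    spearman_screen,
)


def _om(points, ids=None, kind="cnv"):
    """points: cells x features."""
    arr = np.asarray(points, float).T
    ids = ids or [f"c{i}" for i in range(arr.shape[1])]
    return ds.OmicsMatrix(kind, [f"g{i}" for i in range(arr.shape[0])], ids, arr)


class TestDetectOutliers:
    def test_distant_point_plus_tiebroken_identical(self):
        # 10 identical points and 1 distant one; ceil(0.1 * 11) = 2, so the
        # distant point is joined by the lexicographically first identical one
        pts = [[0.0, 0.0]] * 10 + [[50.0, 0.0]]
        ids = [f"c{i:02d}" for i in range(11)]
        out = detect_outliers(_om(pts, ids), 0.10)
        assert out == ["c10", "c00"]

    def test_all_identical_pure_tiebreak(self):
        pts = [[1.0, 1.0]] * 6
        out = detect_outliers(_om(pts), 0.34)  # ceil(0.34 * 6) = 3
        assert out == ["c0", "c1", "c2"]

    def test_exact_size_rule(self):
        pts = [[float(i), 0.0] for i in range(10)]
        for frac, expect in ((0.10, 1), (0.25, 3), (0.5, 5)):
            assert len(detect_outliers(_om(pts), frac)) == expect

    def test_2d_hand_geometry(self):
        # distances to the center (10/3, 0): only c2 is far; fraction 1/3
        # of n=3 removes exactly one point
        pts = [[0.0, 0.0], [0.0, 0.0], [10.0, 0.0]]
        out = detect_outliers(_om(pts), 1 / 3)
        assert out == ["c2"]

    def test_removing_everything_rejected(self):
        with pytest.raises(ValueError):
            detect_outliers(_om([[0.0], [1.0]]), 0.99)

    def test_planted_outliers_recovered(self):
        panel, truth = ds.simulate_panel(
            n_cells=60, n_genes=200, outlier_count=3, seed=5, n_bits=32,
            resist_drugs=1)
        out = detect_outliers(panel.cnv, 3 / 60)
        assert set(out) == set(truth.outlier_ids)


class TestExcludeSilent:
    def _table(self, effects):
        return ds.MutationTable(pd.DataFrame({
            "gene": [f"g{i}" for i in range(len(effects))],
            "cell_line": ["c1"] * len(effects),
            "effect_class": effects,
        }))

    def test_mixed(self):
        out = exclude_silent(self._table(["silent"] * 3 + ["nonsilent"] * 2))
        assert len(out) == 2

    def test_all_silent_empty(self):
        assert len(exclude_silent(self._table(["silent", "silent"]))) == 0

    def test_no_silent_identity(self):
        t = self._table(["nonsilent", "nonsilent"])
        assert exclude_silent(t).records.equals(t.records)


class TestDiscretize:
    def test_quantile_tails(self):
        resp = pd.Series(np.arange(1.0, 9.0), index=[f"c{i}" for i in range(8)])
        calls = discretize_activity(resp, "quantile", q=0.25)
        assert calls.lines_with(-1) == ["c0", "c1"]
        assert calls.lines_with(1) == ["c6", "c7"]
        assert len(calls.lines_with(0)) == 4

    def test_constant_all_moderate(self):
        resp = pd.Series([2.0] * 5, index=[f"c{i}" for i in range(5)])
        calls = discretize_activity(resp)
        assert set(calls.labels.values()) == {0}

    def test_median_split_odd_middle_is_moderate(self):
        resp = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        calls = discretize_activity(resp, "quantile", q=0.5)
        assert calls.labels["c"] == 0
        assert calls.lines_with(-1) == ["a", "b"] and calls.lines_with(1) == ["d", "e"]

    def test_zscore_method(self):
        resp = pd.Series([0.0, 0.1, -0.1, 5.0, -5.0, 0.05, 0.0, 0.02],
                         index=[f"c{i}" for i in range(8)])
        calls = discretize_activity(resp, "zscore", zscore_cut=1.0)
        assert calls.labels["c3"] == 1 and calls.labels["c4"] == -1

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            discretize_activity(pd.Series([1.0, 2.0, 3.0]))


class TestSpearmanScreen:
    def _inputs(self, expr_vals, cnv_vals, pic50):
        ids = [f"c{i}" for i in range(len(pic50))]
        expr = _om([[v] for v in expr_vals], ids, "expression")
        cnv = _om([[v] for v in cnv_vals], ids, "cnv")
        resp = pd.Series(pic50, index=ids)
        labels = {c: (1 if i >= len(ids) // 2 else -1) for i, c in enumerate(ids)}
        calls = ds.ActivityCall("drugX", labels)
        return expr, cnv, calls, resp

    def test_perfect_monotone_passes(self):
        expr, cnv, calls, resp = self._inputs(
            [1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5])
        hits = spearman_screen(expr, cnv, calls, resp, ["g0"])
        assert hits[0].passed
        assert hits[0].rho_expr == pytest.approx(1.0)
        assert hits[0].rho_cnv == pytest.approx(1.0)

    def test_discordant_cnv_sign_fails(self):
        expr, cnv, calls, resp = self._inputs(
            [1, 2, 3, 4, 5], [0.5, 0.4, 0.3, 0.2, 0.1], [1, 2, 3, 4, 5])
        hits = spearman_screen(expr, cnv, calls, resp, ["g0"])
        assert not hits[0].passed
        assert hits[0].rho_expr == pytest.approx(1.0)
        assert hits[0].rho_cnv == pytest.approx(-1.0)

    def test_hand_spearman_point_nine(self):
        expr, cnv, calls, resp = self._inputs(
            [1, 2, 3, 5, 4], [0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5])
        hits = spearman_screen(expr, cnv, calls, resp, ["g0"])
        assert hits[0].rho_expr == pytest.approx(0.9)
        assert hits[0].passed

    def test_zero_variance_gene_reported_failed(self):
        expr, cnv, calls, resp = self._inputs(
            [2, 2, 2, 2, 2], [0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5])
        hits = spearman_screen(expr, cnv, calls, resp, ["g0"])
        assert not hits[0].passed and "zero-variance" in hits[0].reason

    def test_monotone_transform_invariance(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr, cnv, calls, resp = self._inputs(np.exp(base), np.log(base + 1), base)
        hits = spearman_screen(expr, cnv, calls, resp, ["g0"])
        assert hits[0].rho_expr == pytest.approx(1.0)
        assert hits[0].rho_cnv == pytest.approx(1.0)

    def test_too_few_lines(self):
        expr, cnv, calls, resp = self._inputs([1, 2, 3], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_screen(expr, cnv, calls, resp, ["g0"])


class TestFullScreen:
    def _run(self, seed=0, **cfg):
        panel, truth = ds.simulate_panel(
            n_drugs=8, n_cells=80, n_genes=300, n_types=1, driver_count=10,
            resist_count=5, outlier_count=3, missing_fraction=0.0,
            noise_sd=0.1, seed=seed, n_bits=64, resist_drugs=1)
        # drivers genuinely correlate with the response (they generate it),
        # so the null background for exact planted recovery excludes them
        drivers = set().union(*truth.Q_support.values())
        candidates = frozenset(set(panel.expression.gene_ids) - drivers)
        sig = SignatureSet("type1", candidates)
        hits = run_resistance_screen(panel, sig, "D000", ScreenConfig(**cfg))
        return panel, truth, hits

    def test_planted_genes_recovered_no_false_positives(self):
        panel, truth, hits = self._run(seed=3)
        planted = set(truth.resistance_genes["D000"])
        passed = {h.gene for h in hits if h.passed}
        assert passed == planted

    def test_screen_invariant_to_cell_order(self):
        panel, truth, hits = self._run(seed=4)
        perm = np.random.default_rng(1).permutation(len(panel.expression.cell_line_ids))
        order = [panel.expression.cell_line_ids[i] for i in perm]
        shuffled = ds.Panel(
            expression=panel.expression.restrict_cells(order),
            cnv=panel.cnv.restrict_cells(order),
            mutations=panel.mutations,
            response=panel.response.restrict_cells(order),
            fingerprints=panel.fingerprints,
            annotation=panel.annotation,
        )
        drivers = set().union(*truth.Q_support.values())
        sig = SignatureSet("type1",
                           frozenset(set(panel.expression.gene_ids) - drivers))
        hits2 = run_resistance_screen(shuffled, sig, "D000", ScreenConfig())
        assert {h.gene for h in hits2 if h.passed} == {h.gene for h in hits if h.passed}

    def test_zero_outlier_fraction_matches_clean_panel(self):
        panel, truth = ds.simulate_panel(
            n_drugs=8, n_cells=80, n_genes=300, n_types=1, driver_count=10,
            resist_count=5, outlier_count=0, missing_fraction=0.0,
            noise_sd=0.1, seed=6, n_bits=64, resist_drugs=1)
        drivers = set().union(*truth.Q_support.values())
        sig = SignatureSet("type1",
                           frozenset(set(panel.expression.gene_ids) - drivers))
        h_off = run_resistance_screen(panel, sig, "D000",
                                      ScreenConfig(outlier_fraction=0.0))
        assert {h.gene for h in h_off if h.passed} == set(truth.resistance_genes["D000"])
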
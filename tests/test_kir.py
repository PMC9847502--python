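"""Kinome regression: expression filter, design assembly, elastic-net
correctness against a direct-optimization oracle, ranking and rank-sum
intersection semantics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import kirscreen as ks
from kirscreen import kir
from kirscreen.errors import MissingDataError, ValidationError


def oracle_enet(X, y, lam, alpha, tol=1e-14):
    """Direct minimization of the glmnet-convention penalized objective.

    Uses the positive/negative split of beta so the L1 term is smooth on the
    feasible region; solved with L-BFGS-B. Independent of the fitting path
    under test.
    """
    n, p = X.shape

    def obj(z):
        bp, bn, b0 = z[:p], z[p : 2 * p], z[2 * p]
        beta = bp - bn
        resid = y - b0 - X @ beta
        return (
            resid @ resid / (2 * n)
            + lam * (alpha * np.sum(bp + bn) + (1 - alpha) / 2 * beta @ beta)
        )

    z0 = np.zeros(2 * p + 1)
    res = minimize(
        obj,
        z0,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p) + [(None, None)],
        options={"ftol": tol, "gtol": 1e-12, "maxiter": 100_000},
    )
    return res.x[:p] - res.x[p : 2 * p], res.x[2 * p]


def make_design(X, y, kinases=None, gf="FGF2"):
    p = X.shape[1]
    kinases = kinases or tuple(f"K{j:02d}" for j in range(p))
    rows = tuple((f"I{r:03d}", 1.0) for r in range(X.shape[0]))
    return kir.DesignMatrix(rows=rows, kinase_ids=tuple(kinases), X=X, y=y, growth_factor=gf)


class TestExpressionFilter:
    def test_keeps_only_expressed(self):
        panel = ks.KinasePanel(("A", "B"), np.array([2.0, 1.0]))
        m = ks.InhibitionMatrix(("I1",), ("A", "B"), np.array([[0.1, 0.9]]))
        out = kir.filter_by_expression(m, panel, 1.5)
        assert out.kinase_ids == ("A",)

    def test_boundary_value_is_kept(self):
        panel = ks.KinasePanel(("A",), np.array([1.5]))
        m = ks.InhibitionMatrix(("I1",), ("A",), np.array([[0.5]]))
        assert kir.filter_by_expression(m, panel, 1.5).kinase_ids == ("A",)

    def test_zero_cutoff_is_identity(self, small_panel, small_inhibition):
        out = kir.filter_by_expression(small_inhibition, small_panel, 0.0)
        assert out.kinase_ids == small_inhibition.kinase_ids

    def test_unknown_kinase_rejected(self):
        panel = ks.KinasePanel(("A",), np.array([2.0]))
        m = ks.InhibitionMatrix(("I1",), ("A", "B"), np.array([[0.1, 0.9]]))
        with pytest.raises(ValidationError):
            kir.filter_by_expression(m, panel, 1.5)


class TestBuildDesign:
    def _phenotypes(self, inhibition, ladder, gf="FGF2"):
        rows = [
            {"growth_factor": gf, "inhibitor_id": i, "dose_uM": d,
             "delta_kp": -0.01, "n_replicates": 4}
            for i in inhibition.inhibitor_ids
            for d in ladder
        ]
        return pd.DataFrame(rows)

    def test_row_and_column_counts(self, small_inhibition):
        ladder = ks.simulate.DEFAULT_DOSE_LADDER_UM
        phen = self._phenotypes(small_inhibition, ladder)
        d = kir.build_design(small_inhibition, ladder, phen, "FGF2")
        assert d.X.shape == (
            len(small_inhibition.inhibitor_ids) * 6,
            len(small_inhibition.kinase_ids),
        )
        assert np.all((d.X >= 0) & (d.X <= 1))

    def test_zero_dose_row_has_zero_features(self, small_inhibition):
        ladder = (0.0, 5.0)
        phen = self._phenotypes(small_inhibition, ladder)
        d = kir.build_design(small_inhibition, ladder, phen, "FGF2")
        zero_rows = [r for r, (_, dose) in enumerate(d.rows) if dose == 0.0]
        assert np.all(d.X[zero_rows] == 0.0)

    def test_missing_profile_listed(self, small_inhibition):
        ladder = ks.simulate.DEFAULT_DOSE_LADDER_UM
        phen = self._phenotypes(small_inhibition, ladder)
        phen.loc[0, "inhibitor_id"] = "GHOST"
        with pytest.raises(MissingDataError, match="GHOST"):
            kir.build_design(small_inhibition, ladder, phen, "FGF2")

    def test_missing_growth_factor_rejected(self, small_inhibition):
        phen = self._phenotypes(small_inhibition, (5.0,))
        with pytest.raises(MissingDataError):
            kir.build_design(small_inhibition, (5.0,), phen, "EGF")


class TestElasticNetOracle:
    @pytest.mark.parametrize("lam,alpha", [(0.01, 0.15), (0.1, 0.15), (0.05, 0.5)])
    def test_matches_direct_minimization(self, lam, alpha):
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 1, (25, 6))
        beta = np.array([-0.02, 0.0, 0.01, 0.0, 0.0, -0.005])
        y = X @ beta + rng.normal(0, 0.002, 25)
        coef, b0 = kir.elastic_net_fit(X, y, lam, alpha, standardize=False, tol=1e-12)
        coef_o, b0_o = oracle_enet(X, y, lam, alpha)
        np.testing.assert_allclose(coef, coef_o, atol=1e-4)
        assert b0 == pytest.approx(b0_o, abs=1e-4)

    def test_huge_penalty_gives_null_model(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (30, 5))
        y = rng.normal(0, 1, 30)
        coef, b0 = kir.elastic_net_fit(X, y, 1e6, 0.15)
        assert np.all(coef == 0.0)
        assert b0 == pytest.approx(y.mean(), rel=1e-6)

    def test_vanishing_penalty_approaches_ols(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.1, 40)
        coef, b0 = kir.elastic_net_fit(X, y, 1e-10, 0.0, standardize=False, tol=1e-12)
        A = np.column_stack([np.ones(40), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(coef, ols[1:], atol=1e-3)


class TestFitKir:
    def test_zero_response_gives_empty_ranking(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (30, 4))
        d = make_design(X, np.zeros(30))
        with pytest.warns(UserWarning):
            r = kir.fit_kir(d, seed=0)
        assert r.entries == ()

    def test_planted_single_kinase_ranks_first(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (100, 5))
        y = -0.02 * X[:, 0]  # noiseless single-kinase signal
        r = kir.fit_kir(make_design(X, y), seed=0)
        assert r.entries[0][0] == "K00"
        assert r.entries[0][1] < 0
        assert r.entries[0][2] == 1

    def test_selection_invariant_to_column_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (60, 6))
        y = -0.02 * X[:, 1] + 0.01 * X[:, 4] + rng.normal(0, 0.001, 60)
        names = tuple(f"K{j:02d}" for j in range(6))
        r1 = kir.fit_kir(make_design(X, y, names), seed=7)
        perm = [3, 1, 5, 0, 2, 4]
        r2 = kir.fit_kir(
            make_design(X[:, perm], y, tuple(names[j] for j in perm)), seed=7
        )
        assert r1.kinase_ids == r2.kinase_ids
        for (k1, c1, _), (k2, c2, _) in zip(r1.entries, r2.entries):
            assert k1 == k2
            assert c1 == pytest.approx(c2, rel=1e-4, abs=1e-10)

    def test_cv_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (50, 5))
        y = -0.02 * X[:, 2] + rng.normal(0, 0.002, 50)
        r1 = kir.fit_kir(make_design(X, y), seed=13)
        r2 = kir.fit_kir(make_design(X, y), seed=13)
        assert r1.diagnostics["lambda"] == r2.diagnostics["lambda"]
        assert r1.entries == r2.entries

    def test_too_few_rows_rejected(self):
        X = np.ones((5, 2)) * 0.5
        with pytest.raises(ValidationError):
            kir.fit_kir(make_design(X, np.zeros(5)), seed=0)


class TestIntersection:
    def _ranking(self, gf, kinases):
        entries = tuple(
            (k, -0.01 * (len(kinases) - i), i + 1) for i, k in enumerate(kinases)
        )
        return kir.KinaseRanking(gf, entries)

    def test_rank_sum_worked_example(self):
        rankings = [
            self._ranking("F", ["A", "B", "C"]),
            self._ranking("V", ["B", "C", "D"]),
            self._ranking("H", ["C", "B"]),
        ]
        out = kir.intersect_rank_sum(rankings)
        assert out.kinase_ids == ("B", "C")
        assert out.kinases[0] == ("B", 5, (2, 1, 2))
        assert out.kinases[1] == ("C", 6, (3, 2, 1))

    def test_identical_rankings_preserved(self):
        r = self._ranking("F", ["X", "Y", "Z"])
        out = kir.intersect_rank_sum([r, self._ranking("V", ["X", "Y", "Z"])])
        assert out.kinase_ids == ("X", "Y", "Z")

    def test_disjoint_rankings_empty(self):
        out = kir.intersect_rank_sum(
            [self._ranking("F", ["A"]), self._ranking("V", ["B"])]
        )
        assert out.kinase_ids == ()

    def test_single_ranking_rejected(self):
        with pytest.raises(ValidationError):
            kir.intersect_rank_sum([self._ranking("F", ["A"])])
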
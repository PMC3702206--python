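"""Cohort statistics: crosstabs, exact tests, frequency maps, KM, Cox.

Independent oracles: scipy.stats.fisher_exact for the 2x2 test, full
hand enumeration for the 3x3 toy, lifelines for KM and for Cox on tie-free
data (where Breslow and Efron coincide), and a brute-force grid maximizer
of the Breslow partial likelihood for the Cox toys.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from socsmut.cohort_stats import (
    ContingencyTable,
    CoxFitError,
    build_crosstab,
    cox_fit,
    domain_frequency_map,
    fisher_exact_2x2,
    fisher_exact_rxc,
    km_fit,
)
from socsmut.consequence import apply_case_mutations
from socsmut.mutation_io import MutationRecord


class TestBuildCrosstab:
    def test_mutant_coo_tally(self):
        from importlib.resources import files
        df = pd.read_csv(
            str(files("socsmut") / "data" / "mutant_cases_signatures.tsv"),
            sep="\t", na_values=["."],
        )
        df["status"] = "mutant"
        tab = build_crosstab(df, "status", "coo",
                             col_order=["GCB", "ABC", "unclassified"])
        assert tab.counts.tolist() == [[19, 2, 3]]

    def test_empty_cohort(self):
        df = pd.DataFrame({"a": [], "b": []})
        tab = build_crosstab(df, "a", "b")
        assert tab.total == 0

    def test_pairwise_missing_exclusion(self):
        df = pd.DataFrame({
            "g": ["x", "x", "y", "y", "y", None],
            "h": ["p", "q", "p", None, "q", "p"],
        })
        tab = build_crosstab(df, "g", "h")
        assert tab.total == 4  # one missing in each variable dropped

    def test_unknown_variable(self):
        with pytest.raises(KeyError):
            build_crosstab(pd.DataFrame({"a": [1]}), "a", "nope")


class TestFisher2x2:
    def test_pap1_association(self):
        assert round(fisher_exact_2x2([[12, 12], [25, 105]]), 3) == 0.003

    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_diagonal_toy_enumeration(self):
        # margins (3,3)/(3,3): C(6,3)=20 tables; the two extreme tables
        # each have probability 1/20 -> two-sided p = 2/20
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_margin(self):
        assert fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0

    def test_scipy_oracle_500_random_tables(self):
        rng = np.random.default_rng(101)
        for _ in range(500):
            t = rng.integers(0, 30, size=(2, 2))
            ours = fisher_exact_2x2(t)
            theirs = sps.fisher_exact(t)[1]
            assert ours == pytest.approx(theirs, abs=1e-9), t

    def test_wrong_shape(self):
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestFisherRxC:
    def test_2x2_equivalence(self):
        rng = np.random.default_rng(55)
        for _ in range(500):
            t = rng.integers(0, 25, size=(2, 2))
            res = fisher_exact_rxc(t)
            if res.method == "degenerate":
                assert fisher_exact_2x2(t) == 1.0
                continue
            assert res.p == pytest.approx(fisher_exact_2x2(t), abs=1e-12), t

    def test_probability_conservation(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            r, c = rng.integers(2, 4, size=2)
            t = rng.integers(0, 12, size=(r, c))
            res = fisher_exact_rxc(t)
            if res.method == "enumeration":
                assert abs(res.total_prob - 1.0) <= 1e-9, t

    def test_coo_3x2_against_r_oracle(self):
        # independently verified with R stats::fisher.test on this table
        res = fisher_exact_rxc([[51, 47, 32], [19, 2, 3]])
        assert res.method == "enumeration"
        assert res.p == pytest.approx(0.001258065, rel=1e-5)

    def test_zero_row_dropped(self):
        with pytest.warns(UserWarning, match="dropping"):
            res = fisher_exact_rxc([[5, 3], [0, 0], [2, 7]])
        full = fisher_exact_rxc([[5, 3], [2, 7]])
        assert res.p == pytest.approx(full.p, abs=1e-12)

    def test_degenerate_table(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_rxc([[4, 0], [2, 0]]).p == 1.0

    def test_monte_carlo_path_agrees_with_enumeration(self):
        t = [[9, 8, 7], [6, 9, 8], [7, 6, 9]]
        res = fisher_exact_rxc(t, max_tables=1000, B=4000, seed=3)
        assert res.method == "monte_carlo"
        exact = fisher_exact_rxc(t)  # same table, full enumeration
        assert exact.method == "enumeration"
        assert res.p == pytest.approx(exact.p, abs=0.05)

    def test_monte_carlo_seeded(self):
        t = [[9, 8, 7], [6, 9, 8], [7, 6, 9]]
        a = fisher_exact_rxc(t, max_tables=10, B=500, seed=11)
        b = fisher_exact_rxc(t, max_tables=10, B=500, seed=11)
        assert a.p == b.p and a.method == "monte_carlo"


class TestFrequencyMap:
    def test_stop_upstream_of_socs_box(self, socs1):
        from test_consequence import _first_stop_gain
        rec = _first_stop_gain(socs1, hi=socs1.domain("NLS").nt_start - 3)
        cc = apply_case_mutations([rec], socs1)
        fm = domain_frequency_map([cc], socs1)
        row = fm.table.loc["SOCS box"]
        assert row["fraction_conservative"] == 1.0
        assert row["fraction_aggressive"] == 1.0

    def test_substitution_only_downstream_equals_direct(self, socs1):
        from socsmut.consequence import classify_mutation
        recs = []
        for pos in (30, 250):
            for alt in "ACGT":
                if alt == socs1.ref_base(pos):
                    continue
                cand = MutationRecord("A", "substitution", pos, pos,
                                      socs1.ref_base(pos), alt)
                if classify_mutation(cand, socs1).effect != "nonsense":
                    recs.append(cand)
                    break
        cc = apply_case_mutations(recs, socs1)
        fm = domain_frequency_map([cc], socs1)
        assert (fm.table["fraction_conservative"]
                == fm.table["fraction_direct"]).all()
        assert (fm.table["fraction_aggressive"]
                == fm.table["fraction_direct"]).all()

    def test_four_case_hand_enumeration(self, socs1):
        from test_consequence import _first_stop_gain, _random_case
        rng = np.random.default_rng(21)
        cases = [
            apply_case_mutations(_random_case(rng, socs1), socs1)
            for _ in range(4)
        ]
        fm = domain_frequency_map(cases, socs1)
        for name in fm.table.index:
            assert fm.table.loc[name, "fraction_direct"] == pytest.approx(
                sum(name in c.affected_direct for c in cases) / 4
            )
        assert (fm.table["fraction_conservative"]
                <= fm.table["fraction_aggressive"] + 1e-15).all()

    def test_zero_cases_error(self, socs1):
        with pytest.raises(ValueError):
            domain_frequency_map([], socs1)


class TestKaplanMeier:
    def test_all_censored_flat(self):
        curve = km_fit([3, 5, 8], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(100) == 1.0

    def test_hand_product_limit(self):
        curve = km_fit([1, 2, 3], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_single_subject_jump(self):
        curve = km_fit([7], [1])
        assert curve.survival_at(6.9) == 1.0 and curve.survival_at(7) == 0.0

    def test_no_censoring_equals_empirical(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=50)
        curve = km_fit(t, np.ones(50, dtype=int))
        for u in np.quantile(t, [0.1, 0.5, 0.9]):
            assert curve.survival_at(u) == pytest.approx((t > u).mean())

    def test_lifelines_cross_check(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(8)
        t = rng.exponential(12, size=80)
        e = rng.integers(0, 2, size=80)
        if e.sum() == 0:
            e[0] = 1
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        curve = km_fit(t, e)
        for u in np.quantile(t, [0.25, 0.5, 0.75]):
            assert curve.survival_at(u) == pytest.approx(
                float(kmf.predict(u)), abs=1e-9
            )

    def test_grouped(self):
        curves = km_fit([1, 2, 3, 4], [1, 1, 1, 1], groups=["a", "a", "b", "b"])
        assert set(curves) == {"a", "b"}

    def test_empty_error(self):
        with pytest.raises(ValueError):
            km_fit([], [])


def breslow_loglik_oracle(beta, x, t, e):
    """Definitionally-coded Breslow partial log-likelihood (1 covariate)."""
    ll = 0.0
    for i in range(len(t)):
        if e[i] != 1:
            continue
        risk = [j for j in range(len(t)) if t[j] >= t[i]]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


def grid_maximizer(x, t, e, lo=-6, hi=6):
    grid = np.arange(lo, hi, 1e-4)
    lls = [breslow_loglik_oracle(b, x, t, e) for b in grid]
    return grid[int(np.argmax(lls))]


class TestCoxFit:
    def test_constant_covariate_error(self):
        with pytest.raises(CoxFitError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1, 1, 1, 1]}),
                    [1, 2, 3, 4], [1, 1, 0, 1])

    def test_four_subject_toy_vs_grid(self):
        x, t, e = [0, 1, 0, 1], [1, 2, 3, 4], [1, 1, 1, 0]
        fit = cox_fit(pd.DataFrame({"x": x}), t, e)
        assert fit.converged
        assert fit.params["x"] == pytest.approx(grid_maximizer(x, t, e), abs=1e-4)

    def test_eight_subject_toy_vs_grid(self):
        x = [0, 1, 0, 1, 1, 0, 1, 0]
        t = [2, 1, 5, 3, 4, 8, 6, 7]
        e = [1, 1, 1, 1, 0, 1, 1, 0]
        fit = cox_fit(pd.DataFrame({"x": x}), t, e)
        assert fit.params["x"] == pytest.approx(grid_maximizer(x, t, e), abs=1e-4)

    def test_score_vanishes_at_optimum(self):
        from socsmut.cohort_stats import _cox_loglik_derivs
        rng = np.random.default_rng(5)
        n = 120
        X = rng.integers(0, 2, size=(n, 2)).astype(float)
        lam = 0.05 * np.exp(X @ np.array([0.7, -0.4]))
        T = rng.exponential(1 / lam)
        C = rng.uniform(0, 40, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        fit = cox_fit(pd.DataFrame(X, columns=["a", "b"]), t, e)
        _, score, _ = _cox_loglik_derivs(fit.params.to_numpy(), X, t, e, "breslow")
        assert np.max(np.abs(score)) < 1e-6

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(6)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        fit1 = cox_fit(pd.DataFrame({"x": x}), t, e)
        perm = rng.permutation(n)
        fit2 = cox_fit(pd.DataFrame({"x": x[perm]}), t[perm], e[perm])
        assert fit1.params["x"] == pytest.approx(fit2.params["x"], abs=1e-10)

    def test_lifelines_cross_check_tie_free(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(12)
        n = 150
        X = rng.integers(0, 2, size=(n, 2)).astype(float)
        lam = 0.04 * np.exp(X @ np.array([0.9, -0.6]))
        T = rng.exponential(1 / lam)
        C = rng.uniform(0, 60, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        assert len(np.unique(t)) == n  # tie-free: Breslow == Efron
        df = pd.DataFrame(X, columns=["a", "b"])
        fit = cox_fit(df, t, e)
        cph = lifelines.CoxPHFitter().fit(
            df.assign(t=t, e=e), duration_col="t", event_col="e"
        )
        for col in ("a", "b"):
            assert fit.params[col] == pytest.approx(
                cph.params_[col], abs=1e-5
            )
            assert fit.se[col] == pytest.approx(
                cph.standard_errors_[col], abs=1e-5
            )

    def test_complete_case_drop_logged(self):
        x = pd.DataFrame({"x": [0.0, 1.0, np.nan, 1.0, 0.0]})
        fit = cox_fit(x, [1, 2, 3, 4, 5], [1, 1, 1, 0, 1])
        assert fit.n_used == 4
        assert any("dropped 1" in w for w in fit.warnings)

    def test_separation_flagged(self):
        # all events in one arm, monotone likelihood
        x = [0, 0, 0, 1, 1, 1]
        t = [10, 11, 12, 1, 2, 3]
        e = [0, 0, 0, 1, 1, 1]
        fit = cox_fit(pd.DataFrame({"x": x}), t, e)
        assert not fit.converged
        assert fit.warnings

    def test_no_events_error(self):
        with pytest.raises(CoxFitError, match="no events"):
            cox_fit(pd.DataFrame({"x": [0, 1]}), [1, 2], [0, 0])

    def test_efron_close_to_breslow_with_ties(self):
        rng = np.random.default_rng(31)
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        t = rng.integers(1, 15, n).astype(float)  # heavy ties
        e = rng.integers(0, 2, n)
        e[:5] = 1
        fb = cox_fit(pd.DataFrame({"x": x}), t, e, ties="breslow")
        fe = cox_fit(pd.DataFrame({"x": x}), t, e, ties="efron")
        assert fb.params["x"] == pytest.approx(fe.params["x"], abs=0.2)
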
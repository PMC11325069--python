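import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netsi import (
    SIMap,
    adapted_fdr,
    brain_distance_matrix,
    covariate_distance_matrix,
    fit_distance_regression,
    results_to_table,
    ruzicka_similarity,
)
from netsi.reference import CS_TERM_TESTS


class TestRuzicka:
    def test_identity(self, rng):
        x = rng.random(10)
        assert ruzicka_similarity(x, x) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        x = np.array([1.0, 0.0, 2.0, 0.0])
        y = np.array([0.0, 3.0, 0.0, 1.0])
        assert ruzicka_similarity(x, y) == 0.0

    def test_direct_summation(self):
        assert ruzicka_similarity(np.array([0.5, 1.0]),
                                  np.array([1.0, 0.5])) == pytest.approx(0.5)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            ruzicka_similarity(np.zeros(3), np.zeros(3))

    def test_negative_error(self):
        with pytest.raises(ValueError):
            ruzicka_similarity(np.array([-1.0, 2.0]), np.array([1.0, 1.0]))

    @given(st.lists(st.floats(0, 10), min_size=1, max_size=20),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_symmetric(self, xs, data):
        ys = data.draw(st.lists(st.floats(0, 10), min_size=len(xs),
                                max_size=len(xs)))
        x, y = np.array(xs), np.array(ys)
        if np.maximum(x, y).sum() == 0:
            return
        s = ruzicka_similarity(x, y)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(ruzicka_similarity(y, x))


class TestBrainDistanceMatrix:
    def _maps(self, rng, m=5, n=12):
        return [SIMap(f"s{i}", "VN", rng.random(n)) for i in range(m)]

    def test_identical_maps_zero(self, rng):
        v = rng.random(8)
        maps = [SIMap("a", "VN", v), SIMap("b", "VN", v.copy())]
        D = brain_distance_matrix(maps)
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_symmetric_zero_diag(self, rng):
        D = brain_distance_matrix(self._maps(rng))
        np.testing.assert_allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)

    def test_two_loop_oracle(self, rng):
        maps = self._maps(rng)
        D = brain_distance_matrix(maps)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                x, y = maps[i].values, maps[j].values
                ref = 1 - np.minimum(x, y).sum() / np.maximum(x, y).sum()
                assert D.values[i, j] == pytest.approx(ref, abs=1e-12)

    def test_semimetric(self, rng):
        maps = self._maps(rng, m=6)
        D = brain_distance_matrix(maps).values
        assert np.all(D >= 0)
        # zero iff identical
        maps.append(SIMap("dup", "VN", maps[0].values.copy()))
        D2 = brain_distance_matrix(maps).values
        assert D2[0, 6] == 0
        iu = np.triu_indices(6, 1)
        assert np.all(D[iu] > 0)

    def test_values_in_unit_interval(self, rng):
        D = brain_distance_matrix(self._maps(rng)).values
        assert np.all((D >= 0) & (D <= 1))


class TestCovariateDistance:
    def test_numeric(self):
        D = covariate_distance_matrix([1.8, 1.6], "abs_numeric")
        assert D.values[0, 1] == pytest.approx(0.2)

    def test_binary_mismatch(self):
        D = covariate_distance_matrix([0, 0, 1], "binary_mismatch")
        assert D.values[0, 1] == 0
        assert D.values[0, 2] == 1

    def test_constant_zero_matrix(self):
        D = covariate_distance_matrix([3.0] * 5, "abs_numeric")
        assert np.all(D.values == 0)

    def test_bad_binary(self):
        with pytest.raises(ValueError):
            covariate_distance_matrix([0, 2, 1], "binary_mismatch")

    def test_missing_values(self):
        with pytest.raises(ValueError):
            covariate_distance_matrix([1.0, np.nan], "abs_numeric")


def _random_problem(rng, m=12, n_nodes=30):
    maps = [SIMap(f"s{i}", "VN", rng.random(n_nodes)) for i in range(m)]
    ids = tuple(f"s{i}" for i in range(m))
    y = brain_distance_matrix(maps)
    cs = rng.normal(1.7, 0.15, m)
    sex = rng.integers(0, 2, m).astype(float)
    xs = [covariate_distance_matrix(cs, "abs_numeric", ids),
          covariate_distance_matrix(sex, "binary_mismatch", ids)]
    return y, xs, cs, sex


class TestFitDistanceRegression:
    def test_statsmodels_dummy_oracle(self, rng):
        import statsmodels.api as sm

        m = 12
        y, xs, cs, sex = _random_problem(rng, m=m)
        res = fit_distance_regression(y, xs, ["cs", "sex"])
        # independent route: explicit dummy design through statsmodels
        iu, ju = np.triu_indices(m, 1)
        X = np.column_stack([
            np.ones(iu.size),
            xs[0].values[iu, ju],
            xs[1].values[iu, ju],
        ] + [((iu == s) | (ju == s)).astype(float) for s in range(m - 1)])
        fit = sm.OLS(y.values[iu, ju], X).fit()
        for k, name in enumerate(["cs", "sex"], start=1):
            term = res.term(name)
            assert term.estimate == pytest.approx(fit.params[k], abs=1e-8)
            assert term.se == pytest.approx(fit.bse[k], abs=1e-8)
            assert term.t_score == pytest.approx(fit.tvalues[k], abs=1e-6)

    def test_dropped_dummy_invariance(self, rng):
        # covariate estimates do not depend on which subject dummy is dropped
        m = 12
        y, xs, cs, sex = _random_problem(rng, m=m)
        res = fit_distance_regression(y, xs, ["cs", "sex"])
        perm = np.roll(np.arange(m), 1)  # different subject becomes "last"
        ids_p = tuple(y.subject_ids[i] for i in perm)
        y_p = type(y)(ids_p, y.values[np.ix_(perm, perm)], y.kind)
        xs_p = [type(x)(ids_p, x.values[np.ix_(perm, perm)], x.kind) for x in xs]
        res_p = fit_distance_regression(y_p, xs_p, ["cs", "sex"])
        for name in ("cs", "sex"):
            assert res.term(name).estimate == pytest.approx(
                res_p.term(name).estimate, abs=1e-9)
            assert res.term(name).se == pytest.approx(res_p.term(name).se,
                                                      abs=1e-9)

    def test_normal_reference_p(self, rng):
        from scipy.stats import norm

        y, xs, *_ = _random_problem(rng)
        res = fit_distance_regression(y, xs, ["cs", "sex"])
        for t in res.terms:
            assert t.p_value == pytest.approx(2 * norm.sf(abs(t.t_score)))

    def test_permutation_matches_full_refit(self, rng):
        # the fast residualized permutation path must equal a brute-force refit
        m = 12
        y, xs, cs, sex = _random_problem(rng, m=m)
        res = fit_distance_regression(y, xs, ["cs", "sex"], permute_term="cs",
                                      n_permutations=25, seed=99)
        # recompute by hand with the same permutation stream
        perm_rng = np.random.default_rng(99)
        t_obs = res.term("cs").t_score
        exceed = 0
        for _ in range(25):
            perm = perm_rng.permutation(m)
            xs_b = [type(xs[0])(y.subject_ids,
                                xs[0].values[np.ix_(perm, perm)], xs[0].kind),
                    xs[1]]
            r_b = fit_distance_regression(y, xs_b, ["cs", "sex"])
            if abs(r_b.term("cs").t_score) >= abs(t_obs) - 1e-12:
                exceed += 1
        assert res.term("cs").p_permutation == pytest.approx(
            (1 + exceed) / 26)

    def test_too_few_subjects(self, rng):
        y, xs, *_ = _random_problem(rng, m=12)
        ids = y.subject_ids[:8]
        y8 = type(y)(ids, y.values[:8, :8], y.kind)
        xs8 = [type(x)(ids, x.values[:8, :8], x.kind) for x in xs]
        with pytest.raises(ValueError):
            fit_distance_regression(y8, xs8, ["cs", "sex"])

    def test_mismatched_subjects(self, rng):
        y, xs, *_ = _random_problem(rng)
        bad = type(xs[0])(tuple(reversed(xs[0].subject_ids)), xs[0].values,
                          xs[0].kind)
        with pytest.raises(ValueError):
            fit_distance_regression(y, [bad], ["cs"])


class TestAdaptedFdr:
    def test_worked_example(self):
        # step-up adjustment of the 16 reference p-values reproduces the
        # published adjusted value for the 0.1306 entry exactly
        raw = [t.p_value for t in CS_TERM_TESTS]
        adj = adapted_fdr(raw)
        i = raw.index(0.1306)
        assert adj[i] == pytest.approx(0.5224, abs=1e-12)

    def test_all_ones(self):
        np.testing.assert_array_equal(adapted_fdr([1.0] * 5), np.ones(5))

    def test_monotone_and_dominating(self, rng):
        p = np.sort(rng.random(20))
        q = adapted_fdr(p)
        assert np.all(q >= p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        np.testing.assert_allclose(adapted_fdr(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_two_stage_variant(self, rng):
        p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(0.2, 1, 15)])
        q_bh = adapted_fdr(p, method="bh")
        q_ts = adapted_fdr(p, method="two-stage")
        assert np.all(q_ts <= q_bh + 1e-12)  # adaptive variant is less strict

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            adapted_fdr([0.5, 1.2])


class TestResultsTable:
    def test_fdr_only_on_selected_term(self, rng):
        problems = [_random_problem(rng) for _ in range(3)]
        results = [
            fit_distance_regression(y, xs, ["cs", "sex"], network=f"N{i}",
                                    condition="rest")
            for i, (y, xs, *_rest) in enumerate(problems)
        ]
        tab = results_to_table(results, fdr_term="cs")
        assert tab.loc[tab.term == "cs", "p_fdr"].notna().all()
        assert tab.loc[tab.term == "sex", "p_fdr"].isna().all()
        raw = [r.term("cs").p_value for r in results]
        np.testing.assert_allclose(
            tab.loc[tab.term == "cs", "p_fdr"].to_numpy(),
            adapted_fdr(raw))
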
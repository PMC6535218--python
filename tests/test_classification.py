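"""Stepwise Wilks'-lambda DFA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from molarmark import (
    CollinearityError,
    UsageError,
    classification_report,
    fit_lda,
    loo_crossvalidate,
    predict,
    stepwise_dfa,
    stepwise_select,
    wilks_lambda,
)
from molarmark.classification import _sscp


def _three_group_data(rng, n_per=15, p=4, sep=2.0):
    means = rng.normal(scale=sep, size=(3, p))
    X = np.vstack([m + rng.normal(size=(n_per, p)) for m in means])
    labels = np.repeat(["a", "b", "c"], n_per)
    return X, labels


class TestWilksLambda:
    def test_equal_group_means_give_lambda_one(self, rng):
        g1 = rng.normal(size=(10, 3))
        g2 = 2 * g1.mean(axis=0) - g1  # reflected: same mean, same scatter
        X = np.vstack([g1, g2])
        labels = np.repeat(["a", "b"], 10)
        assert wilks_lambda(X, labels) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_separation_gives_zero(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        assert wilks_lambda(X, labels) == 0.0

    def test_matches_eigenvalue_product_oracle(self, rng):
        """Lambda = prod 1/(1 + l_i) over eigenvalues of W^-1 B."""
        X, labels = _three_group_data(rng)
        lam = wilks_lambda(X, labels)
        W, T = _sscp(X, labels, ("a", "b", "c"))
        eig = np.linalg.eigvals(np.linalg.solve(W, T - W))
        oracle = float(np.prod(1.0 / (1.0 + np.real(eig[np.real(eig) > 1e-12]))))
        assert lam == pytest.approx(oracle, abs=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        X, labels = _three_group_data(rng)
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])])
        df["g"] = labels
        mv = MANOVA.from_formula("v0 + v1 + v2 + v3 ~ g", data=df)
        table = mv.mv_test().results["g"]["stat"]
        assert wilks_lambda(X, labels) == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), abs=1e-10
        )

    def test_collinear_variables_rejected(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, 2 * x])
        labels = np.repeat(["a", "b"], 10)
        with pytest.raises(CollinearityError):
            wilks_lambda(X, labels)


class TestStepwiseSelect:
    def test_single_informative_variable_selected(self, rng):
        n = 30
        labels = np.repeat(["a", "b", "c"], n // 3)
        signal = np.repeat([0.0, 10.0, 20.0], n // 3) + rng.normal(scale=0.5, size=n)
        noise = rng.normal(scale=1.0, size=(n, 8))
        X = pd.DataFrame(np.column_stack([signal, noise]),
                         columns=["signal"] + [f"n{i}" for i in range(8)])
        trace = stepwise_select(X, labels)
        assert trace.selected[0] == "signal"

    def test_infinite_entry_threshold_gives_empty_trace(self, rng):
        X, labels = _three_group_data(rng)
        with pytest.warns(UserWarning, match="no variable passed"):
            trace = stepwise_select(X, labels, f_enter=np.inf, f_remove=1.0)
        assert trace.selected == ()

    def test_enter_threshold_must_exceed_remove(self, rng):
        X, labels = _three_group_data(rng)
        with pytest.raises(UsageError):
            stepwise_select(X, labels, f_enter=1.0, f_remove=2.0)

    def test_lambda_nonincreasing_at_each_entry(self, rng):
        X, labels = _three_group_data(rng, p=6, sep=1.0)
        trace = stepwise_select(X, labels)
        lams = [s.wilks_lambda for s in trace.steps if s.action == "enter"]
        assert all(b <= a + 1e-12 for a, b in zip(lams, lams[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_partial_f_oracle(self, seed):
        """Replay every enter/remove decision with directly computed dets."""
        rng = np.random.default_rng(seed)
        X, labels = _three_group_data(rng, n_per=12, p=4, sep=0.8)
        trace = stepwise_select(X, labels)
        oracle = _bruteforce_stepwise(X, labels, 3.84, 2.71)
        assert [(s.action, s.variable) for s in trace.steps] == oracle


def _bruteforce_stepwise(X, labels, f_enter, f_remove):
    """Independent reimplementation using raw determinants and exhaustive
    candidate scans; returns the (action, variable) sequence."""
    n, nv = X.shape
    groups = sorted(set(labels))
    g = len(groups)

    def lam(cols):
        if not cols:
            return 1.0
        sub = X[:, cols]
        grand = sub.mean(axis=0)
        T = (sub - grand).T @ (sub - grand)
        W = np.zeros_like(T)
        for grp in groups:
            s = sub[np.asarray(labels) == grp]
            W += (s - s.mean(axis=0)).T @ (s - s.mean(axis=0))
        detT = np.linalg.det(T)
        return np.linalg.det(W) / detT if detT > 0 else np.nan

    steps, inc = [], []
    while True:
        changed = False
        p = len(inc)
        l0 = lam(inc)
        cands = [
            (j, lam(inc + [j])) for j in range(nv) if j not in inc
        ]
        fs = [
            (j, (n - g - p) / (g - 1) * (l0 / lj - 1.0))
            for j, lj in cands if np.isfinite(lj) and lj > 0
        ]
        if fs and l0 > 0:
            j, f = max(fs, key=lambda t: (t[1], -t[0]))
            if f >= f_enter:
                inc.append(j)
                steps.append(("enter", f"v{j}"))
                changed = True
        while len(inc) > 1:
            p = len(inc)
            l0 = lam(inc)
            if l0 <= 0:
                break
            fs = [
                (j, (n - g - p + 1) / (g - 1) * (lam([k for k in inc if k != j]) / l0 - 1.0))
                for j in inc
            ]
            j, f = min(fs, key=lambda t: (t[1], t[0]))
            if f < f_remove:
                inc.remove(j)
                steps.append(("remove", f"v{j}"))
                changed = True
            else:
                break
        if not changed:
            return steps


class TestFitLDA:
    def test_function_count(self, rng):
        X = rng.normal(size=(60, 9))
        labels = np.repeat(list("abcde"), 12)
        model = fit_lda(X, labels)
        assert model.n_functions == 4
        assert model.percent_variance_per_function.sum() == pytest.approx(100.0, abs=1e-6)

    def test_two_spherical_groups_boundary_is_perpendicular_bisector(self, rng):
        mu_a, mu_b = np.array([0.0, 0.0]), np.array([4.0, 2.0])
        X = np.vstack([
            mu_a + rng.normal(size=(200, 2)),
            mu_b + rng.normal(size=(200, 2)),
        ])
        labels = np.repeat(["a", "b"], 200)
        model = fit_lda(X, labels)
        grid = np.array([
            [x, y] for x in np.linspace(-2, 6, 15) for y in np.linspace(-2, 4, 15)
        ])
        pred = predict(model, grid)
        # empirical boundary vs bisector of the *sample* means
        sa = X[:200].mean(axis=0)
        sb = X[200:].mean(axis=0)
        mid, d = (sa + sb) / 2.0, sb - sa
        side = np.sign((grid - mid) @ d)
        expect = np.where(side > 0, "b", "a")
        mism = (pred != expect)
        # only points essentially on the boundary may disagree (covariance is
        # estimated, not exactly spherical)
        dist_to_boundary = np.abs((grid - mid) @ d) / np.linalg.norm(d)
        assert np.all(dist_to_boundary[mism] < 0.35)

    def test_eigenvalues_match_generalized_eigenproblem(self, rng):
        X, labels = _three_group_data(rng)
        model = fit_lda(X, labels)
        W, T = _sscp(X, labels, ("a", "b", "c"))
        eig = np.sort(np.real(np.linalg.eigvals(np.linalg.solve(W, T - W))))[::-1]
        assert np.allclose(model.eigenvalues, eig[:2], atol=1e-9)

    def test_predictions_match_sklearn_equal_priors(self, rng):
        X, labels = _three_group_data(rng, sep=1.0)
        model = fit_lda(X, labels, priors="equal")
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, labels)
        assert np.array_equal(predict(model, X), sk.predict(X))

    def test_scale_invariance_of_decisions(self, rng):
        X, labels = _three_group_data(rng, sep=1.0)
        scale = np.array([1.0, 1000.0, 0.01, 5.0])
        m1 = fit_lda(X, labels)
        m2 = fit_lda(X * scale, labels)
        assert m1.wilks_lambda == pytest.approx(m2.wilks_lambda, rel=1e-9)
        assert np.allclose(m1.eigenvalues, m2.eigenvalues, rtol=1e-9)
        assert np.array_equal(predict(m1, X), predict(m2, X * scale))

    def test_permutation_invariance(self, rng):
        X, labels = _three_group_data(rng, sep=1.0)
        perm = rng.permutation(len(X))
        m1 = fit_lda(X, labels)
        m2 = fit_lda(X[perm], labels[perm])
        assert np.allclose(m1.canonical_coefficients, m2.canonical_coefficients, atol=1e-9)
        assert np.array_equal(predict(m1, X), predict(m2, X))


class TestClassificationAndLOO:
    def test_perfectly_separated_groups_classify_100(self, rng):
        X = np.vstack([rng.normal(size=(10, 2)), 100 + rng.normal(size=(10, 2))])
        labels = np.repeat(["a", "b"], 10)
        model = fit_lda(X, labels)
        rep = classification_report(model, X, labels)
        assert rep.accuracy_percent == 100.0
        cv = loo_crossvalidate(X, labels)
        assert cv.accuracy_percent == 100.0

    def test_confusion_row_sums_are_group_sizes(self, rng):
        X, labels = _three_group_data(rng, sep=0.5)
        model = fit_lda(X, labels)
        rep = classification_report(model, X, labels)
        assert rep.counts.sum(axis=1).tolist() == [15, 15, 15]
        total = rep.counts.to_numpy().sum()
        assert rep.accuracy_percent == pytest.approx(
            100.0 * np.trace(rep.counts.to_numpy()) / total
        )

    def test_unknown_label_rejected(self, rng):
        X, labels = _three_group_data(rng)
        model = fit_lda(X, labels)
        bad = labels.copy()
        bad[0] = "zz"
        with pytest.raises(UsageError):
            classification_report(model, X, bad)

    def test_loo_matches_explicit_sklearn_refit_per_fold(self, rng):
        """Fold-for-fold oracle: an independent LDA refit on each n-1 subset
        must predict the held-out specimen identically (equal priors)."""
        X, labels = _three_group_data(rng, n_per=12, sep=1.0)
        cv = loo_crossvalidate(X, labels)
        oracle = []
        for i in range(len(X)):
            keep = np.arange(len(X)) != i
            sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X[keep], labels[keep])
            oracle.append(sk.predict(X[i:i + 1])[0])
        oracle_counts = pd.crosstab(
            pd.Series(labels, name="true"), pd.Series(oracle, name="pred")
        ).reindex(index=cv.counts.index, columns=cv.counts.columns, fill_value=0)
        assert cv.counts.equals(oracle_counts)

    def test_loo_not_better_than_resubstitution_on_average(self, rng):
        diffs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            X, labels = _three_group_data(r, n_per=8, p=3, sep=0.7)
            model = fit_lda(X, labels)
            orig = classification_report(model, X, labels).accuracy_percent
            cv = loo_crossvalidate(X, labels).accuracy_percent
            diffs.append(orig - cv)
        assert np.mean(diffs) >= 0.0

    def test_group_smaller_than_two_rejected(self, rng):
        X = rng.normal(size=(11, 2))
        labels = np.array(["a"] * 10 + ["b"])
        with pytest.raises(UsageError):
            loo_crossvalidate(X, labels)


class TestStepwiseDFAPipeline:
    def test_well_separated_groups_reach_100_both_ways(self, rng):
        X, labels = _three_group_data(rng, n_per=12, sep=8.0)
        X = pd.DataFrame(X, columns=list("wxyz"))
        trace, model, orig, cv = stepwise_dfa(X, labels)
        assert orig.accuracy_percent == 100.0
        assert cv.accuracy_percent == 100.0
        assert orig.mode == "original" and cv.mode == "cross_validated"

    def test_proportional_priors_shift_decisions_toward_large_group(self, rng):
        # heavily unbalanced overlapping groups: proportional priors must not
        # classify fewer specimens into the majority group than equal priors
        X = np.vstack([rng.normal(size=(40, 1)), 1.0 + rng.normal(size=(8, 1))])
        labels = np.array(["big"] * 40 + ["small"] * 8)
        m_eq = fit_lda(X, labels, priors="equal")
        m_prop = fit_lda(X, labels, priors="proportional")
        n_big_eq = (predict(m_eq, X) == "big").sum()
        n_big_prop = (predict(m_prop, X) == "big").sum()
        assert n_big_prop >= n_big_eq
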
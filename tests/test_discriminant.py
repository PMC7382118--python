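"""From-scratch LDA/QDA: closed forms, oracles, invariances, CV."""

import json

import numpy as np
import pytest

import carrotshape as cs
from carrotshape.discriminant import confusion_matrix
from carrotshape.errors import (
    NoDataError,
    SchemaError,
    SingularCovarianceError,
    StratificationError,
)


def brute_force_predict(x_rows, classes, priors, means, covs):
    """Independent oracle: explicit prior x Gaussian density comparison
    (in logs, so remote points do not underflow)."""
    from scipy.stats import multivariate_normal

    out = []
    for x in np.atleast_2d(x_rows):
        dens = [
            np.log(p) + multivariate_normal.logpdf(x, mean=m, cov=C)
            for p, m, C in zip(priors, means, covs)
        ]
        out.append(classes[int(np.argmax(dens))])
    return np.array(out)


def make_two_class(rng, n=60, d=2, shift=3.0, equal_cov=True):
    A = rng.normal(size=(d, d)) * 0.3 + np.eye(d)
    cov1 = A @ A.T
    cov2 = cov1 if equal_cov else cov1 * rng.uniform(0.5, 2.0)
    X = np.vstack([
        rng.multivariate_normal(np.zeros(d), cov1, n),
        rng.multivariate_normal(np.full(d, shift), cov2, n),
    ])
    y = np.repeat([1, 2], n)
    return X, y


class TestClosedForm:
    def test_linear_boundary_at_midpoint(self):
        """1-D equal-variance, equal-prior classes at means 0 and 2 put
        the linear boundary at x = 1."""
        model = cs.GaussianDiscriminant.from_parameters(
            [1, 2], [0.5, 0.5], [[0.0], [2.0]], [[[1.0]], [[1.0]]], "linear"
        )
        assert model.predict([[0.99]])[0] == 1
        assert model.predict([[1.01]])[0] == 2
        # exactly on the boundary: tie broken toward the lower class
        assert model.predict([[1.0]])[0] == 1

    def test_quadratic_rule_matches_density_oracle_on_grid(self):
        """1-D heteroscedastic rule (variances 1 and 4, means 0 and 2)
        agrees with explicit density comparison everywhere on a grid."""
        classes, priors = [1, 2], [0.5, 0.5]
        means, covs = [[0.0], [2.0]], [[[1.0]], [[4.0]]]
        model = cs.GaussianDiscriminant.from_parameters(
            classes, priors, means, covs, "quadratic"
        )
        grid = np.linspace(-6, 8, 281)[:, None]
        expected = brute_force_predict(grid, classes, priors, means, covs)
        assert np.array_equal(model.predict(grid), expected)
        # heteroscedastic boundary has two roots: both labels occur on
        # each side far from the means
        pred = model.predict(grid).astype(int)
        assert pred[0] == 2 and pred[-1] == 2 and (pred == 1).any()

    def test_sample_at_class_mean(self):
        rng = np.random.default_rng(3)
        X, y = make_two_class(rng)
        model = cs.GaussianDiscriminant(kind="quadratic").fit(X, y)
        raw_means = np.vstack(
            [X[y == c].mean(axis=0) for c in model.classes_]
        )
        assert np.array_equal(model.predict(raw_means), model.classes_)


class TestFitting:
    def test_duplicated_feature_singular_at_zero_ridge(self):
        rng = np.random.default_rng(0)
        X, y = make_two_class(rng, d=2)
        X = np.hstack([X, X[:, :1]])  # exact duplicate column
        with pytest.raises(SingularCovarianceError) as err:
            cs.GaussianDiscriminant(kind="quadratic", ridge=0.0).fit(X, y)
        assert err.value.features  # offending features are named

    def test_pooled_vs_per_class_covariance(self):
        rng = np.random.default_rng(1)
        X, y = make_two_class(rng, equal_cov=False)
        lda = cs.GaussianDiscriminant(kind="linear", ridge=0.0).fit(X, y)
        qda = cs.GaussianDiscriminant(kind="quadratic", ridge=0.0).fit(X, y)
        C1, C2 = lda.covariances_
        assert np.allclose(C1, C2)  # pooled: shared matrix
        D1, D2 = qda.covariances_
        assert not np.allclose(D1, D2)

    def test_priors_are_class_frequencies(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        y = np.array([1] * 10 + [2] * 20)
        X[y == 2] += 4
        model = cs.GaussianDiscriminant().fit(X, y)
        assert np.allclose(model.priors_, [1 / 3, 2 / 3])

    def test_schema_mismatch(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        X, y = make_two_class(rng)
        df = pd.DataFrame(X, columns=["f1", "f2"])
        model = cs.GaussianDiscriminant().fit(df, y)
        with pytest.raises(SchemaError):
            model.predict(pd.DataFrame(X[:, :1], columns=["f1"]))

    def test_constant_feature_in_one_class_handled_by_auto_ridge(self):
        """A feature with zero variance inside one class (like the root
        count among all-single-root regulars) still fits with the default
        ridge."""
        rng = np.random.default_rng(5)
        X, y = make_two_class(rng)
        X = np.hstack([X, np.where(y == 1, 1.0, rng.choice([1.0, 2.0], y.size))[:, None]])
        model = cs.GaussianDiscriminant(kind="quadratic").fit(X, y)
        assert np.isfinite(model.discriminant_scores(X)).all()


class TestOracles:
    def test_predictions_match_density_oracle_random_problems(self):
        """LDA and QDA agree with the explicit prior x density oracle on
        random 2-class problems with up to 3 features."""
        rng = np.random.default_rng(10)
        for _ in range(20):
            d = int(rng.integers(1, 4))
            X, y = make_two_class(rng, n=40, d=d, shift=2.0,
                                  equal_cov=bool(rng.integers(2)))
            for kind in ("linear", "quadratic"):
                model = cs.GaussianDiscriminant(
                    kind=kind, ridge=0.0, standardize=False
                ).fit(X, y)
                rows = rng.normal(scale=2.0, size=(10, d)) + 1.0
                expected = brute_force_predict(
                    rows, list(model.classes_), model.priors_,
                    model.means_, model.covariances_,
                )
                assert np.array_equal(model.predict(rows), expected), kind

    def test_predictions_match_sklearn_reference(self):
        """Cross-check against an independent reference implementation
        on 200 random rows."""
        from sklearn.discriminant_analysis import (
            LinearDiscriminantAnalysis,
            QuadraticDiscriminantAnalysis,
        )

        rng = np.random.default_rng(11)
        X, y = make_two_class(rng, n=100, d=3, shift=1.5, equal_cov=False)
        rows = rng.normal(scale=1.5, size=(200, 3)) + 0.75
        ours_l = cs.GaussianDiscriminant(
            kind="linear", ridge=0.0, standardize=False
        ).fit(X, y).predict(rows)
        ours_q = cs.GaussianDiscriminant(
            kind="quadratic", ridge=0.0, standardize=False
        ).fit(X, y).predict(rows)
        ref_l = LinearDiscriminantAnalysis().fit(X, y).predict(rows)
        ref_q = QuadraticDiscriminantAnalysis().fit(X, y).predict(rows)
        assert np.array_equal(ours_l, ref_l)
        assert np.array_equal(ours_q, ref_q)

    def test_affine_invariance_of_predictions(self):
        """Per-feature rescaling leaves epsilon=0 predictions unchanged."""
        rng = np.random.default_rng(12)
        X, y = make_two_class(rng, d=3, equal_cov=False)
        scale = rng.uniform(0.1, 50.0, size=3)
        rows = rng.normal(size=(50, 3))
        for kind in ("linear", "quadratic"):
            p1 = cs.GaussianDiscriminant(
                kind=kind, ridge=0.0, standardize=False
            ).fit(X, y).predict(rows)
            p2 = cs.GaussianDiscriminant(
                kind=kind, ridge=0.0, standardize=False
            ).fit(X * scale, y).predict(rows * scale)
            assert np.array_equal(p1, p2), kind

    def test_lda_qda_agree_under_equal_covariances(self):
        """When the generating process truly shares a covariance, the two
        rules agree on >= 95% of test points at large n."""
        rng = np.random.default_rng(13)
        X, y = make_two_class(rng, n=1000, d=2, shift=2.0, equal_cov=True)
        rows, _ = make_two_class(rng, n=500, d=2, shift=2.0, equal_cov=True)
        pl = cs.GaussianDiscriminant(kind="linear").fit(X, y).predict(rows)
        pq = cs.GaussianDiscriminant(kind="quadratic").fit(X, y).predict(rows)
        assert (pl == pq).mean() >= 0.95


class TestEvaluation:
    def test_confusion_and_ccr_arithmetic(self):
        """125/135 correct -> 92.59%; 130/135 -> 96.30%; perfect -> 100."""
        y = np.repeat([1, 2], [56, 79])
        pred = y.copy()
        assert confusion_matrix(y, pred).ccr == 100.00
        pred[:3] = 2       # 3 regular misread as irregular
        pred[56:63] = 1    # 7 irregular misread as regular
        cm = confusion_matrix(y, pred)
        assert cm.counts.tolist() == [[53, 3], [7, 72]]
        assert cm.ccr == 92.59
        pred = y.copy()
        pred[56:61] = 1    # 5 irregular misread
        cm = confusion_matrix(y, pred)
        assert cm.counts.tolist() == [[56, 0], [5, 74]]
        assert cm.ccr == 96.30

    def test_empty_evaluation_errors(self):
        with pytest.raises(NoDataError):
            confusion_matrix(np.array([]), np.array([]))


class TestCrossValidation:
    def test_loo_perfect_separation(self):
        rng = np.random.default_rng(20)
        X = np.r_[rng.normal(-5, 1, 20), rng.normal(5, 1, 20)][:, None]
        y = np.repeat([1, 2], 20)
        res = cs.cross_validate(X, y, kind="linear", scheme="loo")
        assert res.ccr == 100.0

    def test_loo_equals_explicit_refit_loop(self):
        rng = np.random.default_rng(21)
        X, y = make_two_class(rng, n=25, d=2, shift=1.0)
        res = cs.cross_validate(X, y, kind="quadratic", scheme="loo")
        preds = []
        for i in range(len(y)):
            tr = np.arange(len(y)) != i
            m = cs.GaussianDiscriminant(kind="quadratic").fit(X[tr], y[tr])
            preds.append(m.predict(X[i:i + 1])[0])
        expected = round(100.0 * np.mean(np.array(preds) == y), 2)
        assert res.ccr == expected

    def test_kfold_deterministic_and_stratified(self):
        rng = np.random.default_rng(22)
        X, y = make_two_class(rng, n=30)
        r1 = cs.cross_validate(X, y, scheme="kfold", n_folds=5, seed=7)
        r2 = cs.cross_validate(X, y, scheme="kfold", n_folds=5, seed=7)
        assert np.array_equal(r1.fold_assignment, r2.fold_assignment)
        assert r1.ccr == r2.ccr
        for fold in range(5):
            assert np.unique(y[r1.fold_assignment == fold]).size == 2

    def test_stratification_error(self):
        X = np.arange(10, dtype=float)[:, None]
        y = np.array([1] * 8 + [2] * 2)
        with pytest.raises(StratificationError):
            cs.cross_validate(X, y, scheme="kfold", n_folds=5)


def test_json_roundtrip(tmp_path):
    rng = np.random.default_rng(30)
    X, y = make_two_class(rng, equal_cov=False)
    import pandas as pd

    df = pd.DataFrame(X, columns=["alpha", "beta"])
    model = cs.GaussianDiscriminant(kind="quadratic").fit(df, y)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = cs.GaussianDiscriminant.load(path)
    assert np.array_equal(loaded.predict(df), model.predict(df))
    blob = json.loads(path.read_text())
    assert blob["kind"] == "quadratic"
    assert blob["feature_names"] == ["alpha", "beta"]
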
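"""Wrapper feature selection around the quadratic discriminant.

Greedy sequential forward selection: start from the empty set and, at
each step, add whichever candidate feature most improves the
cross-validated correct classification rate of a QDA classifier fitted
on the working set.  Stop when no candidate yields a strict improvement
(delta = 0 by default).  Ties are broken by candidate column order, so a
fixed seed and table yield an identical result.

Also provides the per-feature univariate screen: class means, SDs,
coefficients of variation and a Welch two-sample test per feature —
the standard first look at whether each descriptor differs between the
regular and irregular classes at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .discriminant import cross_validate
from .errors import NoDataError

__all__ = [
    "ForwardDiscriminantSelector",
    "SelectionResult",
    "select_features",
    "per_feature_screen",
    "cv_percent",
]


@dataclass
class SelectionResult:
    selected: list
    trajectory: list  # CV CCR (%) after each inclusion step
    scheme: dict
    candidate_scores: list = field(default_factory=list)

    def to_dict(self):
        return {
            "selected": list(self.selected),
            "trajectory": [float(s) for s in self.trajectory],
            "scheme": dict(self.scheme),
        }


class ForwardDiscriminantSelector(BaseEstimator):
    """Sequential forward selector scored by discriminant CV accuracy.

    Parameters
    ----------
    kind : {"quadratic", "linear"}
        Classifier whose cross-validated CCR drives the search.
    scheme : {"kfold", "loo"}
    n_folds : int
        Folds for the stratified k-fold scheme.
    seed : int
        Shuffling seed for fold assignment; fixes the whole search.
    delta : float
        Minimum CCR improvement (percentage points) required to accept
        another feature; 0 demands strict improvement.
    max_features : int or None
        Optional hard cap on the selected set size.
    """

    def __init__(self, kind="quadratic", scheme="kfold", n_folds=5, seed=0,
                 delta=0.0, max_features=None, ridge="auto"):
        self.kind = kind
        self.scheme = scheme
        self.n_folds = n_folds
        self.seed = seed
        self.delta = delta
        self.max_features = max_features
        self.ridge = ridge

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        if X.shape[1] < 1:
            raise NoDataError("no candidate features")
        y = np.asarray(y)

        candidates = list(X.columns)
        selected: list = []
        trajectory: list = []
        best_so_far = -np.inf
        cap = self.max_features or len(candidates)

        while candidates and len(selected) < cap:
            step_best, step_feat = -np.inf, None
            for feat in candidates:  # column order resolves ties
                score = self._score(X[selected + [feat]], y)
                if score > step_best:
                    step_best, step_feat = score, feat
            if step_best <= best_so_far + self.delta and selected:
                break
            if not selected and step_best <= self._baseline(y) :
                # a lone feature must beat the majority-class baseline
                break
            selected.append(step_feat)
            candidates.remove(step_feat)
            trajectory.append(step_best)
            best_so_far = step_best

        self.selected_ = selected
        self.trajectory_ = trajectory
        self.support_ = np.array([c in selected for c in X.columns])
        self.feature_names_in_ = np.asarray(list(X.columns))
        self.n_features_in_ = X.shape[1]
        self.result_ = SelectionResult(
            selected=list(selected),
            trajectory=list(trajectory),
            scheme={
                "kind": self.kind,
                "scheme": self.scheme,
                "n_folds": self.n_folds,
                "seed": self.seed,
                "delta": self.delta,
            },
        )
        return self

    def _score(self, X, y):
        return cross_validate(
            X, y, kind=self.kind, scheme=self.scheme,
            n_folds=self.n_folds, seed=self.seed, ridge=self.ridge,
        ).ccr

    @staticmethod
    def _baseline(y):
        _, counts = np.unique(y, return_counts=True)
        return round(100.0 * counts.max() / counts.sum(), 2)

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_]
        X = np.asarray(X)
        idx = [list(self.feature_names_in_).index(f) for f in self.selected_]
        return X[:, idx]

    def get_support(self):
        return self.support_


def select_features(table, y, **kwargs):
    """Functional wrapper: returns the :class:`SelectionResult` of a
    forward search over ``table``'s columns."""
    sel = ForwardDiscriminantSelector(**kwargs).fit(table, y)
    return sel.result_


def cv_percent(mean, sd):
    """Coefficient of variation, percent: 100 * SD / mean (NaN at mean 0)."""
    if mean == 0:
        return float("nan")
    return 100.0 * sd / abs(mean)


def per_feature_screen(table, y, alpha=0.05):
    """Univariate two-class screen of every feature column.

    For each feature: per-class mean and population SD, per-class CV%
    and the Welch (unequal-variance) two-sample t-test p-value, with a
    flag for features that differ between classes at level ``alpha``.
    A feature constant in both classes has an undefined test and is
    flagged ``undefined`` rather than raising.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise NoDataError("screen expects exactly two classes")
    g1, g2 = (table[y == c] for c in classes)

    rows = []
    for col in table.columns:
        a, b = g1[col].to_numpy(float), g2[col].to_numpy(float)
        m1, m2 = a.mean(), b.mean()
        s1, s2 = a.std(ddof=0), b.std(ddof=0)
        undefined = s1 == 0 and s2 == 0
        if undefined:
            p = float("nan")
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "feature": col,
                f"mean_{classes[0]}": m1,
                f"sd_{classes[0]}": s1,
                f"cv_pct_{classes[0]}": cv_percent(m1, s1),
                f"mean_{classes[1]}": m2,
                f"sd_{classes[1]}": s2,
                f"cv_pct_{classes[1]}": cv_percent(m2, s2),
                "p_value": p,
                "significant": bool(p < alpha) if not undefined else False,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
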
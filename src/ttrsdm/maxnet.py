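"""Maxnet-style correlative presence/background model.

A feature expansion (linear, quadratic, hinge, product terms built from
training-data statistics only) followed by an L1-penalized binomial fit on
presence/pseudoabsence labels.  This reimplements the maxnet approach as a
penalized logistic regression — the evaluation battery consumes suitability
rankings, for which the two formulations are interchangeable — and stands
in for MaxEnt as the correlative baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

FEATURE_KINDS = ("linear", "quadratic", "hinge", "product")


@dataclass
class FeatureMeta:
    """Training-time statistics needed to rebuild features anywhere."""

    kinds: tuple[str, ...]
    n_hinges: int
    mean: np.ndarray
    std: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    keep: np.ndarray          # non-constant variables
    fmin: np.ndarray          # per-feature [0,1] rescaling
    fmax: np.ndarray

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else list(v) if k == "kinds" else v)
                for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMeta":
        return cls(kinds=tuple(d["kinds"]), n_hinges=int(d["n_hinges"]),
                   **{k: np.asarray(d[k]) for k in
                      ("mean", "std", "vmin", "vmax", "keep", "fmin", "fmax")})


def _raw_features(X, meta: FeatureMeta, clamp: bool) -> np.ndarray:
    X = np.asarray(X, float)[:, meta.keep.astype(bool)]
    if clamp:
        X = np.clip(X, meta.vmin, meta.vmax)
    Z = (X - meta.mean) / meta.std
    blocks = []
    if "linear" in meta.kinds:
        blocks.append(Z)
    if "quadratic" in meta.kinds:
        blocks.append(Z ** 2)
    if "hinge" in meta.kinds:
        for j in range(X.shape[1]):
            lo, hi = meta.vmin[j], meta.vmax[j]
            knots = np.linspace(lo, hi, meta.n_hinges + 2)[1:-1]
            x = X[:, j][:, None]
            fwd = np.maximum(0.0, (x - knots) / (hi - knots))
            rev = np.maximum(0.0, (knots - x) / (knots - lo))
            blocks.append(fwd)
            blocks.append(rev)
    if "product" in meta.kinds and Z.shape[1] >= 2:
        i, j = np.triu_indices(Z.shape[1], k=1)
        blocks.append(Z[:, i] * Z[:, j])
    return np.column_stack(blocks)


def build_features(env_vectors, kinds=("linear", "quadratic", "hinge"),
                   n_hinges: int = 10):
    """Training-time feature construction.

    Returns the feature matrix (each column rescaled to [0, 1] by its
    training range) and the metadata needed to evaluate the identical
    features on new environmental vectors.  Constant variables are dropped
    with a warning.
    """
    X = np.asarray(env_vectors, float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least one variable")
    if n_hinges < 2:
        raise ValueError("n_hinges must be at least 2")
    unknown = set(kinds) - set(FEATURE_KINDS)
    if unknown:
        raise ValueError(f"unknown feature kinds {sorted(unknown)}")
    std = X.std(axis=0)
    keep = std > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant variable(s)",
                      UserWarning, stacklevel=2)
    if not keep.any():
        raise ValueError("all variables are constant")
    Xk = X[:, keep]
    meta = FeatureMeta(
        kinds=tuple(kinds), n_hinges=n_hinges,
        mean=Xk.mean(axis=0), std=Xk.std(axis=0),
        vmin=Xk.min(axis=0), vmax=Xk.max(axis=0),
        keep=keep.astype(float),
        fmin=np.zeros(1), fmax=np.ones(1))
    F = _raw_features(X, meta, clamp=False)
    meta.fmin = F.min(axis=0)
    meta.fmax = np.where(F.max(axis=0) > meta.fmin, F.max(axis=0),
                         meta.fmin + 1.0)
    return (F - meta.fmin) / (meta.fmax - meta.fmin), meta


def apply_features(meta: FeatureMeta, env_vectors, clamp: bool = True) -> np.ndarray:
    F = _raw_features(env_vectors, meta, clamp=clamp)
    return (F - meta.fmin) / (meta.fmax - meta.fmin)


#: default end of the penalty path as a fraction of lambda_max
LAMBDA_PATH_FRACTION = 0.01


def lambda_max(features, labels) -> float:
    """Smallest penalty at which every coefficient is zero."""
    F = np.asarray(features, float)
    y = np.asarray(labels, float)
    resid = y - y.mean()
    return float(np.abs(F.T @ resid).max() / len(y))


def fit_penalized(features, labels, reg_multiplier: float = 1.0,
                  lambda_grid=None, seed: int = 0):
    """L1-penalized binomial fit over a decreasing penalty path.

    The path runs from ``lambda_max`` (all-zero solution) down to
    ``reg_multiplier`` times 1% of it — the glmnet/maxnet convention —
    with warm starts; the coefficients at the final penalty are returned
    as ``(weights, intercept)``.
    """
    F = np.asarray(features, float)
    y = np.asarray(labels, int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    lmax = lambda_max(F, y)
    if lambda_grid is None:
        final = reg_multiplier * LAMBDA_PATH_FRACTION * lmax
        lambda_grid = np.geomspace(lmax, final, 4)[1:]
    clf = LogisticRegression(
        solver="saga", l1_ratio=1.0, warm_start=True, max_iter=1000,
        tol=1e-5, random_state=seed)
    with warnings.catch_warnings():
        # interior path points are warm starts and need not fully converge
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        for lmb in lambda_grid:
            clf.C = 1.0 / (len(y) * lmb)
            clf.fit(F, y)
    coef = clf.coef_.ravel().copy()
    intercept = float(clf.intercept_[0])
    if not coef.any():
        # null model: the unpenalized intercept has the closed form
        # logit(prevalence), which the coordinate solver approaches slowly
        prev = y.mean()
        intercept = float(np.log(prev / (1.0 - prev)))
    return coef, intercept


class MaxnetSDM(BaseEstimator):
    """Correlative presence/background species distribution model.

    Parameters
    ----------
    feature_kinds : feature classes to build; product terms are only added
        when there are >= 2 variables and >= ``products_min_presences``
        presences (mirrors maxnet's sample-size-dependent defaults).
    n_hinges : knots per variable for hinge features.
    reg_multiplier : multiplier on the default penalty (1.0 = default).
    link : "logit" or "cloglog" for mapping the linear predictor to
        suitability.
    clamp : clamp prediction features to the training range.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : fitted weights; feature_meta_ : training statistics.
    """

    def __init__(self, feature_kinds=("linear", "quadratic", "hinge"),
                 n_hinges: int = 10, reg_multiplier: float = 1.0,
                 link: str = "logit", clamp: bool = True,
                 products_min_presences: int = 80, random_state: int = 0):
        self.feature_kinds = feature_kinds
        self.n_hinges = n_hinges
        self.reg_multiplier = reg_multiplier
        self.link = link
        self.clamp = clamp
        self.products_min_presences = products_min_presences
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        kinds = tuple(self.feature_kinds)
        if ("product" not in kinds and X.shape[1] >= 2
                and int((y == 1).sum()) >= self.products_min_presences):
            kinds = kinds + ("product",)
        F, meta = build_features(X, kinds=kinds, n_hinges=self.n_hinges)
        self.feature_meta_ = meta
        self.coef_, self.intercept_ = fit_penalized(
            F, y, reg_multiplier=self.reg_multiplier, seed=self.random_state)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        F = apply_features(self.feature_meta_, X, clamp=self.clamp)
        return F @ self.coef_ + self.intercept_

    def predict_suitability(self, X) -> np.ndarray:
        """Suitability in [0, 1] under the configured link."""
        eta = self.decision_function(X)
        if self.link == "cloglog":
            return -np.expm1(-np.exp(eta))
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_suitability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_suitability(X) >= 0.5).astype(int)

    # -- persistence ---------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "params": self.get_params(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "feature_meta": self.feature_meta_.to_dict(),
        })

    @classmethod
    def from_json(cls, text: str) -> "MaxnetSDM":
        d = json.loads(text)
        params = d["params"]
        params["feature_kinds"] = tuple(params["feature_kinds"])
        est = cls(**params)
        est.coef_ = np.asarray(d["coef"])
        est.intercept_ = float(d["intercept"])
        est.feature_meta_ = FeatureMeta.from_dict(d["feature_meta"])
        return est
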
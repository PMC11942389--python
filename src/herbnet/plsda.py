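"""PLS-DA and OPLS-DA for two-group metabolomics, fitted by NIPALS.

The response is the dummy-coded group membership (PLS1), so the NIPALS
iteration collapses to a closed deterministic form per component:

    w_a = E'f / ||E'f||     (unit-norm weight)
    t_a = E w_a             (score)
    q_a = f't_a / t_a't_a   (y-loading)
    p_a = E't_a / t_a't_a   (x-loading)
    E <- E - t_a p_a',  f <- f - q_a t_a   (deflation)

Model quality follows the SIMCA conventions used in metabolomics:
R2X/R2Y are cumulative explained sums of squares on the training data,
Q2 = 1 - PRESS/SS under deterministic venetian-blind cross-validation,
and the permutation test refits the model under label permutations.
Estimators follow the scikit-learn protocol (``fit``/``transform``/
``predict``, trailing-underscore fitted attributes) and take X as
(n_samples, n_features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InputError, ParameterError, PreprocessingError

__all__ = [
    "PLSDA",
    "OPLSDA",
    "PermutationRecord",
    "fit_plsda",
    "vip_scores",
    "q2_cross_validation",
    "permutation_validate",
    "fit_oplsda",
]


def _as_array(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, list(range(arr.shape[1]))


def _encode_y(y) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise InputError(f"expected exactly two groups, got {len(classes)}")
    return (y == classes[1]).astype(float), classes


def _center_scale(X: np.ndarray, scale: bool, names) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scale:
        std = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(std == 0)
        if bad.size:
            raise PreprocessingError(
                "constant variable(s) under unit-variance scaling: "
                + ", ".join(str(names[i]) for i in bad[:5])
            )
    else:
        std = np.ones(X.shape[1])
    return (X - mean) / std, mean, std


def _nipals_pls1(E: np.ndarray, f: np.ndarray, n_components: int) -> dict:
    """Deterministic NIPALS for a univariate response. E and f are
    centred (and scaled) copies; both are deflated in place."""
    n, p = E.shape
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    ssx0 = float((E**2).sum())
    ssy0 = float((f**2).sum())
    ssx_res = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14:  # residual X carries no Y-covariance; stop early
            ssx_res[a:] = float((E**2).sum())
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            ssx_res[a:] = float((E**2).sum())
            break
        qa = float(f @ t) / tt
        pa = (E.T @ t) / tt
        E -= np.outer(t, pa)
        f -= qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
        ssx_res[a] = float((E**2).sum())
    ssy_expl = q**2 * (T**2).sum(axis=0)
    return {
        "W": W,
        "T": T,
        "P": P,
        "q": q,
        "ssx0": ssx0,
        "ssy0": ssy0,
        "ssx_res": ssx_res,
        "ssy_res": float((f**2).sum()),
        "ssy_explained": ssy_expl,
    }


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """PLS regression coefficients B = W (P'W)^-1 q on the scaled scale."""
    ptw = P.T @ W
    return W @ np.linalg.solve(ptw, q)


class PLSDA(BaseEstimator):
    """Two-group partial least squares discriminant analysis (NIPALS).

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components.
    scale : bool, default True
        Unit-variance scaling after mean-centering (SIMCA convention).

    Attributes
    ----------
    classes_ : list
        The two group labels, sorted; the second is coded 1.
    x_weights_, x_loadings_ : ndarray (n_features, n_components)
    x_scores_ : ndarray (n_samples, n_components)
    y_loadings_ : ndarray (n_components,)
    r2x_, r2y_ : float
        Cumulative explained X / Y sum-of-squares fractions.
    r2x_per_component_ : ndarray
        Cumulative R2X after each component.
    coef_ : ndarray (n_features,)
        Regression vector on the scaled X; ``decision_function`` applies it.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        Xa, names = _as_array(X)
        n, p = Xa.shape
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ParameterError(
                f"n_components must lie in [1, min(n_samples-1, n_features)]"
                f" = [1, {min(n - 1, p)}]"
            )
        y01, self.classes_ = _encode_y(y)
        if len(y01) != n:
            raise InputError("X and y have different numbers of samples")

        Xs, self.x_mean_, self.x_std_ = _center_scale(Xa, self.scale, names)
        self.y_mean_ = float(y01.mean())
        f = y01 - self.y_mean_
        if (f == 0).all():
            raise InputError("response has zero variance (single group?)")

        m = _nipals_pls1(Xs.copy(), f.copy(), self.n_components)
        self.feature_names_in_ = names
        self.x_weights_ = m["W"]
        self.x_scores_ = m["T"]
        self.x_loadings_ = m["P"]
        self.y_loadings_ = m["q"]
        self.ssy_explained_ = m["ssy_explained"]
        self.r2x_per_component_ = 1.0 - m["ssx_res"] / m["ssx0"]
        self.r2x_ = float(self.r2x_per_component_[-1])
        self.r2y_ = 1.0 - m["ssy_res"] / m["ssy0"]
        self.coef_ = _regression_vector(m["W"], m["P"], m["q"])
        return self

    def transform(self, X) -> np.ndarray:
        """Project new samples onto the latent components."""
        Xa, _ = _as_array(X)
        Xs = (Xa - self.x_mean_) / self.x_std_
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        return Xs @ R

    def decision_function(self, X) -> np.ndarray:
        Xa, _ = _as_array(X)
        Xs = (Xa - self.x_mean_) / self.x_std_
        return Xs @ self.coef_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        yhat = self.decision_function(X)
        return np.where(yhat >= 0.5, self.classes_[1], self.classes_[0])


def fit_plsda(X, y, n_components: int = 2, scale: bool = True) -> PLSDA:
    """Thin functional wrapper over :class:`PLSDA`."""
    return PLSDA(n_components=n_components, scale=scale).fit(X, y)


def vip_scores(model: PLSDA) -> np.ndarray:
    """Variable importance in projection (Wold formulation).

    vip_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ), where SSY_a is
    the Y sum of squares explained by component a. Mean squared VIP is 1
    by construction.
    """
    if not hasattr(model, "x_weights_"):
        raise InputError("model is not fitted")
    ssy = model.ssy_explained_
    total = ssy.sum()
    if total <= 0:
        raise InputError("VIP undefined: model explains no Y variance")
    p = model.x_weights_.shape[0]
    return np.sqrt(p * (model.x_weights_**2 @ ssy) / total)


def _blind_folds(y01: np.ndarray, sample_ids, n_folds: int) -> list:
    """Venetian-blind fold assignment on samples ordered by group then id."""
    order = sorted(range(len(y01)), key=lambda i: (y01[i], str(sample_ids[i])))
    return [np.array(order[f::n_folds], dtype=int) for f in range(n_folds)]


def q2_cross_validation(
    X,
    y,
    n_components: int = 2,
    n_folds: int = 7,
    scale: bool = True,
) -> float:
    """Cross-validated predictive ability Q2 = 1 - PRESS/SS.

    Deterministic venetian-blind folds are laid over samples ordered by
    group then sample id; each held-out sample's group code is predicted
    by a model refit on the remainder. SS accumulates squared deviations
    of held-out codes from the training mean, fold by fold.
    """
    Xa, names = _as_array(X)
    sample_ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(Xa)))
    y01, _ = _encode_y(y)
    n = len(y01)
    if n_folds > n:
        raise InputError(f"n_folds={n_folds} exceeds n_samples={n}")
    folds = [f for f in _blind_folds(y01, sample_ids, n_folds) if len(f)]

    press = 0.0
    ss = 0.0
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        y_tr = y01[train]
        if len(np.unique(y_tr)) < 2:
            raise InputError("a cross-validation fold emptied one group")
        Xs, mean, std = _center_scale(Xa[train], scale, names)
        f = y_tr - y_tr.mean()
        a = min(n_components, len(train) - 1, Xa.shape[1])
        m = _nipals_pls1(Xs, f.copy(), a)
        b = _regression_vector(m["W"], m["P"], m["q"])
        yhat = ((Xa[test] - mean) / std) @ b + y_tr.mean()
        press += float(((y01[test] - yhat) ** 2).sum())
        ss += float(((y01[test] - y_tr.mean()) ** 2).sum())
    return 1.0 - press / ss


@dataclass
class PermutationRecord:
    """Outcome of a label-permutation validation of a PLS-DA model."""

    n_permutations: int
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    original_r2y: float
    original_q2: float
    valid: bool


def permutation_validate(
    X,
    y,
    n_components: int = 2,
    n_permutations: int = 100,
    seed: int = 0,
    n_folds: int = 7,
    scale: bool = True,
) -> PermutationRecord:
    """Permutation test of PLS-DA model validity.

    Group labels are permuted ``n_permutations`` times; R2Y and Q2 are
    recomputed per permutation. The model is declared valid when the
    original Q2 exceeds the 95th percentile of the permuted Q2
    distribution.
    """
    if n_permutations < 20:
        raise ParameterError("n_permutations must be >= 20")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    orig_r2y = PLSDA(n_components=n_components, scale=scale).fit(X, y).r2y_
    orig_q2 = q2_cross_validation(X, y, n_components, n_folds, scale)

    perm_r2y = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    for k in range(n_permutations):
        yp = rng.permutation(y)
        perm_r2y[k] = PLSDA(n_components=n_components, scale=scale).fit(X, yp).r2y_
        perm_q2[k] = q2_cross_validation(X, yp, n_components, n_folds, scale)

    valid = orig_q2 > float(np.quantile(perm_q2, 0.95))
    return PermutationRecord(
        n_permutations=n_permutations,
        permuted_r2y=perm_r2y,
        permuted_q2=perm_q2,
        original_r2y=orig_r2y,
        original_q2=orig_q2,
        valid=valid,
    )


class OPLSDA(BaseEstimator):
    """Orthogonal PLS-DA: one predictive component after removal of
    Y-orthogonal variation, plus S-plot coordinates.

    Attributes
    ----------
    t_pred_ : ndarray (n_samples,)
        Predictive scores (on the orthogonal-filtered X).
    t_orth_ : ndarray (n_samples, n_orthogonal)
        Orthogonal scores (empty if no orthogonal structure was found).
    s_plot_ : pandas.DataFrame
        Per-variable ``covariance`` and ``correlation`` with t_pred_.
    """

    def __init__(self, n_orthogonal: int = 1, scale: bool = True):
        self.n_orthogonal = n_orthogonal
        self.scale = scale

    def fit(self, X, y):
        Xa, names = _as_array(X)
        y01, self.classes_ = _encode_y(y)
        Xs, self.x_mean_, self.x_std_ = _center_scale(Xa, self.scale, names)
        f = y01 - y01.mean()
        n = len(f)

        E = Xs.copy()
        t_orth = []
        for _ in range(self.n_orthogonal):
            w = E.T @ f
            w /= np.linalg.norm(w)
            t = E @ w
            p = (E.T @ t) / (t @ t)
            w_o = p - (w @ p) * w
            nwo = np.linalg.norm(w_o)
            if nwo < 1e-10:
                warnings.warn(
                    "no Y-orthogonal structure found; falling back to plain PLS-DA",
                    stacklevel=2,
                )
                break
            w_o /= nwo
            to = E @ w_o
            po = (E.T @ to) / (to @ to)
            E -= np.outer(to, po)
            t_orth.append(to)

        w = E.T @ f
        w /= np.linalg.norm(w)
        tp = E @ w
        self.w_pred_ = w
        self.t_pred_ = tp
        self.t_orth_ = (
            np.column_stack(t_orth) if t_orth else np.empty((n, 0))
        )

        cov = (Xs.T @ (tp - tp.mean())) / (n - 1)
        sd_x = Xs.std(axis=0, ddof=1)
        sd_t = tp.std(ddof=1)
        corr = cov / (sd_x * sd_t)
        self.s_plot_ = pd.DataFrame(
            {"covariance": cov, "correlation": corr}, index=pd.Index(names)
        )
        return self

    def transform(self, X) -> np.ndarray:
        Xa, _ = _as_array(X)
        Xs = (Xa - self.x_mean_) / self.x_std_
        return Xs @ self.w_pred_


def fit_oplsda(X, y, n_orthogonal: int = 1, scale: bool = True) -> OPLSDA:
    """Thin functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(n_orthogonal=n_orthogonal, scale=scale).fit(X, y)
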
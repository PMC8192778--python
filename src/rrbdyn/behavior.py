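"""Brain-behavior association and cross-validated prediction.

RRB factor scores (CI, IS, RM) are regressed on circuit NII features within
the ASD group.  Inference on the overall F statistic is permutation-based
(labels of the outcome permuted, F recomputed), alongside the parametric F
p-value.  Predictive ability is assessed by k-fold cross-validation: the
Pearson correlation between out-of-fold predictions and the actual scores,
with a permutation p-value obtained by rerunning the full cross-validation
under permuted outcomes.

Out-of-fold OLS predictions are linear in the outcome vector, so the
permutation loop is evaluated through a precomputed prediction operator;
this is algebraically identical to refitting every fold per permutation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import KFold

from .exceptions import ConfigurationError, InferenceError

#: (circuit, outcome) cells the dissociation model predicts to be significant.
EXPECTED_PATTERN = {("cognitive", "CI"), ("cognitive", "IS"), ("motor", "RM")}


@dataclass
class BehaviorAssociation:
    outcome: str
    predictors: tuple
    F: float
    df: tuple
    p_parametric: float
    p_permutation: float
    coefficients: dict
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "F": self.F,
            "df": list(self.df),
            "p_parametric": self.p_parametric,
            "p_permutation": self.p_permutation,
            "coefficients": self.coefficients,
            "n_permutations": self.n_permutations,
        }


@dataclass
class CrossValidationResult:
    outcome: str
    k_folds: int
    predicted: np.ndarray
    r_pred_actual: float
    p_permutation: float
    fold_assignment: np.ndarray
    seed: int
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "k_folds": self.k_folds,
            "r_pred_actual": self.r_pred_actual,
            "p_permutation": self.p_permutation,
            "fold_assignment": self.fold_assignment.tolist(),
            "seed": self.seed,
            "n_permutations": self.n_permutations,
        }


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


def _check_xy(X, y):
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != Xm.shape[0]:
        raise InferenceError("X and y shapes do not match")
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(y))):
        raise InferenceError("missing values in X or y")
    if Xm.shape[0] < Xm.shape[1] + 2:
        raise InferenceError("need n >= number of predictors + 2")
    if np.allclose(y, y[0]):
        raise InferenceError("constant outcome")
    return Xm, names, y


def _f_from_r2(r2: float, n: int, p: int) -> float:
    if r2 >= 1.0 - 1e-15:
        return np.inf
    return (r2 / p) / ((1.0 - r2) / (n - p - 1))


def fit_association(X, y, outcome: str = "", n_permutations: int = 5000,
                    seed: int = 0) -> BehaviorAssociation:
    """OLS association with parametric and permutation F inference.

    The permutation p-value is ``(1 + #{F_perm >= F_obs}) / (1 + B)`` over
    ``B`` seeded permutations of ``y``.  F is a monotone function of R^2 at
    fixed dimensions, so permuted statistics are computed from the
    projection of each permuted outcome onto the predictor column space.
    """
    Xm, names, y = _check_xy(X, y)
    n, p = Xm.shape
    Xc = Xm - Xm.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    yc = y - y.mean()
    tss = yc @ yc
    r2 = float((Q.T @ yc) @ (Q.T @ yc) / tss)
    F = _f_from_r2(r2, n, p)
    df = (p, n - p - 1)
    p_param = float(scipy.stats.f.sf(F, *df)) if np.isfinite(F) else 0.0
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), Xm]), y, rcond=None)
    rng = np.random.default_rng(seed)
    Yp = rng.permuted(np.tile(y, (n_permutations, 1)), axis=1) - y.mean()
    proj = Q.T @ Yp.T  # (p, B)
    r2_perm = (proj**2).sum(axis=0) / tss
    F_perm = np.where(r2_perm >= 1.0 - 1e-15, np.inf,
                      (r2_perm / p) / ((1.0 - r2_perm) / (n - p - 1)))
    p_perm = (1.0 + np.sum(F_perm >= F)) / (1.0 + n_permutations)
    return BehaviorAssociation(
        outcome=outcome, predictors=names, F=float(F), df=df,
        p_parametric=p_param, p_permutation=float(p_perm),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        n_permutations=n_permutations,
    )


def _cv_operator(Xa: np.ndarray, folds) -> np.ndarray:
    """Linear map A with out-of-fold OLS predictions = A @ y."""
    n = Xa.shape[0]
    A = np.zeros((n, n))
    for train, test in folds:
        A[np.ix_(test, train)] = Xa[test] @ np.linalg.pinv(Xa[train])
    return A


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def crossval_predict(X, y, outcome: str = "", k_folds: int = 5, seed: int = 0,
                     n_permutations: int = 5000) -> CrossValidationResult:
    """k-fold out-of-fold OLS prediction with permutation inference.

    Folds come from a seeded random permutation of subjects (sizes differ by
    at most one).  ``r_pred_actual`` is the Pearson correlation between the
    concatenated out-of-fold predictions and the actual outcome; its
    permutation p-value reruns the entire cross-validation on permuted
    outcomes.
    """
    Xm, _, y = _check_xy(X, y)
    n, p = Xm.shape
    if n < 2 * k_folds:
        raise ConfigurationError("need n >= 2 * k_folds")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(Xm))
    fold_assignment = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(folds):
        fold_assignment[test] = f
        if len(y) - len(test) < p + 2:
            raise ConfigurationError(
                f"fold {f} leaves fewer than {p + 2} training rows"
            )
    Xa = np.column_stack([np.ones(n), Xm])
    A = _cv_operator(Xa, folds)
    yhat = A @ y
    r_obs = _pearson(yhat, y)
    rng = np.random.default_rng(seed)
    Yp = rng.permuted(np.tile(y, (n_permutations, 1)), axis=1)  # (B, n)
    Yhat = Yp @ A.T
    Yp_c = Yp - Yp.mean(axis=1, keepdims=True)
    Yhat_c = Yhat - Yhat.mean(axis=1, keepdims=True)
    num = np.einsum("bn,bn->b", Yp_c, Yhat_c)
    den = np.sqrt(np.einsum("bn,bn->b", Yp_c, Yp_c)
                  * np.einsum("bn,bn->b", Yhat_c, Yhat_c))
    r_perm = num / den
    p_perm = (1.0 + np.sum(r_perm >= r_obs)) / (1.0 + n_permutations)
    return CrossValidationResult(
        outcome=outcome, k_folds=k_folds, predicted=yhat,
        r_pred_actual=r_obs, p_permutation=float(p_perm),
        fold_assignment=fold_assignment, seed=seed,
        n_permutations=n_permutations,
    )


def crossval_predict_explicit(X, y, k_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Out-of-fold predictions by explicit per-fold OLS refits.

    Reference implementation used to validate the operator-based fast path;
    returns only the prediction vector.
    """
    Xm, _, y = _check_xy(X, y)
    n = Xm.shape[0]
    Xa = np.column_stack([np.ones(n), Xm])
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    yhat = np.empty(n)
    for train, test in kf.split(Xm):
        beta, *_ = np.linalg.lstsq(Xa[train], y[train], rcond=None)
        yhat[test] = Xa[test] @ beta
    return yhat


def specificity_report(features: pd.DataFrame, scores: pd.DataFrame,
                       n_permutations: int = 5000, cv_folds: int = 5,
                       seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """All circuit x outcome associations, flagging the dissociation model.

    ``features`` must contain columns ``cnii_mean``, ``cnii_sd``,
    ``mnii_mean`` indexed like ``scores`` (columns CI, IS, RM).  Cognitive
    predictors are {mean CNII, SD CNII}; the motor predictor is mean MNII.
    The expected dissociation flags cognitive->CI/IS and motor->RM.
    """
    if not features.index.equals(scores.index):
        raise InferenceError("features and scores must be indexed identically")
    blocks = {
        "cognitive": features[["cnii_mean", "cnii_sd"]],
        "motor": features[["mnii_mean"]],
    }
    rows = []
    for ci, (circuit, X) in enumerate(blocks.items()):
        for oi, outcome in enumerate(("CI", "IS", "RM")):
            y = scores[outcome].to_numpy(dtype=float)
            sub_seed = (seed + 7919 * (3 * ci + oi + 1)) % (2**31 - 1)
            assoc = fit_association(X, y, outcome=outcome,
                                    n_permutations=n_permutations,
                                    seed=sub_seed)
            cv = crossval_predict(X, y, outcome=outcome, k_folds=cv_folds,
                                  seed=sub_seed, n_permutations=n_permutations)
            rows.append({
                "circuit": circuit,
                "outcome": outcome,
                "F": assoc.F,
                "df1": assoc.df[0],
                "df2": assoc.df[1],
                "p_parametric": assoc.p_parametric,
                "p_permutation": assoc.p_permutation,
                "cv_r": cv.r_pred_actual,
                "cv_p": cv.p_permutation,
                "significant": assoc.p_permutation < alpha,
                "expected_significant": (circuit, outcome) in EXPECTED_PATTERN,
            })
    return pd.DataFrame(rows)
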
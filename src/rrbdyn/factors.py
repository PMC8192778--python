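"""RRB factor structure from ADI-R item scores.

Nine restricted/repetitive-behavior items are recoded (special codes 6/7/8
map to 0), then decomposed by PCA on the item correlation matrix.  The
number of retained components is the count of eigenvalues above 1; the
retained loadings (eigenvectors scaled by sqrt(eigenvalue)) are varimax
rotated with Kaiser row normalization, and subjects are scored by
least-squares regression onto the rotated loadings.  Components are
labeled CI / IS / RM when their top-loading items match the canonical item
grouping; otherwise they keep numeric labels.  The full eigenvalue profile
is retained so a scree plot can be inspected by hand.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ParameterError, ValidationError

#: The nine ADI-R RRB item codes handled by this package.
RRB_ITEMS = (67, 68, 69, 70, 71, 75, 76, 77, 78)

#: Canonical item grouping of the three RRB factors.
ITEM_GROUPS = {"CI": (68, 76), "IS": (67, 70), "RM": (69, 77, 78)}

_VALID_RAW = {0, 1, 2, 3, 6, 7, 8}
_VALID_RECODED = {0, 1, 2, 3}


def _item_columns(items: pd.DataFrame):
    cols = []
    for it in RRB_ITEMS:
        for cand in (it, str(it), f"item{it}", f"item_{it}"):
            if cand in items.columns:
                cols.append(cand)
                break
        else:
            raise ValidationError(f"item {it} missing from item table")
    return cols


def recode_items(raw: pd.DataFrame) -> pd.DataFrame:
    """Map ADI-R special codes 6/7/8 to 0; scores 0-3 pass through.

    Raises on any value outside {0,1,2,3,6,7,8}, naming subject and item.
    """
    cols = _item_columns(raw)
    out = raw.copy()
    for c in cols:
        vals = out[c]
        bad = ~vals.isin(sorted(_VALID_RAW))
        if bad.any():
            subj = bad.idxmax()
            raise ValidationError(
                f"invalid score {vals.loc[subj]!r} for subject {subj!r}, item {c}"
            )
        out[c] = vals.where(~vals.isin([6, 7, 8]), 0).astype(int)
    out.attrs["provenance"] = "recoded"
    return out


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-8,
            max_iter: int = 1000):
    """Varimax rotation (SVD iteration), optionally Kaiser-normalized.

    Returns (rotated loadings, orthogonal rotation matrix).
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, m = L.shape
    if m < 2:
        return L, np.eye(m)
    if normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(m)
    crit_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        grad = L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        crit = s.sum()
        if crit_old != 0 and crit < crit_old * (1 + tol):
            break
        crit_old = crit
    Lr = L @ R
    if normalize:
        Lr = Lr * h[:, None]
    return Lr, R


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over components of the variance of squared loadings."""
    L2 = np.asarray(loadings) ** 2
    return float((L2.var(axis=0)).sum())


class VarimaxPCA(TransformerMixin, BaseEstimator):
    """PCA of the item correlation matrix with varimax-rotated components.

    Parameters
    ----------
    n_components : int or None
        ``None`` retains components with eigenvalue > 1 (Kaiser rule).
    tol, max_iter : varimax convergence controls.

    Attributes
    ----------
    eigenvalues_ : ndarray, descending, sums to the number of items.
    n_components_ : int
    loadings_ : (n_items, m) rotated loadings, sign-fixed so each
        component's largest-magnitude loading is positive.
    rotation_ : (m, m) orthogonal rotation matrix.
    variance_explained_ : per-component proportion after rotation.
    """

    def __init__(self, n_components: int | None = None, tol: float = 1e-8,
                 max_iter: int = 1000):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, k = X.shape
        if n <= k:
            raise ValidationError(f"need more subjects ({n}) than items ({k})")
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError(f"zero-variance item at column {int(np.argmax(sd == 0))}")
        self.mean_ = X.mean(axis=0)
        self.scale_ = sd
        corr = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.eigenvalues_ = np.clip(evals, 0, None)
        m = (int(np.sum(self.eigenvalues_ > 1.0))
             if self.n_components is None else int(self.n_components))
        if m == 0:
            raise ParameterError("no eigenvalue exceeds 1; degenerate solution")
        raw = evecs[:, :m] * np.sqrt(self.eigenvalues_[:m])
        rotated, R = varimax(raw, normalize=True, tol=self.tol,
                             max_iter=self.max_iter)
        # fix sign: largest-|loading| entry of each component positive
        signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0),
                                np.arange(m)])
        signs[signs == 0] = 1.0
        rotated = rotated * signs
        R = R * signs
        self.n_components_ = m
        self.unrotated_loadings_ = raw
        self.loadings_ = rotated
        self.rotation_ = R
        self.variance_explained_ = (rotated**2).sum(axis=0) / k
        self.n_features_in_ = k
        return self

    def transform(self, X):
        """Component scores by least-squares regression on the loadings."""
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        L = self.loadings_
        return Z @ L @ np.linalg.inv(L.T @ L)


@dataclass
class FactorSolution:
    """Rotated item-PCA solution with labeled subject scores."""

    n_components: int
    loadings: pd.DataFrame  # items x components
    rotation_matrix: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    total_variance_explained: float
    scores: pd.DataFrame  # subjects x components
    component_labels: tuple
    estimator: VarimaxPCA


def _label_components(loadings: np.ndarray, item_codes) -> tuple:
    """Greedy CI/IS/RM labeling by squared-loading mass on canonical items."""
    m = loadings.shape[1]
    codes = [int(str(c).lstrip("item_")) if not isinstance(c, (int, np.integer))
             else int(c) for c in item_codes]
    mass = {}
    for label, group in ITEM_GROUPS.items():
        rows = [codes.index(g) for g in group if g in codes]
        for comp in range(m):
            mass[(label, comp)] = float((loadings[rows, comp] ** 2).sum())
    labels = [None] * m
    used = set()
    for (label, comp), _ in sorted(mass.items(), key=lambda kv: -kv[1]):
        if label in used or labels[comp] is not None or mass[(label, comp)] <= 0:
            continue
        # the component's top item must not contradict the label: it either
        # belongs to the group or to no canonical group at all
        top_item = codes[int(np.argmax(np.abs(loadings[:, comp])))]
        all_canonical = {i for g in ITEM_GROUPS.values() for i in g}
        if top_item in all_canonical and top_item not in ITEM_GROUPS[label]:
            continue
        labels[comp] = label
        used.add(label)
    return tuple(lb if lb is not None else f"C{idx + 1}"
                 for idx, lb in enumerate(labels))


def pca_varimax(items: pd.DataFrame) -> FactorSolution:
    """Full factor pipeline on a recoded item table."""
    if items.attrs.get("provenance") != "recoded":
        items = recode_items(items)
    cols = _item_columns(items)
    X = items[cols].to_numpy(dtype=float)
    est = VarimaxPCA().fit(X)
    labels = _label_components(est.loadings_, cols)
    loadings = pd.DataFrame(est.loadings_, index=cols, columns=labels)
    scores = pd.DataFrame(est.transform(X), index=items.index, columns=labels)
    return FactorSolution(
        n_components=est.n_components_, loadings=loadings,
        rotation_matrix=est.rotation_, eigenvalues=est.eigenvalues_,
        variance_explained=est.variance_explained_,
        total_variance_explained=float(est.variance_explained_.sum()),
        scores=scores, component_labels=labels, estimator=est,
    )


def score_with_external_weights(items: pd.DataFrame,
                                weights: pd.DataFrame) -> pd.DataFrame:
    """Factor scores as weighted sums of standardized item scores.

    ``weights`` is a 9-item x 3-factor table (e.g. previously published
    factor weights); its index must cover every RRB item.
    """
    if items.attrs.get("provenance") != "recoded":
        items = recode_items(items)
    cols = _item_columns(items)
    codes = [int(str(c).lstrip("item_")) if not isinstance(c, (int, np.integer))
             else int(c) for c in cols]
    widx = [int(str(i).lstrip("item_")) if not isinstance(i, (int, np.integer))
            else int(i) for i in weights.index]
    missing = [c for c in codes if c not in widx]
    if missing:
        raise ValidationError(f"items missing from weights: {missing}")
    W = weights.to_numpy(dtype=float)[[widx.index(c) for c in codes]]
    X = items[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    return pd.DataFrame(Z @ W, index=items.index, columns=weights.columns)
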
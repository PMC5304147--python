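"""Orthogonal partial least squares discriminant analysis (OPLS-DA), built
from scratch on NIPALS.

The class labels are expanded to a one-hot dummy response Y.  X-variation
that is exactly uncorrelated with Y is removed first: in each orthogonal
round, a provisional PLS component is fitted, its X-loading is projected
off the span of X'Y, and the resulting orthogonal weight defines a score
that is deflated out of X.  Because each orthogonal weight is constructed
orthogonal to every column of X'Y, the orthogonal scores have exactly zero
covariance with every dummy column.  Predictive components are then fitted
on the filtered matrix by standard NIPALS PLS2.

Model quality is reported as R2X (fraction of X sum of squares captured by
the predictive + orthogonal components, with the split retained), R2Y
(fraction of the centred dummy sum of squares explained), and Q2
(cross-validated 1 - PRESS/TSS, stratified interleaved "venetian blinds"
folds).  Anything with Q2 well below R2Y is overfitted; Q2 <= R2Y always.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Preprocessor",
    "preprocess",
    "OplsModel",
    "fit_opls_da",
    "cross_validate",
    "export_scores_loadings",
]

logger = logging.getLogger(__name__)

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


# ---------------------------------------------------------------- preprocessing

@dataclass
class Preprocessor:
    """Column centring/scaling record, reusable on new data.

    ``scaling``: "uv" (unit variance, the default convention for
    metabolomic concentration blocks), "pareto" (sqrt of sd) or "center".
    """

    scaling: str
    columns: list[str]
    mean_: np.ndarray
    scale_: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        arr, cols = _as_matrix(X)
        if cols != self.columns:
            if set(self.columns) <= set(cols):
                idx = [cols.index(c) for c in self.columns]
                arr = arr[:, idx]
            else:
                raise ValueError("input lacks columns seen at fit time")
        return (arr - self.mean_) / self.scale_

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.scale_ + self.mean_


def _as_matrix(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def preprocess(
    X: pd.DataFrame | np.ndarray, scaling: str = "uv"
) -> tuple[np.ndarray, Preprocessor]:
    """Centre (and scale) columns; drop zero-variance columns with a warning."""
    if scaling not in ("uv", "pareto", "center"):
        raise ValueError("scaling must be one of 'uv', 'pareto', 'center'")
    arr, cols = _as_matrix(X)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(arr).any():
        raise ValueError("missing values are not supported")
    sd = arr.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero variance")
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        logger.warning("dropping zero-variance columns: %s", dropped)
    else:
        dropped = []
    kept_cols = [c for c, k in zip(cols, keep) if k]
    arr = arr[:, keep]
    mean = arr.mean(axis=0)
    if scaling == "uv":
        scale = sd[keep]
    elif scaling == "pareto":
        scale = np.sqrt(sd[keep])
    else:
        scale = np.ones(keep.sum())
    prep = Preprocessor(scaling, kept_cols, mean, scale, dropped)
    return (arr - mean) / scale, prep


# ------------------------------------------------------------------ NIPALS core

def _nipals_component(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One NIPALS PLS2 component (w, t, p, c) on current X, Y."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if np.linalg.norm(u) == 0:
        u = Y.sum(axis=1)
    t_old = None
    for _ in range(NIPALS_MAX_ITER):
        w = X.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise np.linalg.LinAlgError("NIPALS: X'u vanished (rank exhausted)")
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            raise np.linalg.LinAlgError("NIPALS: zero score vector")
        c = Y.T @ t / tt
        cc = float(c @ c)
        if cc == 0:
            break
        u = Y @ c / cc
        if t_old is not None and np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
            break
        t_old = t
    p = X.T @ t / float(t @ t)
    return w, t, p, c


def _nipals_pls2(
    X: np.ndarray, Y: np.ndarray, n_comp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS2 with X and Y deflation; returns W, T, P, C (columns = comps)."""
    X, Y = X.copy(), Y.copy()
    n, m = X.shape
    W = np.zeros((m, n_comp))
    T = np.zeros((n, n_comp))
    P = np.zeros((m, n_comp))
    C = np.zeros((Y.shape[1], n_comp))
    for a in range(n_comp):
        w, t, p, c = _nipals_component(X, Y)
        X -= np.outer(t, p)
        Y -= np.outer(t, c)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p, c
    return W, T, P, C


def _orthogonal_filter(
    X: np.ndarray, Y: np.ndarray, n_orth: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sequentially remove ``n_orth`` Y-orthogonal components from X.

    Each orthogonal weight is the provisional PLS loading projected off the
    column space of X'Y, which makes the resulting score exactly orthogonal
    to every response column.
    """
    X = X.copy()
    m = X.shape[1]
    Wo = np.zeros((m, n_orth))
    To = np.zeros((X.shape[0], n_orth))
    Po = np.zeros((m, n_orth))
    kept = 0
    for _ in range(n_orth):
        A = X.T @ Y
        q, r = np.linalg.qr(A)
        rank = int((np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r).max())).sum())
        basis = q[:, :rank]
        w, t, p, c = _nipals_component(X, Y)
        w_o = p - basis @ (basis.T @ p)
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            logger.warning("no Y-orthogonal variation left; stopping at %d orthogonal "
                           "components", kept)
            break
        w_o /= norm
        t_o = X @ w_o
        p_o = X.T @ t_o / float(t_o @ t_o)
        X -= np.outer(t_o, p_o)
        Wo[:, kept], To[:, kept], Po[:, kept] = w_o, t_o, p_o
        kept += 1
    return X, Wo[:, :kept], To[:, :kept], Po[:, :kept]


def _fix_signs(W, T, P, C=None):
    """Deterministic sign convention: the largest-magnitude X-loading of each
    component is positive."""
    for a in range(P.shape[1]):
        j = int(np.argmax(np.abs(P[:, a])))
        if P[j, a] < 0:
            W[:, a] *= -1
            T[:, a] *= -1
            P[:, a] *= -1
            if C is not None:
                C[:, a] *= -1


# ----------------------------------------------------------------------- model

@dataclass
class OplsModel:
    """A fitted OPLS-DA model (see module docstring for the algorithm)."""

    classes: list[str]
    preprocessor: Preprocessor
    y_mean: np.ndarray
    weights: np.ndarray        # predictive W  (variables x A)
    scores: np.ndarray         # predictive T  (samples x A)
    loadings: np.ndarray       # predictive P  (variables x A)
    y_loadings: np.ndarray     # C             (classes x A)
    ortho_weights: np.ndarray  # Wo            (variables x Ao)
    ortho_scores: np.ndarray   # To            (samples x Ao)
    ortho_loadings: np.ndarray # Po            (variables x Ao)
    r2x: float
    r2x_predictive: float
    r2x_orthogonal: float
    r2y: float
    sample_ids: list[str]
    labels: list[str]
    q2: float | None = None

    @property
    def n_predictive(self) -> int:
        return self.scores.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return self.ortho_scores.shape[1]

    def _filter_new(self, Xs: np.ndarray) -> np.ndarray:
        X = Xs.copy()
        for a in range(self.n_orthogonal):
            t_o = X @ self.ortho_weights[:, a]
            X -= np.outer(t_o, self.ortho_loadings[:, a])
        return X

    def predict_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predictive score coordinates of new samples."""
        Xf = self._filter_new(self.preprocessor.transform(X))
        R = self.weights @ np.linalg.inv(self.loadings.T @ self.weights)
        return Xf @ R

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted dummy-response matrix (samples x classes)."""
        Xf = self._filter_new(self.preprocessor.transform(X))
        R = self.weights @ np.linalg.inv(self.loadings.T @ self.weights)
        B = R @ self.y_loadings.T
        return Xf @ B + self.y_mean

    def predict_classes(self, X: pd.DataFrame | np.ndarray) -> list[str]:
        yhat = self.predict(X)
        return [self.classes[i] for i in np.argmax(yhat, axis=1)]

    def summary(self) -> dict:
        return {
            "classes": list(self.classes),
            "n_predictive": self.n_predictive,
            "n_orthogonal": self.n_orthogonal,
            "r2x": self.r2x,
            "r2x_predictive": self.r2x_predictive,
            "r2x_orthogonal": self.r2x_orthogonal,
            "r2y": self.r2y,
            "q2": self.q2,
        }


def _dummy_matrix(labels: list[str], classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not among classes {classes}")
        Y[i, index[lab]] = 1.0
    return Y


def fit_opls_da(
    X: pd.DataFrame | np.ndarray,
    labels,
    n_predictive: int | None = None,
    n_orthogonal: int = 1,
    scaling: str = "uv",
    classes: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> OplsModel:
    """Fit an OPLS-DA model.

    Parameters
    ----------
    X
        Samples x variables block (DataFrame keeps variable names).
    labels
        Class label per sample (>= 2 classes).
    n_predictive
        Number of predictive components; defaults to n_classes - 1.
    n_orthogonal
        Number of Y-orthogonal components to strip before the predictive fit.
    scaling
        Column scaling: "uv" (default), "pareto" or "center".
    classes
        Fixed class ordering (defaults to sorted unique labels); useful in
        cross-validation where a training split may miss a class.
    """
    labels = [str(l) for l in labels]
    arr, _ = _as_matrix(X)
    if len(labels) != arr.shape[0]:
        raise ValueError("labels length must match number of samples")
    if classes is None:
        classes = sorted(set(labels))
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(labels).value_counts()
    small = counts[counts < 2]
    if not small.empty:
        logger.warning("classes with < 2 samples: %s", list(small.index))
    if n_predictive is None:
        n_predictive = len(classes) - 1
    if n_predictive < 1 or n_orthogonal < 0:
        raise ValueError("need n_predictive >= 1 and n_orthogonal >= 0")

    Xs, prep = preprocess(X, scaling)
    Y = _dummy_matrix(labels, classes)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    rank = int(np.linalg.matrix_rank(Xs))
    if n_predictive + n_orthogonal >= rank:
        new_orth = max(0, rank - 1 - n_predictive)
        new_pred = min(n_predictive, max(1, rank - 1))
        logger.warning(
            "rank %d too low for %d+%d components; reducing to %d predictive, "
            "%d orthogonal", rank, n_predictive, n_orthogonal, new_pred, new_orth,
        )
        n_predictive, n_orthogonal = new_pred, new_orth

    ss_x0 = float((Xs**2).sum())
    ss_y0 = float((Yc**2).sum())

    Xf, Wo, To, Po = _orthogonal_filter(Xs, Yc, n_orthogonal)
    W, T, P, C = _nipals_pls2(Xf, Yc, n_predictive)
    _fix_signs(W, T, P, C)
    _fix_signs(Wo, To, Po)

    ss_pred = float(sum((T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) for a in range(T.shape[1])))
    ss_orth = float(sum((To[:, a] @ To[:, a]) * (Po[:, a] @ Po[:, a]) for a in range(To.shape[1])))
    y_res = Yc - T @ C.T
    r2y = 1.0 - float((y_res**2).sum()) / ss_y0

    ids = [str(s) for s in sample_ids] if sample_ids is not None else [
        str(i) for i in range(arr.shape[0])
    ]
    return OplsModel(
        classes=list(classes),
        preprocessor=prep,
        y_mean=y_mean,
        weights=W,
        scores=T,
        loadings=P,
        y_loadings=C,
        ortho_weights=Wo,
        ortho_scores=To,
        ortho_loadings=Po,
        r2x=(ss_pred + ss_orth) / ss_x0,
        r2x_predictive=ss_pred / ss_x0,
        r2x_orthogonal=ss_orth / ss_x0,
        r2y=r2y,
        sample_ids=ids,
        labels=labels,
    )


# ------------------------------------------------------------- cross-validation

def venetian_blind_folds(labels: list[str], k_folds: int) -> np.ndarray:
    """Stratified interleaved fold assignment: samples are ordered by class
    (then original position) and dealt to folds cyclically."""
    order = sorted(range(len(labels)), key=lambda i: (labels[i], i))
    folds = np.empty(len(labels), dtype=int)
    for pos, i in enumerate(order):
        folds[i] = pos % k_folds
    return folds


def cross_validate(
    X: pd.DataFrame | np.ndarray,
    labels,
    n_predictive: int | None = None,
    n_orthogonal: int = 1,
    k_folds: int = 7,
    scaling: str = "uv",
) -> float:
    """K-fold cross-validated Q2 = 1 - PRESS/TSS over the dummy matrix.

    Folds are stratified venetian blinds with a fixed ordering, so the
    result is deterministic.  The whole pipeline (scaling, orthogonal
    filtering, predictive fit) is refitted inside each fold.
    """
    labels = [str(l) for l in labels]
    arr, cols = _as_matrix(X)
    n = arr.shape[0]
    if not 2 <= k_folds <= n:
        raise ValueError("k_folds must be between 2 and n_samples")
    classes = sorted(set(labels))
    Y = _dummy_matrix(labels, classes)
    folds = venetian_blind_folds(labels, k_folds)
    press = 0.0
    frame = pd.DataFrame(arr, columns=cols)
    for k in range(k_folds):
        test = folds == k
        train = ~test
        if not test.any():
            continue
        train_labels = [l for l, tr in zip(labels, train) if tr]
        if set(train_labels) != set(classes):
            logger.warning("fold %d training split misses a class", k)
        model = fit_opls_da(
            frame.loc[train], train_labels,
            n_predictive=n_predictive, n_orthogonal=n_orthogonal,
            scaling=scaling, classes=classes,
        )
        yhat = model.predict(frame.loc[test])
        press += float(((Y[test] - yhat) ** 2).sum())
    tss = float(((Y - Y.mean(axis=0)) ** 2).sum())
    return 1.0 - press / tss


# ---------------------------------------------------------------------- export

def export_scores_loadings(model: OplsModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular scores (one row per sample) and loadings (one row per retained
    variable), CSV-ready.

    Scores columns: t1..tA (predictive), to1.. (orthogonal).  Loadings
    columns: p1..pA, w1..wA, po1.., plus the class loadings are attached to
    the scores frame's attrs for plotting layers.
    """
    A, Ao = model.n_predictive, model.n_orthogonal
    scores = pd.DataFrame({"sample_id": model.sample_ids, "class": model.labels})
    for a in range(A):
        scores[f"t{a + 1}"] = model.scores[:, a]
    for a in range(Ao):
        scores[f"to{a + 1}"] = model.ortho_scores[:, a]
    loadings = pd.DataFrame({"variable": model.preprocessor.columns})
    for a in range(A):
        loadings[f"p{a + 1}"] = model.loadings[:, a]
        loadings[f"w{a + 1}"] = model.weights[:, a]
    for a in range(Ao):
        loadings[f"po{a + 1}"] = model.ortho_loadings[:, a]
    return scores, loadings
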
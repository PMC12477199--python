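"""From-scratch PCA and OPLS-DA with VIP, cross-validated Q2 and
permutation validation.

PCA is a singular value decomposition of the column-centered (and
optionally column-scaled) sample x compound matrix.  OPLS-DA follows the
orthogonal-signal-correction construction for a single response: a NIPALS
PLS1 weight vector ``w`` proportional to ``X' y`` defines the predictive
direction; per orthogonal component, the part of the X-loading orthogonal
to ``w`` spawns an orthogonal score/loading pair that is deflated from X
before the final one-component predictive fit.  Model quality is
summarized as R2Y (training label variance explained) and Q2 (the same
quantity under stratified k-fold cross-validation); chance correlation is
assessed by refitting under random label permutations.

VIP (variable importance in projection) here is the predictive-component
VIP; with one predictive component it reduces to sqrt(p) * |w_j| for p
variables, so mean(VIP^2) = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["PcaResult", "OplsDaModel", "PermutationResult",
           "pca", "opls_da", "permutation_test", "uv_scale"]


def uv_scale(X: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-variance scale columns; returns (scaled, mean, sd).

    Uses the sample standard deviation (n-1 denominator).  Raises on
    constant columns, which have no defined UV scale.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(
            f"column {j} is constant; UV scaling is undefined — drop the "
            f"column or choose scaling='none'/'pareto'")
    return (X - mean) / sd, mean, sd


@dataclass
class PcaResult:
    scores: np.ndarray                  # samples x components
    loadings: np.ndarray                # variables x components
    explained_variance_ratio: np.ndarray


def pca(X: np.ndarray, scaling: str = "uv", n_components: int | None = None) -> PcaResult:
    """Principal component analysis by SVD of the centered, scaled matrix.

    ``scaling``: 'uv' (unit variance), 'pareto' (divide by sqrt(sd)) or
    'none' (center only).  Sign convention: the largest-magnitude loading
    of each component is positive, so results are reproducible across
    LAPACK builds.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("pca needs a 2-D matrix with >= 2 samples and >= 2 variables")
    if np.isnan(X).any():
        raise ValueError("pca input contains missing values; fill upstream")
    if scaling == "uv":
        Xs, _, _ = uv_scale(X)
    elif scaling == "pareto":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column; pareto scaling undefined — "
                             "drop the column or use scaling='none'")
        Xs = (X - X.mean(axis=0)) / np.sqrt(sd)
    elif scaling == "none":
        Xs = X - X.mean(axis=0)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")

    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    total = float(np.sum(s ** 2))
    ratio = s ** 2 / total if total > 0 else np.zeros_like(s)
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for a in range(k):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=ratio[:k])


# ---------------------------------------------------------------------------
# OPLS-DA

@dataclass
class _OplsCore:
    """Fitted directions on an already-scaled X and centered y."""

    w: np.ndarray                       # predictive weights, unit norm
    t: np.ndarray                       # predictive scores
    p: np.ndarray                       # predictive loadings
    c: float                            # y-loading
    W_orth: np.ndarray                  # variables x n_ortho
    P_orth: np.ndarray
    T_orth: np.ndarray                  # samples x n_ortho


def _fit_core(Xs: np.ndarray, yc: np.ndarray, n_ortho: int) -> _OplsCore:
    w = Xs.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("y is uncorrelated with every column; no model")
    w = w / nw
    W_o, P_o, T_o = [], [], []
    Xf = Xs
    for _ in range(n_ortho):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:            # no orthogonal variation left
            break
        w_o /= n_o
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    stack = lambda v, n: (np.column_stack(v) if v else np.empty((n, 0)))
    return _OplsCore(w=w, t=t, p=p, c=c,
                     W_orth=stack(W_o, Xs.shape[1]),
                     P_orth=stack(P_o, Xs.shape[1]),
                     T_orth=stack(T_o, Xs.shape[0]))


def _filter_new(core: _OplsCore, Xs: np.ndarray) -> np.ndarray:
    """Remove the fitted orthogonal variation from new (scaled) data."""
    Xf = np.asarray(Xs, dtype=float)
    for a in range(core.W_orth.shape[1]):
        t_o = Xf @ core.W_orth[:, a]
        Xf = Xf - np.outer(t_o, core.P_orth[:, a])
    return Xf


@dataclass
class OplsDaModel:
    """One-predictive-component OPLS-DA for a binary class contrast."""

    classes: tuple
    weights: np.ndarray
    scores_pred: np.ndarray
    loadings_pred: np.ndarray
    y_loading: float
    scores_orth: np.ndarray
    loadings_orth: np.ndarray
    weights_orth: np.ndarray
    r2y: float
    q2: float
    vip: np.ndarray
    n_ortho: int
    cv_folds: int
    seed: int | None
    x_mean: np.ndarray = field(repr=False, default=None)
    x_sd: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class score for new samples (sign gives the class)."""
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_sd
        core = _OplsCore(w=self.weights, t=self.scores_pred,
                         p=self.loadings_pred, c=self.y_loading,
                         W_orth=self.weights_orth, P_orth=self.loadings_orth,
                         T_orth=self.scores_orth)
        t = _filter_new(core, Xs) @ self.weights
        return t * self.y_loading + self.y_mean


def _encode_labels(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"opls_da needs exactly 2 classes, got {classes}")
    return np.where(y == classes[1], 1.0, -1.0), classes


def opls_da(X: np.ndarray, y, n_ortho: int = 1, cv_folds: int = 7,
            seed: int | None = 0) -> OplsDaModel:
    """Fit OPLS-DA with one predictive and ``n_ortho`` orthogonal components.

    X is UV-scaled internally; y holds two class labels, encoded -1/+1.
    Q2 comes from seeded stratified ``cv_folds``-fold cross-validation with
    per-fold rescaling and refitting; R2Y from the training residuals.
    """
    X = np.asarray(X, dtype=float)
    y_enc, classes = _encode_labels(y)
    for cls, lab in zip((-1.0, 1.0), classes):
        if int(np.sum(y_enc == cls)) < 3:
            raise ValueError(
                f"class {lab!r} has fewer than 3 samples; cross-validation "
                f"is undefined")
    if X.shape[0] != len(y_enc):
        raise ValueError("X and y have inconsistent sample counts")

    Xs, x_mean, x_sd = uv_scale(X)
    y_mean = float(y_enc.mean())
    yc = y_enc - y_mean
    core = _fit_core(Xs, yc, n_ortho)

    resid = yc - core.t * core.c
    ss_tot = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / ss_tot

    p_vars = X.shape[1]
    vip = np.sqrt(p_vars) * np.abs(core.w)   # unit-norm w → mean(VIP²) = 1

    # cross-validated Q2: stratified folds, model refitted per fold
    n_splits = min(cv_folds, int(np.min(np.bincount((y_enc > 0).astype(int)))))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=None if seed is None else int(seed) % (2 ** 31))
    press = 0.0
    for train, test in skf.split(X, y_enc):
        Xtr, mtr, str_ = uv_scale(X[train])
        ytr_mean = float(y_enc[train].mean())
        core_cv = _fit_core(Xtr, y_enc[train] - ytr_mean, n_ortho)
        Xte = (X[test] - mtr) / str_
        t_te = _filter_new(core_cv, Xte) @ core_cv.w
        yhat = t_te * core_cv.c + ytr_mean
        press += float(np.sum((y_enc[test] - yhat) ** 2))
    q2 = 1.0 - press / float(np.sum((y_enc - y_enc.mean()) ** 2))

    return OplsDaModel(classes=classes, weights=core.w, scores_pred=core.t,
                       loadings_pred=core.p, y_loading=core.c,
                       scores_orth=core.T_orth, loadings_orth=core.P_orth,
                       weights_orth=core.W_orth, r2y=r2y, q2=q2, vip=vip,
                       n_ortho=n_ortho, cv_folds=n_splits, seed=seed,
                       x_mean=x_mean, x_sd=x_sd, y_mean=y_mean)


@dataclass
class PermutationResult:
    n_perm: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    p_r2y: float
    p_q2: float


def permutation_test(X: np.ndarray, y, n_ortho: int = 1, cv_folds: int = 7,
                     n_perm: int = 200, seed: int | None = 0) -> PermutationResult:
    """Label-permutation validation of an OPLS-DA model.

    y is permuted uniformly and the full model (including cross-validated
    Q2) refitted per permutation; empirical p-values use the add-one rule
    p = (1 + #{perm >= observed}) / (n_perm + 1), so the floor is
    1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    obs = opls_da(X, y, n_ortho=n_ortho, cv_folds=cv_folds,
                  seed=int(rng.integers(2 ** 31)))
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        while len(np.unique(yp)) < 2:   # cannot happen for 2-class input
            yp = rng.permutation(y)
        m = opls_da(X, yp, n_ortho=n_ortho, cv_folds=cv_folds,
                    seed=int(rng.integers(2 ** 31)))
        r2s[i] = m.r2y
        q2s[i] = m.q2
    p_r2y = (1 + int(np.sum(r2s >= obs.r2y))) / (n_perm + 1)
    p_q2 = (1 + int(np.sum(q2s >= obs.q2))) / (n_perm + 1)
    return PermutationResult(n_perm=n_perm, observed_r2y=obs.r2y,
                             observed_q2=obs.q2, permuted_r2y=r2s,
                             permuted_q2=q2s, p_r2y=p_r2y, p_q2=p_q2)
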
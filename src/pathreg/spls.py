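"""Sparse partial least squares (SPLS) regression engine.

Regresses the pathway-gene response block Y (n x q) on the TF predictor block
X (n x p) with simultaneous dimension reduction and variable selection.  The
implementation follows the Chun-Keles surrogate formulation: at each step the
dominant left singular vector of Z = X' Y_res is soft-thresholded,

    w_i = sign(u_i) * (|u_i| - eta * max_j |u_j|)_+ ,

its support is merged into the active set A, and a dense NIPALS PLS fit with
the current number of components is refit on X restricted to A.  ``eta`` in
[0, 1) controls sparsity (eta = 0 recovers ordinary PLS); ``K`` is the number
of latent components, admissible up to min{p, (v-1)n/v} under v-fold
cross-validation.  ``tune_spls`` selects (eta, K) by mean squared prediction
error (MSPE) over a grid, preferring smaller K then larger eta on ties.

Predictors are centered and unit-scaled internally and responses centered;
reported coefficients are on the original variable scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranking import build_ranking

__all__ = [
    "SPLSModel",
    "CVResult",
    "SPLS",
    "SPLSResults",
    "nipals_pls",
    "sparse_direction",
    "spls_fit",
    "tune_spls",
    "rank_regulators_spls",
]

logger = logging.getLogger(__name__)

_DEFAULT_ETA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


def nipals_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> np.ndarray:
    """Dense PLS2 regression coefficients via NIPALS.

    ``X`` (n x p) and ``Y`` (n x q) are assumed centered.  Returns the p x q
    coefficient matrix B such that ``Y ~ X @ B``.  Deflation of Y may exhaust
    its variance before ``n_components`` steps; the fit then stops early at
    the achieved number of components (logged).
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] != 1:
        Y = Y.T
    n, p = X.shape
    q = Y.shape[1]
    if n_components < 1:
        raise ValueError("need at least one component")
    n_components = min(n_components, p, n - 1)

    Xd = X.copy()
    Yd = Y.copy()
    y_scale0 = np.linalg.norm(Y)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((q, n_components))
    achieved = 0
    for k in range(n_components):
        if np.linalg.norm(Yd) <= 1e-12 * max(y_scale0, 1.0):
            logger.info("NIPALS: Y variance exhausted after %d component(s)", achieved)
            break
        # start from the Y column with the largest remaining variance
        u = Yd[:, np.argmax((Yd**2).sum(axis=0))].copy()
        w = np.zeros(p)
        for _ in range(500):
            w_new = Xd.T @ u
            norm = np.linalg.norm(w_new)
            if norm <= 1e-15:
                break
            w_new /= norm
            t = Xd @ w_new
            tt = t @ t
            if tt <= 1e-300:
                break
            c = Yd.T @ t / tt
            denom = c @ c
            if denom <= 1e-300:
                break
            u_new = Yd @ c / denom
            converged = np.linalg.norm(w_new - w) < 1e-12
            w, u = w_new, u_new
            if converged:
                break
        if np.linalg.norm(w) <= 1e-15:
            break
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-300:
            break
        p_load = Xd.T @ t / tt
        c = Yd.T @ t / tt
        Xd -= np.outer(t, p_load)
        Yd -= np.outer(t, c)
        W[:, k], P[:, k], C[:, k] = w, p_load, c
        achieved += 1
    if achieved == 0:
        return np.zeros((p, q))
    W, P, C = W[:, :achieved], P[:, :achieved], C[:, :achieved]
    return W @ np.linalg.solve(P.T @ W, C.T)


def sparse_direction(Z: np.ndarray, eta: float) -> np.ndarray:
    """Soft-thresholded dominant left singular vector of ``Z`` (p x q).

    Components smaller in magnitude than ``eta`` times the largest are zeroed;
    survivors are shrunk toward zero and the result is renormalized to unit
    length.  ``eta = 0`` returns the singular vector unchanged.
    """
    if not 0.0 <= eta < 1.0:
        raise ValueError("eta should have a value between 0 and 1")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.ndim != 2:
        raise ValueError("Z must be a p x q matrix")
    if not np.any(Z):
        raise ValueError("Z is identically zero")
    if Z.shape[1] == 1:
        u = Z[:, 0] / np.linalg.norm(Z[:, 0])
    else:
        u_mat, _, _ = np.linalg.svd(Z, full_matrices=False)
        u = u_mat[:, 0]
    # deterministic sign: largest-magnitude component positive
    pivot = np.argmax(np.abs(u))
    if u[pivot] < 0:
        u = -u
    threshold = eta * np.max(np.abs(u))
    w = np.sign(u) * np.maximum(np.abs(u) - threshold, 0.0)
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    return w


@dataclass
class SPLSModel:
    """Fitted sparse PLS state.

    ``coefficients`` (p x q) is on the original variable scale; rows outside
    the active set are exactly zero.  ``directions`` holds the K sparse weight
    vectors (length p) in fitting order.
    """

    eta: float
    K: int
    active_set: np.ndarray
    directions: list
    coefficients: np.ndarray
    intercept: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    n_components_used: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.intercept


def _preprocess(X, Y, scale_x: bool, center: bool):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching sample counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("inputs must be finite")
    n, p = X.shape
    x_center = X.mean(axis=0) if center else np.zeros(p)
    y_center = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    Xc = X - x_center
    Yc = Y - y_center
    if scale_x:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale <= 0] = 1.0
    else:
        x_scale = np.ones(p)
    return Xc / x_scale, Yc, x_center, x_scale, y_center


def _spls_path(Xs, Yc, eta: float, n_components: int):
    """Active-set SPLS on standardized data; yields (B_std, A, w) per step."""
    n, p = Xs.shape
    path = []
    active: np.ndarray = np.zeros(0, dtype=int)
    B = np.zeros((p, Yc.shape[1]))
    directions = []
    for k in range(1, n_components + 1):
        Y_res = Yc - Xs @ B
        Z = Xs.T @ Y_res
        if not np.any(np.abs(Z) > 1e-12 * max(1.0, np.abs(Yc).max())):
            if k == 1:
                raise ValueError("response uncorrelated with all predictors")
            path.append((B.copy(), active.copy(), None))
            continue
        w = sparse_direction(Z, eta)
        support = np.flatnonzero(w)
        if support.size == 0 and k == 1:
            raise ValueError("response uncorrelated with all predictors")
        directions.append(w)
        active = np.union1d(active, support).astype(int)
        B = np.zeros((p, Yc.shape[1]))
        n_comp = min(k, active.size, n - 1)
        B[active] = nipals_pls(Xs[:, active], Yc, n_comp)
        path.append((B.copy(), active.copy(), w))
    return path, directions


def spls_fit(
    X,
    Y,
    eta: float,
    n_components: int,
    scale_x: bool = True,
    center: bool = True,
) -> SPLSModel:
    """Fit sparse PLS with sparsity ``eta`` and ``n_components`` components."""
    if not 0.0 <= eta < 1.0:
        raise ValueError("eta should have a value between 0 and 1")
    if n_components < 1:
        raise ValueError("need at least one component")
    Xs, Yc, x_center, x_scale, y_center = _preprocess(X, Y, scale_x, center)
    if Xs.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    path, directions = _spls_path(Xs, Yc, eta, n_components)
    B_std, active, _ = path[-1]
    coefficients = B_std / x_scale[:, None]
    intercept = y_center - x_center @ coefficients
    return SPLSModel(
        eta=eta,
        K=n_components,
        active_set=active,
        directions=directions,
        coefficients=coefficients,
        intercept=intercept,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        n_components_used=len(directions),
    )


@dataclass
class CVResult:
    """Cross-validation grid and the selected (eta, K)."""

    grid: pd.DataFrame
    best_eta: float
    best_K: int
    v: int
    seed: int


def max_components(n: int, p: int, v: int) -> int:
    """Admissible upper bound for K: min{p, (v-1)n/v}."""
    return int(min(p, (v - 1) * n // v))


def _cv_folds(n: int, v: int, seed: int):
    if v < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), v)
    if min(f.size for f in folds) < 2:
        raise ValueError("a fold has fewer than 2 samples; use fewer folds")
    return folds


def tune_spls(
    X,
    Y,
    eta_grid=None,
    K_grid=None,
    v: int = 10,
    seed: int = 0,
    scale_x: bool = True,
    center: bool = True,
) -> CVResult:
    """Select (eta, K) by v-fold cross-validated MSPE over a grid.

    MSPE(eta, K) is the mean over folds of ||Y_test - Yhat_test||_F^2 /
    (n_test * q).  Ties (within relative 1e-9) prefer smaller K, then larger
    eta — the sparser, simpler model at equal prediction error.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    q = Y.shape[1]
    k_cap = max_components(n, p, v)
    if eta_grid is None:
        eta_grid = _DEFAULT_ETA_GRID
    if K_grid is None:
        K_grid = range(1, min(k_cap, 10) + 1)
    eta_grid = [float(e) for e in eta_grid]
    K_grid = sorted(int(k) for k in K_grid)
    if not eta_grid or not K_grid:
        raise ValueError("eta and K grids must be nonempty")
    for eta in eta_grid:
        if not 0.0 <= eta < 1.0:
            raise ValueError("eta should have a value between 0 and 1")
    if K_grid[-1] > k_cap:
        raise ValueError(f"K must satisfy 1 <= K <= min{{p, (v-1)n/v}} = {k_cap}")
    if K_grid[0] < 1:
        raise ValueError("K must be >= 1")

    folds = _cv_folds(n, v, seed)
    k_max = K_grid[-1]
    sse = np.zeros((len(eta_grid), len(K_grid)))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        X_tr, Y_tr = X[mask], Y[mask]
        X_te, Y_te = X[fold], Y[fold]
        Xs, Yc, x_center, x_scale, y_center = _preprocess(X_tr, Y_tr, scale_x, center)
        denom = fold.size * q
        for i, eta in enumerate(eta_grid):
            path, _ = _spls_path(Xs, Yc, eta, k_max)
            for j, k in enumerate(K_grid):
                B_std = path[k - 1][0]
                coef = B_std / x_scale[:, None]
                pred = (X_te - x_center) @ coef + y_center
                sse[i, j] += ((Y_te - pred) ** 2).sum() / denom
    mspe = sse / len(folds)

    grid = pd.DataFrame(
        [
            {"eta": eta, "K": k, "mspe": mspe[i, j]}
            for i, eta in enumerate(eta_grid)
            for j, k in enumerate(K_grid)
        ]
    )
    best = mspe.min()
    tol = 1e-9 * max(best, 1e-300)
    candidates = [
        (k, -eta, i, j)
        for i, eta in enumerate(eta_grid)
        for j, k in enumerate(K_grid)
        if mspe[i, j] <= best + tol
    ]
    _, _, i_best, j_best = min(candidates)
    return CVResult(
        grid=grid,
        best_eta=eta_grid[i_best],
        best_K=K_grid[j_best],
        v=v,
        seed=seed,
    )


def rank_regulators_spls(
    model: SPLSModel, tf_ids, gene_ids, top_k: int
) -> pd.DataFrame:
    """Rank TFs from the sparse coefficient matrix.

    Connectivity is the number of responses with a nonzero coefficient;
    strength is the sum of absolute coefficients.  All-zero predictors are
    excluded.  Ordering and tie-breaks match the TGMI ranking.
    """
    B = np.asarray(model.coefficients)
    if B.shape != (len(tf_ids), len(gene_ids)):
        raise ValueError("coefficient matrix does not match the given ID axes")
    nonzero = np.abs(B) > 0
    connectivity = nonzero.sum(axis=1)
    strength = np.abs(B).sum(axis=1)
    keep = connectivity > 0
    records = pd.DataFrame(
        {
            "tf_id": np.asarray(list(tf_ids))[keep],
            "connectivity": connectivity[keep],
            "strength": strength[keep],
        }
    )
    return build_ranking(records, top_k, "spls")


class SPLS:
    """Sparse PLS model of a pathway response block on a TF predictor block.

    Parameters
    ----------
    X, Y
        Samples x predictors and samples x responses arrays, or genes x
        samples ``ExpressionMatrix``/DataFrame blocks (transposed internally).
    """

    def __init__(self, X, Y, predictor_ids=None, response_ids=None,
                 scale_x: bool = True, center: bool = True):
        from .io import ExpressionMatrix

        if isinstance(X, ExpressionMatrix):
            predictor_ids = predictor_ids or list(X.gene_ids)
            X = X.values.T
        if isinstance(Y, ExpressionMatrix):
            response_ids = response_ids or list(Y.gene_ids)
            Y = Y.values.T
        if isinstance(X, pd.DataFrame):
            predictor_ids = predictor_ids or list(X.index)
            X = X.to_numpy(dtype=float).T
        if isinstance(Y, pd.DataFrame):
            response_ids = response_ids or list(Y.index)
            Y = Y.to_numpy(dtype=float).T
        self.X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self.Y = Y[:, None] if Y.ndim == 1 else Y
        self.predictor_ids = (
            list(predictor_ids)
            if predictor_ids is not None
            else [f"x{i}" for i in range(self.X.shape[1])]
        )
        self.response_ids = (
            list(response_ids)
            if response_ids is not None
            else [f"y{i}" for i in range(self.Y.shape[1])]
        )
        self.scale_x = scale_x
        self.center = center

    @classmethod
    def from_expression(cls, expr, spec, **kwargs) -> "SPLS":
        from .io import assemble_design

        tf_m, path_m, _ = assemble_design(expr, spec)
        return cls(tf_m, path_m, **kwargs)

    def fit(self, eta: float, K: int, top_k: int = 50) -> "SPLSResults":
        model = spls_fit(self.X, self.Y, eta, K, self.scale_x, self.center)
        ranking = rank_regulators_spls(
            model, self.predictor_ids, self.response_ids, top_k
        )
        return SPLSResults(self, model, ranking, cv=None)

    def fit_cv(
        self,
        eta_grid=None,
        K_grid=None,
        v: int = 10,
        seed: int = 0,
        top_k: int = 50,
    ) -> "SPLSResults":
        """Tune (eta, K) by cross-validated MSPE, then fit at the optimum."""
        cv = tune_spls(
            self.X, self.Y, eta_grid, K_grid, v, seed, self.scale_x, self.center
        )
        model = spls_fit(
            self.X, self.Y, cv.best_eta, cv.best_K, self.scale_x, self.center
        )
        ranking = rank_regulators_spls(
            model, self.predictor_ids, self.response_ids, top_k
        )
        return SPLSResults(self, model, ranking, cv=cv)


@dataclass
class SPLSResults:
    """Fitted SPLS state with the TF ranking and optional CV trace."""

    model_spec: SPLS
    model: SPLSModel
    ranking: pd.DataFrame
    cv: CVResult | None = None

    @property
    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.model.coefficients,
            index=self.model_spec.predictor_ids,
            columns=self.model_spec.response_ids,
        )

    def summary(self) -> str:
        n, p = self.model_spec.X.shape
        q = self.model_spec.Y.shape[1]
        lines = [
            "Sparse partial least squares (SPLS)",
            f"  samples: {n}  predictors: {p}  responses: {q}",
            f"  eta={self.model.eta}  K={self.model.K}  "
            f"active predictors: {self.model.active_set.size}",
        ]
        if self.cv is not None:
            best = self.cv.grid.loc[
                (self.cv.grid["eta"] == self.cv.best_eta)
                & (self.cv.grid["K"] == self.cv.best_K),
                "mspe",
            ].iloc[0]
            lines.append(
                f"  {self.cv.v}-fold CV: best MSPE {best:.6g} at "
                f"(eta={self.cv.best_eta}, K={self.cv.best_K})"
            )
        lines += ["", "Top regulators by connectivity:"]
        head = self.ranking.head(10)
        if head.empty:
            lines.append("  (no active predictors)")
        else:
            lines.append(
                head.to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                ).replace("\n", "\n  ")
            )
        return "\n".join(lines)
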
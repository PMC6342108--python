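"""Maximum-likelihood-population-effects (MLPE) regression on distance
matrices, with AIC/AICc model comparison.

Pairwise distance regressions violate ordinary-regression independence:
two pairs sharing an individual are correlated.  The MLPE model adds a
random effect per individual,

    y_ij = b0 + sum_m b_m x_m,ij + u_i + u_j + e_ij,
    u_i ~ N(0, s2_u) iid,   e_ij ~ N(0, s2_e) iid,

so cov(y) = s2_e I + s2_u Z Z^T with Z the pair-to-individual incidence
matrix (two unit entries per row).  The exact Gaussian likelihood is
maximized by profiling: for a fixed variance ratio phi = s2_u / s2_e the
GLS estimates of beta and s2_e are closed-form via the Woodbury identity
(only an n_individuals-sized system is ever factorized), leaving a smooth
one-dimensional profile in log(phi) for scalar optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .popgen import PairwiseMatrix

__all__ = [
    "MlpeFit",
    "ModelComparison",
    "MLPERegressor",
    "fit_mlpe",
    "information_criteria",
    "k_for_model",
]

_LOG2PI = np.log(2.0 * np.pi)


def k_for_model(model_type: str, n_surfaces: int = 1, n_categories: int = 2) -> int:
    """Parameter-count convention used for AIC/AICc.

    null = 1 (intercept); distance = 2; categorical = categories + 1;
    single continuous surface = 4 (two transformation parameters, equation
    choice, intercept); composite = 2 * n_surfaces + 1.
    """
    if model_type == "null":
        return 1
    if model_type == "distance":
        return 2
    if model_type == "categorical":
        return n_categories + 1
    if model_type == "continuous":
        return 4
    if model_type == "composite":
        return 2 * n_surfaces + 1
    raise ValueError(f"unknown model type {model_type!r}")


@dataclass
class MlpeFit:
    """Fitted MLPE model with information criteria."""

    beta0: float
    beta: np.ndarray
    sigma2_u: float
    sigma2_eps: float
    loglik: float
    n_ind: int
    n_pairs: int
    k: int
    AIC: float
    AICc: float
    beta_se: np.ndarray = field(default_factory=lambda: np.array([]))
    name: str = "model"

    def summary_row(self) -> dict:
        return {
            "Surface": self.name,
            "k": self.k,
            "AIC": self.AIC,
            "AICc": self.AICc,
            "loglik": self.loglik,
            "sigma2_u": self.sigma2_u,
            "sigma2_eps": self.sigma2_eps,
        }


@dataclass
class ModelComparison:
    """AICc ranking of a candidate set: delta, Akaike weight, rank."""

    table: pd.DataFrame  # columns: name, k, AIC, AICc, delta_AICc, weight, rank

    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()

    def best(self) -> str:
        return str(self.table.loc[self.table["rank"] == 1, "name"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _pair_incidence_counts(pairs: np.ndarray, n_ind: int):
    """Return Z^T Z (dense, n x n) for the given pair index."""
    ztz = np.zeros((n_ind, n_ind))
    for i, j in pairs:
        ztz[i, i] += 1
        ztz[j, j] += 1
        ztz[i, j] += 1
        ztz[j, i] += 1
    return ztz


class MLPERegressor:
    """Exact-ML MLPE mixed model for pairwise distance regressions.

    Parameters
    ----------
    standardize : bool
        Center/scale each predictor over the pairs before fitting (the
        convention for resistance distances; the response is left as-is).
    n_restarts : int
        Independent starts of the profile optimization (the profile is
        unimodal in practice; restarts guard against plateau edge cases).

    Attributes (after :meth:`fit`)
    ------------------------------
    beta0_, beta_, sigma2_u_, sigma2_eps_, loglik_ : floats / arrays
    beta_se_ : ndarray
        GLS standard errors of the slopes (same predictor scaling as fit).
    """

    def __init__(self, standardize: bool = True, n_restarts: int = 3,
                 tol: float = 1e-10, fix_phi: float | None = None):
        self.standardize = standardize
        self.n_restarts = n_restarts
        self.tol = tol
        self.fix_phi = fix_phi  # pin the variance ratio (0 = plain OLS)

    def get_params(self, deep: bool = True) -> dict:
        return {"standardize": self.standardize, "n_restarts": self.n_restarts,
                "tol": self.tol}

    def set_params(self, **params) -> "MLPERegressor":
        for key, val in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    # -- likelihood machinery ------------------------------------------------

    def _profile(self, phi: float):
        """Profile negative log-likelihood at variance ratio phi >= 0.

        Uses V = s2_e (I + phi Z Z^T); Woodbury gives
        (I + phi ZZ^T)^{-1} = I - Z (ZtZ + I/phi)^{-1} Z^T  (phi > 0),
        and Sylvester log|I + phi ZZ^T| = log|I_n + phi ZtZ|.
        """
        X, y, pairs, n = self._X, self._y, self._pairs, self._n_ind
        npairs = len(y)
        if phi <= 0:
            xtvx = X.T @ X
            xtvy = X.T @ y
            logdet = 0.0

            def vinv(m):
                return m
        else:
            a = self._ztz * phi + np.eye(n)
            chol = np.linalg.cholesky(a)
            logdet = 2.0 * np.log(np.diag(chol)).sum()

            def vinv(m):
                zt_m = self._zt_apply(m)
                w = np.linalg.solve(a, zt_m * phi)
                return m - self._z_apply(w)

            xtvx = X.T @ vinv(X)
            xtvy = X.T @ vinv(y)
        beta = np.linalg.solve(xtvx, xtvy)
        resid = y - X @ beta
        quad = float(resid @ vinv(resid))
        quad = max(quad, 1e-300)
        s2e = quad / npairs
        nll = 0.5 * (npairs * (_LOG2PI + np.log(s2e) + 1.0) + logdet)
        return nll, beta, s2e, xtvx

    def _z_apply(self, w: np.ndarray) -> np.ndarray:
        """Z @ w for w of shape (n_ind,) or (n_ind, p)."""
        return w[self._pairs[:, 0]] + w[self._pairs[:, 1]]

    def _zt_apply(self, m: np.ndarray) -> np.ndarray:
        """Z^T @ m for m of shape (n_pairs,) or (n_pairs, p)."""
        out_shape = (self._n_ind,) + m.shape[1:]
        out = np.zeros(out_shape)
        np.add.at(out, self._pairs[:, 0], m)
        np.add.at(out, self._pairs[:, 1], m)
        return out

    # -- public API -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, pairs: np.ndarray):
        """Fit the model.

        Parameters
        ----------
        X : (n_pairs, p) predictor values per pair (may be p = 0 for the
            null model).
        y : (n_pairs,) response per pair.
        pairs : (n_pairs, 2) integer individual indices of each pair.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        y = np.asarray(y, dtype=float)
        pairs = np.asarray(pairs, dtype=int)
        n_ind = int(pairs.max()) + 1 if len(pairs) else 0
        p = X.shape[1]

        if p:
            sd = X.std(axis=0, ddof=0)
            if (sd == 0).any():
                raise ValueError("constant predictor column")
            if self.standardize:
                self._x_mean = X.mean(axis=0)
                self._x_sd = sd
                X = (X - self._x_mean) / self._x_sd
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X]))
            if rank < p + 1:
                raise ValueError("perfectly collinear predictors")
        Xd = np.column_stack([np.ones(len(y)), X]) if p else np.ones((len(y), 1))

        self._X, self._y, self._pairs, self._n_ind = Xd, y, pairs, n_ind
        self._ztz = _pair_incidence_counts(pairs, n_ind)

        if self.fix_phi is not None:
            phi = float(self.fix_phi)
            nll = self._profile(phi)[0]
        else:
            best = None
            brackets = [(-12.0, 4.0), (-6.0, 8.0), (-2.0, 12.0)][: self.n_restarts]
            for lo, hi in brackets:
                res = minimize_scalar(
                    lambda t: self._profile(np.exp(t))[0],
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                if best is None or res.fun < best.fun:
                    best = res
            # compare against the boundary phi = 0 (no individual effect)
            nll0 = self._profile(0.0)[0]
            if nll0 <= best.fun + self.tol:
                phi = 0.0
                nll = nll0
            else:
                phi = float(np.exp(best.x))
                nll = float(best.fun)

        _, beta, s2e, xtvx = self._profile(phi)
        self.loglik_ = -nll
        self.beta0_ = float(beta[0])
        self.beta_ = beta[1:].copy()
        self.sigma2_eps_ = float(s2e)
        self.sigma2_u_ = float(phi * s2e)
        cov = np.linalg.inv(xtvx) * s2e
        self.beta_se_ = np.sqrt(np.diag(cov))[1:]
        self.n_ind_ = n_ind
        self.n_pairs_ = len(y)
        del self._X, self._y
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Marginal (fixed-effect) prediction for new pair predictors."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.standardize and len(self.beta_):
            X = (X - self._x_mean) / self._x_sd
        return self.beta0_ + X @ self.beta_ if len(self.beta_) else np.full(
            len(X), self.beta0_
        )


def fit_mlpe(
    y: PairwiseMatrix,
    X: list[PairwiseMatrix] | None = None,
    k_override: int | None = None,
    model_type: str = "continuous",
    n_surfaces: int = 1,
    n_categories: int = 2,
    name: str = "model",
) -> MlpeFit:
    """Fit an MLPE model of one distance matrix on others.

    All matrices must share labels in the same order.  Predictors are
    standardized over the lower-triangle pairs.  AIC = -2l + 2k and
    AICc = AIC + 2k(k+1)/(n_ind - k - 1), with k given by the model-type
    convention unless ``k_override`` is supplied.
    """
    X = X or []
    for xm in X:
        if xm.labels != y.labels:
            raise ValueError("predictor matrix labels do not match response")
    pairs = y.pair_index()
    yv = y.lower_triangle()
    if X:
        xv = np.column_stack([xm.lower_triangle() for xm in X])
    else:
        xv = np.empty((len(yv), 0))
        if model_type == "continuous":
            model_type = "null"
    reg = MLPERegressor().fit(xv, yv, pairs)
    n_ind = y.n
    if k_override is not None:
        k = int(k_override)
    else:
        k = k_for_model(model_type, n_surfaces=n_surfaces,
                        n_categories=n_categories)
    aic = -2.0 * reg.loglik_ + 2.0 * k
    denom = n_ind - k - 1
    aicc = aic + (2.0 * k * (k + 1) / denom if denom > 0 else np.inf)
    return MlpeFit(
        beta0=reg.beta0_,
        beta=reg.beta_,
        sigma2_u=reg.sigma2_u_,
        sigma2_eps=reg.sigma2_eps_,
        loglik=reg.loglik_,
        n_ind=n_ind,
        n_pairs=reg.n_pairs_,
        k=k,
        AIC=aic,
        AICc=aicc,
        beta_se=reg.beta_se_,
        name=name,
    )


def information_criteria(fits: list[MlpeFit], criterion: str = "AICc") -> ModelComparison:
    """Delta-AICc, Akaike weights and ranks for a set of candidate fits."""
    if not fits:
        raise ValueError("empty model list")
    vals = np.array([getattr(f, criterion) for f in fits])
    delta = vals - vals.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    order = np.argsort(vals, kind="stable")
    rank = np.empty(len(fits), dtype=int)
    rank[order] = np.arange(1, len(fits) + 1)
    table = pd.DataFrame(
        {
            "name": [f.name for f in fits],
            "k": [f.k for f in fits],
            "AIC": [f.AIC for f in fits],
            "AICc": [f.AICc for f in fits],
            f"delta_{criterion}": delta,
            "weight": w,
            "rank": rank,
        }
    )
    return ModelComparison(table)
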
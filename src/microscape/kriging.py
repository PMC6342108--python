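"""Ordinary kriging interpolation of point measurements.

Humidity, temperature and elevation in the study design are measured at
trap stations and interpolated to the full analysis extent.  Ordinary
kriging is the best linear unbiased predictor under a stationary variogram;
with a zero nugget it interpolates the data exactly, and far from all data
it relaxes toward the sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .surfaces import GridSurface, SamplePoints

__all__ = ["VariogramModel", "OrdinaryKriging", "krige_surface", "fit_variogram"]


@dataclass
class VariogramModel:
    """An isotropic variogram: nugget + partial sill rising over a range."""

    family: str = "exponential"  # or "spherical"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in {"exponential", "spherical"}:
            raise ValueError(f"unknown variogram family '{self.family}'")
        if self.nugget < 0 or self.partial_sill <= 0 or self.range_ <= 0:
            raise ValueError("variogram requires nugget >= 0, sill > 0, range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            gamma = self.partial_sill * (1.0 - np.exp(-3.0 * h / self.range_))
        else:  # spherical
            ratio = np.minimum(h / self.range_, 1.0)
            gamma = self.partial_sill * (1.5 * ratio - 0.5 * ratio**3)
        out = np.where(h > 0, self.nugget + gamma, 0.0)
        return out


def _empirical_variogram(pts: SamplePoints, bin_width: float):
    xy = np.column_stack([pts.x, pts.y])
    d = cdist(xy, xy)
    iu = np.triu_indices(len(pts), k=1)
    dists = d[iu]
    sq = 0.5 * (pts.values[:, None] - pts.values[None, :]) ** 2
    semiv = sq[iu]
    edges = np.arange(0, dists.max() + bin_width, bin_width)
    mids, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dists > lo) & (dists <= hi)
        if sel.sum() >= 3:
            mids.append(0.5 * (lo + hi))
            gammas.append(semiv[sel].mean())
            counts.append(int(sel.sum()))
    return np.array(mids), np.array(gammas), np.array(counts)


def fit_variogram(
    pts: SamplePoints, family: str = "exponential", bin_width: float | None = None
) -> VariogramModel:
    """Fit a variogram by weighted least squares on the empirical semivariogram.

    Bins are weighted by their pair counts.  The nugget is constrained to be
    non-negative; a degenerate fit falls back to a pure-sill model at the
    sample variance and half the maximum pair distance.
    """
    if bin_width is None:
        xy = np.column_stack([pts.x, pts.y])
        span = max(np.ptp(pts.x), np.ptp(pts.y))
        bin_width = span / 12 if span > 0 else 1.0
    mids, gammas, counts = _empirical_variogram(pts, bin_width)
    var = pts.values.var()
    fallback = VariogramModel(
        family, 0.0, max(var, 1e-12), max(mids.max() if mids.size else 1.0, 1e-6)
    )
    if mids.size < 3:
        return fallback

    def resid(theta):
        nugget, psill, rng = np.exp(theta)
        model = VariogramModel(family, nugget - 1e-12 if nugget < 1e-12 else nugget,
                               psill, rng)
        return np.sqrt(counts) * (model(mids) - gammas)

    x0 = np.log([max(gammas[0] * 0.1, 1e-8), max(var, 1e-8), mids[-1] / 2])
    try:
        sol = least_squares(resid, x0, method="lm", max_nfev=200)
        nugget, psill, rng = np.exp(sol.x)
        return VariogramModel(family, nugget, psill, rng)
    except Exception:
        return fallback


class OrdinaryKriging(RegressorMixin, BaseEstimator):
    """Ordinary kriging with an exponential or spherical variogram.

    Parameters
    ----------
    variogram : VariogramModel or "auto"
        With ``"auto"`` the variogram is fitted by weighted least squares on
        the empirical semivariogram at fit time.
    family : str
        Variogram family used when fitting automatically.

    Attributes
    ----------
    variogram_ : VariogramModel
        The variogram used for prediction.
    X_ : ndarray of shape (n, 2)
        Training coordinates.
    """

    def __init__(self, variogram="auto", family: str = "exponential"):
        self.variogram = variogram
        self.family = family

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_points, 2) coordinates")
        if len(X) < 2:
            raise ValueError("kriging requires at least 2 points")
        # duplicate coordinates make the kriging system singular
        _, idx, cnt = np.unique(X, axis=0, return_index=True, return_counts=True)
        if (cnt > 1).any():
            dupes = X[np.sort(idx[cnt > 1])]
            raise ValueError(f"duplicate point coordinates: {dupes.tolist()}")
        self.X_ = X
        self.y_ = y
        if self.variogram == "auto":
            pts = SamplePoints(X[:, 0], X[:, 1], y)
            self.variogram_ = fit_variogram(pts, self.family)
        else:
            self.variogram_ = self.variogram
        n = len(X)
        gamma = self.variogram_(cdist(X, X))
        # ordinary kriging system with Lagrange multiplier row/column
        a = np.ones((n + 1, n + 1))
        a[:n, :n] = gamma
        a[n, n] = 0.0
        self._lhs = a
        return self

    def predict(self, X, return_weights: bool = False):
        check_is_fitted(self, "variogram_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(self.X_)
        g = self.variogram_(cdist(X, self.X_))
        rhs = np.ones((X.shape[0], n + 1))
        rhs[:, :n] = g
        try:
            w = np.linalg.solve(self._lhs, rhs.T).T
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular kriging system") from exc
        pred = w[:, :n] @ self.y_
        if return_weights:
            return pred, w[:, :n]
        return pred


def krige_surface(
    pts: SamplePoints,
    grid: GridSurface,
    model: VariogramModel | str = "auto",
    family: str = "exponential",
) -> GridSurface:
    """Interpolate point measurements onto the geometry of ``grid``.

    ``grid`` supplies only the target geometry (shape, cell size, origin,
    mask); its values are ignored.
    """
    ok = OrdinaryKriging(variogram=model, family=family)
    ok.fit(np.column_stack([pts.x, pts.y]), pts.values)
    rows, cols = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    x0, y0 = grid.origin
    xs = x0 + (cols.ravel() + 0.5) * grid.cell_size
    ys = y0 - (rows.ravel() + 0.5) * grid.cell_size
    sel = ~grid.mask.ravel()
    vals = np.full(grid.n_rows * grid.n_cols, np.nan)
    vals[sel] = ok.predict(np.column_stack([xs[sel], ys[sel]]))
    return GridSurface(
        vals.reshape(grid.shape), grid.cell_size, grid.origin, mask=grid.mask.copy()
    )
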
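"""Resistance-surface transformations and commute-time distances.

An environmental surface is turned into a resistance hypothesis with one of
eight curves: two families (monomolecular, a saturating exponential
``1 - exp(-b x)``; Ricker, the hump-shaped ``x exp(-b x)``) crossed with
optional *reverse* (mirror the input axis) and *inverse* (mirror the output
axis) modes.  Input values are first rescaled to [0, 10]; the transformed
values are rescaled to [1, r], so ``r`` is the maximum resistance and the
landscape minimum is fixed at 1.

Connectivity between sample locations is the commute distance of the random
walk on the 8-neighbor raster graph, ``C_ij = vol(G) * R_eff(i, j)`` --
functionally equivalent to circuit-theory (Circuitscape) resistance
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .popgen import PairwiseMatrix
from .surfaces import GridSurface

__all__ = [
    "TransformSpec",
    "FAMILIES",
    "MODES",
    "transform_surface",
    "combine_surfaces",
    "commute_distance_matrix",
    "raster_graph",
]

FAMILIES = ("monomolecular", "ricker")
MODES = ("plain", "inverse", "reverse", "inverse-reverse")

R_CAP_DEFAULT = 2500.0
_X_MAX = 10.0  # input rescale upper bound


@dataclass
class TransformSpec:
    """One of the eight resistance transformations.

    shape ``b`` controls curvature; magnitude ``r`` is the maximum
    resistance after rescaling (resistance values are explored up to a cap,
    2,500 by default).
    """

    family: str = "monomolecular"
    mode: str = "plain"
    shape: float = 0.5
    magnitude: float = 100.0
    r_cap: float = R_CAP_DEFAULT

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not self.shape > 0:
            raise ValueError("shape b must be > 0")
        if not (1.0 < self.magnitude <= self.r_cap):
            raise ValueError(f"magnitude r must be in (1, {self.r_cap}]")

    @property
    def name(self) -> str:
        return f"{self.mode} {self.family}" if self.mode != "plain" else self.family

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mode": self.mode,
            "shape": self.shape,
            "magnitude": self.magnitude,
        }


def _base_curve(x: np.ndarray, family: str, b: float) -> np.ndarray:
    if family == "monomolecular":
        return 1.0 - np.exp(-b * x)
    # Ricker: hump-shaped with pre-rescale maximum at x = 1/b
    return x * np.exp(-b * x)


def transform_curve(x01: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply the transformation to values already rescaled to [0, 10].

    Returns values rescaled to [1, r] using the min/max over ``x01``.
    """
    x = np.asarray(x01, dtype=float)
    if spec.mode in ("reverse", "inverse-reverse"):
        x = _X_MAX - x
    y = _base_curve(x, spec.family, spec.shape)
    if spec.mode in ("inverse", "inverse-reverse"):
        y = (np.nanmax(y) + np.nanmin(y)) - y
    lo, hi = np.nanmin(y), np.nanmax(y)
    if hi - lo <= 0:
        return np.ones_like(y)
    return 1.0 + (y - lo) / (hi - lo) * (spec.magnitude - 1.0)


def transform_surface(s: GridSurface, spec: TransformSpec) -> GridSurface:
    """Transform an environmental surface into a resistance surface.

    The result has minimum exactly 1 and maximum exactly ``r`` over
    unmasked cells.  Raises on a constant input surface, where the
    transformation is undefined.
    """
    vals = s.unmasked()
    lo, hi = vals.min(), vals.max()
    if hi - lo <= 0:
        raise ValueError("transformation undefined on zero range (flat surface)")
    x01 = (s.values - lo) / (hi - lo) * _X_MAX
    x01 = np.where(s.mask, np.nan, x01)
    flat = x01[~s.mask]
    y = np.full_like(x01, np.nan)
    y[~s.mask] = transform_curve(flat, spec)
    return s.copy_with(y)


def combine_surfaces(transformed: list[GridSurface]) -> GridSurface:
    """Additive composite of transformed surfaces, rescaled to minimum 1."""
    if len(transformed) < 2:
        raise ValueError("composite requires at least 2 surfaces")
    base = transformed[0]
    total = np.zeros_like(base.values)
    mask = base.mask.copy()
    for t in transformed:
        if t.shape != base.shape:
            raise ValueError("surfaces must share geometry")
        mask |= t.mask
        total = total + np.where(t.mask, 0.0, t.values)
    total = np.where(mask, np.nan, total)
    shift = 1.0 - np.nanmin(total)
    return base.copy_with(total + shift, mask=mask)


# ---------------------------------------------------------------------------
# raster graph and commute distances

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def raster_graph(rs: GridSurface, conductance_rule: str = "mean_conductance"):
    """Sparse weighted adjacency of the 8-neighbor graph on unmasked cells.

    Edge conductance between adjacent cells i, j is the arithmetic mean of
    the cell conductances 1/R_i and 1/R_j (``mean_conductance``) or the
    reciprocal of the mean cell resistance (``mean_resistance``); diagonal
    neighbors are down-weighted by 1/sqrt(2) for the longer step.

    Returns (adjacency CSR matrix, index grid mapping (row, col) -> vertex,
    -1 for masked cells).
    """
    n_rows, n_cols = rs.shape
    index = -np.ones(rs.shape, dtype=int)
    cells = np.argwhere(~rs.mask)
    index[tuple(cells.T)] = np.arange(len(cells))
    res = rs.values
    rows, cols, data = [], [], []
    for dr, dc in _OFFSETS:
        if (dr, dc) < (0, 0) or (dr, dc) == (0, -1):
            continue  # each undirected edge once (offsets with positive order)
        r0 = np.arange(max(0, -dr), min(n_rows, n_rows - dr))
        c0 = np.arange(max(0, -dc), min(n_cols, n_cols - dc))
        rr, cc = np.meshgrid(r0, c0, indexing="ij")
        i = index[rr, cc]
        j = index[rr + dr, cc + dc]
        ok = (i >= 0) & (j >= 0)
        i, j = i[ok], j[ok]
        ri = res[rr, cc][ok]
        rj = res[rr + dr, cc + dc][ok]
        if conductance_rule == "mean_conductance":
            cond = 0.5 * (1.0 / ri + 1.0 / rj)
        elif conductance_rule == "mean_resistance":
            cond = 1.0 / (0.5 * (ri + rj))
        else:
            raise ValueError(f"unknown conductance rule {conductance_rule!r}")
        if dr != 0 and dc != 0:
            cond = cond / np.sqrt(2.0)
        rows.extend([i, j])
        cols.extend([j, i])
        data.extend([cond, cond])
    n = len(cells)
    adj = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return adj, index


def commute_distance_matrix(
    rs: GridSurface,
    points: np.ndarray,
    labels: list[str] | None = None,
    conductance_rule: str = "mean_conductance",
) -> PairwiseMatrix:
    """Pairwise commute distances between sample locations on a resistance
    surface.

    Each point is snapped to its containing cell.  The commute distance is
    ``vol(G) * R_eff(i, j)`` with the effective resistance computed from
    sparse solves of the grounded graph Laplacian (one LU factorization,
    one solve per distinct point cell).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2) map coordinates")
    if labels is None:
        labels = [f"pt{k}" for k in range(len(points))]

    bad = []
    cells = []
    for k, (x, y) in enumerate(points):
        row, col = rs.cell_of(x, y)
        if rs.mask[row, col]:
            bad.append(labels[k])
        cells.append((row, col))
    if bad:
        raise ValueError(f"points fall in masked cells: {bad}")

    adj, index = raster_graph(rs, conductance_rule)
    n = adj.shape[0]
    n_comp, comp = connected_components(adj, directed=False)
    verts = np.array([index[r, c] for r, c in cells])
    if n_comp > 1 and len(set(comp[verts])) > 1:
        raise ValueError("point pairs lie in disconnected graph components")

    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sp.diags(deg) - adj
    vol = float(deg.sum())  # = 2 * total edge conductance

    # grounded Laplacian: delete the row/column of a reference vertex
    ground = int(verts[0])
    keep = np.ones(n, dtype=bool)
    keep[ground] = False
    lg = lap[keep][:, keep].tocsc()
    lu = splu(lg)
    pos = np.cumsum(keep) - 1  # vertex -> grounded index

    uniq = sorted(set(int(v) for v in verts))
    sols: dict[int, np.ndarray] = {}
    for v in uniq:
        if v == ground:
            continue
        e = np.zeros(n - 1)
        e[pos[v]] = 1.0
        sols[v] = lu.solve(e)

    def reff(u: int, v: int) -> float:
        if u == v:
            return 0.0
        if u == ground:
            return float(sols[v][pos[v]])
        if v == ground:
            return float(sols[u][pos[u]])
        return float(
            sols[u][pos[u]] + sols[v][pos[v]] - sols[u][pos[v]] - sols[v][pos[u]]
        )

    m = len(points)
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            out[a, b] = out[b, a] = vol * reff(int(verts[a]), int(verts[b]))
    return PairwiseMatrix(list(labels), out, kind="commute")
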
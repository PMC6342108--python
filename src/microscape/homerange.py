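"""Kernel home ranges from telemetry, overlap, activity and sex comparisons.

The utilization distribution (UD) of an individual is a bivariate Gaussian
kernel density over its radiolocations with the reference bandwidth

    h_ref = ((sd_x + sd_y) / 2) * n^(-1/6),

evaluated on a regular grid.  The home range at an isopleth level (95% by
default) is the smallest-density region holding that probability mass; its
area is reported in hectares.  Overlap between two individuals is the
directed percentage of one home range covered by the other.  Nightly
activity is summarized as consecutive-step distances and per-night maxima;
sex differences are tested with the Mann-Whitney U statistic (exact null
distribution for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .surfaces import GridSurface

__all__ = [
    "TelemetryTrack",
    "UtilizationDistribution",
    "HomeRangeEstimate",
    "reference_bandwidth",
    "kde_homerange",
    "overlap_matrix",
    "activity_metrics",
    "mwu_test",
    "load_telemetry",
]


@dataclass
class TelemetryTrack:
    """Timestamped fixes of one radio-tracked individual."""

    individual_id: str
    sex: str
    x: np.ndarray
    y: np.ndarray
    timestamps: list[datetime]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.timestamps)):
            raise ValueError("fix arrays must have equal length")
        for earlier, later in zip(self.timestamps, self.timestamps[1:]):
            if later <= earlier:
                raise ValueError(
                    f"timestamps of {self.individual_id!r} must be strictly "
                    "increasing"
                )

    @property
    def n_fixes(self) -> int:
        return len(self.x)


@dataclass
class UtilizationDistribution:
    """A kernel density surface integrating to one over its grid."""

    individual_id: str
    density: GridSurface
    h: float
    fixes: np.ndarray  # (n, 2), kept so UDs can be re-evaluated on any grid

    def isopleth_mask(self, level: float = 0.95) -> np.ndarray:
        """Boolean grid of the smallest-density region holding ``level``."""
        return _isopleth_mask(self.density.values, self.density.cell_size, level)

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return _gaussian_density(self.fixes, self.h, x, y)


@dataclass
class HomeRangeEstimate:
    individual_id: str
    level: float
    area_ha: float


def reference_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Bivariate reference bandwidth ((sd_x + sd_y)/2) * n^(-1/6)."""
    n = len(x)
    sd = 0.5 * (np.std(x, ddof=1) + np.std(y, ddof=1))
    return float(sd * n ** (-1.0 / 6.0))


def _gaussian_density(fixes: np.ndarray, h: float,
                      x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = x[..., None] - fixes[:, 0]
    dy = y[..., None] - fixes[:, 1]
    kern = np.exp(-(dx**2 + dy**2) / (2 * h**2))
    return kern.sum(axis=-1) / (len(fixes) * 2 * np.pi * h**2)


def _isopleth_mask(density: np.ndarray, cell_size: float, level: float) -> np.ndarray:
    if not 0 < level < 1:
        raise ValueError("isopleth level must be in (0, 1)")
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    mass = np.cumsum(flat[order]) * cell_size**2
    cut = int(np.searchsorted(mass, level)) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:cut]] = True
    return mask.reshape(density.shape)


def kde_homerange(
    t: TelemetryTrack,
    level: float = 0.95,
    cell: float | None = None,
    h: float | None = None,
) -> tuple[UtilizationDistribution, HomeRangeEstimate]:
    """Kernel UD and home-range area for one track.

    The evaluation grid covers the fix bounding box padded by 3h with cell
    edge h/4 unless overridden.  Area (hectares) counts isopleth cells.
    """
    if t.n_fixes < 5:
        raise ValueError(f"{t.individual_id!r}: at least 5 fixes required")
    if np.std(t.x) == 0 and np.std(t.y) == 0:
        raise ValueError(f"{t.individual_id!r}: all fixes identical")
    if h is None:
        h = reference_bandwidth(t.x, t.y)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if cell is None:
        cell = h / 4.0
    pad = 3.0 * h
    x0, x1 = t.x.min() - pad, t.x.max() + pad
    y0, y1 = t.y.min() - pad, t.y.max() + pad
    n_cols = max(int(np.ceil((x1 - x0) / cell)), 8)
    n_rows = max(int(np.ceil((y1 - y0) / cell)), 8)
    xc = x0 + (np.arange(n_cols) + 0.5) * cell
    yc = y1 - (np.arange(n_rows) + 0.5) * cell
    gx, gy = np.meshgrid(xc, yc)
    fixes = np.column_stack([t.x, t.y])
    dens = _gaussian_density(fixes, h, gx, gy)
    dens = dens / (dens.sum() * cell**2)  # renormalize the truncated grid
    grid = GridSurface(dens, cell, origin=(x0, y1))
    ud = UtilizationDistribution(t.individual_id, grid, h, fixes)
    mask = ud.isopleth_mask(level)
    area_ha = float(mask.sum()) * cell**2 / 1e4
    return ud, HomeRangeEstimate(t.individual_id, level, area_ha)


def overlap_matrix(
    uds: list[UtilizationDistribution], level: float = 0.95
) -> pd.DataFrame:
    """Directed home-range overlap percentages.

    ``overlap[A, B] = area(isopleth_A intersect isopleth_B) / area(isopleth_A)
    * 100``.  UDs are re-evaluated on a common grid spanning all ranges (the
    finest cell size among the inputs), so differently gridded UDs compare
    correctly.
    """
    cell = min(ud.density.cell_size for ud in uds)
    x0 = min(ud.density.origin[0] for ud in uds)
    y1 = max(ud.density.origin[1] for ud in uds)
    x1 = max(ud.density.origin[0] + ud.density.n_cols * ud.density.cell_size
             for ud in uds)
    y0 = min(ud.density.origin[1] - ud.density.n_rows * ud.density.cell_size
             for ud in uds)
    # coarsen the common grid if widely separated ranges would blow it up
    max_cells = 4_000_000
    while ((x1 - x0) / cell) * ((y1 - y0) / cell) > max_cells:
        cell *= 2.0
    n_cols = int(np.ceil((x1 - x0) / cell))
    n_rows = int(np.ceil((y1 - y0) / cell))
    xc = x0 + (np.arange(n_cols) + 0.5) * cell
    yc = y1 - (np.arange(n_rows) + 0.5) * cell
    masks = {}
    for ud in uds:
        dens = np.empty((n_rows, n_cols))
        chunk = max(1, int(2_000_000 / max(n_cols, 1)))
        for start in range(0, n_rows, chunk):
            gx, gy = np.meshgrid(xc, yc[start:start + chunk])
            dens[start:start + chunk] = ud.evaluate(gx, gy)
        dens = dens / (dens.sum() * cell**2)
        masks[ud.individual_id] = _isopleth_mask(dens, cell, level)
    ids = [ud.individual_id for ud in uds]
    out = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for a in ids:
        area_a = masks[a].sum()
        for b in ids:
            inter = (masks[a] & masks[b]).sum()
            out.loc[a, b] = 100.0 * inter / area_a if area_a else np.nan
    return out


def _night_of(ts: datetime) -> datetime.date:
    """Night identifier: a 12:00->12:00 window labelled by its first date."""
    return (ts - timedelta(hours=12)).date()


def activity_metrics(t: TelemetryTrack) -> pd.DataFrame:
    """Consecutive step distances per night with nightly maxima.

    Fixes are grouped into nights (noon-to-noon windows); each row is one
    step between consecutive fixes of the same night, with columns night,
    t_start, t_end, distance_m, is_night_max.
    """
    order = np.argsort([ts.timestamp() for ts in t.timestamps])
    xs, ys = t.x[order], t.y[order]
    tss = [t.timestamps[k] for k in order]
    rows = []
    for k in range(1, len(tss)):
        if _night_of(tss[k]) != _night_of(tss[k - 1]):
            continue
        d = float(np.hypot(xs[k] - xs[k - 1], ys[k] - ys[k - 1]))
        rows.append({
            "individual": t.individual_id,
            "night": _night_of(tss[k]),
            "t_start": tss[k - 1],
            "t_end": tss[k],
            "distance_m": d,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["individual", "night", "t_start", "t_end",
                                     "distance_m", "is_night_max"])
    df["is_night_max"] = (
        df.groupby("night")["distance_m"].transform("max") == df["distance_m"]
    )
    return df


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U for sample sizes (n1, n2) without ties.

    Counts rank arrangements by the standard recurrence
    f(n1, n2, u) = f(n1 - 1, n2, u - n2) + f(n1, n2 - 1, u).
    Returns P(U <= u) for u = 0..n1*n2.
    """
    max_u = n1 * n2
    # dp[m][u]: arrangements with current first-sample size a, second m
    counts = {(0, 0): np.array([1.0])}

    def f(a: int, b: int) -> np.ndarray:
        if (a, b) in counts:
            return counts[(a, b)]
        if a == 0 or b == 0:
            out = np.array([1.0])
        else:
            fa = f(a - 1, b)
            fb = f(a, b - 1)
            out = np.zeros(a * b + 1)
            out[b:][: len(fa)] += fa
            out[: len(fb)] += fb
        counts[(a, b)] = out
        return out

    dist = f(n1, n2)
    dist = dist / dist.sum()
    assert len(dist) == max_u + 1
    return np.cumsum(dist)


def mwu_test(a, b) -> dict:
    """Mann-Whitney U test between two samples.

    Exact two-sided p by enumeration of the null U distribution when
    n_a * n_b <= 400 and the data are tie-free; otherwise the normal
    approximation with tie correction.  Returns min-U, both one-sided U
    statistics and the p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([a, b]))
    ra = ranks[:na].sum()
    u_a = ra - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    u_min = min(u_a, u_b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < na + nb
    if na * nb <= 400 and not has_ties:
        cdf = _exact_u_cdf(na, nb)
        p = min(2.0 * cdf[int(round(u_min))], 1.0)
    else:
        n = na + nb
        mu = na * nb / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            from scipy.stats import norm

            z = (u_min - mu + 0.5) / np.sqrt(sigma2)  # continuity correction
            p = min(2.0 * norm.cdf(z), 1.0)
    return {"U": float(u_min), "U_a": float(u_a), "U_b": float(u_b),
            "p": float(p)}


# ---------------------------------------------------------------------------
# telemetry I/O


def load_telemetry(path) -> list[TelemetryTrack]:
    """Read telemetry CSV (individual, sex, x, y, timestamp ISO 8601)."""
    df = pd.read_csv(path, dtype={"individual": str})
    for col in ("individual", "x", "y", "timestamp"):
        if col not in df.columns:
            raise ValueError(f"telemetry CSV must have column '{col}'")
    tracks = []
    for iid, grp in df.groupby("individual", sort=True):
        try:
            stamps = [datetime.fromisoformat(str(s)) for s in grp["timestamp"]]
        except ValueError as exc:
            raise ValueError(f"unparseable timestamp for {iid!r}: {exc}") from exc
        order = np.argsort([s.timestamp() for s in stamps])
        sex = str(grp["sex"].iloc[0]) if "sex" in grp.columns else "unknown"
        tracks.append(TelemetryTrack(
            individual_id=str(iid),
            sex=sex,
            x=grp["x"].to_numpy(float)[order],
            y=grp["y"].to_numpy(float)[order],
            timestamps=[stamps[k] for k in order],
        ))
    return tracks


def write_telemetry(tracks: list[TelemetryTrack], path) -> None:
    rows = []
    for t in tracks:
        for x, y, ts in zip(t.x, t.y, t.timestamps):
            rows.append({"individual": t.individual_id, "sex": t.sex,
                         "x": x, "y": y, "timestamp": ts.isoformat()})
    pd.DataFrame(rows).to_csv(path, index=False)
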
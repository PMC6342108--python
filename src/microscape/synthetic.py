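"""Synthetic data with the statistical structure the pipeline assumes.

The generators emulate a microgeographic desert study system: spatially
autocorrelated environmental rasters (an NDVI-like greenness index in
[-1, 1], relative humidity in %, air temperature in degrees C, elevation in
m), family-structured microsatellite panels with designed U/HS/FS/PO dyads,
pairwise genetic distances drawn from the MLPE generative model on a known
true resistance transformation, and nightly radiotracking fixes (10 per
individual inside a 21:00-01:30 window at 30-minute intervals).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .genotypes import GenotypeTable
from .homerange import TelemetryTrack
from .popgen import PairwiseMatrix
from .resistance import TransformSpec, commute_distance_matrix, transform_surface
from .surfaces import GridSurface

__all__ = [
    "gen_random_field",
    "sim_genetic_distances",
    "sim_microsat_families",
    "sim_radiolocations",
    "SyntheticScenario",
    "mapimi_small",
]


def gen_random_field(
    n_rows: int,
    n_cols: int,
    cell_size: float,
    correlation_length: float,
    mean: float,
    sd: float,
    seed: int | None = None,
    clip: tuple[float, float] | None = None,
    origin: tuple[float, float] | None = None,
) -> GridSurface:
    """Gaussian random field: smoothed white noise scaled to mean/sd.

    ``correlation_length`` (meters) sets the Gaussian smoothing scale; below
    one cell the field degrades to white noise (with a warning).  ``clip``
    bounds the values (used for the NDVI-like surface, clipped to [-1, 1]).
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_rows, n_cols))
    sigma_cells = correlation_length / cell_size
    if sigma_cells < 1.0:
        warnings.warn("correlation length below cell size; returning white noise")
        field_vals = noise
    else:
        field_vals = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    if sd > 0:
        emp_sd = field_vals.std()
        field_vals = (field_vals - field_vals.mean()) / (emp_sd if emp_sd else 1.0)
        field_vals = mean + sd * field_vals
    else:
        field_vals = np.full((n_rows, n_cols), mean)
    if clip is not None:
        field_vals = np.clip(field_vals, *clip)
    if origin is None:
        origin = (0.0, n_rows * cell_size)
    return GridSurface(field_vals, cell_size, origin=origin)


def sim_genetic_distances(
    rs: GridSurface,
    points: np.ndarray,
    labels: list[str],
    beta0: float = 0.5,
    beta1: float = 0.1,
    sigma2_u: float = 0.005,
    sigma2_eps: float = 0.005,
    seed: int | None = None,
    clip: bool = True,
) -> PairwiseMatrix:
    """Pairwise distances from the MLPE generative model on a resistance
    surface.

    y_ij = beta0 + beta1 * z_ij + u_i + u_j + e_ij with z the standardized
    commute distance, u_i ~ N(0, sigma2_u) per individual and e_ij iid.
    With ``clip`` the result is bounded to [0, 1] (a Dps-like dissimilarity).
    """
    if sigma2_u < 0 or sigma2_eps < 0:
        raise ValueError("variances must be non-negative")
    commute = commute_distance_matrix(rs, points, labels=labels)
    z = commute.lower_triangle()
    z = (z - z.mean()) / z.std()
    rng = np.random.default_rng(seed)
    n = len(labels)
    u = rng.normal(0, np.sqrt(sigma2_u), size=n)
    pairs = commute.pair_index()
    eps = rng.normal(0, np.sqrt(sigma2_eps), size=len(z))
    y = beta0 + beta1 * z + u[pairs[:, 0]] + u[pairs[:, 1]] + eps
    if clip:
        y = np.clip(y, 0.0, 1.0)
    mat = np.zeros((n, n))
    mat[pairs[:, 0], pairs[:, 1]] = y
    mat[pairs[:, 1], pairs[:, 0]] = y
    return PairwiseMatrix(list(labels), mat, kind="Dps")


# ---------------------------------------------------------------------------
# family-structured microsatellite panels


def _draw_genotype(freq_alleles: np.ndarray, freq_p: np.ndarray, rng) -> tuple:
    return tuple(rng.choice(freq_alleles, size=2, p=freq_p))


def _mendelian_child(g_mother: tuple, g_father: tuple, rng) -> tuple:
    return (g_mother[rng.integers(2)], g_father[rng.integers(2)])


def sim_microsat_families(
    n_loci: int = 8,
    n_alleles: int = 10,
    dirichlet_concentration: float = 1.0,
    n_unrelated: int = 20,
    n_po: int = 3,
    n_fs: int = 3,
    n_hs: int = 3,
    seed: int | None = None,
    coords_extent: float | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate a microsatellite panel with designed family structure.

    Allele frequencies per locus are symmetric-Dirichlet draws; founders are
    in Hardy-Weinberg proportions; PO/FS/HS dyads arise by Mendelian
    transmission.  Returns the genotype table and a truth table of dyad
    relationships (one row per designed dyad).
    """
    rng = np.random.default_rng(seed)
    alleles = np.arange(1, n_alleles + 1)
    freqs = rng.dirichlet(np.full(n_alleles, dirichlet_concentration), size=n_loci)
    loci = [f"L{k + 1}" for k in range(n_loci)]

    individuals: list[tuple[str, list[tuple]]] = []
    truth_rows: list[dict] = []
    counter = [0]

    def founder() -> tuple[str, list[tuple]]:
        counter[0] += 1
        iid = f"ind{counter[0]:03d}"
        geno = [_draw_genotype(alleles, freqs[l], rng) for l in range(n_loci)]
        individuals.append((iid, geno))
        return iid, geno

    def child(gm: list[tuple], gf: list[tuple]) -> tuple[str, list[tuple]]:
        counter[0] += 1
        iid = f"ind{counter[0]:03d}"
        geno = [_mendelian_child(gm[l], gf[l], rng) for l in range(n_loci)]
        individuals.append((iid, geno))
        return iid, geno

    for _ in range(n_unrelated):
        founder()
    for _ in range(n_po):
        pid, pg = founder()
        _, mate_g = founder()
        cid, _ = child(pg, mate_g)
        truth_rows.append({"id_a": pid, "id_b": cid, "relationship": "PO"})
    for _ in range(n_fs):
        _, gm = founder()
        _, gf = founder()
        c1, g1 = child(gm, gf)
        c2, g2 = child(gm, gf)
        truth_rows.append({"id_a": c1, "id_b": c2, "relationship": "FS"})
    for _ in range(n_hs):
        _, gm = founder()  # shared parent
        _, gf1 = founder()
        _, gf2 = founder()
        c1, _ = child(gm, gf1)
        c2, _ = child(gm, gf2)
        truth_rows.append({"id_a": c1, "id_b": c2, "relationship": "HS"})

    ids = [iid for iid, _ in individuals]
    calls = np.array([[list(g) for g in geno] for _, geno in individuals])
    x = y = None
    if coords_extent is not None:
        x = rng.uniform(0, coords_extent, size=len(ids))
        y = rng.uniform(0, coords_extent, size=len(ids))
    sexes = [("M", "F")[int(rng.integers(2))] for _ in ids]
    table = GenotypeTable(ids, loci, calls, x=x, y=y, sex=sexes)
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# radiotracking


def sim_radiolocations(
    centers: np.ndarray,
    sigma: float = 10.0,
    n_fixes: int = 10,
    nights: int = 2,
    seed: int | None = None,
    start_date: datetime | None = None,
    sexes: list[str] | None = None,
) -> list[TelemetryTrack]:
    """Nightly radiolocation tracks around home-range centers.

    Fixes are bivariate normal (sd ``sigma`` m) around each center;
    timestamps sit on a 30-minute lattice inside the 21:00-01:30 tracking
    window, spread over ``nights`` consecutive nights.
    """
    if n_fixes < 5:
        raise ValueError("at least 5 fixes per individual required")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    rng = np.random.default_rng(seed)
    if start_date is None:
        start_date = datetime(2017, 6, 1)
    # 21:00, 21:30, ..., 01:30 -> ten half-hour slots spanning midnight
    slots = [timedelta(hours=21) + k * timedelta(minutes=30) for k in range(10)]
    tracks = []
    for k, (cx, cy) in enumerate(centers):
        xs = rng.normal(cx, sigma, size=n_fixes)
        ys = rng.normal(cy, sigma, size=n_fixes)
        stamps: list[datetime] = []
        night = 0
        per_night = int(np.ceil(n_fixes / nights))
        while len(stamps) < n_fixes:
            base = start_date + timedelta(days=night)
            take = min(per_night, n_fixes - len(stamps))
            chosen = np.sort(rng.choice(len(slots), size=take, replace=False))
            stamps.extend(base + slots[c] for c in chosen)
            night += 1
        sex = sexes[k] if sexes else ("M", "F")[k % 2]
        tracks.append(TelemetryTrack(f"R{k + 1}", sex, xs, ys, stamps))
    return tracks


# ---------------------------------------------------------------------------
# bundled scenario


@dataclass
class SyntheticScenario:
    """A complete synthetic study: rasters, genotypes, distances, telemetry.

    Defaults describe the bundled small desert scenario: a 60 x 60 grid of
    5 m cells (300 m extent), four environmental surfaces, genetic distances
    generated by an inverse-monomolecular resistance transformation of the
    greenness surface, 40 georeferenced individuals, an 8-locus panel, and
    nightly telemetry.
    """

    seed: int = 42
    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 5.0
    correlation_length: float = 50.0
    n_individuals: int = 40
    true_surface: str = "ndvi"
    true_spec: TransformSpec = field(
        default_factory=lambda: TransformSpec(
            family="monomolecular", mode="inverse", shape=1.0, magnitude=200.0
        )
    )
    beta0: float = 0.5
    beta1: float = 0.15
    sigma2_u: float = 0.0005
    sigma2_eps: float = 0.0005
    n_loci: int = 8
    n_alleles: int = 10
    n_telemetry: int = 9
    telemetry_sigma: float = 12.0

    # surface targets: (mean, sd, clip)
    SURFACE_PARAMS = {
        "ndvi": (0.17, 0.13, (-1.0, 1.0)),  # ~30% of cells below 0.1
        "humidity": (44.0, 8.0, (0.0, 100.0)),
        "temperature": (30.0, 3.0, None),
        "elevation": (1152.0, 15.0, None),
    }

    def generate(self) -> dict:
        """Produce every input of the pipeline; bit-reproducible per seed."""
        rng = np.random.default_rng(self.seed)
        surf_seeds = {name: int(rng.integers(2**31 - 1))
                      for name in self.SURFACE_PARAMS}
        surfaces = {
            name: gen_random_field(
                self.n_rows, self.n_cols, self.cell_size,
                self.correlation_length, mean, sd,
                seed=surf_seeds[name], clip=clip,
            )
            for name, (mean, sd, clip) in self.SURFACE_PARAMS.items()
        }
        extent_x = self.n_cols * self.cell_size
        extent_y = self.n_rows * self.cell_size
        pts = np.column_stack([
            rng.uniform(0.02 * extent_x, 0.98 * extent_x, self.n_individuals),
            rng.uniform(0.02 * extent_y, 0.98 * extent_y, self.n_individuals),
        ])
        genotypes, truth_dyads = sim_microsat_families(
            n_loci=self.n_loci, n_alleles=self.n_alleles,
            n_unrelated=max(self.n_individuals - 12, 4),
            n_po=2, n_fs=2, n_hs=2,
            seed=int(rng.integers(2**31 - 1)),
        )
        labels = [f"ind{k + 1:03d}" for k in range(self.n_individuals)]
        rs_true = transform_surface(surfaces[self.true_surface], self.true_spec)
        y = sim_genetic_distances(
            rs_true, pts, labels,
            beta0=self.beta0, beta1=self.beta1,
            sigma2_u=self.sigma2_u, sigma2_eps=self.sigma2_eps,
            seed=int(rng.integers(2**31 - 1)),
        )
        centers = pts[: self.n_telemetry]
        telemetry = sim_radiolocations(
            centers, sigma=self.telemetry_sigma, n_fixes=10, nights=2,
            seed=int(rng.integers(2**31 - 1)),
        )
        return {
            "surfaces": surfaces,
            "points": pts,
            "labels": labels,
            "genotypes": genotypes,
            "truth_dyads": truth_dyads,
            "genetic_distances": y,
            "telemetry": telemetry,
            "true_resistance": rs_true,
            "truth": {
                "true_surface": self.true_surface,
                "true_spec": self.true_spec.to_dict(),
                "beta0": self.beta0,
                "beta1": self.beta1,
                "sigma2_u": self.sigma2_u,
                "sigma2_eps": self.sigma2_eps,
                "seed": self.seed,
            },
        }


def mapimi_small(seed: int = 42, **overrides) -> SyntheticScenario:
    """The bundled small desert scenario (60 x 60 cells of 5 m)."""
    return SyntheticScenario(seed=seed, **overrides)
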
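"""Genetic-algorithm optimization of resistance surfaces against genetic
distance, correlation pre-filtering, and bootstrap model selection.

Each candidate surface is optimized independently: the GA searches the
transformation space (family, mode, shape b, magnitude r) maximizing -AIC of
the MLPE regression of pairwise genetic distance on the commute distances of
the transformed surface.  Weakly correlated surfaces (|Spearman rho| below a
threshold) may then be combined into composite surfaces and optimized
jointly.  Model robustness is assessed by repeatedly refitting every
candidate on random 75% subsamples of individuals and tallying average AICc
rank, average Akaike weight, and how often each model ranks first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ga import GaConfig, GeneSpec, GeneticAlgorithm
from .mlpe import MlpeFit, fit_mlpe, information_criteria
from .popgen import PairwiseMatrix
from .resistance import (
    FAMILIES,
    MODES,
    TransformSpec,
    combine_surfaces,
    commute_distance_matrix,
    transform_surface,
)
from .surfaces import GridSurface

__all__ = [
    "OptimizedModel",
    "BootstrapSummary",
    "ResistanceOptimizer",
    "optimize_single",
    "optimize_categorical",
    "optimize_multi",
    "spearman_filter",
    "bootstrap_selection",
]

DEFAULT_SHAPE_BOUNDS = (0.01, 10.0)
DEFAULT_MAGNITUDE_BOUNDS = (1.0001, 2500.0)


@dataclass
class OptimizedModel:
    """Result of a GA surface optimization."""

    surface_ids: list[str]
    specs: list[TransformSpec] | None  # None for categorical models
    category_values: dict[float, float] | None
    objective: float  # AIC of the best model (GA objective)
    fit: MlpeFit
    contributions: dict[str, float] = field(default_factory=dict)
    history: list[float] = field(default_factory=list)
    model_type: str = "continuous"

    @property
    def name(self) -> str:
        return "+".join(self.surface_ids)


@dataclass
class BootstrapSummary:
    """Bootstrap model-selection tallies across subsample iterations."""

    table: pd.DataFrame  # name, avg_weight, avg_rank, top_pct
    iterations: int
    fraction: float

    def best(self) -> str:
        return str(self.table.sort_values("top_pct", ascending=False)["name"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _predictor_from_specs(
    surfaces: list[GridSurface],
    specs: list[TransformSpec],
    points: np.ndarray,
    labels: list[str],
) -> PairwiseMatrix:
    transformed = [transform_surface(s, sp) for s, sp in zip(surfaces, specs)]
    rs = transformed[0] if len(transformed) == 1 else combine_surfaces(transformed)
    return commute_distance_matrix(rs, points, labels=labels)


class ResistanceOptimizer:
    """GA search estimator for resistance-transformation parameters.

    Parameters
    ----------
    surfaces : list of GridSurface
        One surface for a single-surface model, several for a composite.
    kind : {"continuous", "categorical", "composite"}
        Chromosome layout; ``categorical`` optimizes one resistance value
        per category of a (binary or few-valued) surface with the first
        category pinned at 1 for identifiability.
    config : GaConfig
    shape_bounds, magnitude_bounds : (lo, hi)
        Search bounds for b and r (r on a log scale).

    Attributes (after :meth:`fit`)
    ------------------------------
    best_model_ : OptimizedModel
    """

    def __init__(
        self,
        surfaces: list[GridSurface],
        surface_ids: list[str] | None = None,
        kind: str = "continuous",
        config: GaConfig | None = None,
        shape_bounds=DEFAULT_SHAPE_BOUNDS,
        magnitude_bounds=DEFAULT_MAGNITUDE_BOUNDS,
    ):
        self.surfaces = surfaces
        self.surface_ids = surface_ids or [f"surface{k}" for k in range(len(surfaces))]
        self.kind = kind
        self.config = config or GaConfig()
        self.shape_bounds = shape_bounds
        self.magnitude_bounds = magnitude_bounds

    # -- chromosome layout ----------------------------------------------------

    def _genes(self) -> list[GeneSpec]:
        b_lo, b_hi = self.shape_bounds
        r_lo, r_hi = self.magnitude_bounds
        if self.kind == "categorical":
            cats = np.unique(self.surfaces[0].unmasked())
            if len(cats) < 2:
                raise ValueError("categorical surface has a single category")
            self._categories = cats
            # one gene per non-reference category (reference fixed at 1)
            return [
                GeneSpec("continuous", lo=r_lo, hi=r_hi, log=True)
                for _ in cats[1:]
            ]
        per_surface = [
            GeneSpec("categorical", choices=tuple(
                (f, m) for f in FAMILIES for m in MODES
            )),
            GeneSpec("continuous", lo=b_lo, hi=b_hi, log=True),
            GeneSpec("continuous", lo=r_lo, hi=r_hi, log=True),
        ]
        return per_surface * len(self.surfaces)

    def _decode(self, chrom: list) -> list[TransformSpec]:
        specs = []
        for k in range(len(self.surfaces)):
            (family, mode), b, r = chrom[3 * k], chrom[3 * k + 1], chrom[3 * k + 2]
            specs.append(TransformSpec(family=family, mode=mode, shape=b,
                                       magnitude=max(r, 1.0001)))
        return specs

    def _categorical_surface(self, chrom: list) -> GridSurface:
        s = self.surfaces[0]
        values = np.full_like(s.values, np.nan)
        lut = {self._categories[0]: 1.0}
        for cat, val in zip(self._categories[1:], chrom):
            lut[cat] = float(val)
        for cat, val in lut.items():
            values = np.where(s.values == cat, val, values)
        return s.copy_with(values)

    # -- fitting ---------------------------------------------------------------

    def fit(self, y: PairwiseMatrix, points: np.ndarray):
        """Run the GA; fitness is -AIC of the MLPE fit on commute distances."""
        labels = y.labels
        n_surf = len(self.surfaces)
        if self.kind == "composite" and n_surf < 2:
            raise ValueError("composite optimization needs at least 2 surfaces")
        model_type = {"continuous": "continuous", "categorical": "categorical",
                      "composite": "composite"}[self.kind]
        genes = self._genes()
        cache: dict[tuple, float] = {}

        def evaluate(chrom: list) -> float:
            key = tuple(chrom)
            if key in cache:
                return cache[key]
            try:
                if self.kind == "categorical":
                    rs = self._categorical_surface(chrom)
                    pred = commute_distance_matrix(rs, points, labels=labels)
                    n_cat = len(self._categories)
                    fit = fit_mlpe(y, [pred], model_type="categorical",
                                   n_categories=n_cat)
                else:
                    specs = self._decode(chrom)
                    pred = _predictor_from_specs(self.surfaces, specs, points, labels)
                    fit = fit_mlpe(y, [pred], model_type=model_type,
                                   n_surfaces=n_surf)
                val = -fit.AIC
            except (ValueError, np.linalg.LinAlgError):
                val = -np.inf
            cache[key] = val
            return val

        result = GeneticAlgorithm(genes, evaluate, self.config).run()

        # refit the winner to expose the full MlpeFit
        if self.kind == "categorical":
            rs = self._categorical_surface(result.best)
            pred = commute_distance_matrix(rs, points, labels=labels)
            n_cat = len(self._categories)
            fit = fit_mlpe(y, [pred], model_type="categorical",
                           n_categories=n_cat, name=self.surface_ids[0])
            cat_values = {float(c): (1.0 if k == 0 else float(result.best[k - 1]))
                          for k, c in enumerate(self._categories)}
            self.best_model_ = OptimizedModel(
                surface_ids=list(self.surface_ids),
                specs=None,
                category_values=cat_values,
                objective=fit.AIC,
                fit=fit,
                history=result.history,
                model_type="categorical",
            )
            return self

        specs = self._decode(result.best)
        pred = _predictor_from_specs(self.surfaces, specs, points, labels)
        name = "+".join(self.surface_ids)
        fit = fit_mlpe(y, [pred], model_type=model_type, n_surfaces=n_surf,
                       name=name)
        contributions: dict[str, float] = {}
        if n_surf > 1:
            means = np.array([
                float(np.nanmean(transform_surface(s, sp).values))
                for s, sp in zip(self.surfaces, specs)
            ])
            pct = means / means.sum() * 100.0
            contributions = dict(zip(self.surface_ids, pct))
        self.best_model_ = OptimizedModel(
            surface_ids=list(self.surface_ids),
            specs=specs,
            category_values=None,
            objective=fit.AIC,
            fit=fit,
            contributions=contributions,
            history=result.history,
            model_type=model_type,
        )
        return self

    def fit_runs(self, y: PairwiseMatrix, points: np.ndarray, n_runs: int = 3):
        """Independent GA runs (distinct seeds) to confirm convergence.

        Returns (best OptimizedModel, list of all run results).
        """
        runs = []
        for k in range(n_runs):
            cfg = GaConfig(**{**self.config.__dict__, "seed": self.config.seed + k})
            opt = ResistanceOptimizer(
                self.surfaces, self.surface_ids, self.kind, cfg,
                self.shape_bounds, self.magnitude_bounds,
            )
            opt.fit(y, points)
            runs.append(opt.best_model_)
        best = min(runs, key=lambda m: m.objective)
        self.best_model_ = best
        return best, runs


# ---------------------------------------------------------------------------
# wrapper functions


def optimize_single(
    s: GridSurface, y: PairwiseMatrix, points: np.ndarray,
    cfg: GaConfig | None = None, surface_id: str = "surface",
) -> OptimizedModel:
    """Optimize one continuous surface's transformation against y."""
    opt = ResistanceOptimizer([s], [surface_id], kind="continuous",
                              config=cfg or GaConfig())
    opt.fit(y, points)
    return opt.best_model_


def optimize_categorical(
    s: GridSurface, y: PairwiseMatrix, points: np.ndarray,
    cfg: GaConfig | None = None, surface_id: str = "feature",
) -> OptimizedModel:
    """Optimize per-category resistance values of a categorical surface."""
    opt = ResistanceOptimizer([s], [surface_id], kind="categorical",
                              config=cfg or GaConfig())
    opt.fit(y, points)
    return opt.best_model_


def optimize_multi(
    surfaces: list[GridSurface], y: PairwiseMatrix, points: np.ndarray,
    cfg: GaConfig | None = None, surface_ids: list[str] | None = None,
) -> OptimizedModel:
    """Jointly optimize several surfaces into an additive composite."""
    if len(surfaces) < 2:
        raise ValueError("multisurface optimization needs at least 2 surfaces")
    opt = ResistanceOptimizer(surfaces, surface_ids, kind="composite",
                              config=cfg or GaConfig())
    opt.fit(y, points)
    return opt.best_model_


def spearman_filter(
    surfaces: dict[str, GridSurface], threshold: float = 0.29
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Cell-wise Spearman correlation between surfaces.

    Returns the surface pairs with |rho| below the threshold (candidates
    for composite models) and the full correlation matrix.
    """
    names = list(surfaces)
    base = surfaces[names[0]]
    for name in names[1:]:
        if surfaces[name].shape != base.shape:
            raise ValueError(f"surface {name!r} shape differs from {names[0]!r}")
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    retained: list[tuple[str, str]] = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ok = ~(surfaces[a].mask | surfaces[b].mask)
            r, _ = spearmanr(surfaces[a].values[ok], surfaces[b].values[ok])
            rho.loc[a, b] = rho.loc[b, a] = r
            if abs(r) < threshold:
                retained.append((a, b))
    return retained, rho


@dataclass
class _Candidate:
    """A candidate for bootstrap refitting: name + a fixed predictor matrix
    (or None for the null model) + the k convention of its type."""

    name: str
    predictor: PairwiseMatrix | None
    model_type: str
    n_surfaces: int = 1
    n_categories: int = 2


def candidates_from_models(
    models: list[OptimizedModel],
    surfaces: dict[str, GridSurface],
    y: PairwiseMatrix,
    points: np.ndarray,
    include_distance: bool = True,
    include_null: bool = True,
    coords: np.ndarray | None = None,
) -> list[_Candidate]:
    """Freeze each optimized model's predictor matrix for bootstrap refits."""
    cands: list[_Candidate] = []
    for m in models:
        if m.model_type == "categorical":
            s = surfaces[m.surface_ids[0]]
            values = np.full_like(s.values, np.nan)
            for cat, val in m.category_values.items():
                values = np.where(s.values == cat, val, values)
            rs = s.copy_with(values)
            pred = commute_distance_matrix(rs, points, labels=y.labels)
            cands.append(_Candidate(m.name, pred, "categorical",
                                    n_categories=len(m.category_values)))
        else:
            surf = [surfaces[sid] for sid in m.surface_ids]
            pred = _predictor_from_specs(surf, m.specs, points, y.labels)
            cands.append(_Candidate(m.name, pred, m.model_type,
                                    n_surfaces=len(surf)))
    if include_distance:
        pts = coords if coords is not None else points
        dist = PairwiseMatrix.from_coords(y.labels, pts[:, 0], pts[:, 1])
        cands.append(_Candidate("Distance", dist, "distance"))
    if include_null:
        cands.append(_Candidate("Null", None, "null"))
    return cands


def bootstrap_selection(
    candidates: list[_Candidate],
    y: PairwiseMatrix,
    iterations: int = 500,
    fraction: float = 0.75,
    seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap model selection over individual subsamples.

    Per iteration ``ceil(fraction * n)`` individuals are drawn without
    replacement; every candidate (with its already-optimized transformation
    frozen) is refit by MLPE on the subsampled matrices and the candidates
    are ranked by AICc.  Reports per candidate the average AICc rank,
    average Akaike weight, and the percentage of iterations it ranked first.
    """
    n = y.n
    n_sub = int(np.ceil(fraction * n))
    k_max = max(
        (c.n_categories + 1 if c.model_type == "categorical"
         else {"null": 1, "distance": 2, "continuous": 4}.get(
             c.model_type, 2 * c.n_surfaces + 1))
        for c in candidates
    )
    if n_sub < k_max + 2:
        raise ValueError("subsample too small for the largest candidate model")
    rng = np.random.default_rng(seed)
    names = [c.name for c in candidates]
    ranks = np.zeros((iterations, len(candidates)))
    weights = np.zeros_like(ranks)
    tops = np.zeros(len(candidates))
    all_ids = np.array(y.labels)
    for it in range(iterations):
        if n_sub == n:
            sub_ids = list(all_ids)
        else:
            sub_ids = list(all_ids[np.sort(rng.choice(n, size=n_sub, replace=False))])
        y_sub = y.subset(sub_ids)
        fits = []
        for c in candidates:
            preds = [] if c.predictor is None else [c.predictor.subset(sub_ids)]
            fits.append(
                fit_mlpe(y_sub, preds, model_type=c.model_type,
                         n_surfaces=c.n_surfaces, n_categories=c.n_categories,
                         name=c.name)
            )
        comp = information_criteria(fits)
        tab = comp.table.set_index("name")
        ranks[it] = tab.loc[names, "rank"].to_numpy()
        weights[it] = tab.loc[names, "weight"].to_numpy()
        tops[int(np.argmin(ranks[it]))] += 1
    table = pd.DataFrame(
        {
            "name": names,
            "avg_weight": weights.mean(axis=0),
            "avg_rank": ranks.mean(axis=0),
            "top_pct": tops / iterations * 100.0,
        }
    ).sort_values("avg_rank").reset_index(drop=True)
    return BootstrapSummary(table=table, iterations=iterations, fraction=fraction)
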
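import numpy as np
import pytest

from microscape.ga import GaConfig, GeneSpec, GeneticAlgorithm
from microscape.mlpe import fit_mlpe, information_criteria
from microscape.optimize import (
    ResistanceOptimizer,
    bootstrap_selection,
    candidates_from_models,
    optimize_categorical,
    optimize_multi,
    optimize_single,
    spearman_filter,
)
from microscape.popgen import PairwiseMatrix
from microscape.surfaces import GridSurface
from microscape.synthetic import gen_random_field, sim_genetic_distances

FAST_GA = dict(population=12, max_generations=8, stagnation=4)


@pytest.fixture(scope="module")
def tiny_study():
    """12x12 raster, 15 individuals, strong signal from the 'env' surface."""
    rng = np.random.default_rng(21)
    env = gen_random_field(12, 12, 5.0, 15.0, 0.3, 0.2, seed=5)
    from microscape.resistance import TransformSpec, transform_surface

    spec = TransformSpec("monomolecular", "inverse", shape=0.6, magnitude=80.0)
    rs = transform_surface(env, spec)
    pts = np.column_stack([rng.uniform(2, 58, 15), rng.uniform(2, 58, 15)])
    labels = [f"i{k}" for k in range(15)]
    y = sim_genetic_distances(rs, pts, labels, beta0=0.5, beta1=0.08,
                              sigma2_u=0.001, sigma2_eps=0.001, seed=9)
    return env, pts, labels, y


class TestGeneticAlgorithm:
    def test_fitness_history_non_decreasing(self):
        genes = [GeneSpec("continuous", lo=-5, hi=5)] * 3
        ga = GeneticAlgorithm(
            genes, lambda c: -sum((v - 1.0) ** 2 for v in c),
            GaConfig(population=12, max_generations=25, stagnation=10, seed=3),
        )
        res = ga.run()
        assert (np.diff(res.history) >= 0).all()
        assert res.best_fitness > -0.5  # near the optimum at (1,1,1)

    def test_determinism(self):
        genes = [GeneSpec("continuous", lo=0, hi=1),
                 GeneSpec("categorical", choices=("a", "b", "c"))]
        fitness = lambda c: c[0] + (c[1] == "b")
        cfg = GaConfig(population=10, max_generations=10, stagnation=5, seed=7)
        r1 = GeneticAlgorithm(genes, fitness, cfg).run()
        r2 = GeneticAlgorithm(genes, fitness, cfg).run()
        assert r1.best == r2.best
        assert r1.history == r2.history

    def test_population_floor(self):
        with pytest.raises(ValueError):
            GaConfig(population=5)


class TestSingleSurface:
    def test_deterministic_rerun(self, tiny_study):
        env, pts, labels, y = tiny_study
        cfg = GaConfig(seed=11, **FAST_GA)
        m1 = optimize_single(env, y, pts, cfg, "env")
        m2 = optimize_single(env, y, pts, cfg, "env")
        assert m1.specs[0] == m2.specs[0]
        assert m1.objective == m2.objective

    def test_beats_null_on_strong_signal(self, tiny_study):
        env, pts, labels, y = tiny_study
        cfg = GaConfig(seed=1, **FAST_GA)
        model = optimize_single(env, y, pts, cfg, "env")
        null = fit_mlpe(y, [], name="Null")
        assert model.fit.AIC < null.AIC - 2

    def test_flat_surface_errors(self, tiny_study):
        _, pts, labels, y = tiny_study
        flat = GridSurface(np.full((12, 12), 1.0), 5.0)
        with pytest.raises(ValueError, match="zero range"):
            optimize_single(flat, y, pts, GaConfig(seed=0, **FAST_GA))


class TestCategorical:
    def test_first_category_pinned_and_ratio(self, tiny_study):
        env, pts, labels, y = tiny_study
        binary = GridSurface((env.values >= np.median(env.values)).astype(float),
                             env.cell_size, env.origin)
        cfg = GaConfig(seed=2, **FAST_GA)
        model = optimize_categorical(binary, y, pts, cfg, "feature")
        values = model.category_values
        assert values[0.0] == 1.0
        assert len(values) == 2
        assert model.fit.k == 3

    def test_single_category_errors(self, tiny_study):
        _, pts, labels, y = tiny_study
        ones = GridSurface(np.ones((12, 12)), 5.0)
        with pytest.raises(ValueError, match="single category"):
            optimize_categorical(ones, y, pts, GaConfig(seed=0, **FAST_GA))


class TestMultiSurface:
    def test_contributions_sum_to_100(self, tiny_study):
        env, pts, labels, y = tiny_study
        other = gen_random_field(12, 12, 5.0, 15.0, 30.0, 3.0, seed=77)
        cfg = GaConfig(seed=3, **FAST_GA)
        model = optimize_multi([env, other], y, pts, cfg, ["env", "other"])
        assert sum(model.contributions.values()) == pytest.approx(100.0, abs=0.1)
        assert model.fit.k == 5
        assert set(model.contributions) == {"env", "other"}

    def test_requires_two_surfaces(self, tiny_study):
        env, pts, labels, y = tiny_study
        with pytest.raises(ValueError):
            optimize_multi([env], y, pts, GaConfig(seed=0, **FAST_GA))


class TestSpearmanFilter:
    def test_self_pair_excluded_monotone_rho_one(self):
        s = gen_random_field(30, 30, 5.0, 20.0, 0.0, 1.0, seed=1)
        mono = s.copy_with(np.exp(s.values))  # monotone transform
        retained, rho = spearman_filter({"a": s, "b": mono}, threshold=0.29)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert ("a", "b") not in retained

    def test_independent_noise_retained(self):
        with pytest.warns(UserWarning, match="white noise"):
            a = gen_random_field(100, 100, 5.0, 0.0, 0.0, 1.0, seed=2)
            b = gen_random_field(100, 100, 5.0, 0.0, 0.0, 1.0, seed=3)
        retained, rho = spearman_filter({"a": a, "b": b}, threshold=0.29)
        assert abs(rho.loc["a", "b"]) < 0.05
        assert ("a", "b") in retained

    def test_shape_mismatch(self):
        a = gen_random_field(10, 10, 5.0, 10.0, 0.0, 1.0, seed=1)
        b = gen_random_field(12, 10, 5.0, 10.0, 0.0, 1.0, seed=2)
        with pytest.raises(ValueError, match="shape"):
            spearman_filter({"a": a, "b": b})


class TestBootstrap:
    def make_candidates(self, tiny_study, seed=4):
        env, pts, labels, y = tiny_study
        cfg = GaConfig(seed=seed, **FAST_GA)
        model = optimize_single(env, y, pts, cfg, "env")
        return candidates_from_models([model], {"env": env}, y, pts)

    def test_single_candidate_trivial(self, tiny_study):
        env, pts, labels, y = tiny_study
        cands = [c for c in self.make_candidates(tiny_study)
                 if c.name == "env"]
        summary = bootstrap_selection(cands, y, iterations=10, seed=0)
        assert summary.table["top_pct"].iloc[0] == 100.0
        assert summary.table["avg_rank"].iloc[0] == 1.0

    def test_full_fraction_single_iteration_matches_full_fit(self, tiny_study):
        env, pts, labels, y = tiny_study
        cands = self.make_candidates(tiny_study)
        summary = bootstrap_selection(cands, y, iterations=1, fraction=1.0,
                                      seed=0)
        fits = []
        for c in cands:
            preds = [] if c.predictor is None else [c.predictor]
            fits.append(fit_mlpe(y, preds, model_type=c.model_type,
                                 n_surfaces=c.n_surfaces,
                                 n_categories=c.n_categories, name=c.name))
        comp = information_criteria(fits).table.set_index("name")
        tab = summary.table.set_index("name")
        for name in tab.index:
            assert tab.loc[name, "avg_weight"] == pytest.approx(
                comp.loc[name, "weight"], abs=1e-12
            )
            assert tab.loc[name, "avg_rank"] == comp.loc[name, "rank"]

    def test_bounds_and_determinism(self, tiny_study):
        env, pts, labels, y = tiny_study
        cands = self.make_candidates(tiny_study)
        s1 = bootstrap_selection(cands, y, iterations=20, seed=5)
        s2 = bootstrap_selection(cands, y, iterations=20, seed=5)
        assert s1.table.equals(s2.table)
        t = s1.table
        assert ((t["avg_weight"] >= 0) & (t["avg_weight"] <= 1)).all()
        assert ((t["avg_rank"] >= 1) & (t["avg_rank"] <= len(t))).all()
        assert t["top_pct"].sum() == pytest.approx(100.0)

    def test_subsample_floor(self, tiny_study):
        env, pts, labels, y = tiny_study
        cands = self.make_candidates(tiny_study)
        with pytest.raises(ValueError, match="subsample"):
            bootstrap_selection(cands, y, iterations=2, fraction=0.2, seed=0)
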
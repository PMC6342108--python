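import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from microscape.genotypes import MISSING
from microscape.popgen import (
    allele_frequencies,
    diversity_summary,
    dps_matrix,
    genotype_table_log_prob,
    hwe_exact_test,
    hwe_test_all_loci,
    pairwise_fst,
)
from microscape.synthetic import sim_microsat_families

from conftest import make_table


class TestAlleleFrequencies:
    def test_hand_counts(self):
        g = make_table([[(1, 1)], [(1, 2)]])
        f = allele_frequencies(g)
        assert f.frequencies[0] == {1: 0.75, 2: 0.25}
        assert f.n_typed == [2]

    def test_monomorphic(self):
        g = make_table([[(5, 5)], [(5, 5)]])
        assert allele_frequencies(g).frequencies[0] == {5: 1.0}

    def test_sum_to_one_random_table(self):
        g, _ = sim_microsat_families(seed=2)
        f = allele_frequencies(g)
        for freq in f.frequencies:
            assert sum(freq.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v > 0 for v in freq.values())

    def test_missing_excluded_and_all_missing_errors(self):
        g = make_table([[(1, 2)], [(MISSING, MISSING)]])
        f = allele_frequencies(g)
        assert f.n_typed == [1]
        g2 = make_table([[(MISSING, MISSING)], [(MISSING, MISSING)]])
        with pytest.raises(ValueError, match="L0"):
            allele_frequencies(g2)


class TestDiversity:
    def test_one_locus_hand_computation(self):
        # AA, AB, BB: Na=2, Ne=2, Ho=1/3, uHe=(6/5)(1-0.5)=0.6
        g = make_table([[(1, 1)], [(1, 2)], [(2, 2)]])
        d = diversity_summary(g)
        row = d.per_locus.iloc[0]
        assert row["Na"] == 2
        assert row["Ne"] == pytest.approx(2.0)
        assert row["Ho"] == pytest.approx(1 / 3)
        assert row["uHe"] == pytest.approx(0.6)
        assert row["FIS"] == pytest.approx(1 - (1 / 3) / 0.6)

    def test_overall_fis_aggregation(self):
        # mean Ho 0.65 over mean uHe 0.84 must give FIS ~ 0.226 (prints 0.23/0.22)
        assert 1 - 0.65 / 0.84 == pytest.approx(0.2262, abs=1e-4)

    def test_monomorphic_locus_flagged(self):
        g = make_table([[(1, 1), (3, 4)], [(1, 1), (3, 3)]])
        d = diversity_summary(g)
        row = d.per_locus.iloc[0]
        assert row["Ho"] == 0.0
        assert row["uHe"] == 0.0
        assert np.isnan(row["FIS"])

    def test_bounds_and_ne_le_na(self):
        g, _ = sim_microsat_families(seed=9)
        d = diversity_summary(g)
        df = d.per_locus
        assert ((df["Ho"] >= 0) & (df["Ho"] <= 1)).all()
        assert ((df["uHe"] >= 0) & (df["uHe"] <= 1)).all()
        assert (df["Ne"] <= df["Na"] + 1e-12).all()
        assert (df["Ne"] >= 1).all()
        # uHe >= 1 - sum p^2 (the unbiased correction inflates)
        n = df["n"]
        assert (df["uHe"] >= (1 - 1 / df["Ne"]) - 1e-12).all()

    def test_requires_two_individuals(self):
        g = make_table([[(1, 2)]])
        with pytest.raises(ValueError):
            diversity_summary(g)


def _enumerate_hwe_p(calls: np.ndarray) -> float:
    """Exact HWE p by exhaustive enumeration over genotype tables.

    Enumerates all multisets of n diploid genotypes consistent with the
    observed allele counts, weighting each by its conditional probability.
    """
    calls = np.asarray(calls)
    n = len(calls)
    alleles, counts = np.unique(calls.ravel(), return_counts=True)
    target = dict(zip(alleles.tolist(), counts.tolist()))
    pairs = list(itertools.combinations_with_replacement(alleles.tolist(), 2))

    tables = []

    def rec(idx, remaining, current):
        if idx == len(pairs):
            if remaining == 0:
                tables.append(list(current))
            return
        if remaining == 0:
            counts_now = {}
            for (a, b), m in current:
                counts_now[a] = counts_now.get(a, 0) + m
                counts_now[b] = counts_now.get(b, 0) + m
            if counts_now == target:
                tables.append(list(current))
            return
        a, b = pairs[idx]
        for m in range(remaining + 1):
            used = {}
            feasible = True
            for (x, yv), mm in current + [((a, b), m)]:
                used[x] = used.get(x, 0) + mm
                used[yv] = used.get(yv, 0) + mm
            for al, u in used.items():
                if u > target.get(al, 0):
                    feasible = False
                    break
            if feasible:
                rec(idx + 1, remaining - m, current + [((a, b), m)])

    rec(0, n, [])

    def table_logp(tab):
        geno_counts = np.array([m for _, m in tab if m > 0])
        h = sum(m for (a, b), m in tab if a != b)
        allele_counts = np.array(list(target.values()))
        return (
            gammaln(n + 1) - gammaln(geno_counts + 1).sum() + h * np.log(2)
            + gammaln(allele_counts + 1).sum() - gammaln(2 * n + 1)
        )

    obs = genotype_table_log_prob(calls)
    total = 0.0
    hit = 0.0
    for tab in tables:
        # keep only tables whose allele counts match exactly
        counts_now = {}
        for (a, b), m in tab:
            counts_now[a] = counts_now.get(a, 0) + m
            counts_now[b] = counts_now.get(b, 0) + m
        if counts_now != target:
            continue
        lp = table_logp(tab)
        p = np.exp(lp)
        total += p
        if lp <= obs + 1e-9:
            hit += p
    assert total == pytest.approx(1.0, abs=1e-9)
    return hit


class TestHWE:
    def test_monomorphic_p_one(self):
        g = make_table([[(1, 1)], [(1, 1)], [(1, 1)]])
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_exact_test(g, "L0", reps=1000, seed=0) == 1.0

    def test_monte_carlo_matches_enumeration(self):
        # n=5, all heterozygotes at a 2-allele locus
        g = make_table([[(1, 2)]] * 5, ids=[f"h{k}" for k in range(5)])
        exact = _enumerate_hwe_p(g.calls[:, 0, :])
        reps = 20_000
        p_mc = hwe_exact_test(g, "L0", reps=reps, seed=42)
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(p_mc - exact) < 3 * se + 1e-6

    def test_enumeration_agreement_three_alleles(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([1, 2, 3], size=(6, 2))
        g = make_table([[tuple(c)] for c in calls])
        exact = _enumerate_hwe_p(g.calls[:, 0, :])
        reps = 20_000
        p_mc = hwe_exact_test(g, "L0", reps=reps, seed=1)
        se = np.sqrt(max(exact * (1 - exact), 1e-8) / reps)
        assert abs(p_mc - exact) < 3 * se + 2e-3

    def test_seed_determinism(self):
        g, _ = sim_microsat_families(seed=4)
        p1 = hwe_exact_test(g, "L1", reps=2000, seed=99)
        p2 = hwe_exact_test(g, "L1", reps=2000, seed=99)
        assert p1 == p2

    def test_bonferroni_helper(self):
        g, _ = sim_microsat_families(n_loci=4, seed=4)
        df = hwe_test_all_loci(g, reps=1000, seed=0)
        assert len(df) == 4
        assert (df["p_bonferroni"] >= df["p"]).all()
        assert (df["p_bonferroni"] <= 1).all()

    def test_reps_floor(self):
        g = make_table([[(1, 2)], [(1, 2)]])
        with pytest.raises(ValueError):
            hwe_exact_test(g, "L0", reps=10, seed=0)


class TestFst:
    def test_fixed_differences_theta_one(self):
        g = make_table([[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]])
        groups = {"i0": "A", "i1": "A", "i2": "B", "i3": "B"}
        m = pairwise_fst(g, groups)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_panmictic_theta_near_zero(self):
        rng = np.random.default_rng(12)
        thetas = []
        for rep in range(5):
            g, _ = sim_microsat_families(
                n_loci=8, n_alleles=8, n_unrelated=100, n_po=0, n_fs=0,
                n_hs=0, seed=100 + rep,
            )
            groups = {iid: ("A" if k < 50 else "B")
                      for k, iid in enumerate(g.individual_ids)}
            thetas.append(pairwise_fst(g, groups).values[0, 1])
        assert max(abs(t) for t in thetas) < 0.02

    def test_hand_variance_components(self):
        # two pops, one locus: pop A = {AA, AA, AB}, pop B = {BB, AB, BB}
        g = make_table([[(1, 1)], [(1, 1)], [(1, 2)],
                        [(2, 2)], [(1, 2)], [(2, 2)]])
        groups = {f"i{k}": ("A" if k < 3 else "B") for k in range(6)}
        theta = pairwise_fst(g, groups).values[0, 1]

        # longhand Weir-Cockerham components for allele 1 (allele 2 mirrors)
        r, n1, n2 = 2, 3.0, 3.0
        nbar = 3.0
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        p1, p2 = 5 / 6, 1 / 6
        h1, h2 = 1 / 3, 1 / 3
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        expected = (2 * a) / (2 * (a + b + c))  # both alleles contribute equally
        assert theta == pytest.approx(expected, rel=1e-12)

    def test_group_errors(self):
        g = make_table([[(1, 1)], [(1, 2)], [(2, 2)]])
        with pytest.raises(ValueError):
            pairwise_fst(g, {"i0": "A", "i1": "A", "i2": "B"})  # B has n=1


class TestDps:
    def test_identical_and_disjoint(self):
        g = make_table([
            [(1, 2), (3, 3)],
            [(1, 2), (3, 3)],
            [(4, 5), (6, 7)],
        ])
        m = dps_matrix(g)
        assert m.values[0, 1] == 0.0
        assert m.values[0, 2] == 1.0
        assert np.allclose(np.diag(m.values), 0.0)

    def test_one_shared_per_locus(self):
        g = make_table([[(1, 2), (3, 4)], [(2, 5), (4, 6)]])
        assert dps_matrix(g).values[0, 1] == pytest.approx(0.5)

    def test_double_shared_counting(self):
        # AA vs AB shares one copy; AB vs AB shares two
        g = make_table([[(1, 1)], [(1, 2)], [(1, 2)]])
        m = dps_matrix(g)
        assert m.values[0, 1] == pytest.approx(0.5)
        assert m.values[1, 2] == pytest.approx(0.0)

    def test_pseudo_metric_on_random_table(self, family_panel):
        g, _ = family_panel
        m = dps_matrix(g)
        v = m.values
        assert np.allclose(v, v.T)
        assert (v >= 0).all() and (v <= 1).all()
        assert np.allclose(np.diag(v), 0)

    def test_pairwise_deletion_and_error(self):
        g = make_table([
            [(1, 2), (MISSING, MISSING)],
            [(1, 2), (3, 3)],
        ])
        assert dps_matrix(g).values[0, 1] == 0.0  # only co-typed locus counts
        g2 = make_table([
            [(1, 2), (MISSING, MISSING)],
            [(MISSING, MISSING), (3, 3)],
        ])
        with pytest.raises(ValueError, match="i0"):
            dps_matrix(g2)
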
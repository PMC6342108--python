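"""Microsatellite diversity, Hardy-Weinberg testing, FST and Dps distances.

All statistics follow the standard estimators used in microsatellite
population genetics:

* unbiased expected heterozygosity ``uHe = 2n/(2n-1) * (1 - sum p^2)``,
* effective allele number ``Ne = 1 / sum p^2``,
* Weir & Cockerham's variance-components theta for (pairwise) FST,
* Levene's conditional probability and a Monte-Carlo allele-permutation
  exact test for Hardy-Weinberg equilibrium,
* the proportion-of-shared-alleles dissimilarity D_PS between individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "AlleleFrequencyTable",
    "DiversitySummary",
    "PairwiseMatrix",
    "allele_frequencies",
    "diversity_summary",
    "hwe_exact_test",
    "hwe_test_all_loci",
    "genotype_table_log_prob",
    "pairwise_fst",
    "dps_matrix",
]


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele relative frequencies over typed individuals."""

    loci: list[str]
    frequencies: list[dict[int, float]]  # one map per locus
    n_typed: list[int]

    def freq(self, locus_index: int, allele: int) -> float:
        try:
            return self.frequencies[locus_index][allele]
        except KeyError:
            raise KeyError(
                f"allele {allele} absent from frequency table at locus "
                f"{self.loci[locus_index]!r}"
            ) from None


@dataclass
class DiversitySummary:
    """Per-locus and mean diversity statistics."""

    per_locus: pd.DataFrame  # columns locus, n, Na, Ne, Ho, uHe, FIS
    mean_Na: float
    mean_Ne: float
    mean_Ho: float
    mean_uHe: float
    overall_FIS: float

    def to_csv(self, path) -> None:
        df = self.per_locus.copy()
        mean_row = pd.DataFrame(
            [{
                "locus": "MEAN",
                "n": df["n"].mean(),
                "Na": self.mean_Na,
                "Ne": self.mean_Ne,
                "Ho": self.mean_Ho,
                "uHe": self.mean_uHe,
                "FIS": self.overall_FIS,
            }]
        )
        pd.concat([df, mean_row], ignore_index=True).to_csv(path, index=False)


@dataclass
class PairwiseMatrix:
    """A labelled symmetric matrix of pairwise quantities."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        """Vector of the n(n-1)/2 below-diagonal entries, row-major."""
        iu = np.tril_indices(self.n, k=-1)
        return self.values[iu]

    def pair_index(self) -> np.ndarray:
        """(n_pairs, 2) indices matching :meth:`lower_triangle` order."""
        iu = np.tril_indices(self.n, k=-1)
        return np.column_stack(iu)

    def subset(self, labels: list[str]) -> "PairwiseMatrix":
        idx = {l: k for k, l in enumerate(self.labels)}
        sel = [idx[l] for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(sel, sel)], self.kind)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "generic") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(float), kind)

    @classmethod
    def from_coords(cls, labels, x, y) -> "PairwiseMatrix":
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(np.column_stack([x, y])))
        return cls(list(labels), d, kind="euclidean")


# ---------------------------------------------------------------------------
# allele frequencies and diversity


def allele_frequencies(g: GenotypeTable) -> AlleleFrequencyTable:
    """Allele relative frequencies per locus, over typed individuals only."""
    freqs: list[dict[int, float]] = []
    n_typed: list[int] = []
    missing = g.missing_mask()
    for l, locus in enumerate(g.loci):
        typed = ~missing[:, l]
        if not typed.any():
            raise ValueError(f"locus {locus!r} has no typed individuals")
        alleles = g.calls[typed, l, :].ravel()
        codes, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        freqs.append({int(a): c / total for a, c in zip(codes, counts)})
        n_typed.append(int(typed.sum()))
    return AlleleFrequencyTable(list(g.loci), freqs, n_typed)


def diversity_summary(g: GenotypeTable) -> DiversitySummary:
    """Na, Ne, Ho, uHe and FIS per locus plus across-locus means.

    The across-locus inbreeding coefficient is ``1 - mean(Ho)/mean(uHe)``;
    monomorphic loci have uHe = 0 and an undefined FIS (NaN, excluded from
    the per-locus FIS reporting but retained in the Ho/uHe means).
    """
    if g.n_individuals < 2:
        raise ValueError("diversity statistics require at least 2 individuals")
    missing = g.missing_mask()
    rows = []
    for l, locus in enumerate(g.loci):
        typed = ~missing[:, l]
        n = int(typed.sum())
        calls = g.calls[typed, l, :]
        codes, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / counts.sum()
        na = len(codes)
        sum_p2 = float((p**2).sum())
        ne = 1.0 / sum_p2
        ho = float((calls[:, 0] != calls[:, 1]).mean()) if n else np.nan
        uhe = (2 * n) / (2 * n - 1) * (1 - sum_p2) if n >= 1 else np.nan
        fis = 1 - ho / uhe if uhe > 0 else np.nan
        rows.append(
            {"locus": locus, "n": n, "Na": na, "Ne": ne, "Ho": ho,
             "uHe": uhe, "FIS": fis}
        )
    df = pd.DataFrame(rows)
    mean_ho = float(df["Ho"].mean())
    mean_uhe = float(df["uHe"].mean())
    overall_fis = 1 - mean_ho / mean_uhe if mean_uhe > 0 else np.nan
    return DiversitySummary(
        per_locus=df,
        mean_Na=float(df["Na"].mean()),
        mean_Ne=float(df["Ne"].mean()),
        mean_Ho=mean_ho,
        mean_uHe=mean_uhe,
        overall_FIS=overall_fis,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene conditional probability, Monte Carlo)


def genotype_table_log_prob(genotypes: np.ndarray) -> float:
    """Log conditional probability of a one-locus genotype table.

    ``genotypes`` is (n, 2) of allele codes.  The probability of observing
    these genotype counts given the marginal allele counts under random
    union of gametes is ``n! * 2^h * prod_a c_a! / ((2n)! / ... )`` --
    Levene's exact multinomial formula (h = number of heterozygotes).
    """
    genotypes = np.asarray(genotypes, dtype=int)
    n = len(genotypes)
    pairs = np.sort(genotypes, axis=1)
    _, geno_counts = np.unique(pairs, axis=0, return_counts=True)
    _, allele_counts = np.unique(pairs.ravel(), return_counts=True)
    h = int((pairs[:, 0] != pairs[:, 1]).sum())
    logp = (
        gammaln(n + 1)
        - gammaln(geno_counts + 1).sum()
        + h * np.log(2)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
    )
    return float(logp)


def hwe_exact_test(
    g: GenotypeTable, locus: str, reps: int = 100_000, seed: int | None = None
) -> float:
    """Monte-Carlo exact test for Hardy-Weinberg equilibrium at one locus.

    The observed allele list is repeatedly permuted into random diploid
    genotype tables; the p-value is the proportion of tables (the observed
    one included) whose Levene conditional probability is no larger than
    the observed table's.
    """
    if reps < 1000:
        raise ValueError("use at least 1000 Monte-Carlo replicates")
    l = g.loci.index(locus)
    typed = ~g.missing_mask()[:, l]
    calls = g.calls[typed, l, :]
    if len(np.unique(calls)) < 2:
        warnings.warn(f"locus {locus!r} is monomorphic; HWE p set to 1")
        return 1.0
    rng = np.random.default_rng(seed)
    obs_logp = genotype_table_log_prob(calls)
    alleles = calls.ravel().copy()
    n = len(calls)
    hits = 0
    tol = 1e-9
    for _ in range(reps):
        rng.shuffle(alleles)
        sim_logp = genotype_table_log_prob(alleles.reshape(n, 2))
        if sim_logp <= obs_logp + tol:
            hits += 1
    return (hits + 1) / (reps + 1)


def hwe_test_all_loci(
    g: GenotypeTable, reps: int = 100_000, seed: int | None = None
) -> pd.DataFrame:
    """HWE p-values for every locus with Bonferroni-adjusted values."""
    rng = np.random.default_rng(seed)
    rows = []
    for locus in g.loci:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p = hwe_exact_test(g, locus, reps=reps, seed=sub_seed)
        rows.append({"locus": locus, "p": p})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df


# ---------------------------------------------------------------------------
# Weir & Cockerham theta (FST)


def _wc_components(calls_by_group: list[np.ndarray]):
    """Weir-Cockerham a, b, c summed over alleles for one locus.

    ``calls_by_group`` holds the (n_i, 2) genotype arrays of each group.
    Returns (a_sum, b_sum, c_sum).
    """
    r = len(calls_by_group)
    ns = np.array([len(c) for c in calls_by_group], dtype=float)
    if (ns < 1).any() or r < 2:
        return 0.0, 0.0, 0.0
    alleles = np.unique(np.concatenate([c.ravel() for c in calls_by_group]))
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([(c == allele).mean() for c in calls_by_group])
        h_i = np.array(
            [((c[:, 0] == allele) != (c[:, 1] == allele)).mean()
             for c in calls_by_group]
        )
        pbar = (ns * p_i).sum() / (r * nbar)
        s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def pairwise_fst(g: GenotypeTable, groups: dict[str, object]) -> PairwiseMatrix:
    """Pairwise Weir-Cockerham theta between groups of individuals.

    Multilocus theta sums the variance components over loci and alleles.
    Small negative estimates are reported as computed.
    """
    labels = sorted({str(v) for v in groups.values()})
    if len(labels) < 2:
        raise ValueError("pairwise FST requires at least 2 groups")
    members = {
        lab: [i for i, iid in enumerate(g.individual_ids)
              if str(groups.get(iid)) == lab]
        for lab in labels
    }
    missing = g.missing_mask()
    for lab, mem in members.items():
        typed_counts = (~missing[mem, :]).sum(axis=0)
        if (typed_counts < 2).all():
            raise ValueError(
                f"group {lab!r} has fewer than 2 typed individuals at every locus"
            )
    out = np.full((len(labels), len(labels)), np.nan)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a_tot = abc_tot = 0.0
            for l in range(g.n_loci):
                calls_by_group = []
                ok = True
                for lab in (labels[i], labels[j]):
                    mem = [k for k in members[lab] if not missing[k, l]]
                    if len(mem) < 2:
                        ok = False
                        break
                    calls_by_group.append(g.calls[mem, l, :])
                if not ok:
                    continue
                a, b, c = _wc_components(calls_by_group)
                a_tot += a
                abc_tot += a + b + c
            theta = a_tot / abc_tot if abc_tot != 0 else 0.0
            out[i, j] = out[j, i] = theta
    return PairwiseMatrix(labels, out, kind="FST")


# ---------------------------------------------------------------------------
# proportion-of-shared-alleles distance


def _shared_alleles(pair_a: np.ndarray, pair_b: np.ndarray) -> int:
    """Multiset intersection size of two diploid genotypes (0, 1 or 2)."""
    a1, a2 = pair_a
    b1, b2 = pair_b
    # optimal pairing = size of multiset intersection
    shared = 0
    bb = [b1, b2]
    for a in (a1, a2):
        if a in bb:
            bb.remove(a)
            shared += 1
    return shared


def dps_matrix(g: GenotypeTable) -> PairwiseMatrix:
    """Individual-level genetic dissimilarity 1 - proportion of shared alleles.

    Per dyad only loci typed in both members count; D_PS = 1 - (sum of
    matched alleles) / (2 * number of co-typed loci).
    """
    n = g.n_individuals
    missing = g.missing_mask()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            co = ~(missing[i] | missing[j])
            if not co.any():
                raise ValueError(
                    f"dyad ({g.individual_ids[i]!r}, {g.individual_ids[j]!r}) "
                    "has no co-typed loci"
                )
            shared = sum(
                _shared_alleles(g.calls[i, l], g.calls[j, l])
                for l in np.flatnonzero(co)
            )
            out[i, j] = out[j, i] = 1.0 - shared / (2.0 * co.sum())
    return PairwiseMatrix(list(g.individual_ids), out, kind="Dps")
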
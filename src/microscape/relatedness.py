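"""Maximum-likelihood dyad relationship classification and relative pruning.

Each dyad is scored under the four standard relationship hypotheses via
their identity-by-descent coefficient vectors (k0, k1, k2):

* unrelated (U):          (1, 0, 0)
* half siblings (HS):     (0.5, 0.5, 0)
* full siblings (FS):     (0.25, 0.5, 0.25)
* parent-offspring (PO):  (0, 1, 0)

The multilocus likelihood treats loci as independent and allele frequencies
as known.  A dyad sharing no allele at some locus has zero likelihood under
PO (Mendelian exclusion).  First-order relatives (FS, PO) can then be pruned
by a deterministic greedy vertex cover so the retained individuals contain
no first-order dyad.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .popgen import AlleleFrequencyTable, allele_frequencies

__all__ = [
    "RelationshipCall",
    "IBD_COEFFICIENTS",
    "relationship_classify",
    "classify_all_dyads",
    "prune_first_order",
]

IBD_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}

FIRST_ORDER = {"FS", "PO"}


@dataclass
class RelationshipCall:
    dyad: tuple[str, str]
    loglik: dict[str, float]
    best: str
    first_order: bool

    def as_row(self) -> dict:
        return {
            "id_a": self.dyad[0],
            "id_b": self.dyad[1],
            **{f"logL_{r}": self.loglik[r] for r in ("U", "HS", "FS", "PO")},
            "best": self.best,
        }


def _genotype_prob(a1: int, a2: int, freq: dict[int, float]) -> float:
    p1, p2 = freq[a1], freq[a2]
    return p1 * p1 if a1 == a2 else 2 * p1 * p2


def _transition_prob(g1: tuple[int, int], g2: tuple[int, int],
                     freq: dict[int, float]) -> float:
    """P(genotype g2 | genotype g1, exactly one gene IBD)."""
    a1, a2 = g1
    b1, b2 = g2
    if a1 == a2:  # g1 homozygous aa
        if b1 == b2:
            return freq[a1] if b1 == a1 else 0.0
        if a1 in (b1, b2):
            other = b2 if b1 == a1 else b1
            return freq[other]
        return 0.0
    # g1 heterozygous ab
    if b1 == b2:
        return freq[b1] / 2 if b1 in (a1, a2) else 0.0
    shared = {a1, a2} & {b1, b2}
    if not shared:
        return 0.0
    if len(shared) == 2:
        return (freq[a1] + freq[a2]) / 2
    s = shared.pop()
    other = b2 if b1 == s else b1
    return freq[other] / 2


def _dyad_locus_likelihood(
    g1: tuple[int, int], g2: tuple[int, int], freq: dict[int, float],
    k: tuple[float, float, float],
) -> float:
    k0, k1, k2 = k
    p_g1 = _genotype_prob(*g1, freq)
    same = tuple(sorted(g1)) == tuple(sorted(g2))
    lik = k0 * p_g1 * _genotype_prob(*g2, freq)
    if k1:
        lik += k1 * p_g1 * _transition_prob(g1, g2, freq)
    if k2 and same:
        lik += k2 * p_g1
    return lik


def relationship_classify(
    g: GenotypeTable,
    freqs: AlleleFrequencyTable,
    dyad: tuple[str, str],
) -> RelationshipCall:
    """Classify one dyad as U / HS / FS / PO by multilocus ML.

    Loci missing in either member are skipped (pairwise deletion).  An
    allele absent from the frequency table raises a KeyError.
    """
    idx = {iid: k for k, iid in enumerate(g.individual_ids)}
    i, j = idx[dyad[0]], idx[dyad[1]]
    missing = g.missing_mask()
    loglik = {r: 0.0 for r in IBD_COEFFICIENTS}
    for l in range(g.n_loci):
        if missing[i, l] or missing[j, l]:
            continue
        g1 = tuple(g.calls[i, l])
        g2 = tuple(g.calls[j, l])
        freq = freqs.frequencies[l]
        for allele in set(g1) | set(g2):
            if allele not in freq:
                raise KeyError(
                    f"allele {allele} at locus {g.loci[l]!r} absent from "
                    "frequency table"
                )
        for rel, k in IBD_COEFFICIENTS.items():
            lik = _dyad_locus_likelihood(g1, g2, freq, k)
            loglik[rel] += np.log(lik) if lik > 0 else -np.inf
    best = max(loglik, key=lambda r: loglik[r])
    return RelationshipCall(
        dyad=dyad, loglik=loglik, best=best, first_order=best in FIRST_ORDER
    )


def classify_all_dyads(
    g: GenotypeTable, freqs: AlleleFrequencyTable | None = None
) -> list[RelationshipCall]:
    """Relationship calls for every pair of individuals."""
    if freqs is None:
        freqs = allele_frequencies(g)
    return [
        relationship_classify(g, freqs, (a, b))
        for a, b in combinations(g.individual_ids, 2)
    ]


def calls_to_frame(calls: list[RelationshipCall]) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in calls])


def prune_first_order(
    g: GenotypeTable, calls: list[RelationshipCall]
) -> tuple[GenotypeTable, list[str]]:
    """Remove individuals until no first-order dyad remains.

    Greedy vertex cover on the graph of first-order dyads: repeatedly drop
    the highest-degree individual, breaking ties by lexicographically
    smallest id, so the retained "unrelated" dataset is reproducible.

    Returns the pruned table and the removal order.
    """
    edges = {frozenset(c.dyad) for c in calls if c.first_order}
    edges = {e for e in edges if len(e) == 2}
    removed: list[str] = []
    while edges:
        degree: dict[str, int] = {}
        for e in edges:
            for v in e:
                degree[v] = degree.get(v, 0) + 1
        max_deg = max(degree.values())
        victim = min(v for v, d in degree.items() if d == max_deg)
        removed.append(victim)
        edges = {e for e in edges if victim not in e}
    keep = [iid for iid in g.individual_ids if iid not in set(removed)]
    return g.subset(keep), removed
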
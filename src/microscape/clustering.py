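"""Non-model-based genetic clustering: PCA + K-means/BIC scan and DAPC.

Genotypes are encoded as an individuals x (locus, allele) matrix of allele
counts (0/1/2), missing calls imputed by the locus-allele mean.  A K-means
scan over the retained principal components is scored with a spherical
Gaussian-mixture BIC so the number of genetic clusters can be read off the
BIC minimum; discriminant analysis of principal components (DAPC) then
describes between-group structure for a chosen grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .genotypes import MISSING, GenotypeTable

__all__ = ["encode_allele_counts", "KMeansBICScan", "DAPC",
           "kmeans_bic_scan", "dapc_fit"]


def encode_allele_counts(g: GenotypeTable) -> tuple[np.ndarray, list[str]]:
    """One-hot allele-count encoding: (n, sum_l Na_l) matrix of 0/1/2.

    Missing individual-locus calls are replaced by the locus mean count of
    each allele (computed over typed individuals), which keeps the column
    means unchanged.
    """
    missing = g.missing_mask()
    cols: list[np.ndarray] = []
    names: list[str] = []
    for l, locus in enumerate(g.loci):
        typed = ~missing[:, l]
        alleles = np.unique(g.calls[typed, l, :])
        for a in alleles:
            cnt = (g.calls[:, l, :] == a).sum(axis=1).astype(float)
            mean = cnt[typed].mean()
            cnt[~typed] = mean
            cols.append(cnt)
            names.append(f"{locus}.{a}")
    return np.column_stack(cols), names


def _kmeans_bic(Z: np.ndarray, labels: np.ndarray, K: int) -> float:
    """Spherical-Gaussian BIC for a K-means partition (Pelleg-Moore form).

    The clusters share one spherical variance sigma^2 = WSS / (d (n - K));
    the log-likelihood includes the mixing proportions n_k / n, and the
    parameter count is (K - 1) proportions + K d means + 1 variance.  Unlike
    the raw  n log(WSS/n) + K log n  score, this is not fooled by the WSS
    drop that hard assignment extracts from pure noise.
    """
    n, d = Z.shape
    if n - K <= 0:
        return np.inf
    wss = 0.0
    for k in range(K):
        pts = Z[labels == k]
        wss += float(((pts - pts.mean(axis=0)) ** 2).sum())
    s2 = max(wss / (d * (n - K)), 1e-300)
    ll = 0.0
    for k in range(K):
        nk = int((labels == k).sum())
        if nk == 0:
            return np.inf
        ll += (nk * np.log(nk) - nk * np.log(n)
               - nk * d / 2.0 * np.log(2 * np.pi * s2) - (nk - 1) * d / 2.0)
    p = (K - 1) + K * d + 1
    return -2.0 * ll + p * np.log(n)


@dataclass
class ClusterScan:
    """Result of a K-means scan: BIC per K and assignments at the optimum."""

    K_values: list[int]
    bic: list[float]
    best_K: int
    assignments: np.ndarray
    labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.K_values, "BIC": self.bic})


class KMeansBICScan(ClusterMixin, BaseEstimator):
    """Scan K = 1..K_max with K-means on retained PCs, scored by BIC.

    Parameters
    ----------
    k_max : int
        Largest number of clusters to evaluate.
    n_pcs : int or None
        Principal components retained before clustering (None = all).
    n_restarts : int
        K-means restarts per K.
    random_state : int
        Seed for PCA-independent K-means restarts.

    Attributes
    ----------
    bic_ : list of float
        BIC per K, aligned with ``k_values_``.
    best_k_ : int
        argmin of the BIC.
    labels_ : ndarray
        Cluster assignment of each sample at ``best_k_``.
    """

    def __init__(self, k_max: int = 10, n_pcs: int | None = None,
                 n_restarts: int = 20, random_state: int = 0):
        self.k_max = k_max
        self.n_pcs = n_pcs
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = len(X)
        if self.k_max >= n:
            raise ValueError("k_max must be smaller than the number of samples")
        n_pcs = self.n_pcs
        max_rank = min(n, X.shape[1])
        if n_pcs is None or n_pcs > max_rank:
            n_pcs = max_rank
        pca = PCA(n_components=min(n_pcs, min(n, X.shape[1])),
                  random_state=self.random_state)
        Z = pca.fit_transform(X - X.mean(axis=0))
        d = Z.shape[1]
        self.pca_ = pca
        k_values, bics, labelings = [], [], []
        for K in range(1, self.k_max + 1):
            if K == 1:
                labels = np.zeros(n, dtype=int)
            else:
                km = KMeans(n_clusters=K, n_init=self.n_restarts,
                            random_state=self.random_state)
                labels = km.fit_predict(Z)
            bic = _kmeans_bic(Z, labels, K)
            k_values.append(K)
            bics.append(float(bic))
            labelings.append(labels)
        best_idx = int(np.argmin(bics))
        self.k_values_ = k_values
        self.bic_ = bics
        self.best_k_ = k_values[best_idx]
        self.labels_ = labelings[best_idx]
        return self

    def scan_result(self, labels: list[str] | None = None) -> ClusterScan:
        check_is_fitted(self, "bic_")
        return ClusterScan(self.k_values_, self.bic_, self.best_k_,
                           self.labels_, labels or [])


class DAPC(ClassifierMixin, BaseEstimator):
    """Discriminant analysis of principal components.

    PCA reduces the allele-count matrix to ``n_pcs`` axes; linear
    discriminant analysis then finds axes maximizing between-group over
    within-group variance.  ``explained_variance_fraction_`` reports the
    share of total genotype variance carried by the retained PCs.
    """

    def __init__(self, n_pcs: int = 20):
        self.n_pcs = n_pcs

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = np.unique(y)
        if len(groups) < 2:
            raise ValueError("discrimination undefined for K=1")
        n = len(X)
        if self.n_pcs >= n - len(groups) + 1:
            raise ValueError(
                "n_pcs must be smaller than n_individuals - n_groups"
            )
        full = PCA(n_components=min(n, X.shape[1]))
        full.fit(X - X.mean(axis=0))
        self.pca_ = PCA(n_components=self.n_pcs)
        Z = self.pca_.fit_transform(X - X.mean(axis=0))
        self.explained_variance_fraction_ = float(
            full.explained_variance_ratio_[: self.n_pcs].sum()
        )
        self.lda_ = LinearDiscriminantAnalysis()
        self.lda_.fit(Z, y)
        self.classes_ = self.lda_.classes_
        self._mean = X.mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "lda_")
        Z = self.pca_.transform(np.asarray(X, dtype=float) - self._mean)
        return self.lda_.transform(Z)

    def predict(self, X):
        check_is_fitted(self, "lda_")
        Z = self.pca_.transform(np.asarray(X, dtype=float) - self._mean)
        return self.lda_.predict(Z)

    def predict_proba(self, X):
        check_is_fitted(self, "lda_")
        Z = self.pca_.transform(np.asarray(X, dtype=float) - self._mean)
        return self.lda_.predict_proba(Z)


# ---------------------------------------------------------------------------
# genotype-table wrappers


def kmeans_bic_scan(
    g: GenotypeTable, K_max: int, n_pcs: int | None = None, seed: int = 0
) -> ClusterScan:
    """K-means/BIC scan of a genotype table over retained PCs."""
    X, _ = encode_allele_counts(g)
    scan = KMeansBICScan(k_max=K_max, n_pcs=n_pcs, random_state=seed).fit(X)
    return scan.scan_result(list(g.individual_ids))


def dapc_fit(g: GenotypeTable, groups: dict[str, object], n_pcs: int = 20) -> DAPC:
    """Fit DAPC on a genotype table with known group assignments."""
    X, _ = encode_allele_counts(g)
    y = np.array([str(groups[iid]) for iid in g.individual_ids])
    return DAPC(n_pcs=n_pcs).fit(X, y)
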
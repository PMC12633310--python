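"""Spatial nanocluster statistics and mass-photometry mixture fits.

Receptor nanoclusters are quantified from gold-nanoparticle label
coordinates: particles are grouped by single-linkage connected components
under a physical distance cutoff, and cluster-size distributions are
compared between conditions with a two-sided Mann-Whitney rank-sum test.
Mass-photometry event lists are decomposed into Gaussian components
(monomer/dimer/tetramer hypotheses) by expectation-maximization, with an
optional constraint tying component means to integer multiples of a shared
monomer mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "SingleLinkageClusters",
    "SizeDistribution",
    "size_distribution",
    "compare_sizes",
    "MassMixture",
]


class SingleLinkageClusters(ClusterMixin, BaseEstimator):
    """Single-linkage clustering under a Euclidean distance cutoff.

    Two points within ``cutoff`` share a cluster; membership is transitive
    (connected components of the within-cutoff neighborhood graph).  The
    default cutoff of 30 nm corresponds to ~3x a 10 nm gold-nanoparticle
    label diameter.

    Fitted attributes: ``labels_``, ``n_clusters_``, ``sizes_``.
    """

    def __init__(self, cutoff: float = 30.0):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        X = np.asarray(X, dtype=float)
        n = len(X)
        if n == 0:
            self.labels_ = np.empty(0, dtype=int)
            self.n_clusters_ = 0
            self.sizes_ = np.empty(0, dtype=int)
            return self
        pairs = cKDTree(X).query_pairs(self.cutoff, output_type="ndarray")
        if len(pairs):
            g = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                           shape=(n, n))
        else:
            g = coo_matrix((n, n))
        n_comp, labels = connected_components(g, directed=False)
        self.labels_ = labels
        self.n_clusters_ = int(n_comp)
        self.sizes_ = np.bincount(labels)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class SizeDistribution:
    """Cluster sizes with their empirical CDF and summary statistics."""

    sizes: np.ndarray
    median: float
    mean: float
    n_clusters: int

    def ecdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        s = np.sort(self.sizes)
        out = np.searchsorted(s, x, side="right") / len(s)
        return out if out.size > 1 else float(out[0])

    def ecdf_table(self) -> np.ndarray:
        """(size, cumulative probability) rows at each distinct size."""
        s = np.sort(self.sizes)
        uniq = np.unique(s)
        return np.column_stack([uniq, self.ecdf(uniq)])


def size_distribution(labels: np.ndarray) -> SizeDistribution:
    """Cluster-size distribution from per-point cluster labels.

    Labels < 0 (unassigned background points) are ignored.
    """
    labels = np.asarray(labels)
    labels = labels[labels >= 0]
    if len(labels) == 0:
        raise ValueError("no clustered points")
    sizes = np.bincount(labels)
    sizes = sizes[sizes > 0]
    return SizeDistribution(sizes=sizes, median=float(np.median(sizes)),
                            mean=float(np.mean(sizes)), n_clusters=len(sizes))


def compare_sizes(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison of cluster sizes.

    Exact enumeration for small samples without ties, normal approximation
    with tie correction otherwise.  Identical constant samples return
    p = 1 by convention.  Returns (U statistic, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 clusters per condition")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


class MassMixture(BaseEstimator):
    """1-D Gaussian mixture for mass-photometry event lists, fit by EM.

    With ``monomer_multiples`` set (e.g. ``(2, 4)`` for a dimer/tetramer
    hypothesis), component means are constrained to integer multiples of a
    shared monomer mass, which is itself re-estimated each M step; the
    fitted means then satisfy the multiple relation exactly by
    construction.

    Fitted attributes: ``means_`` (kDa), ``sds_``, ``weights_``,
    ``responsibilities_``, ``loglik_path_`` (non-decreasing),
    ``converged_``; ``monomer_mass_`` when constrained.
    """

    def __init__(self, n_components: int = 2,
                 monomer_multiples: tuple[int, ...] | None = None,
                 max_iter: int = 500, tol: float = 1e-8, min_sd: float = 1e-3):
        self.n_components = n_components
        self.monomer_multiples = monomer_multiples
        self.max_iter = max_iter
        self.tol = tol
        self.min_sd = min_sd

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        K = self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if len(x) < 50:
            raise ValueError("need >= 50 events")
        mult = None
        if self.monomer_multiples is not None:
            mult = np.asarray(self.monomer_multiples, dtype=float)
            if len(mult) != K:
                raise ValueError("monomer_multiples must have n_components entries")

        # quantile initialization
        q = (np.arange(K) + 0.5) / K
        means = np.quantile(x, q)
        sds = np.full(K, max(float(np.std(x)) / K, self.min_sd))
        weights = np.full(K, 1.0 / K)
        if mult is not None:
            m0 = float(np.sum(means * mult) / np.sum(mult**2))
            means = m0 * mult

        loglik_path = []
        prev = -np.inf
        self.converged_ = False
        for _ in range(self.max_iter):
            # E step
            logp = (np.log(np.clip(weights, 1e-300, None))[:, None]
                    - np.log(sds)[:, None]
                    - 0.5 * np.log(2 * np.pi)
                    - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2)
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            ll = float(lse.sum())
            loglik_path.append(ll)
            r = np.exp(logp - lse)
            # M step
            nk = r.sum(axis=1)
            weights = nk / len(x)
            if mult is None:
                means = (r @ x) / np.clip(nk, 1e-300, None)
            else:
                inv_var = 1.0 / sds**2
                num = float(np.sum(inv_var * mult * (r @ x)))
                den = float(np.sum(inv_var * mult**2 * nk))
                monomer = num / max(den, 1e-300)
                means = monomer * mult
                self.monomer_mass_ = monomer
            var = (r * (x[None, :] - means[:, None]) ** 2).sum(axis=1) \
                / np.clip(nk, 1e-300, None)
            sds = np.sqrt(np.clip(var, self.min_sd**2, None))
            if ll - prev < self.tol * max(abs(ll), 1.0):
                self.converged_ = True
                break
            prev = ll

        order = np.argsort(means)
        self.means_ = means[order]
        self.sds_ = sds[order]
        self.weights_ = weights[order]
        self.responsibilities_ = r[order].T
        self.loglik_path_ = np.asarray(loglik_path)
        self.loglik_ = float(loglik_path[-1])
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        logp = (np.log(np.clip(self.weights_, 1e-300, None))[:, None]
                - np.log(self.sds_)[:, None]
                - 0.5 * ((x[None, :] - self.means_[:, None]) / self.sds_[:, None]) ** 2)
        return np.argmax(logp, axis=0)
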
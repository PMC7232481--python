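"""Longitudinal community statistics on ASV count tables.

Implements the analysis chain applied to the reactor 16S amplicon data:
first-order Hill diversity and evenness per sample, Hellinger
standardisation, Bray-Curtis dissimilarities, non-metric multidimensional
scaling (NMDS, Kruskal stress-1), seeded k-means with Calinski-Harabasz
model-order selection, Dufrene-Legendre indicator-value analysis at a chosen
taxonomic rank, rank-level relative-abundance summaries, and a one-way ANOVA
for cluster/parameter association.

The Hill number of order q is the effective number of taxa,
``qD = (sum p_i^q)^(1/(1-q))``; at q=1 the limit is ``exp`` of the Shannon
entropy, and the first-order evenness used here is the ratio ``1E = 1D / 0D``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "RANKS",
    "ASVTable",
    "OrdinationResult",
    "ClusterResult",
    "IndValResult",
    "AnovaResult",
    "hill_diversity",
    "hill_evenness",
    "hellinger",
    "bray_curtis",
    "nmds",
    "kmeans_cluster",
    "calinski_harabasz",
    "choose_k",
    "hierarchical_linkage",
    "indval",
    "aggregate_relative_abundance",
    "one_way_anova",
]

#: Taxonomic ranks carried in the semicolon-delimited lineage strings.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class ASVTable:
    """Samples x taxa count table with taxonomy and sample metadata.

    ``counts`` has sample ids as the index and taxon ids as columns;
    ``taxonomy`` maps taxon id to a semicolon-delimited lineage of at most
    7 ranks (domain ... species); ``metadata`` is indexed by sample id and
    carries at least ``reactor`` and ``day``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in counts")
        arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if (arr.sum(axis=1) <= 0).any():
            raise ValueError("every analysed sample needs a positive row sum")
        missing = set(counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxa without taxonomy: {sorted(missing)[:5]} ...")
        too_long = [
            t for t in counts.columns if len(str(self.taxonomy[t]).split(";")) > 7
        ]
        if too_long:
            raise ValueError(f"taxonomy longer than 7 ranks for {too_long[:5]}")
        if not counts.index.equals(self.metadata.index):
            raise ValueError("metadata index must match counts index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def rank_of(self, taxon: str, rank: str) -> str:
        parts = [p.strip() for p in str(self.taxonomy[taxon]).split(";")]
        i = RANKS.index(rank)
        if i < len(parts) and parts[i]:
            return parts[i]
        return "unclassified"

    def aggregate_by_rank(self, rank: str) -> pd.DataFrame:
        """Sum counts of taxa sharing the same name at ``rank``."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; known: {RANKS}")
        groups = {t: self.rank_of(t, rank) for t in self.counts.columns}
        return self.counts.T.groupby(pd.Series(groups)).sum().T

    def to_tsv(self, counts_path, metadata_path=None) -> None:
        out = self.counts.T.copy()
        out.insert(0, "taxonomy", self.taxonomy.reindex(out.index))
        out.index.name = "taxon"
        out.to_csv(counts_path, sep="\t")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path) -> "ASVTable":
        raw = pd.read_csv(counts_path, sep="\t", index_col=0)
        if "taxonomy" not in raw.columns:
            raise ValueError("counts table must carry a 'taxonomy' column")
        taxonomy = raw["taxonomy"].rename_axis(None)
        counts = raw.drop(columns="taxonomy").T.astype(int)
        counts = counts.rename_axis(index=None, columns=None)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        metadata = metadata.reindex(counts.index)
        return cls(counts=counts, taxonomy=taxonomy, metadata=metadata)


def _clean_row(counts_row) -> np.ndarray:
    row = np.asarray(counts_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if (row < 0).any():
        raise ValueError("counts must be non-negative")
    row = row[row > 0]
    if row.size == 0:
        raise ValueError("empty sample: all counts are zero")
    return row


def hill_diversity(counts_row, q: float = 1.0) -> float:
    """Hill number of order q: the effective number of taxa in one sample.

    q=0 is richness; q=1 is exp(Shannon entropy); other orders follow the
    general formula.  Zero-count taxa are ignored.
    """
    row = _clean_row(counts_row)
    p = row / row.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_evenness(counts_row) -> float:
    """First-order Hill evenness, 1E = 1D / 0D, in (0, 1]."""
    return hill_diversity(counts_row, 1.0) / hill_diversity(counts_row, 0.0)


def hellinger(table) -> np.ndarray:
    """Hellinger standardisation: per-sample square root of relative abundances.

    Every transformed row has unit Euclidean norm.
    """
    X = np.asarray(table, dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    sums = X.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("zero-sum sample row cannot be standardised")
    return np.sqrt(X / sums)


def bray_curtis(table) -> np.ndarray:
    """Square symmetric Bray-Curtis dissimilarity matrix of sample rows."""
    X = np.asarray(table, dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample rows make the dissimilarity undefined")
    return squareform(pdist(X, metric="braycurtis"))


def _classical_scaling(dissim: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson classical scaling, used as a warm start for NMDS."""
    n = dissim.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dissim**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(lam)


def _stress1(coords: np.ndarray, dissim_condensed: np.ndarray) -> float:
    """Kruskal stress-1 with monotone-regressed disparities."""
    d = pdist(coords)
    order = np.argsort(dissim_condensed, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(order.size), d[order])
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS embedding with its Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    converged: bool
    seed: int

    def to_frame(self, index=None) -> pd.DataFrame:
        cols = [f"NMDS{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, columns=cols, index=index)


def nmds(
    dissim,
    dims: int = 2,
    restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Iterative majorisation (SMACOF) with monotone regression of embedded
    distances on the input dissimilarities.  One warm start from classical
    scaling plus ``restarts - 1`` random starts; the embedding with the
    lowest stress-1 wins.  Identical seed and input give identical output.
    """
    D = np.asarray(dissim, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for an ordination")
    rng = np.random.default_rng(seed)
    condensed = squareform(D, checks=False)
    inits = [_classical_scaling(D, dims)]
    inits += [rng.standard_normal((n, dims)) for _ in range(max(0, restarts - 1))]
    best_coords, best_stress = None, np.inf
    for init in inits:
        coords, _ = smacof(
            D,
            metric=False,
            n_components=dims,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            random_state=0,
        )
        s1 = _stress1(coords, condensed)
        if s1 < best_stress:
            best_stress, best_coords = s1, coords
    best_coords = best_coords - best_coords.mean(axis=0)
    return OrdinationResult(
        coordinates=best_coords,
        stress=best_stress,
        converged=bool(np.isfinite(best_stress)),
        seed=seed,
    )


def kmeans_cluster(matrix, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Seeded k-means (k-means++ init, best of ``n_init`` restarts).

    Returns 1-based cluster labels, one per sample row.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, n-1] = [2, {n - 1}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X) + 1


def calinski_harabasz(matrix, labels) -> float:
    """Calinski-Harabasz statistic, (B/(k-1)) / (W/(n-k)).

    Returns +inf when the within-cluster scatter is exactly zero (every
    cluster collapsed onto a point).
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 non-empty clusters")
    W = sum(
        float(((X[labels == u] - X[labels == u].mean(axis=0)) ** 2).sum())
        for u in uniq
    )
    if W == 0.0:
        return float("inf")
    return float(calinski_harabasz_score(X, labels))


@dataclass(frozen=True)
class ClusterResult:
    """Chosen partition with the Calinski-Harabasz curve behind the choice."""

    k: int
    labels: np.ndarray
    ch_by_k: dict[int, float]
    chosen_k_rule: str
    weak_structure: bool


def choose_k(matrix, k_max: int, seed: int = 0) -> ClusterResult:
    """Cluster at k = 2..k_max and keep the Calinski-Harabasz argmax.

    A flat CH curve (max/min ratio below 1.25) flags ``weak_structure``:
    the data do not support a clear partition and the reported k=argmax is
    nominal.  A hierarchical dendrogram for visual comparison is available
    from :func:`hierarchical_linkage`.
    """
    X = np.asarray(matrix, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, X.shape[0] - 1)
    ch: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(2, k_max + 1):
        labels = kmeans_cluster(X, k, seed=seed)
        labels_by_k[k] = labels
        ch[k] = calinski_harabasz(X, labels)
    finite = {k: v for k, v in ch.items() if np.isfinite(v)}
    ranked = finite or ch
    best_k = max(sorted(ranked), key=lambda k: ranked[k])
    values = np.array([v for v in ch.values() if np.isfinite(v)])
    weak = bool(values.size and values.max() < 1.25 * values.min())
    if weak:
        # flat CH curve: no supported partition, fall back to a nominal k=2
        best_k = 2
        rule = "flat Calinski-Harabasz curve; nominal k=2 (weak structure)"
    else:
        rule = "argmax Calinski-Harabasz over k=2..k_max"
    return ClusterResult(
        k=best_k,
        labels=labels_by_k[best_k],
        ch_by_k=ch,
        chosen_k_rule=rule,
        weak_structure=weak,
    )


def hierarchical_linkage(dissim) -> np.ndarray:
    """Average-linkage hierarchical clustering of a dissimilarity matrix.

    Emitted for dendrogram inspection alongside the k-means partition; it is
    not an automated decision criterion.
    """
    D = np.asarray(dissim, dtype=float)
    return linkage(squareform(D, checks=False), method="average")


@dataclass(frozen=True)
class IndValResult:
    """Indicator-value analysis output.

    ``summary`` has one row per taxon: the best cluster, specificity A,
    fidelity B, indval = 100*A*B, and the permutation p-value of the
    taxon's maximum indval.  ``per_cluster`` carries the full taxon x
    cluster indval matrix.
    """

    summary: pd.DataFrame
    per_cluster: pd.DataFrame
    n_perm: int
    seed: int


def _indval_components(X: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    k = uniq.size
    n, g = X.shape
    means = np.empty((k, g))
    occ = np.empty((k, g))
    for i, u in enumerate(uniq):
        sub = X[labels == u]
        means[i] = sub.mean(axis=0)
        occ[i] = (sub > 0).mean(axis=0)
    total = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(total > 0, means / total, 0.0)
    return 100.0 * A * occ, A, occ


def indval(
    table,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> IndValResult:
    """Dufrene-Legendre indicator-value analysis of a rank-aggregated table.

    ``table`` is a samples x taxa abundance table (a DataFrame keeps taxon
    names); abundances are converted to per-sample proportions first.  For
    each taxon and cluster, A is the cluster's share of the across-cluster
    mean abundance (specificity) and B the within-cluster occurrence
    fraction (fidelity); indval = 100*A*B.  Each taxon's p-value is the
    permutation tail probability of its maximum indval under random label
    reassignment, ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    df = pd.DataFrame(table)
    labels = np.asarray(labels)
    if labels.size != df.shape[0]:
        raise ValueError("one label per sample row is required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    counts = df.to_numpy(dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("zero-sum sample row")
    X = counts / sums
    iv, A, B = _indval_components(X, labels, uniq)
    obs = iv.max(axis=0)
    best = iv.argmax(axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        iv_p, _, _ = _indval_components(X, perm, uniq)
        exceed += iv_p.max(axis=0) >= obs - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    summary = pd.DataFrame(
        {
            "cluster": uniq[best],
            "A": A[best, np.arange(X.shape[1])],
            "B": B[best, np.arange(X.shape[1])],
            "indval": obs,
            "p_value": pvals,
        },
        index=df.columns,
    )
    per_cluster = pd.DataFrame(iv.T, index=df.columns, columns=uniq)
    return IndValResult(summary=summary, per_cluster=per_cluster, n_perm=n_perm, seed=seed)


def aggregate_relative_abundance(
    table: ASVTable, rank: str = "genus", floor: float = 0.01
) -> pd.DataFrame:
    """Rank-level composition with rare groups pooled under a floor.

    Counts are summed per rank value and converted to per-sample
    proportions; groups that never reach ``floor`` in any sample are pooled
    into a single "<1% abundance" column (label follows the floor).  Rows
    sum to 1.
    """
    agg = table.aggregate_by_rank(rank)
    rel = agg.div(agg.sum(axis=1), axis=0)
    rare = rel.columns[(rel.max(axis=0) < floor)]
    if len(rare):
        label = f"<{floor:.0%} abundance"
        pooled = rel[rare].sum(axis=1)
        rel = rel.drop(columns=rare)
        rel[label] = pooled
    return rel


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    degenerate: bool = False


def one_way_anova(values_by_cluster: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA across clusters of a process parameter.

    Returns the F statistic and upper-tail p-value; a zero within-group
    variance with equal means is flagged degenerate (F undefined).
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_cluster]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(g.size for g in groups)
    if n_total - len(groups) < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    means = [g.mean() for g in groups]
    if within == 0.0 and np.allclose(means, means[0]):
        return AnovaResult(F=float("nan"), p_value=float("nan"), degenerate=True)
    with np.errstate(invalid="ignore"):
        F, p = stats.f_oneway(*groups)
    return AnovaResult(F=float(F), p_value=float(p), degenerate=False)
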
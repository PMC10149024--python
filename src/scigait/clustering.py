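"""Gait-cluster discovery: PCA, Ward-based k selection, k-means, core
features, and cluster comparison statistics.

The pipeline mirrors a standard unsupervised phenotyping recipe: gait
parameters are standardised, projected onto the principal components
that explain a target share of the variance, the number of clusters is
read off a Ward dendrogram elbow, and k-means partitions the principal
component scores.  Cluster labels are re-indexed by decreasing mean
6MWT distance, so cluster 1 always contains the best walkers.

A compact, interpretable "core" feature set is then derived: the five
largest-|loading| features of each retained PC, filtered to those that
differ across clusters (Kruskal–Wallis) and de-duplicated by Pearson
correlation.  Group comparisons use Kruskal–Wallis for continuous and
Fisher's exact test for categorical variables, with Dunn's post-hoc
test for pairwise contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import fisher_exact, kruskal, norm, rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

DEFAULT_VARIANCE_TARGET = 0.65
DEFAULT_ALPHA = 0.05
DEFAULT_CORR_THRESHOLD = 0.9
TOP_FEATURES_PER_PC = 5
KMEANS_RESTARTS = 50


class ClusteringError(ValueError):
    pass


@dataclass
class PcaModel:
    means: np.ndarray
    sds: np.ndarray
    loadings: pd.DataFrame  # features × PCs
    explained_variance_ratio: np.ndarray
    n_retained: int
    feature_names: list

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        z = (table[self.feature_names].to_numpy() - self.means) / self.sds
        return z @ self.loadings.to_numpy()[:, : self.n_retained]


@dataclass
class ClusterResult:
    assignments: np.ndarray
    pc_scores: np.ndarray
    k: int
    core_features: list
    kw_pvalues: pd.Series
    dunn_tables: dict  # feature -> DataFrame of pairwise p
    composition: pd.DataFrame | None = None


def significance_stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(feature_table: pd.DataFrame,
            variance_target: float = DEFAULT_VARIANCE_TARGET) -> PcaModel:
    """PCA on standardised features; retain the smallest number of PCs
    whose cumulative explained variance reaches ``variance_target``.

    Constant features cannot be standardised and are dropped with a
    warning before the decomposition.
    """
    if len(feature_table) < 2:
        raise ClusteringError("need at least two trials")
    table = feature_table.copy()
    sds0 = table.std(ddof=1)
    constant = sds0[sds0 == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant features before PCA: {constant}")
        table = table.drop(columns=constant)
    means = table.mean().to_numpy()
    sds = table.std(ddof=1).to_numpy()
    z = (table.to_numpy() - means) / sds
    pca = PCA()
    pca.fit(z)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    n_retained = int(np.searchsorted(cum, variance_target) + 1)
    n_retained = min(n_retained, len(evr))
    loadings = pd.DataFrame(
        pca.components_.T, index=table.columns,
        columns=[f"PC{i + 1}" for i in range(len(evr))])
    return PcaModel(means=means, sds=sds, loadings=loadings,
                    explained_variance_ratio=evr, n_retained=max(n_retained, 1),
                    feature_names=table.columns.tolist())


# ---------------------------------------------------------------------------
# choice of k and k-means
# ---------------------------------------------------------------------------

def choose_k(pc_scores: np.ndarray, k_range=range(2, 9)) -> int:
    """Elbow on the Ward dendrogram: pick the k whose merge (k → k−1
    clusters) is highest relative to the previous merge; ties resolve to
    the smaller k."""
    n = len(pc_scores)
    if n < 4:
        raise ClusteringError("need at least 4 observations to choose k")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ClusteringError("empty k range")
    heights = linkage(pc_scores, method="ward")[:, 2]  # n-1 merge heights

    def merge_height(c: int) -> float:
        # height of the merge reducing c+1 clusters to c
        return heights[n - 1 - c]

    best_k, best_score = None, -np.inf
    for k in ks:
        denom = merge_height(k)
        score = merge_height(k - 1) / denom if denom > 0 else np.inf
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return int(best_k)


def cluster_kmeans(pc_scores: np.ndarray, k: int, seed: int = 0,
                   sixmwt_distance=None) -> np.ndarray:
    """K-means with multiple restarts; labels re-indexed so cluster 0 has
    the largest mean 6MWT distance (when distances are supplied)."""
    n = len(pc_scores)
    if k < 2:
        raise ClusteringError("k must be >= 2")
    if k > n:
        raise ClusteringError(f"k={k} exceeds n={n}")
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(pc_scores)
    if sixmwt_distance is not None:
        d = np.asarray(sixmwt_distance, dtype=float)
        order = np.argsort([-np.mean(d[labels == c]) for c in range(k)])
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        labels = remap[labels]
    return labels


# ---------------------------------------------------------------------------
# core feature selection
# ---------------------------------------------------------------------------

def select_core_features(
    pca: PcaModel, feature_table: pd.DataFrame, assignments: np.ndarray,
    alpha: float = DEFAULT_ALPHA, corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    top_per_pc: int = TOP_FEATURES_PER_PC,
) -> list:
    """Union of the top-|loading| features per retained PC, kept only if
    they differ across clusters (Kruskal–Wallis p < alpha), then pruned
    of redundant pairs (|Pearson r| > threshold keeps the smaller-p
    member).  Ordered by PC then |loading|."""
    candidates: list = []
    for pc in pca.loadings.columns[: pca.n_retained]:
        ranked = pca.loadings[pc].abs().sort_values(ascending=False)
        for name in ranked.index[:top_per_pc]:
            if name not in candidates:
                candidates.append(name)

    pvals = {}
    for name in candidates:
        groups = [feature_table[name].to_numpy()[assignments == c]
                  for c in np.unique(assignments)]
        try:
            pvals[name] = kruskal(*groups).pvalue
        except ValueError:  # all values identical
            pvals[name] = 1.0
    kept = [n for n in candidates if pvals[n] < alpha]

    # redundancy pruning: of each highly correlated pair, drop the larger p
    removed: set = set()
    for a, b in itertools.combinations(kept, 2):
        if a in removed or b in removed:
            continue
        r = np.corrcoef(feature_table[a], feature_table[b])[0, 1]
        if np.abs(r) > corr_threshold:
            removed.add(a if pvals[a] > pvals[b] else b)
    core = [n for n in kept if n not in removed]
    if not core:
        warnings.warn("no core features survived filtering")
    return core


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def dunn_test(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Dunn's post-hoc test after Kruskal–Wallis.

    Rank all observations jointly; the pairwise statistic is the mean
    rank difference over its null standard error with tie correction

        z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)),
        T = Σ(t³ − t) / (12(N − 1)).

    Returns the symmetric (z, p) matrices; p is the unadjusted
    two-sided normal tail probability.
    """
    sizes = np.array([len(g) for g in groups])
    if np.any(sizes == 0):
        raise ClusteringError("empty group in Dunn test")
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    mean_ranks = []
    i0 = 0
    for n in sizes:
        mean_ranks.append(ranks[i0:i0 + n].mean())
        i0 += n
    k = len(groups)
    z = np.zeros((k, k))
    p = np.ones((k, k))
    base_var = N * (N + 1) / 12.0 - tie_term
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zij = (mean_ranks[i] - mean_ranks[j]) / se
        pij = 2.0 * norm.sf(abs(zij))
        z[i, j] = z[j, i] = zij
        p[i, j] = p[j, i] = min(pij, 1.0)
    return z, p


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a flat p-value vector."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def fisher_test(table: np.ndarray, n_mc: int = 20000, seed: int = 0) -> float:
    """Fisher's exact test; exact for 2×2, Monte-Carlo (fixed seed) for
    larger tables, following the conditional-on-margins convention: the
    p-value is the probability of a table no more likely than the one
    observed."""
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(fisher_exact(table).pvalue)
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))

    def log_prob(tab):
        from scipy.special import gammaln
        return -np.sum(gammaln(tab + 1.0))

    obs = log_prob(table)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        tab = np.zeros_like(table)
        np.add.at(tab, (rows, perm), 1)
        if log_prob(tab) <= obs + 1e-9:
            hits += 1
    return (hits + 1.0) / (n_mc + 1.0)


def compare_clusters(
    core_features: list, feature_table: pd.DataFrame,
    clinical_table: pd.DataFrame | None, assignments: np.ndarray,
    control_features: pd.DataFrame | None = None, seed: int = 0,
) -> dict:
    """Cluster comparison statistics.

    Returns a dict with:

    * ``composition``: per clinical variable, Kruskal–Wallis H/p for
      continuous columns and Fisher exact p for categorical ones;
    * ``dunn``: per core feature, the pairwise Dunn p table (clusters
      plus, when given, the healthy-control group ``HC``) alongside a
      Holm-adjusted variant;
    * ``kw``: per core feature, the across-cluster Kruskal–Wallis p.
    """
    clusters = np.unique(assignments)
    if len(clusters) < 2:
        raise ClusteringError("need at least two clusters")
    for c in clusters:
        if not np.any(assignments == c):
            raise ClusteringError("empty cluster")

    rows = []
    if clinical_table is not None:
        for col in clinical_table.columns:
            series = clinical_table[col]
            if pd.api.types.is_numeric_dtype(series):
                groups = [series.to_numpy()[assignments == c] for c in clusters]
                res = kruskal(*groups)
                rows.append({"variable": col, "test": "kruskal-wallis",
                             "statistic": res.statistic, "p": res.pvalue,
                             "stars": significance_stars(res.pvalue)})
            else:
                tab = pd.crosstab(assignments, series).to_numpy()
                p = fisher_test(tab, seed=seed)
                rows.append({"variable": col, "test": "fisher",
                             "statistic": np.nan, "p": p,
                             "stars": significance_stars(p)})
    composition = pd.DataFrame(rows)

    kw_p, dunn_tables = {}, {}
    group_names = [f"cluster_{c + 1}" for c in clusters]
    for name in core_features:
        groups = [feature_table[name].to_numpy()[assignments == c] for c in clusters]
        kw_p[name] = kruskal(*groups).pvalue
        all_groups, names = list(groups), list(group_names)
        if control_features is not None and name in control_features:
            all_groups.append(control_features[name].to_numpy())
            names.append("HC")
        z, p = dunn_test(all_groups)
        iu = np.triu_indices(len(all_groups), 1)
        adj = np.ones_like(p)
        adj[iu] = holm_adjust(p[iu])
        adj.T[iu] = adj[iu]
        dunn_tables[name] = {
            "z": pd.DataFrame(z, index=names, columns=names),
            "p": pd.DataFrame(p, index=names, columns=names),
            "p_holm": pd.DataFrame(adj, index=names, columns=names),
        }
    return {"composition": composition, "kw": pd.Series(kw_p),
            "dunn": dunn_tables}


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def run_clustering(
    feature_table: pd.DataFrame, sixmwt_distance=None, seed: int = 0,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    alpha: float = DEFAULT_ALPHA, corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    k: int | None = None, k_range=range(2, 9),
) -> ClusterResult:
    """Full procedure: PCA → choose k (Ward elbow) → k-means → core features."""
    pca = fit_pca(feature_table, variance_target)
    scores = pca.transform(feature_table)
    if k is None:
        k = choose_k(scores, k_range)
    labels = cluster_kmeans(scores, k, seed=seed, sixmwt_distance=sixmwt_distance)
    core = select_core_features(pca, feature_table, labels, alpha, corr_threshold)
    kw_p = {}
    for name in core:
        groups = [feature_table[name].to_numpy()[labels == c] for c in np.unique(labels)]
        kw_p[name] = kruskal(*groups).pvalue
    return ClusterResult(assignments=labels, pc_scores=scores, k=k,
                         core_features=core, kw_pvalues=pd.Series(kw_p),
                         dunn_tables={})
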
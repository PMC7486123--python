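"""scRNA-seq stage: QC, normalisation, gating, clustering, DE, classifier stability.

The processing chain mirrors the original Seurat-v2-era analysis of manually
collected, high-depth BLA neurons: cells under 10,000 total counts are
dropped, counts are normalised to counts-per-million (CPM, not per-10k),
non-neuronal cells are gated on Snap25 and interneurons on Gad1, variable
genes are chosen by a binned mean/dispersion z-score, cells are embedded
with PCA, clustered on a shared-nearest-neighbour graph with Louvain
modularity maximisation, and cluster markers are tested with a two-sided
Wilcoxon rank-sum test under Bonferroni control.
"""

from __future__ import annotations

import logging
import random as _random
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterResult, CountMatrix, DEResult, ExpressionMatrix, RFExperimentResult

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNTS = 10_000
DEFAULT_SNN_PRUNE = 1.0 / 15.0


def qc_filter(m: CountMatrix, min_counts: int = DEFAULT_MIN_COUNTS) -> tuple[CountMatrix, dict]:
    """Drop cells with total counts strictly below ``min_counts``.

    Returns the filtered matrix and a report dict with the removed cell ids
    and counts. A matrix whose every cell fails QC yields an empty matrix
    plus a warning in the report rather than an error.
    """
    totals = m.total_counts
    keep = totals >= min_counts
    removed = totals.index[~keep]
    report = {
        "min_counts": int(min_counts),
        "n_input": int(m.n_cells),
        "n_removed": int((~keep).sum()),
        "removed_cells": list(map(str, removed)),
    }
    if keep.sum() == 0 and m.n_cells > 0:
        report["warning"] = "all cells removed by QC"
        logger.warning("qc_filter removed every cell (min_counts=%d)", min_counts)
    return CountMatrix(m.counts.loc[:, keep]), report


def to_cpm(m: CountMatrix) -> ExpressionMatrix:
    """Convert counts to counts-per-million: CPM[g,c] = counts[g,c] / total_c * 1e6."""
    totals = m.total_counts
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][:5]
        raise ValueError(f"cells with zero total counts (QC them first): {list(bad)}")
    cpm = m.counts.astype(np.float64).div(totals.astype(np.float64), axis=1) * 1e6
    return ExpressionMatrix(cpm)


def gate_cell_classes(
    e: ExpressionMatrix,
    neuronal_gene: str = "Snap25",
    neuronal_min: float = 250.0,
    inh_gene: str = "Gad1",
    inh_min: float = 100.0,
) -> dict[str, pd.Index]:
    """Partition cells into non_neuronal / interneuron / excitatory classes.

    Non-neuronal: Snap25 CPM < 250 (strict). Interneuron: remaining cells
    with Gad1 CPM > 100 (strict). Excitatory: the remainder. Boundary values
    therefore stay in the "neuronal" and "excitatory" classes.
    """
    for g in (neuronal_gene, inh_gene):
        if g not in e.genes:
            raise KeyError(f"gate gene {g!r} absent from expression matrix")
    snap = e.cpm.loc[neuronal_gene]
    gad = e.cpm.loc[inh_gene]
    non_neuronal = e.cells[snap < neuronal_min]
    neuronal = e.cells[snap >= neuronal_min]
    inh = neuronal[gad.loc[neuronal] > inh_min]
    exc = neuronal[gad.loc[neuronal] <= inh_min]
    return {"non_neuronal": non_neuronal, "interneuron": inh, "excitatory": exc}


def select_variable_genes(
    e: ExpressionMatrix,
    x_low: float = 0.125,
    x_high: float = 3.0,
    y_cutoff: float = 1.0,
    n_bins: int = 20,
    cells: Sequence[str] | None = None,
) -> list[str]:
    """Mean/dispersion variable-gene selection (binned z-scored dispersion).

    Per gene, on the CPM layer: mean_stat = ln(mean(CPM) + 1) and
    dispersion = ln(var(CPM) / mean(CPM)). Dispersions are z-scored within
    ``n_bins`` equal-width bins of mean_stat, and genes satisfying
    ``x_low <= mean_stat <= x_high`` and ``z >= y_cutoff`` are returned.
    Genes with zero variance (or zero mean) have undefined dispersion and
    are excluded.
    """
    cpm = e.cpm if cells is None else e.cpm.loc[:, list(cells)]
    x = cpm.values
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(len(mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_stat = np.log1p(mean)
        disp = np.log(var / mean)
    ok = np.isfinite(disp)
    if not ok.any():
        return []
    # z-score dispersion within equal-width bins of the mean statistic
    edges = np.linspace(mean_stat[ok].min(), mean_stat[ok].max(), n_bins + 1)
    which = np.clip(np.digitize(mean_stat, edges) - 1, 0, n_bins - 1)
    z = np.full(len(mean), np.nan)
    for b in range(n_bins):
        sel = ok & (which == b)
        if sel.sum() == 0:
            continue
        d = disp[sel]
        sd = d.std(ddof=1) if sel.sum() > 1 else 0.0
        z[sel] = 0.0 if sd == 0 else (d - d.mean()) / sd
    keep = ok & (mean_stat >= x_low) & (mean_stat <= x_high) & (z >= y_cutoff)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("select_variable_genes: %d genes with undefined dispersion excluded", n_dropped)
    return list(cpm.index[keep])


def pca_embed(
    e: ExpressionMatrix,
    genes: Sequence[str],
    n_pcs: int = 10,
) -> pd.DataFrame:
    """PCA scores of cells on z-scored log-expression of ``genes``.

    Each gene's ln(1+CPM) profile is standardised over cells before PCA.
    The sign of each component is fixed by making the loading of largest
    magnitude positive, so scores are reproducible across runs.
    """
    genes = [g for g in genes if g in e.genes]
    if len(genes) < 2:
        raise ValueError("need at least 2 variable genes for PCA")
    X = e.log.loc[genes].values.T.astype(np.float64)  # cells x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    nonconst = sd > 0
    X = (X[:, nonconst] - mu[nonconst]) / sd[nonconst]
    max_pcs = min(X.shape[0] - 1, X.shape[1])
    if n_pcs > max_pcs:
        logger.warning("n_pcs=%d clipped to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=e.cells, columns=[f"PC{i + 1}" for i in range(n_pcs)])


def _snn_graph(scores: np.ndarray, k: int, prune: float) -> ig.Graph:
    """k-NN -> shared-nearest-neighbour Jaccard graph, edges below ``prune`` dropped.

    Neighbour sets include the cell itself (as in the Seurat SNN
    construction), so every Jaccard weight lies in (0, 1].
    """
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(scores)
    _, idx = nn.kneighbors(scores)
    member = np.zeros((n, n), dtype=np.uint8)
    rows = np.repeat(np.arange(n), k)
    member[rows, idx.ravel()] = 1
    member[np.arange(n), np.arange(n)] = 1  # self always a neighbour
    setsize = member.sum(axis=1)
    inter = (member @ member.T).astype(np.float64)
    union = setsize[:, None] + setsize[None, :] - inter
    with np.errstate(invalid="ignore"):
        jac = inter / union
    np.fill_diagonal(jac, 0.0)
    jac[jac < prune] = 0.0
    iu = np.triu_indices(n, 1)
    w = jac[iu]
    nz = w > 0
    edges = list(zip(iu[0][nz].tolist(), iu[1][nz].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = w[nz].tolist()
    return g


def cluster_graph(
    scores: pd.DataFrame,
    resolution: float,
    k: int = 20,
    n_pcs: int = 10,
    prune: float = DEFAULT_SNN_PRUNE,
    seed: int = 0,
) -> ClusterResult:
    """Louvain clustering of the SNN graph built in PC space.

    Labels are relabelled contiguously from 0 in decreasing cluster-size
    order, so label 0 is always the largest cluster.
    """
    n = scores.shape[0]
    if k >= n:
        logger.warning("k=%d clipped to %d (n_cells-1)", k, n - 1)
        k = n - 1
    use = scores.iloc[:, : min(n_pcs, scores.shape[1])].values
    g = _snn_graph(use, k=k, prune=prune)
    ig.set_random_number_generator(_random.Random(int(seed)))
    part = g.community_multilevel(weights="weight", resolution=float(resolution))
    raw = np.asarray(part.membership)
    order = pd.Series(raw).value_counts().index  # decreasing size
    remap = {int(old): new for new, old in enumerate(order)}
    labels = pd.Series([remap[int(v)] for v in raw], index=scores.index, name="cluster")
    return ClusterResult(labels=labels, resolution=resolution, n_pcs=n_pcs, k=k, prune=prune)


# ---------------------------------------------------------------------------
# rank-sum testing


def rank_sum_test(x: np.ndarray, y: np.ndarray, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    ``method='auto'`` uses the exact permutation distribution when both
    samples have <= 8 observations and no ties are present, and the
    tie-corrected normal approximation otherwise; 'exact' and 'normal'
    force the respective path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def _ranksum_screen(
    X: np.ndarray, a_cols: np.ndarray, b_cols: np.ndarray
) -> np.ndarray:
    """Vectorised two-sided tie-corrected normal-approximation rank-sum.

    ``X`` is genes x cells; returns one p-value per gene for group a vs b.
    Continuity correction of 0.5 is applied, matching the conventional
    large-sample Mann-Whitney test.
    """
    sub = X[:, np.concatenate([a_cols, b_cols])]
    n_a, n_b = len(a_cols), len(b_cols)
    n = n_a + n_b
    ranks = stats.rankdata(sub, axis=1)
    r_a = ranks[:, :n_a].sum(axis=1)
    u = r_a - n_a * (n_a + 1) / 2.0
    mean_u = n_a * n_b / 2.0
    # tie correction: sum over tied groups of (t^3 - t), per gene
    tie_term = np.zeros(sub.shape[0])
    srt = np.sort(sub, axis=1)
    has_tie = (np.diff(srt, axis=1) == 0).any(axis=1)
    for i in np.nonzero(has_tie)[0]:
        _, t = np.unique(srt[i], return_counts=True)
        tie_term[i] = float((t**3 - t).sum())
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(sub.shape[0])
    pos = var_u > 0
    z = (np.abs(u[pos] - mean_u) - 0.5) / np.sqrt(var_u[pos])
    p[pos] = 2.0 * stats.norm.sf(np.maximum(z, 0.0))
    return np.minimum(p, 1.0)


def differential_expression(
    e: ExpressionMatrix,
    labels: pd.Series,
    cluster_a: int,
    cluster_b: int,
    alpha: float = 0.05,
    min_cells_detected: int = 3,
) -> DEResult:
    """Two-sided Wilcoxon rank-sum DE between two clusters, Bonferroni-adjusted.

    Only genes detected (CPM > 0) in at least ``min_cells_detected`` cells of
    the two clusters combined are tested; the Bonferroni denominator is the
    number of genes actually tested. Direction (``enriched_in``) is the
    cluster with the larger mean CPM.
    """
    cells_a = labels.index[labels == cluster_a]
    cells_b = labels.index[labels == cluster_b]
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both clusters must be non-empty")
    if min(len(cells_a), len(cells_b)) < 3:
        raise ValueError("clusters of size < 3 give a rank-sum test with no useful power")
    sub = e.cpm.loc[:, list(cells_a) + list(cells_b)]
    detected = (sub.values > 0).sum(axis=1) >= min_cells_detected
    n_tested = int(detected.sum())
    logger.info("differential_expression: testing %d/%d genes past detection floor", n_tested, len(detected))
    logx = np.log1p(sub.values[detected])
    a_cols = np.arange(len(cells_a))
    b_cols = np.arange(len(cells_a), len(cells_a) + len(cells_b))
    p_raw = _ranksum_screen(logx, a_cols, b_cols)
    p_adj = np.minimum(p_raw * n_tested, 1.0)
    mean_a = sub.values[detected][:, a_cols].mean(axis=1)
    mean_b = sub.values[detected][:, b_cols].mean(axis=1)
    log_fc = np.log((mean_a + 1.0) / (mean_b + 1.0))
    enriched = np.where(mean_a >= mean_b, cluster_a, cluster_b)
    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "enriched_in": enriched,
        },
        index=sub.index[detected],
    )
    return DEResult(table=table, cluster_a=cluster_a, cluster_b=cluster_b, n_tested=n_tested)


def rf_subsample_experiment(
    e: ExpressionMatrix,
    labels: pd.Series,
    variable_genes: Sequence[str],
    n_train_grid: Iterable[int] = (50, 100, 200, 400, 800),
    n_reps: int = 100,
    n_trees: int = 500,
    seed: int = 0,
) -> RFExperimentResult:
    """Random-forest subsample classification stability experiment.

    For each training-set size, ``n_reps`` random subsets of cells are drawn;
    a random forest (``n_trees`` trees, default split criteria) is trained on
    the subset's log-expression over ``variable_genes`` and predicts the
    cluster identity of every remaining cell. Draws missing a class are
    redrawn (and counted in the log).
    """
    X = e.log.loc[list(variable_genes)].values.T
    y = labels.loc[e.cells].values
    n = X.shape[0]
    n_classes = len(np.unique(y))
    rng = np.random.default_rng(seed)
    acc: dict[tuple[int, int], float] = {}
    miss_count = np.zeros(n)
    holdout_count = np.zeros(n)
    n_redraws = 0
    for n_train in n_train_grid:
        if n_train >= n:
            raise ValueError(f"n_train={n_train} >= n_cells={n}")
        for rep in range(n_reps):
            while True:
                train = rng.choice(n, size=n_train, replace=False)
                if len(np.unique(y[train])) == n_classes:
                    break
                n_redraws += 1
            test = np.setdiff1d(np.arange(n), train)
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            wrong = pred != y[test]
            acc[(n_train, rep)] = 1.0 - wrong.mean()
            miss_count[test] += wrong
            holdout_count[test] += 1
    if n_redraws:
        logger.info("rf_subsample_experiment: %d training draws redrawn (missing class)", n_redraws)
    accuracies = pd.Series(acc, name="accuracy")
    accuracies.index = pd.MultiIndex.from_tuples(accuracies.index, names=["n_train", "replicate"])
    with np.errstate(invalid="ignore"):
        rate = np.where(holdout_count > 0, miss_count / np.maximum(holdout_count, 1), np.nan)
    per_cell = pd.Series(rate, index=e.cells, name="misclassification_rate")
    return RFExperimentResult(accuracies=accuracies, per_cell_miss=per_cell)


def embed_2d(
    scores: pd.DataFrame,
    method: str = "tsne",
    perplexity: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded 2-D embedding of PC scores for visualisation (plumbing only)."""
    n = scores.shape[0]
    if perplexity >= n / 3:
        raise ValueError(f"perplexity={perplexity} too large for {n} cells")
    if method != "tsne":
        raise ValueError(f"unknown embedding method {method!r}")
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=int(seed), init="pca")
    xy = ts.fit_transform(scores.values)
    return pd.DataFrame(xy, index=scores.index, columns=["dim1", "dim2"])


def exact_ranksum_enumeration(x: Sequence[float], y: Sequence[float]) -> float:
    """Exhaustive-enumeration two-sided rank-sum p-value (small samples).

    Enumerates every assignment of the pooled ranks to group x and computes
    the probability of a rank sum at least as extreme as observed. Intended
    as a slow reference for small problems; used by the 'auto' exact path's
    cross-checks rather than the genome-wide screen.
    """
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    obs = ranks[:n_x].sum()
    mean = ranks.sum() * n_x / len(pooled)
    dev = abs(obs - mean)
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), n_x):
        s = ranks[list(comb)].sum()
        if abs(s - mean) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total
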
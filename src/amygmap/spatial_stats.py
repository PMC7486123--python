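"""Spatial expression statistics: phenotype index, winner-take-all phenotyping,
distance-binned correlation profiles, and hierarchical clustering of CPA rows.

The phenotype index of a cell is (E_Cplx1 - E_Negr1) / (E_Cplx1 + E_Negr1),
where E is the counts-per-area expression of each discrete nucleus marker:
cells exclusively expressing Negr1 score -1, exclusively Cplx1 score +1, and
doubly-expressing cells fall in between. Graded (within-nucleus) structure is
summarised by Pearson correlation of each cell's 12-gene panel with every
other cell in the same section, averaged in 100-um distance bins and split by
same vs opposite binarised phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

GATE_GENE = "Slc17a7"
GATE_CPA = 0.004
DEFAULT_BIN_WIDTH_UM = 100.0


def phenotype_index(
    cells: pd.DataFrame | pd.Series,
    gene_a: str = "Negr1",
    gene_b: str = "Cplx1",
) -> pd.Series | float:
    """Relative-expression index (E_b - E_a)/(E_b + E_a) in [-1, 1].

    Accepts a table of cells (returns a Series aligned to it) or a single
    cell record (returns a float). Cells expressing neither gene have an
    undefined index, returned as NaN and excluded downstream.
    """
    single = isinstance(cells, pd.Series)
    frame = cells.to_frame().T if single else cells
    for g in (gene_a, gene_b):
        if g not in frame.columns:
            raise KeyError(f"gene column {g!r} missing from cell table")
    e_a = frame[gene_a].astype(float)
    e_b = frame[gene_b].astype(float)
    denom = e_a + e_b
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = (e_b - e_a) / denom
    idx = idx.where(denom > 0)
    return float(idx.iloc[0]) if single else idx.rename("phenotype_index")


def binarize_phenotype(
    cells: pd.DataFrame,
    gate_gene: str = GATE_GENE,
    gate_cpa: float = GATE_CPA,
    gene_a: str = "Negr1",
    gene_b: str = "Cplx1",
) -> pd.DataFrame:
    """Gate excitatory cells and assign winner-take-all discrete phenotypes.

    Cells with gate-gene CPA below ``gate_cpa`` (strict) are removed.
    Survivors are labelled by the higher-expressed of the two markers
    (``NEGR1`` / ``CPLX1``); exact nonzero ties break deterministically to
    CPLX1 and are logged; both-zero cells are labelled ``none``.
    """
    for g in (gate_gene, gene_a, gene_b):
        if g not in cells.columns:
            raise KeyError(f"gene column {g!r} missing from cell table")
    gated = cells[cells[gate_gene] >= gate_cpa].copy()
    e_a = gated[gene_a].astype(float).to_numpy()
    e_b = gated[gene_b].astype(float).to_numpy()
    pheno = np.where(e_a + e_b == 0, "none", np.where(e_a > e_b, "NEGR1", "CPLX1"))
    n_tie = int(((e_a == e_b) & (e_a > 0)).sum())
    if n_tie:
        logger.info("binarize_phenotype: %d exact marker ties broken toward CPLX1", n_tie)
    gated["phenotype"] = pheno
    return gated


@dataclass
class CorrelationProfile:
    """Distance-binned correlation curve for one seed cell.

    ``table`` is indexed by bin (left edge, half-open [b, b+width)) with
    columns same_mean, same_n, opp_mean, opp_n; empty bins hold NaN means.
    """

    seed_cell_id: str
    bin_width_um: float
    table: pd.DataFrame


def _pearson_to_seed(seed_vec: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Pearson r between one vector and each row of ``mat`` (NaN if degenerate)."""
    sv = seed_vec - seed_vec.mean()
    s_norm = np.sqrt((sv**2).sum())
    if s_norm == 0:
        raise ValueError("seed cell has a zero-variance expression vector")
    m = mat - mat.mean(axis=1, keepdims=True)
    m_norm = np.sqrt((m**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (m @ sv) / (m_norm * s_norm)
    return r


def correlation_profile(
    seed_cell_id: str,
    cells: pd.DataFrame,
    genes: list[str],
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
) -> CorrelationProfile:
    """Per-seed spatial profile of expression correlation, split by phenotype.

    Pearson r is computed between the seed's panel vector and every other
    cell in the same section; Euclidean distances are taken in the template
    frame, binned at ``bin_width_um`` with half-open left-closed edges, and
    averaged per bin separately for cells of the same and opposite
    binarised phenotype. The seed is excluded from its own profile.
    """
    sec_cells = cells[cells["section"] == cells.set_index("cell_id").loc[seed_cell_id, "section"]]
    sec_cells = sec_cells.set_index("cell_id")
    seed = sec_cells.loc[seed_cell_id]
    others = sec_cells.drop(index=seed_cell_id)
    others = others[others["phenotype"] != "none"]
    r = _pearson_to_seed(
        seed[genes].to_numpy(float), others[genes].to_numpy(float)
    )
    d = np.hypot(
        others["x_um"].to_numpy(float) - float(seed["x_um"]),
        others["y_um"].to_numpy(float) - float(seed["y_um"]),
    )
    same = (others["phenotype"] == seed["phenotype"]).to_numpy()
    n_bins = int(np.floor(d.max() / bin_width_um)) + 1 if len(d) else 0
    which = np.minimum((d // bin_width_um).astype(int), max(n_bins - 1, 0))
    rows = []
    for b in range(n_bins):
        inb = which == b
        row = {"bin": b * bin_width_um}
        for cls, mask in (("same", inb & same), ("opp", inb & ~same)):
            vals = r[mask]
            vals = vals[np.isfinite(vals)]
            row[f"{cls}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{cls}_n"] = len(vals)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("bin")[["same_mean", "same_n", "opp_mean", "opp_n"]]
    return CorrelationProfile(seed_cell_id=seed_cell_id, bin_width_um=bin_width_um, table=table)


def profiles_for_all_seeds(
    cells: pd.DataFrame,
    genes: list[str],
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
) -> pd.DataFrame:
    """Per-seed binned mean correlations for every phenotyped cell (vectorised).

    Equivalent to running :func:`correlation_profile` over every cell with a
    NEGR1/CPLX1 phenotype, returned as one long table (seed_cell_id, bin,
    same_mean, opp_mean). Distances are only computed within sections.
    """
    out = []
    for _, sec in cells[cells["phenotype"] != "none"].groupby("section", sort=False):
        X = sec[genes].to_numpy(float)
        sd = X.std(axis=1)
        if (sd == 0).any():
            raise ValueError("zero-variance expression vectors present; drop them first")
        Xc = X - X.mean(axis=1, keepdims=True)
        Xn = Xc / np.sqrt((Xc**2).sum(axis=1, keepdims=True))
        C = Xn @ Xn.T
        xy = sec[["x_um", "y_um"]].to_numpy(float)
        D = np.hypot(xy[:, 0:1] - xy[:, 0:1].T, xy[:, 1:2] - xy[:, 1:2].T)
        same = (sec["phenotype"].to_numpy()[:, None] == sec["phenotype"].to_numpy()[None, :])
        n = len(sec)
        bins = (D // bin_width_um).astype(int)
        n_bins = bins.max() + 1
        eye = np.eye(n, dtype=bool)
        for cls, mask in (("same", same & ~eye), ("opp", ~same)):
            # per-seed per-bin sums via bincount on flattened (seed, bin) keys
            keys = (np.arange(n)[:, None] * n_bins + bins)[mask]
            sums = np.bincount(keys, weights=C[mask], minlength=n * n_bins).reshape(n, n_bins)
            cnts = np.bincount(keys, minlength=n * n_bins).reshape(n, n_bins)
            with np.errstate(invalid="ignore"):
                means = sums / cnts
            df = pd.DataFrame(means, index=sec["cell_id"].to_numpy(),
                              columns=np.arange(n_bins) * bin_width_um)
            long = df.stack(future_stack=True).rename(f"{cls}_mean")
            out.append(long)
    same_all = pd.concat([s for s in out if s.name == "same_mean"])
    opp_all = pd.concat([s for s in out if s.name == "opp_mean"])
    res = pd.concat([same_all, opp_all], axis=1)
    res.index.names = ["seed_cell_id", "bin"]
    return res.reset_index()


def aggregate_profiles(profiles: pd.DataFrame | list[CorrelationProfile]) -> pd.DataFrame:
    """Across-seed mean and SD of per-seed bin means, per bin and class.

    Accepts either the long table from :func:`profiles_for_all_seeds` or a
    list of :class:`CorrelationProfile`. Bins empty for a given seed are
    missing for that seed and simply do not contribute; the SD of a
    single-seed bin is reported as 0 by convention.
    """
    if isinstance(profiles, list):
        if len(profiles) < 1:
            raise ValueError("need at least one profile")
        widths = {p.bin_width_um for p in profiles}
        if len(widths) != 1:
            raise ValueError("profiles have inconsistent bin grids")
        frames = []
        for p in profiles:
            t = p.table[["same_mean", "opp_mean"]].copy()
            t["seed_cell_id"] = p.seed_cell_id
            frames.append(t.reset_index())
        long = pd.concat(frames, ignore_index=True)
    else:
        long = profiles
    rows = []
    for b, grp in long.groupby("bin"):
        for cls in ("same", "opp"):
            v = grp[f"{cls}_mean"].dropna()
            if len(v) == 0:
                rows.append((b, cls, np.nan, np.nan, 0))
            else:
                rows.append((b, cls, v.mean(), v.std(ddof=1) if len(v) > 1 else 0.0, len(v)))
    return pd.DataFrame(rows, columns=["bin", "cls", "mean_r", "sd", "n_seeds"])


def profile_distance_trend(aggregate: pd.DataFrame, cls: str = "same") -> tuple[float, float]:
    """Spearman rho and p of mean correlation vs bin distance for one class."""
    sub = aggregate[(aggregate["cls"] == cls) & aggregate["mean_r"].notna()]
    rho, p = spearmanr(sub["bin"], sub["mean_r"])
    return float(rho), float(p)


def cluster_mfish(
    cells: pd.DataFrame,
    genes: list[str],
    k: int,
    method: str = "ward_d2",
    metric: str = "euclidean",
) -> tuple[pd.Series, np.ndarray]:
    """Ward-D2 hierarchical clustering of sum-to-1-normalised CPA rows.

    Each cell's CPA vector is normalised to sum 1 (zero-total cells are
    excluded and logged); agglomeration uses Ward's D2 criterion on
    Euclidean distances and the tree is cut at ``k`` clusters. Returns the
    labels (1..k, indexed by cell_id) and the scipy linkage matrix.
    """
    if method != "ward_d2" or metric != "euclidean":
        raise ValueError("only Ward-D2 linkage on Euclidean distances is supported")
    X = cells[genes].to_numpy(float)
    totals = X.sum(axis=1)
    keep = totals > 0
    if (~keep).any():
        logger.info("cluster_mfish: %d zero-total cells excluded", int((~keep).sum()))
    Xn = X[keep] / totals[keep, None]
    Z = linkage(Xn, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=cells.loc[keep, "cell_id"].to_numpy(), name="cluster"), Z


def bimodality_summary(
    indices: pd.Series | np.ndarray,
    n_bins: int = 20,
    extreme_threshold: float = 0.8,
) -> dict:
    """Histogram of phenotype indices over [-1, 1] plus an extremeness fraction.

    The extremeness fraction is the share of defined indices with
    ``|index| >= extreme_threshold``. Empty (or all-undefined) input yields
    zero counts and a None fraction.
    """
    v = np.asarray(pd.Series(indices).dropna(), dtype=float)
    counts, edges = np.histogram(v, bins=n_bins, range=(-1.0, 1.0))
    frac = float((np.abs(v) >= extreme_threshold).mean()) if len(v) else None
    return {
        "counts": counts,
        "edges": edges,
        "n": int(len(v)),
        "extreme_threshold": extreme_threshold,
        "extreme_fraction": frac,
    }
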
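"""Monte-Carlo null models for projection enrichment and spatial restriction.

Whether a retrogradely labelled projection population is enriched in the LA
or BA is judged against repeated random selection of equal-size cell sets
from the pool of excitatory BLA neurons: 1000 draws give the null mean and
95% percentile interval, and enrichment is declared when the observed count
falls outside it. Spatial restriction within a nucleus is judged the same
way on the mean pairwise distance statistic. Cell-body-area group
differences use unpaired two-sided Mann-Whitney U tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 1000


@dataclass
class NullDistribution:
    """Monte-Carlo null of a statistic with percentile CI and empirical p.

    ``p_value`` uses the +1 correction, (1 + #draws at least as extreme) /
    (1 + n_iter), so it is never exactly 0; 0 exceedances in 1000 draws
    reports p = 1/1001 < 0.001.
    """

    statistic: str
    observed: float
    draws: np.ndarray
    n_iter: int
    ci_level: float = 0.95

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def ci(self) -> tuple[float, float]:
        lo = (1.0 - self.ci_level) / 2.0 * 100.0
        return tuple(np.percentile(self.draws, [lo, 100.0 - lo]))

    def contains_observed(self) -> bool:
        lo, hi = self.ci
        return lo <= self.observed <= hi

    @property
    def enriched(self) -> bool:
        """True when the observed statistic falls outside the 95% CI."""
        return not self.contains_observed()

    def p_two_sided(self) -> float:
        dev = abs(self.observed - self.mean)
        extreme = int((np.abs(self.draws - self.mean) >= dev - 1e-12).sum())
        return (1 + extreme) / (1 + self.n_iter)

    def p_lower(self) -> float:
        extreme = int((self.draws <= self.observed + 1e-12).sum())
        return (1 + extreme) / (1 + self.n_iter)

    def summary(self) -> dict:
        lo, hi = self.ci
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.mean,
            "ci_low": float(lo),
            "ci_high": float(hi),
            "n_iter": self.n_iter,
            "p_two_sided": self.p_two_sided(),
            "enriched": self.enriched,
        }


def mc_enrichment(
    observed: pd.DataFrame,
    pool: pd.DataFrame,
    region: str = "LA",
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    replace: bool = False,
) -> NullDistribution:
    """Monte-Carlo enrichment null for a projection's regional cell count.

    Draws ``n_iter`` random selections of N cells (N = number of observed
    projection cells) from the excitatory pool — without replacement by
    default — and counts how many fall in ``region``. The observed count is
    compared against the 95% percentile interval of the draws.
    """
    for frame, name in ((observed, "observed"), (pool, "pool")):
        if "region" not in frame.columns:
            raise ValueError(f"{name} table lacks a 'region' column (run assign_region)")
    n = len(observed)
    if not replace and n > len(pool):
        raise ValueError(f"N={n} observed cells exceed pool size {len(pool)}")
    obs_count = int((observed["region"] == region).sum())
    in_region = (pool["region"] == region).to_numpy()
    rng = np.random.default_rng(seed)
    draws = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        pick = rng.choice(len(pool), size=n, replace=replace)
        draws[i] = int(in_region[pick].sum())
    return NullDistribution(
        statistic=f"n_cells_in_{region}", observed=float(obs_count), draws=draws.astype(float),
        n_iter=n_iter,
    )


def mean_pairwise_distance(cells: pd.DataFrame) -> float:
    """Mean Euclidean pairwise distance of a coordinate table (um)."""
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    if len(xy) < 2:
        raise ValueError("need at least 2 cells for a pairwise distance")
    return float(pdist(xy).mean())


def median_pairwise_distance(cells: pd.DataFrame) -> float:
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    if len(xy) < 2:
        raise ValueError("need at least 2 cells for a pairwise distance")
    return float(np.median(pdist(xy)))


def mc_distance_restriction(
    observed: pd.DataFrame,
    pool: pd.DataFrame,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    statistic: str = "mean",
) -> NullDistribution:
    """Spatial-restriction null: is the projection tighter than random cells?

    The statistic is the mean (or median) pairwise distance of the observed
    cells; the null repeats it on equal-size random subsets of the pool.
    Restriction is a one-sided question — use :meth:`NullDistribution.p_lower`
    for the probability of a null draw at least as tight as observed.
    """
    stat_fn = {"mean": mean_pairwise_distance, "median": median_pairwise_distance}[statistic]
    obs_stat = stat_fn(observed)
    n = len(observed)
    if n > len(pool):
        raise ValueError("observed set larger than pool")
    xy = pool[["x_um", "y_um"]].to_numpy(float)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_iter)
    for i in range(n_iter):
        pick = rng.choice(len(pool), size=n, replace=False)
        draws[i] = pdist(xy[pick]).mean() if statistic == "mean" else float(np.median(pdist(xy[pick])))
    return NullDistribution(
        statistic=f"{statistic}_pairwise_distance_um", observed=obs_stat, draws=draws,
        n_iter=n_iter,
    )


def area_compare(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests on cell-body areas.

    No multiplicity adjustment is applied (each pair is reported raw); the
    number of comparisons performed is logged. Groups need n >= 3.
    """
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
    rows = []
    for a, b in combinations(groups, 2):
        res = mannwhitneyu(groups[a], groups[b], alternative="two-sided", method="auto")
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    logger.info("area_compare: %d pairwise comparisons, no multiplicity adjustment", len(rows))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p_value"])
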
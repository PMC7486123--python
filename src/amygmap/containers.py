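"""Core in-memory containers shared across pipeline stages.

Counts and expression live in gene x cell :class:`pandas.DataFrame` objects
(genes as rows, matching the on-disk orientation of the delimited and
matrix-market inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer gene x cell count matrix.

    Parameters
    ----------
    counts
        DataFrame with gene identifiers as the index and cell identifiers as
        columns; entries are non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate cell identifiers")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("negative counts")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    @property
    def total_counts(self) -> pd.Series:
        """Per-cell total counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class ExpressionMatrix:
    """CPM-normalised expression with a ln(1 + CPM) layer.

    ``cpm`` columns each sum to 1e6 whenever the originating cell had any
    counts. The log layer is computed lazily and cached.
    """

    cpm: pd.DataFrame
    _log: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def log(self) -> pd.DataFrame:
        if self._log is None:
            self._log = np.log1p(self.cpm)
        return self._log

    @property
    def genes(self) -> pd.Index:
        return self.cpm.index

    @property
    def cells(self) -> pd.Index:
        return self.cpm.columns


@dataclass
class ClusterResult:
    """Graph-clustering labels for the retained cells.

    Labels are contiguous integers from 0, ordered by decreasing cluster
    size (cluster 0 is the largest).
    """

    labels: pd.Series
    resolution: float
    n_pcs: int
    k: int
    prune: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class DEResult:
    """Per-gene two-group differential expression with Bonferroni control.

    ``table`` columns: log_fc (natural-log fold change of mean CPM),
    p_raw, p_adj, enriched_in (cluster id with the higher mean).
    ``n_tested`` is the Bonferroni denominator (genes passing the
    detection floor).
    """

    table: pd.DataFrame
    cluster_a: int
    cluster_b: int
    n_tested: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


@dataclass
class RFExperimentResult:
    """Random-forest subsample classification experiment.

    ``accuracies`` is indexed by (n_train, replicate); ``per_cell_miss``
    maps each cell to its misclassification rate across the replicates in
    which it was held out.
    """

    accuracies: pd.Series
    per_cell_miss: pd.Series

    def mean_accuracy(self, n_train: int) -> float:
        return float(self.accuracies.xs(n_train, level="n_train").mean())
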
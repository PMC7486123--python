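"""End-to-end orchestration: simulate -> scRNA-seq -> spatial -> projections.

`run_all` executes the full synthetic study under one seed and returns a
structured report whose every number is traceable to a stage, the resolved
configuration (echoed and hashed into the report) and the seed. The report
is deterministic: the same config and seed reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import __version__, sc_pipeline, spatial_stats, synthdata
from .projection_null import mc_distance_restriction, mc_enrichment
from .spatial_register import assign_region


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run.

    Stage thresholds default to the study's printed values (QC 10,000
    counts; Snap25 250 / Gad1 100 CPM gates; variable-gene cutoffs
    0.125/3/1; 10 PCs; resolutions 0.2 and 0.8; Bonferroni alpha 0.05;
    Slc17a7 CPA gate 0.004; 1000 Monte-Carlo iterations). Unknown keys in
    ``from_dict`` raise rather than being ignored.
    """

    seed: int = 0
    sc: dict[str, Any] = field(default_factory=dict)          # ScSimConfig overrides
    spatial: dict[str, Any] = field(default_factory=dict)     # SpatialSimConfig overrides
    qc_min_counts: int = 10_000
    neuronal_min_cpm: float = 250.0
    inh_max_cpm: float = 100.0
    vargenes_x_low: float = 0.125
    vargenes_x_high: float = 3.0
    vargenes_y_cutoff: float = 1.0
    n_pcs: int = 10
    knn_k: int = 20
    resolution_coarse: float = 0.2
    resolution_fine: float = 0.8
    de_alpha: float = 0.05
    rf_n_train: int = 100
    rf_n_reps: int = 20
    gate_cpa: float = 0.004
    profile_bin_um: float = 100.0
    mc_n_iter: int = 1000
    proj_n_cells: int = 80
    proj_spread_um: float = 150.0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and math.isnan(x):
        return None
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage on synthetic data and return the reproducibility report."""
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }

    # --- simulate + scRNA-seq stage
    sc_cfg = synthdata.ScSimConfig(seed=config.seed, **config.sc)
    counts, truth = synthdata.gen_counts(sc_cfg)
    filtered, qc_report = sc_pipeline.qc_filter(counts, config.qc_min_counts)
    e = sc_pipeline.to_cpm(filtered)
    classes = sc_pipeline.gate_cell_classes(
        e, neuronal_min=config.neuronal_min_cpm, inh_min=config.inh_max_cpm
    )
    exc = classes["excitatory"]
    from .containers import CountMatrix  # local to avoid cycle at import time

    e_exc = sc_pipeline.to_cpm(CountMatrix(filtered.counts.loc[:, exc]))
    var_genes = sc_pipeline.select_variable_genes(
        e_exc, x_low=config.vargenes_x_low, x_high=config.vargenes_x_high,
        y_cutoff=config.vargenes_y_cutoff,
    )
    scores = sc_pipeline.pca_embed(e_exc, var_genes, n_pcs=config.n_pcs)
    coarse = sc_pipeline.cluster_graph(
        scores, resolution=config.resolution_coarse, k=config.knn_k,
        n_pcs=config.n_pcs, seed=config.seed,
    )
    fine = sc_pipeline.cluster_graph(
        scores, resolution=config.resolution_fine, k=config.knn_k,
        n_pcs=config.n_pcs, seed=config.seed,
    )
    truth_pop = truth.population.loc[coarse.labels.index]
    sizes = coarse.sizes()
    sc_report = {
        "qc": qc_report,
        "n_excitatory": int(len(exc)),
        "n_interneuron": int(len(classes["interneuron"])),
        "n_non_neuronal": int(len(classes["non_neuronal"])),
        "n_variable_genes": len(var_genes),
        "n_coarse_clusters": coarse.n_clusters,
        "n_fine_clusters": fine.n_clusters,
        "coarse_sizes": sizes.to_dict(),
        "minor_cluster_fraction": float(sizes.min() / sizes.sum()),
        "ari_vs_truth": float(adjusted_rand_score(truth_pop.values, coarse.labels.values)),
    }
    if coarse.n_clusters >= 2:
        de = sc_pipeline.differential_expression(
            e_exc, coarse.labels, 0, 1, alpha=config.de_alpha
        )
        sc_report["n_de_genes"] = int(len(de.significant(config.de_alpha)))
        sc_report["n_genes_tested"] = de.n_tested
        rf = sc_pipeline.rf_subsample_experiment(
            e_exc, coarse.labels, var_genes,
            n_train_grid=[config.rf_n_train], n_reps=config.rf_n_reps,
            seed=config.seed + 1,
        )
        sc_report["rf_mean_accuracy"] = rf.mean_accuracy(config.rf_n_train)
    report["scrnaseq"] = sc_report

    # --- spatial stage
    sp_cfg = synthdata.SpatialSimConfig(seed=config.seed, **config.spatial)
    cells, sp_truth = synthdata.gen_all_sections(sp_cfg)
    gated = spatial_stats.binarize_phenotype(cells, gate_cpa=config.gate_cpa)
    idx = spatial_stats.phenotype_index(gated)
    summary = spatial_stats.bimodality_summary(idx)
    phen = gated[gated["phenotype"] != "none"]
    profiles = spatial_stats.profiles_for_all_seeds(
        phen, list(sp_cfg.marker_panel), bin_width_um=config.profile_bin_um
    )
    agg = spatial_stats.aggregate_profiles(profiles)
    rho, p_trend = spatial_stats.profile_distance_trend(agg, "same")
    near = agg[agg["bin"] == 0].set_index("cls")["mean_r"]
    report["spatial"] = {
        "n_cells": int(len(cells)),
        "n_gated": int(len(gated)),
        "n_phenotyped": int(len(phen)),
        "extreme_fraction": summary["extreme_fraction"],
        "same_trend_spearman_rho": rho,
        "same_trend_p": p_trend,
        "nearest_bin_same_r": float(near["same"]),
        "nearest_bin_opp_r": float(near["opp"]),
    }

    # --- projection stage: an LA-targeted projection and a BA-restricted one
    tpl = synthdata.default_template("intermediate")
    pool = assign_region(
        phen[phen["section"] == "intermediate"], tpl
    )
    pool = pool[pool["region"] != "outside"]
    la_centroid = tpl.la.centroid
    ba_centroid = tpl.ba.centroid
    obs_la = synthdata.gen_projection_cells(
        tpl, "LA", (la_centroid.x, la_centroid.y), config.proj_spread_um,
        config.proj_n_cells, seed=config.seed + 11,
    )
    obs_la = assign_region(obs_la, tpl)
    enrich = mc_enrichment(obs_la, pool, region="LA", n_iter=config.mc_n_iter,
                           seed=config.seed + 12)
    obs_ba = synthdata.gen_projection_cells(
        tpl, "BA", (ba_centroid.x, ba_centroid.y), config.proj_spread_um,
        config.proj_n_cells, seed=config.seed + 13,
    )
    restrict = mc_distance_restriction(
        obs_ba, pool[pool["region"] == "BA"], n_iter=config.mc_n_iter,
        seed=config.seed + 14,
    )
    report["projections"] = {
        "la_enrichment": enrich.summary(),
        "ba_restriction": {**restrict.summary(), "p_restriction": restrict.p_lower()},
    }
    return _jsonable(report)
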
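"""End-to-end orchestration: normalise → filter → correlations → landscape →
element classification → PCA validation → temporal clustering → set
comparison, with a machine-readable summary report.

The pipeline's narrative is a count chain — genes retained after the TPM
filter, after top-expressor removal, split into attractor /
pseudo-attractor / non-attractor / no-response, then the stringent and
fold-change comparison sets — so counts are first-class content of both
the log and the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attractor_landscape import (attractor_boundary, sample_ensembles,
                                  spd_landscape, whole_transcriptome_trajectory)
from .corr_metrics import temporal_series
from .element_classify import (classify_elements, element_trajectories,
                               no_response_genes, partition_elements,
                               rank_genes)
from .io_normalize import (filter_low_expression, read_expression,
                           read_gene_lengths, remove_top_expressed,
                           tpm_normalize)
from .synthetic_data import SyntheticConfig, generate_timecourse
from .temporal_clustering import (compare_sets, fold_change_set,
                                  refine_groups, stringent_filter,
                                  ward_cluster)
from .trajectory_pca import pc_trajectory, zscore_normalize

logger = logging.getLogger("attractorscape")

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Every tunable of the full analysis, with the study defaults."""

    counts_path: str | None = None
    lengths_path: str | None = None
    design_path: str | None = None
    synthetic: dict | None = None        # SyntheticConfig fields
    tpm_threshold: float = 5.0
    summary_rule: str = "mean"
    drop_top: int = 2
    element_size: int = 100
    ensemble_repeats: int = 100
    mi_bins: int = 10
    mi_permutations: int = 100
    no_response_fold: float = 1.12
    ranking_mode: str = "sd"
    deviation_scale: str = "tpm"
    endpoint_rule: str = "last"
    initial_clusters: int = 13
    refine_r: float = 0.7
    stringent_tpm: float = 500.0
    stringent_fold: float = 3.0
    comparison_fold: float = 2.0
    grid_size: int = 100
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def __post_init__(self) -> None:
        for name in ("tpm_threshold", "element_size", "ensemble_repeats",
                     "mi_bins", "mi_permutations", "no_response_fold",
                     "refine_r", "stringent_tpm", "stringent_fold",
                     "comparison_fold", "grid_size"):
            if getattr(self, name) <= 0 and name != "tpm_threshold":
                raise ValueError(f"{name} must be positive")


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        counts, lengths, _design, truth = generate_timecourse(
            SyntheticConfig(**syn))
        return counts, lengths, truth
    if not (config.counts_path and config.lengths_path and config.design_path):
        raise ValueError("provide counts/lengths/design paths or a synthetic block")
    counts = read_expression(config.counts_path, config.design_path)
    lengths = read_gene_lengths(config.lengths_path)
    return counts, lengths, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary report dict."""
    cfg = config
    counts, lengths, truth = _load_inputs(cfg)
    logger.info("stage=input genes=%d samples=%d", *counts.values.shape)

    tpm = tpm_normalize(counts, lengths)
    filtered = filter_low_expression(tpm, cfg.tpm_threshold, cfg.summary_rule)
    logger.info("stage=tpm_filter retained=%d removed=%d",
                filtered.log["low_expression_filter"]["retained"],
                filtered.log["low_expression_filter"]["removed"])
    expr = remove_top_expressed(filtered, cfg.drop_top)
    dropped_top = expr.log["top_expressed_removed"]["dropped"]
    logger.info("stage=top_removal dropped=%s genes=%d", dropped_top,
                expr.values.shape[0])

    series = {m: temporal_series(expr, m, k=cfg.mi_bins,
                                 n_permutations=cfg.mi_permutations,
                                 seed=cfg.seed)
              for m in ("pearson", "spearman", "bicor", "mi_c")}

    ensemble = sample_ensembles(expr, cfg.element_size,
                                repeats=cfg.ensemble_repeats, seed=cfg.seed,
                                k=cfg.mi_bins,
                                n_permutations=cfg.mi_permutations,
                                scale=cfg.deviation_scale)
    landscape = spd_landscape(ensemble, grid_size=cfg.grid_size)
    boundary = attractor_boundary(landscape)
    whole_traj = whole_transcriptome_trajectory(ensemble)
    logger.info("stage=landscape peaks=%d boundary_level=%.4g",
                len(landscape.peaks), boundary.level)

    ordering = rank_genes(expr, mode=cfg.ranking_mode)
    partition = partition_elements(ordering, cfg.element_size,
                                   ranking_mode=cfg.ranking_mode)
    trajectories = element_trajectories(partition, expr, k=cfg.mi_bins,
                                        n_permutations=cfg.mi_permutations,
                                        seed=cfg.seed,
                                        scale=cfg.deviation_scale)
    classification = classify_elements(
        trajectories, boundary, whole_traj, partition=partition, expr=expr,
        peak=landscape.major_peak[:2], endpoint=cfg.endpoint_rule,
        k=cfg.mi_bins, n_permutations=cfg.mi_permutations, seed=cfg.seed,
        scale=cfg.deviation_scale)
    sets = classification.gene_sets
    attractor_all = sets["attractor"] | sets["pseudo_attractor"]
    non_attr = sets["non_attractor"]
    no_resp = no_response_genes(expr, genes=non_attr,
                                fold_threshold=cfg.no_response_fold)
    collective_non = non_attr - no_resp
    logger.info("stage=classify attractor=%d non_attractor=%d no_response=%d",
                len(attractor_all), len(non_attr), len(no_resp))

    pca = {}
    pca_sets = {"whole": set(expr.gene_ids), "attractor": attractor_all,
                "non_attractor": non_attr}
    for name, genes in pca_sets.items():
        if genes:
            pca[name] = pc_trajectory(expr, sorted(genes), gene_set=name)

    clustering = None
    if attractor_all:
        zsub = zscore_normalize(expr, sorted(attractor_all))
        # cluster on replicate-averaged z profiles
        zmean = zsub.T.groupby(
            expr.design.loc[zsub.columns, "time_min"].to_numpy()).mean().T
        kk = min(cfg.initial_clusters, zmean.shape[0])
        initial = ward_cluster(zmean, kk)
        clustering = refine_groups(initial, zmean, r_threshold=cfg.refine_r)
        logger.info("stage=cluster initial=%d refined=%d", kk,
                    clustering.n_groups)

    stringent = stringent_filter(expr, attractor_all, cfg.stringent_tpm,
                                 cfg.stringent_fold) if attractor_all else set()
    fold_set = fold_change_set(expr, cfg.comparison_fold)
    venn = compare_sets(attractor_all, fold_set)

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items() if v is not None},
        "counts": {
            "input_genes": int(counts.values.shape[0]),
            "retained_after_tpm_filter":
                filtered.log["low_expression_filter"]["retained"],
            "removed_by_tpm_filter":
                filtered.log["low_expression_filter"]["removed"],
            "dropped_top_expressed": dropped_top,
            "analysed_genes": int(expr.values.shape[0]),
            "elements": partition.p,
            "attractor": len(attractor_all),
            "core_attractor": len(sets["attractor"]),
            "pseudo_attractor": len(sets["pseudo_attractor"]),
            "non_attractor": len(non_attr),
            "no_response": len(no_resp),
            "collective_non_attractor": len(collective_non),
            "stringent": len(stringent),
            "fold_change": len(fold_set),
            "venn": venn.counts,
        },
        "element_labels": classification.element_labels,
        "element_distances": [round(d, 6) for d in
                              classification.element_distances],
        "landscape": {
            "n_peaks": len(landscape.peaks),
            "major_peak": list(landscape.major_peak),
            "boundary_level": boundary.level,
            "n_superimposed": landscape.n_superimposed,
        },
        "correlation_series": {
            m: {str(rep): [round(v, 6) for v in s.values[rep]]
                for rep in s.values.columns}
            for m, s in series.items()
        },
        "pca": {name: {"top2_variance": p.top2_variance,
                       "trajectory": p.scores.round(6).to_dict("list")}
                for name, p in pca.items()},
        "clustering": ({"initial": int(clustering.initial_clusters.nunique()),
                        "refined_groups": clustering.n_groups,
                        "converged": clustering.converged}
                       if clustering is not None else None),
    }
    report["gene_sets"] = {
        "attractor": sorted(attractor_all),
        "non_attractor": sorted(non_attr),
        "no_response": sorted(no_resp),
        "stringent": sorted(stringent),
        "fold_change": sorted(fold_set),
    }
    if truth is not None:
        truth_attr = set(truth.attractor_genes) & set(expr.gene_ids)
        inter = len(truth_attr & attractor_all)
        union = len(truth_attr | attractor_all)
        report["truth_recovery"] = {
            "planted_attractor_in_analysis": len(truth_attr),
            "jaccard_attractor": (inter / union) if union else float("nan"),
            "outliers_dropped": sorted(set(truth.outlier_genes)
                                       & set(dropped_top)),
        }
    return report


def write_report(report: dict, output_dir: str | Path) -> Path:
    """Write the JSON report plus a short human-readable summary."""
    if not report:
        raise ValueError("empty report")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True,
                               default=_json_default))
    lines = ["attractorscape summary", "======================"]
    for key, val in report.get("counts", {}).items():
        lines.append(f"{key}: {val}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    if isinstance(obj, (pd.Series, np.ndarray)):
        return list(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
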
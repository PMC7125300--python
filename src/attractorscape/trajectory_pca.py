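"""Principal-component sample trajectories as a validation of gene sets.

Samples (time × replicate columns) are projected onto the first two
principal axes of the z-score-normalised samples × genes matrix; per-time
scores are averaged over replicates.  An attractor gene set is expected to
track the whole-transcriptome trajectory in this plane, a non-attractor
set to show a smaller-scale drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .corr_metrics import CorrelationSeries, temporal_series
from .io_normalize import ExpressionMatrix

__all__ = ["PCTrajectory", "zscore_normalize", "pc_trajectory",
           "set_correlation_curves"]


@dataclass
class PCTrajectory:
    scores: pd.DataFrame          # index time_min, columns ["pc1", "pc2"]
    variance_explained: np.ndarray  # fraction per component, all components
    gene_set: str = ""

    @property
    def top2_variance(self) -> float:
        return float(self.variance_explained[:2].sum())


def zscore_normalize(expr: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Per-gene z-scores across samples (population SD).

    Constant genes carry no directional information and are dropped with a
    warning.
    """
    values = expr.values if genes is None else expr.values.loc[list(genes)]
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.all():
        raise ValueError("every gene in the subset is constant")
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant genes")
        values, mu, sd = values[~constant], mu[~constant], sd[~constant]
    return values.sub(mu, axis=0).div(sd, axis=0)


def pc_trajectory(expr: ExpressionMatrix, genes=None, normalize: bool = True,
                  gene_set: str = "") -> PCTrajectory:
    """Replicate-averaged (PC1, PC2) sample trajectory for one gene set.

    PCA is fitted on the samples × genes matrix of the subset (samples are
    the observations).  Each component's sign is fixed so that its loading
    vector has a positive sum, removing the SVD sign ambiguity.
    """
    if normalize:
        mat = zscore_normalize(expr, genes)
    else:
        mat = expr.values if genes is None else expr.values.loc[list(genes)]
    x = mat.to_numpy(dtype=float).T  # samples × genes
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    pca = PCA()
    scores = pca.fit_transform(x)
    sign = np.where(pca.components_.sum(axis=1) >= 0, 1.0, -1.0)
    scores = scores * sign
    sc = pd.DataFrame(scores[:, :2], index=mat.columns,
                      columns=["pc1", "pc2"])
    sc["time_min"] = expr.design.loc[sc.index, "time_min"].to_numpy()
    mean_sc = sc.groupby("time_min")[["pc1", "pc2"]].mean()
    return PCTrajectory(scores=mean_sc,
                        variance_explained=pca.explained_variance_ratio_,
                        gene_set=gene_set)


def set_correlation_curves(expr: ExpressionMatrix, gene_sets: dict,
                           metrics=("pearson", "spearman", "bicor", "mi_c"),
                           **mi_kwargs) -> dict:
    """Temporal correlation curves restricted to each gene set.

    Returns {(set_name, metric): CorrelationSeries}.
    """
    out: dict[tuple, CorrelationSeries] = {}
    for name, genes in gene_sets.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        sub = expr.subset_genes(genes)
        for metric in metrics:
            out[(name, metric)] = temporal_series(sub, metric, **mi_kwargs)
    return out
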
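"""Transcriptomic elements and attractor / non-attractor gene classification.

Genes are ranked by temporal variability, cut into consecutive blocks of n
genes ("transcriptomic elements"; the final block takes the last n genes
and may overlap its predecessor), and each element's (R_v, MI_v) trajectory
is classified against the attractor basin:

* in_basin — the trajectory endpoint lies inside the basin boundary;
* above_basin — outside, at higher MI_v than the basin peak (the element
  outran the whole-transcriptome convergence);
* below_basin — outside, at lower MI_v (weak or incoherent response).

Elements above or in the basin form the core attractor set.  Below-basin
elements whose trajectories stay closer than average (mean pointwise
Euclidean distance) to the whole-transcriptome trajectory are
pseudo-attractor candidates; they are confirmed only if their merged gene
set's trajectory itself enters the basin.  Genes whose maximal temporal
fold change stays below 1.12 form the separate no-response set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .attractor_landscape import (BasinBoundary, CorrelationTrajectory,
                                  _dev_arrays, _traj_from_rows, point_in_basin)
from .io_normalize import ExpressionMatrix

__all__ = [
    "ElementPartition",
    "ClassificationResult",
    "rank_genes",
    "partition_elements",
    "element_trajectories",
    "classify_elements",
    "no_response_genes",
    "max_fold_change",
]


@dataclass
class ElementPartition:
    ordering: list
    n: int
    elements: list  # list of gene-ID lists, each of length n
    ranking_mode: str = "sd"

    @property
    def p(self) -> int:
        return len(self.elements)


@dataclass
class ClassificationResult:
    element_labels: list            # per element: above_basin/in_basin/below_basin
    element_distances: list         # per element: mean distance to whole trajectory
    gene_sets: dict                 # attractor, pseudo_attractor, non_attractor
    merged_trajectories: dict = field(default_factory=dict)
    merged_in_basin: dict = field(default_factory=dict)
    pseudo_candidate_elements: list = field(default_factory=list)
    distance_threshold: float = float("nan")


def max_fold_change(expr: ExpressionMatrix, genes=None,
                    pseudo_tpm: float = 0.5) -> pd.Series:
    """Max fold change between any two time points, replicate-averaged.

    Computed as max/min of the replicate-mean temporal profile; a
    pseudo-expression of `pseudo_tpm` guards against zero denominators on
    count-derived TPMs.
    """
    prof = expr.replicate_mean()
    if genes is not None:
        prof = prof.loc[list(genes)]
    lo = prof.min(axis=1).clip(lower=pseudo_tpm)
    hi = prof.max(axis=1).clip(lower=pseudo_tpm)
    return hi / lo


def rank_genes(expr: ExpressionMatrix, mode: str = "sd") -> list:
    """Rank genes by temporal variability, descending.

    Modes: ``sd`` — standard deviation of the replicate-averaged profile
    over time; ``rms`` — root-mean-square of the raw (uncentred) profile;
    ``fold_change`` — max fold change between any two time points.  Ties
    break deterministically by gene ID.
    """
    prof = expr.replicate_mean()
    if prof.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    if mode == "sd":
        score = prof.std(axis=1, ddof=0)
    elif mode == "rms":
        score = np.sqrt((prof**2).mean(axis=1))
    elif mode == "fold_change":
        score = max_fold_change(expr)
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    # stable sort over an ID-sorted table gives a deterministic tie-break
    order = score.loc[sorted(score.index)].sort_values(
        ascending=False, kind="mergesort")
    return list(order.index)


def partition_elements(ordering, n: int = 100,
                       ranking_mode: str = "sd") -> ElementPartition:
    """Cut a ranked gene list into ceil(N/n) elements of exactly n genes.

    The final element takes the last n genes of the ranking and therefore
    overlaps the previous element when n does not divide N.
    """
    ordering = list(ordering)
    big_n = len(ordering)
    if n > big_n:
        raise ValueError(f"element size {n} exceeds gene count {big_n}")
    p = ceil(big_n / n)
    elements = [ordering[i * n:(i + 1) * n] for i in range(p - 1)]
    elements.append(ordering[big_n - n:])
    return ElementPartition(ordering=ordering, n=n, elements=elements,
                            ranking_mode=ranking_mode)


def element_trajectories(partition: ElementPartition, expr: ExpressionMatrix,
                         k: int = 10, n_permutations: int = 100,
                         seed=0, scale: str = "tpm") -> list[CorrelationTrajectory]:
    """Replicate-averaged (R_v, MI_v) trajectory of every element."""
    if partition.n < k:
        raise ValueError("element size below the MI bin count")
    dev_by_rep = _dev_arrays(expr, scale=scale)
    idx = pd.Index(expr.gene_ids)
    rng = np.random.default_rng(seed)
    times = next(iter(dev_by_rep.values()))[1]
    out = []
    for e, genes in enumerate(partition.elements):
        rows = idx.get_indexer(genes)
        if (rows < 0).any():
            raise KeyError(f"element {e} has genes absent from the matrix")
        pts = _traj_from_rows(dev_by_rep, rows, k, n_permutations, rng)
        out.append(CorrelationTrajectory(
            points=pd.DataFrame(pts, index=times, columns=["rv", "miv"]),
            subject=f"element_{e + 1:02d}"))
    return out


def _traj_distance(a: CorrelationTrajectory, b: CorrelationTrajectory) -> float:
    """Mean pointwise Euclidean distance over the shared time grid."""
    pa = a.points[["rv", "miv"]].to_numpy()
    pb = b.points[["rv", "miv"]].to_numpy()
    if pa.shape != pb.shape:
        raise ValueError("trajectories have different time grids")
    return float(np.mean(np.linalg.norm(pa - pb, axis=1)))


def classify_elements(trajectories: list, boundary: BasinBoundary,
                      whole_traj: CorrelationTrajectory,
                      partition: ElementPartition | None = None,
                      expr: ExpressionMatrix | None = None,
                      peak: tuple | None = None,
                      endpoint: str = "last", k: int = 10,
                      n_permutations: int = 100, seed=0,
                      scale: str = "tpm") -> ClassificationResult:
    """Label element trajectories against the basin and emit gene sets.

    `endpoint="last"` evaluates basin membership at the final time point;
    ``"last2"`` requires the last two points inside.  `peak` is the
    (R_v, MI_v) location of the major density peak (defaults to the
    boundary centroid).  An endpoint outside the basin is labelled
    ``above_basin`` when its MI_v exceeds the peak's MI_v — the element
    retains more mutual information with the t0 state than the converged
    whole-transcriptome mixture — and ``below_basin`` otherwise.  When
    `partition` and `expr` are given, pseudo-attractor candidates are
    confirmed by recomputing the merged candidate set's trajectory and
    testing its endpoint against the basin.
    """
    if peak is None:
        peak = tuple(np.mean(boundary.polyline[:, :2], axis=0))
    peak_miv = float(np.asarray(peak, dtype=float)[1])
    labels = []
    for traj in trajectories:
        pts = traj.points[["rv", "miv"]].to_numpy()
        tail = pts[-2:] if endpoint == "last2" else pts[-1:]
        inside = all(point_in_basin(p, boundary) for p in tail)
        if inside:
            labels.append("in_basin")
        elif pts[-1, 1] > peak_miv:
            labels.append("above_basin")
        else:
            labels.append("below_basin")
    distances = [_traj_distance(t, whole_traj) for t in trajectories]
    thr = float(np.mean(distances))
    candidates = [e for e, (lab, d) in enumerate(zip(labels, distances))
                  if lab == "below_basin" and d < thr]

    result = ClassificationResult(element_labels=labels,
                                  element_distances=distances,
                                  gene_sets={},
                                  pseudo_candidate_elements=candidates,
                                  distance_threshold=thr)
    if partition is None:
        return result

    core_elements = [e for e, lab in enumerate(labels)
                     if lab in ("above_basin", "in_basin")]
    attractor = _union(partition, core_elements)
    pseudo_confirmed = False
    pseudo: set = set()
    if candidates and expr is not None:
        merged_genes = _union(partition, candidates)
        traj = _merged_trajectory(expr, sorted(merged_genes), k,
                                  n_permutations, seed, scale)
        result.merged_trajectories["pseudo_candidates"] = traj
        pseudo_confirmed = point_in_basin(traj.endpoint, boundary)
        result.merged_in_basin["pseudo_candidates"] = pseudo_confirmed
        if pseudo_confirmed:
            pseudo = merged_genes - attractor
    non_attractor = set(partition.ordering) - attractor - pseudo
    result.gene_sets = {
        "attractor": attractor,
        "pseudo_attractor": pseudo,
        "non_attractor": non_attractor,
    }
    if expr is not None:
        combined = sorted(attractor | pseudo)
        if combined:
            traj = _merged_trajectory(expr, combined, k, n_permutations, seed,
                                      scale)
            result.merged_trajectories["attractor_combined"] = traj
            result.merged_in_basin["attractor_combined"] = point_in_basin(
                traj.endpoint, boundary)
    return result


def _union(partition: ElementPartition, element_idx) -> set:
    out: set = set()
    for e in element_idx:
        out.update(partition.elements[e])
    return out


def _merged_trajectory(expr, genes, k, n_permutations, seed, scale="tpm"):
    from .attractor_landscape import trajectory_for_genes

    return trajectory_for_genes(expr, genes, k=k,
                                n_permutations=n_permutations, seed=seed,
                                subject="merged", scale=scale)


def no_response_genes(expr: ExpressionMatrix, genes=None,
                      fold_threshold: float = 1.12,
                      pseudo_tpm: float = 0.5) -> set:
    """Genes whose maximal temporal fold change stays below `fold_threshold`."""
    fold = max_fold_change(expr, genes=genes, pseudo_tpm=pseudo_tpm)
    return set(fold.index[fold < fold_threshold])
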
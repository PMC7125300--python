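"""Ward clustering of attractor genes into temporal groups, correlation-
threshold refinement, and gene-set filters for follow-up comparison.

Replicate-averaged z-score profiles are Ward-clustered into k initial
clusters.  Refinement then enforces a coherence rule — every gene should
correlate (Pearson r >= threshold, default 0.7) with its group's mean
profile: misfit genes are pooled and recursively re-clustered into
coherent subgroups, subgroups are absorbed into the best-matching existing
group when their mean profiles correlate above the threshold, and groups
whose mean profiles are mutually correlated above the threshold are merged.
The merge pass is what lets a deliberately over-split initial clustering
(k = 13) collapse back onto the underlying temporal pattern families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .element_classify import max_fold_change
from .io_normalize import ExpressionMatrix

__all__ = ["TemporalGrouping", "SetComparison", "ward_cluster",
           "refine_groups", "stringent_filter", "fold_change_set",
           "compare_sets"]


@dataclass
class TemporalGrouping:
    initial_clusters: pd.Series    # gene -> initial cluster id
    groups: pd.Series              # gene -> refined group id
    group_profiles: pd.DataFrame   # group id × time, mean z-score profile
    refinement_threshold: float
    converged: bool
    n_iterations: int

    @property
    def n_groups(self) -> int:
        return int(self.groups.nunique())


@dataclass
class SetComparison:
    common: set
    a_only: set
    b_only: set

    @property
    def counts(self) -> dict:
        return {"common": len(self.common), "a_only": len(self.a_only),
                "b_only": len(self.b_only)}


def ward_cluster(zscores: pd.DataFrame, k: int) -> pd.Series:
    """Cut a Ward-linkage hierarchy of gene profiles at k clusters."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > zscores.shape[0]:
        raise ValueError("k exceeds the gene count")
    if k == 1 or zscores.shape[0] == 1:
        return pd.Series(1, index=zscores.index, name="cluster")
    link = linkage(zscores.to_numpy(dtype=float), method="ward")
    labels = fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=zscores.index, name="cluster")


def _profile_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _group_means(z: pd.DataFrame, groups: pd.Series) -> dict:
    return {g: z.loc[groups.index[groups == g]].mean(axis=0).to_numpy()
            for g in sorted(groups.unique())}


def _coherent_split(z: pd.DataFrame, genes: list, r_threshold: float,
                    next_id: int) -> pd.Series:
    """Recursively Ward-bisect a gene pool until every gene correlates with
    its subgroup mean at r >= threshold (singletons are trivially coherent)."""
    out = pd.Series(index=pd.Index(genes), dtype=int)
    stack = [genes]
    gid = next_id
    while stack:
        pool = stack.pop()
        sub = z.loc[pool]
        mean = sub.mean(axis=0).to_numpy()
        ok = [_profile_corr(sub.loc[g].to_numpy(), mean) >= r_threshold
              for g in pool]
        if all(ok) or len(pool) == 1:
            out.loc[pool] = gid
            gid += 1
            continue
        halves = ward_cluster(sub, 2)
        for h in (1, 2):
            part = list(halves.index[halves == h])
            if part:
                stack.append(part)
    return out


def refine_groups(clusters: pd.Series, zscores: pd.DataFrame,
                  r_threshold: float = 0.7,
                  max_iterations: int = 10) -> TemporalGrouping:
    """Refine an initial clustering into coherent temporal groups.

    Iterates three passes until stable (or the iteration cap): merge groups
    whose mean profiles correlate at r >= threshold; pool genes below the
    threshold to their group mean and re-cluster them into coherent
    subgroups; absorb subgroups into the best-matching existing group.
    """
    groups = clusters.copy().astype(int)
    z = zscores.loc[groups.index]
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        changed = False

        # 1. merge mutually correlated groups (closest pair first)
        while True:
            means = _group_means(z, groups)
            ids = sorted(means)
            best, best_r = None, r_threshold
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    r = _profile_corr(means[a], means[b])
                    if r >= best_r:
                        best, best_r = (a, b), r
            if best is None:
                break
            a, b = best
            groups[groups == b] = a
            changed = True

        # 2. pool misfit genes and re-cluster them coherently
        means = _group_means(z, groups)
        misfit = [g for g in groups.index
                  if _profile_corr(z.loc[g].to_numpy(),
                                   means[groups[g]]) < r_threshold]
        if misfit:
            changed = True
            keep = groups.drop(misfit)
            sub = _coherent_split(z, misfit, r_threshold,
                                  next_id=int(groups.max()) + 1)
            # 3. absorb coherent subgroups into best-matching kept group
            kept_means = (_group_means(z, keep) if not keep.empty else {})
            for gid in sorted(sub.unique()):
                members = list(sub.index[sub == gid])
                mean = z.loc[members].mean(axis=0).to_numpy()
                best, best_r = None, r_threshold
                for kid, kmean in kept_means.items():
                    r = _profile_corr(mean, kmean)
                    if r >= best_r:
                        best, best_r = kid, r
                if best is not None:
                    sub.loc[members] = best
            groups = pd.concat([keep, sub]).loc[groups.index].astype(int)

        if not changed:
            converged = True
            break

    # relabel 1..G in first-appearance order for stable output
    relabel = {old: new for new, old in
               enumerate(dict.fromkeys(groups.to_list()), start=1)}
    groups = groups.map(relabel)
    profiles = pd.DataFrame(
        {g: z.loc[groups.index[groups == g]].mean(axis=0)
         for g in sorted(groups.unique())}).T
    return TemporalGrouping(initial_clusters=clusters, groups=groups,
                            group_profiles=profiles,
                            refinement_threshold=r_threshold,
                            converged=converged, n_iterations=it)


def stringent_filter(tpm: ExpressionMatrix, genes, tpm_min: float = 500.0,
                     fold_min: float = 3.0, pseudo_tpm: float = 0.5) -> set:
    """Strongly expressed, strongly changing genes within a set.

    Keeps genes whose replicate-averaged profile exceeds `tpm_min` at some
    time point AND swings by at least `fold_min` between two time points.
    """
    genes = list(genes)
    prof = tpm.replicate_mean().loc[genes]
    fold = max_fold_change(tpm, genes=genes, pseudo_tpm=pseudo_tpm)
    keep = (prof.max(axis=1) > tpm_min) & (fold >= fold_min)
    return set(prof.index[keep])


def fold_change_set(tpm: ExpressionMatrix, fold_min: float = 2.0,
                    genes=None, pseudo_tpm: float = 0.5) -> set:
    """Genes with more than `fold_min` change between any two time points."""
    if len(tpm.time_points) < 2:
        raise ValueError("need at least 2 time points")
    fold = max_fold_change(tpm, genes=genes, pseudo_tpm=pseudo_tpm)
    return set(fold.index[fold > fold_min])


def compare_sets(set_a, set_b) -> SetComparison:
    """Venn-style comparison of two gene sets."""
    a, b = set(set_a), set(set_b)
    return SetComparison(common=a & b, a_only=a - b, b_only=b - a)
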
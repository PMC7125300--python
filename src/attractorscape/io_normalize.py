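"""Reading count matrices, TPM normalisation and expression filtering.

The analysis operates on a genes × samples table tied to a sample design
(time point in minutes × biological replicate).  Counts are converted to
Transcripts Per Million (TPM) using per-gene lengths, lowly expressed genes
are removed at a TPM threshold, and the most extreme high expressors (in
E. coli, rnpB and lpp) are dropped because they distort transcriptome-wide
correlation estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_gene_lengths",
    "tpm_normalize",
    "filter_low_expression",
    "remove_top_expressed",
]

TPM_SCALE = 1.0e6


@dataclass
class ExpressionMatrix:
    """Genes × samples expression table with an attached sample design.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative numeric table, index = gene IDs, columns = sample IDs.
    design : pandas.DataFrame
        One row per sample with columns ``time_min`` and ``replicate``,
        indexed by sample ID.  Every sample column of `values` must map to
        exactly one (time, replicate) pair.
    unit : {"counts", "TPM"}
    """

    values: pd.DataFrame
    design: pd.DataFrame
    unit: str = "counts"
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dups)[:5]}")
        if not np.issubdtype(np.asarray(self.values.values).dtype, np.number):
            raise ValueError("non-numeric cell in expression table")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression table")
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        pairs = self.design.loc[self.values.columns, ["time_min", "replicate"]]
        if pairs.duplicated().any():
            raise ValueError("design maps two samples to the same (time, replicate)")
        if self.unit == "TPM":
            colsum = self.values.sum(axis=0).to_numpy(dtype=float)
            if not np.allclose(colsum, TPM_SCALE, rtol=1e-6):
                raise ValueError("TPM columns must sum to 1e6")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def time_points(self) -> list[float]:
        return sorted(self.design.loc[self.sample_ids, "time_min"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self.design.loc[self.sample_ids, "replicate"].unique())

    def sample_for(self, time_min: float, replicate) -> str:
        d = self.design.loc[self.sample_ids]
        hit = d[(d["time_min"] == time_min) & (d["replicate"] == replicate)]
        if hit.empty:
            raise KeyError(f"no sample at t={time_min} replicate {replicate!r}")
        return hit.index[0]

    def replicate_columns(self, replicate) -> list[str]:
        """Sample IDs of one replicate, ordered by time."""
        d = self.design.loc[self.sample_ids]
        d = d[d["replicate"] == replicate].sort_values("time_min")
        if d.empty:
            raise KeyError(f"replicate {replicate!r} absent from design")
        return list(d.index)

    def replicate_mean(self) -> pd.DataFrame:
        """Genes × time matrix averaged over replicates (columns = time_min)."""
        d = self.design.loc[self.sample_ids]
        out = {}
        for t in self.time_points:
            cols = d[d["time_min"] == t].index
            out[t] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        sub = self.values.loc[gene_ids]
        em = ExpressionMatrix.__new__(ExpressionMatrix)
        em.values, em.design, em.unit, em.log = sub, self.design, self.unit, dict(self.log)
        return em


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(table_path: str | Path, design_path: str | Path,
                    unit: str = "counts") -> ExpressionMatrix:
    """Read a genes × samples TSV/CSV plus a sample design CSV.

    The design file must have columns ``sample_id,time_min,replicate`` and
    cover every sample column of the expression table.
    """
    values = _read_table(table_path)
    design = pd.read_csv(design_path, sep=None, engine="python")
    if "sample_id" not in design.columns:
        raise ValueError("design file needs a sample_id column")
    design = design.set_index("sample_id")
    for col in ("time_min", "replicate"):
        if col not in design.columns:
            raise ValueError(f"design file needs a {col} column")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {table_path}: {exc}") from exc
    return ExpressionMatrix(values=values, design=design, unit=unit)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, length_bases) → Series of lengths."""
    df = _read_table(path)
    return df.iloc[:, 0].astype(float)


def tpm_normalize(counts: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million normalisation of a count matrix.

    Per sample: rate_j = count_j / (length_j / 1000) and
    TPM_j = 1e6 * rate_j / sum_k rate_k, so each column sums to 1e6.
    """
    if counts.unit != "counts":
        raise ValueError("tpm_normalize expects a counts matrix")
    lengths = gene_lengths.reindex(counts.values.index)
    if lengths.isna().any():
        missing = counts.values.index[lengths.isna()]
        raise ValueError(f"genes without a length: {list(missing)[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.values.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = list(colsum.index[colsum == 0])
        raise ValueError(f"all-zero sample columns: {bad}")
    tpm = rate.div(colsum, axis=1) * TPM_SCALE
    return ExpressionMatrix(values=tpm, design=counts.design, unit="TPM",
                            log=dict(counts.log))


_SUMMARY_RULES = {"mean": np.mean, "min": np.min, "max": np.max}


def filter_low_expression(tpm: ExpressionMatrix, threshold: float = 5.0,
                          summary_rule: str = "mean") -> ExpressionMatrix:
    """Drop genes whose summary TPM across all samples is ≤ `threshold`.

    The default summary is the mean over all samples (times × replicates);
    ``min`` and ``max`` are available for stricter / looser readings of a
    per-sample threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if summary_rule not in _SUMMARY_RULES:
        raise ValueError(f"summary_rule must be one of {sorted(_SUMMARY_RULES)}")
    summary = tpm.values.apply(_SUMMARY_RULES[summary_rule], axis=1)
    keep = summary > threshold
    out = tpm.subset_genes(tpm.values.index[keep])
    out.log["low_expression_filter"] = {
        "threshold": threshold,
        "summary_rule": summary_rule,
        "retained": int(keep.sum()),
        "removed": int((~keep).sum()),
    }
    return out


def remove_top_expressed(tpm: ExpressionMatrix, k: int = 2,
                         rule: str = "max") -> ExpressionMatrix:
    """Drop the k genes with the highest overall expression.

    "Highest" defaults to the max TPM over all samples: the genes this
    targets (rnpB/lpp-like) are extreme in single samples, not on average.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= tpm.values.shape[0]:
        raise ValueError("k must be smaller than the gene count")
    if k == 0:
        out = tpm.subset_genes(tpm.values.index)
        out.log["top_expressed_removed"] = {"k": 0, "dropped": []}
        return out
    summary = tpm.values.apply(_SUMMARY_RULES[rule], axis=1)
    dropped = list(summary.nlargest(k).index)
    out = tpm.subset_genes([g for g in tpm.values.index if g not in set(dropped)])
    out.log["top_expressed_removed"] = {"k": k, "dropped": dropped}
    return out
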
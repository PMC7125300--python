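"""Seeded synthetic time-course count matrices with planted temporal structure.

The generator emulates a short bioreactor time course (6 time points in the
first 10 minutes, 3 biological replicates) whose TPM marginals are
lognormal above a noise floor.  Genes are planted in three strata:

* attractor genes — strong, coherent temporal dynamics drawn from six
  canonical pattern families (gradual decay/activation, fast activation
  with decay and re-activation, early activation with decay, early
  activation/decay followed by plateau);
* weak responders — the same pattern families at small amplitude;
* no-response genes — flat profiles whose maximal fold change stays below
  the 1.12 rule used downstream.

Two extreme high expressors are planted to mimic the rnpB/lpp outliers of
E. coli transcriptomes.  Ground-truth labels are returned for recovery
tests.  Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_normalize import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PATTERN_LABELS",
    "pattern_template",
    "generate_timecourse",
    "write_dataset",
]

PATTERN_LABELS = ("A", "B", "C", "D", "E", "F")

DEFAULT_TIME_POINTS = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass
class SyntheticConfig:
    """Conditions for one synthetic time-course experiment.

    Amplitudes are expressed as maximal fold changes across time in the
    noiseless template: attractor genes draw folds from
    `attractor_fold_range`, weak responders from `weak_fold_range`, and
    no-response genes from `no_response_fold_range` (kept below the 1.12
    fold rule).  `noise_cv` is the multiplicative lognormal replicate
    coefficient of variation; bioreactor time-course experiments rarely quantify
    biological replicate noise, so the 0.1 default reflects typical bulk
    RNA-seq replicate scatter.
    """

    n_genes: int = 3000
    time_points: tuple = DEFAULT_TIME_POINTS
    n_replicates: int = 3
    lognormal_mu: float = 3.0     # ln-TPM location (median ~20 TPM)
    lognormal_sigma: float = 1.5  # ln-TPM scale
    group_fractions: dict = field(default_factory=lambda: {
        lab: 1.0 / 6.0 for lab in PATTERN_LABELS})
    attractor_fraction: float = 0.5
    no_response_fraction: float = 0.02
    attractor_fold_range: tuple = (3.0, 8.0)
    weak_fold_range: tuple = (1.15, 1.5)
    no_response_fold_range: tuple = (1.0, 1.10)
    noise_cv: float = 0.1
    n_outlier_genes: int = 2
    outlier_factor: float = 50.0  # × the 99th percentile of baselines
    median_library_size: float = 1.0e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")
        tp = np.asarray(self.time_points, dtype=float)
        if tp[0] != 0 or not np.all(np.diff(tp) > 0):
            raise ValueError("time_points must be strictly increasing from 0")
        for name in ("attractor_fraction", "no_response_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.attractor_fraction + self.no_response_fraction > 1:
            raise ValueError("attractor + no_response fractions exceed 1")
        gf = np.array([self.group_fractions.get(l, 0.0) for l in PATTERN_LABELS])
        if (gf < 0).any() or abs(gf.sum() - 1.0) > 1e-9:
            raise ValueError("group_fractions must be non-negative and sum to 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class GroundTruth:
    """Per-gene planted labels: pattern family, stratum, baseline TPM."""

    table: pd.DataFrame  # index gene_id; pattern_label, is_attractor,
                         # is_no_response, is_outlier, baseline_tpm, fold

    @property
    def attractor_genes(self) -> list:
        return list(self.table.index[self.table["is_attractor"]])

    @property
    def no_response_genes(self) -> list:
        return list(self.table.index[self.table["is_no_response"]])

    @property
    def outlier_genes(self) -> list:
        return list(self.table.index[self.table["is_outlier"]])


def pattern_template(label: str, time_points) -> np.ndarray:
    """Unit-scale temporal profile of one of the six pattern families.

    Profiles start at 1.0 at t=0.  A: gradual decay; B: gradual
    activation; C: fast activation, decay, then re-activation (at the
    5-minute point); D: early activation followed by decay; E: early
    activation followed by plateau; F: early decay followed by plateau.
    """
    t = np.asarray(time_points, dtype=float)
    if t.size == 0 or t[0] != 0:
        raise ValueError("time_points must start at 0")
    if t.size == 1:
        return np.ones(1)
    tmax = t[-1]
    s = t / tmax  # linear time in [0, 1]
    fast = 1.0 - np.exp(-t / 0.4)  # saturates within ~1 min
    if label == "A":
        return 1.0 - 0.8 * s
    if label == "B":
        return 1.0 + 2.0 * s
    if label == "C":
        # fast rise, decay towards baseline, re-activation from the 5-min point
        reactivation = np.where(t >= 5.0, (t - 5.0) / max(tmax - 5.0, 1e-9), 0.0)
        return 1.0 + 2.0 * fast - 1.8 * np.clip(s * 2.5, 0, 1) + 1.5 * reactivation
    if label == "D":
        return 1.0 + 2.0 * fast - 2.0 * np.clip(s * 1.25, 0, 1)
    if label == "E":
        return 1.0 + 2.0 * fast
    if label == "F":
        return 1.0 - 0.8 * fast
    raise ValueError(f"unknown pattern label {label!r}")


def _scaled_profile(template: np.ndarray, fold: float) -> np.ndarray:
    """Map a template onto a profile with exact max/min fold = `fold`,
    anchored at its geometric temporal mean.

    Geometric-mean anchoring keeps the transcriptome's total output nearly
    constant over time when activation and decay patterns are mixed, which
    matters because TPM is compositional: column-sum drift would otherwise
    leak a global apparent fold change into every gene.
    """
    lo, hi = template.min(), template.max()
    if hi == lo:
        return np.ones_like(template)
    u = (template - lo) / (hi - lo)
    prof = fold ** u
    return prof / np.exp(np.mean(np.log(prof)))


def generate_timecourse(config: SyntheticConfig):
    """Generate (counts, gene_lengths, design, truth) for one experiment.

    Baseline TPMs are lognormal(mu, sigma); noiseless profiles are
    amplitude-scaled pattern templates; replicate noise is multiplicative
    lognormal with the configured CV; counts are back-computed from TPM via
    gene lengths and a library-size constant.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    t = np.asarray(cfg.time_points, dtype=float)
    n_t = t.size

    gene_ids = np.array([f"g{i:05d}" for i in range(n)])
    baseline = np.exp(rng.normal(cfg.lognormal_mu, cfg.lognormal_sigma, size=n))
    lengths = np.round(np.exp(rng.normal(np.log(1000.0), 0.35, size=n))).clip(150)

    n_attr = int(round(cfg.attractor_fraction * n))
    n_nr = int(round(cfg.no_response_fraction * n))
    order = rng.permutation(n)
    attr_idx = order[:n_attr]
    nr_idx = order[n_attr:n_attr + n_nr]
    weak_idx = order[n_attr + n_nr:]

    # outliers: flat extreme expressors drawn from the weak/other stratum
    n_out = min(cfg.n_outlier_genes, weak_idx.size)
    out_idx = weak_idx[:n_out]
    weak_idx = weak_idx[n_out:]
    if n_out:
        baseline[out_idx] = cfg.outlier_factor * np.quantile(baseline, 0.99)

    labels = np.array([""] * n, dtype=object)
    folds = np.ones(n)
    profiles = np.ones((n, n_t))

    gf = np.array([cfg.group_fractions.get(l, 0.0) for l in PATTERN_LABELS])
    for idx, fold_range in ((attr_idx, cfg.attractor_fold_range),
                            (weak_idx, cfg.weak_fold_range)):
        if idx.size == 0:
            continue
        pat = rng.choice(len(PATTERN_LABELS), size=idx.size, p=gf)
        f = rng.uniform(*fold_range, size=idx.size)
        for lab_i, lab in enumerate(PATTERN_LABELS):
            sel = idx[pat == lab_i]
            if sel.size == 0:
                continue
            labels[sel] = lab
            folds[sel] = f[pat == lab_i]
            template = pattern_template(lab, t)
            for g, fv in zip(sel, f[pat == lab_i]):
                profiles[g] = _scaled_profile(template, fv)

    # TPM is compositional: a gene's realised relative profile is its raw
    # profile divided by the column total, so freely prescribed absolute
    # profiles cannot all keep their planted fold changes.  The attractor
    # stratum keeps raw (geometric-mean-anchored) dynamics and absorbs the
    # residual drift; every other gene is constructed so that its realised
    # relative profile equals its planted one exactly.  With rest profiles
    # r_j = d_j * h(t) and attractor column mass s_attr(t), requiring
    # h(t)/S(t) constant gives h(t) = kappa * s_attr(t) / (1 - kappa W(t)),
    # W(t) = sum_rest b_j d_j(t), kappa fixed by the t0 mass split.
    rest_idx = np.concatenate([weak_idx, nr_idx, out_idx]).astype(np.intp)
    rest_rel = np.ones((rest_idx.size, n_t))
    pos_of = {g: i for i, g in enumerate(rest_idx)}
    for g in weak_idx:
        rest_rel[pos_of[g]] = profiles[g]
    if nr_idx.size:
        f = rng.uniform(*cfg.no_response_fold_range, size=nr_idx.size)
        folds[nr_idx] = f
        for g, fv in zip(nr_idx, f):
            rest_rel[pos_of[g]] = (fv ** (t / t[-1]) if n_t > 1
                                   else np.ones(1))
    # outliers stay flat in relative terms (rest_rel row of ones)

    s_attr = (baseline[attr_idx, None] * profiles[attr_idx]).sum(axis=0) \
        if attr_idx.size else np.zeros(n_t)
    w = (baseline[rest_idx, None] * rest_rel).sum(axis=0)
    if attr_idx.size and rest_idx.size:
        phi0 = w[0] / (s_attr[0] + w[0])
        kappa = phi0 / w[0]
        denom = 1.0 - kappa * w
        if (denom <= 0.05).any():
            raise RuntimeError("degenerate stratum mass balance")
        h = kappa * s_attr / denom
    else:
        h = np.ones(n_t)
    for g in rest_idx:
        profiles[g] = rest_rel[pos_of[g]] * h

    tpm_clean = baseline[:, None] * profiles  # genes × time, noiseless

    sigma_ln = np.sqrt(np.log1p(cfg.noise_cv**2))
    reps = [chr(ord("a") + r) for r in range(cfg.n_replicates)]
    sample_ids, columns, design_rows = [], [], []
    for rep in reps:
        noise = np.exp(rng.normal(-sigma_ln**2 / 2, sigma_ln,
                                  size=(n, n_t))) if cfg.noise_cv > 0 else 1.0
        tpm_rep = tpm_clean * noise
        for j, tp in enumerate(t):
            tname = f"{tp:g}"
            sid = f"t{tname}_{rep}"
            sample_ids.append(sid)
            columns.append(tpm_rep[:, j])
            design_rows.append((sid, tp, rep))

    tpm_mat = np.column_stack(columns)
    # counts back-computed from TPM: count = TPM * (length/1kb) * C, with C
    # chosen so the median library size hits the configured value
    rate = tpm_mat * (lengths[:, None] / 1000.0)
    c = cfg.median_library_size / np.median(rate.sum(axis=0))
    counts = np.round(rate * c)

    design = pd.DataFrame(design_rows, columns=["sample_id", "time_min",
                                                "replicate"]).set_index("sample_id")
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    expr = ExpressionMatrix(values=counts_df, design=design, unit="counts")

    is_attr = np.zeros(n, dtype=bool)
    is_attr[attr_idx] = True
    is_nr = np.zeros(n, dtype=bool)
    is_nr[nr_idx] = True
    is_out = np.zeros(n, dtype=bool)
    is_out[out_idx] = True
    truth = GroundTruth(pd.DataFrame({
        "pattern_label": labels,
        "is_attractor": is_attr,
        "is_no_response": is_nr,
        "is_outlier": is_out,
        "baseline_tpm": baseline,
        "fold": folds,
    }, index=pd.Index(gene_ids, name="gene_id")))

    gene_lengths = pd.Series(lengths, index=pd.Index(gene_ids, name="gene_id"),
                             name="length")
    return expr, gene_lengths, design.reset_index(), truth


def write_dataset(outdir: str | Path, expr: ExpressionMatrix,
                  gene_lengths: pd.Series, design: pd.DataFrame,
                  truth: GroundTruth, config: SyntheticConfig | None = None) -> dict:
    """Write counts/lengths/design/truth (and config) as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "design": outdir / "design.csv",
        "truth": outdir / "truth.tsv",
    }
    expr.values.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    gene_lengths.rename_axis("gene_id").to_frame().to_csv(paths["lengths"], sep="\t")
    design.to_csv(paths["design"], index=False)
    truth.table.to_csv(paths["truth"], sep="\t")
    if config is not None:
        paths["config"] = outdir / "config.json"
        cfg = asdict(config)
        cfg["time_points"] = list(cfg["time_points"])
        paths["config"].write_text(json.dumps(cfg, indent=2))
    return {k: str(v) for k, v in paths.items()}
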
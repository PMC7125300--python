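# attractorscape

Attractor-landscape analysis of short time-course RNA-seq experiments.

When a population of cells is pushed from one stable physiological state to
another — the motivating case is *E. coli* switching from anaerobic to
aerobic growth within ten minutes of air supply in a bioreactor — the
transcriptome traces a trajectory through expression state space.  Treating
the aerobic end state as an attractor, `attractorscape` asks which part of
the transcriptome carries the coherent dynamics that guide that transition,
and which genes merely drift.  It is a library plus CLI for:

* TPM normalisation of a genes × samples count matrix with a
  (time × replicate) design, a low-expression filter, and removal of the
  extreme high expressors (rnpB/lpp-like) that distort transcriptome-wide
  correlations;
* maximum-likelihood fitting of candidate expression distributions
  (lognormal, Pareto, Burr XII, loglogistic, Weibull, gamma) with AIC
  comparison and Q-Q diagnostics;
* temporal correlation metrics between the transcriptome at time *t*ᵢ and
  *t*₀: Pearson, Spearman, biweight midcorrelation, and a bias-corrected
  histogram mutual-information correlation;
* the deviation-correlation landscape: with deviation vectors
  *v*ⱼ(*t*ᵢ) = *x*ⱼ(*t*ᵢ) − x̄ⱼ,

  - *R*ᵥ(*t*ᵢ) = V(*t*ᵢ)·V(*t*₀) / (|V(*t*ᵢ)||V(*t*₀)|)  (cosine of
    deviation vectors),
  - *MI*ᵥ(*t*ᵢ) = MI(V(*t*ᵢ), V(*t*₀)) / MI(V(*t*₀), V(*t*₀)), with MI
    estimated on a K = 10 equal-frequency rank histogram and corrected by
    the minimum MI over 100 random permutations,

  evaluated for ensembles of n randomly chosen genes, turned into a
  superimposed 2-D kernel-density landscape whose major peak marks the
  attractor and whose basin boundary is the closed iso-contour at the
  inflection z-level;
* classification of rank-ordered 100-gene "transcriptomic elements" against
  the basin into attractor / pseudo-attractor / non-attractor sets, plus
  the 1.12-fold no-response rule;
* PCA sample-trajectory validation and Ward clustering of attractor genes
  into temporal pattern groups with a Pearson-0.7 refinement;
* a seeded synthetic time-course generator with planted ground truth
  (six temporal pattern families, attractor / weak / no-response strata,
  two extreme-expressor outliers) for recovery testing.

## Worked example

```python
from attractorscape import PipelineConfig, run_pipeline

cfg = PipelineConfig(synthetic={"n_genes": 1200}, seed=5,
                     ranking_mode="fold_change", deviation_scale="log")
report = run_pipeline(cfg)
print(report["counts"])
print("jaccard vs planted truth:",
      round(report["truth_recovery"]["jaccard_attractor"], 3))
print("temporal groups:", report["clustering"]["refined_groups"])
```

prints (seed 5):

```
{'input_genes': 1200, 'retained_after_tpm_filter': 1188,
 'removed_by_tpm_filter': 12, 'dropped_top_expressed': ['g00611', 'g00210'],
 'analysed_genes': 1186, 'elements': 12, 'attractor': 500,
 'core_attractor': 500, 'pseudo_attractor': 0, 'non_attractor': 686,
 'no_response': 7, 'collective_non_attractor': 679, 'stringent': 204,
 'fold_change': 592, 'venn': {'common': 500, 'a_only': 0, 'b_only': 92}}
jaccard vs planted truth: 0.845
temporal groups: 6
```

Reading the count chain: of 1200 simulated genes, 1188 pass the 5-TPM
filter and the two planted extreme expressors are removed (they are exactly
the generator's outlier genes).  The 1186 analysed genes form 12 ranked
elements; the elements whose (*R*ᵥ, *MI*ᵥ) trajectories end in or above the
attractor basin contribute 500 attractor genes (Jaccard 0.845 against the
planted stratum).  Among the 686 non-attractor genes, 7 fall below the
1.12-fold no-response rule.  Ward clustering of the attractor genes into 13
initial clusters collapses to 6 temporal groups after the correlation-0.7
refinement — the planted number of pattern families.

The same run from a shell:

```bash
attractorscape simulate --n-genes 1200 --seed 5 --out data/
attractorscape run --config config.yaml --out results/
```

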
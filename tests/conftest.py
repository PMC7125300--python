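import numpy as np
import pandas as pd
import pytest

from attractorscape import (ExpressionMatrix, SyntheticConfig,
                            filter_low_expression, generate_timecourse,
                            remove_top_expressed, tpm_normalize)


def make_expr(values, times, reps, unit="counts", gene_ids=None):
    """Build a small ExpressionMatrix from a genes × samples array.

    Columns are ordered replicate-major: all times of rep 1, then rep 2...
    """
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids, rows = [], []
    for r in reps:
        for t in times:
            sid = f"t{t:g}_{r}"
            sample_ids.append(sid)
            rows.append((sid, float(t), r))
    design = pd.DataFrame(rows, columns=["sample_id", "time_min",
                                         "replicate"]).set_index("sample_id")
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(values=df, design=design, unit=unit)


@pytest.fixture(scope="session")
def small_synth():
    """A 500-gene synthetic experiment with ground truth."""
    cfg = SyntheticConfig(n_genes=500, seed=7)
    counts, lengths, design, truth = generate_timecourse(cfg)
    return cfg, counts, lengths, design, truth


@pytest.fixture(scope="session")
def small_tpm(small_synth):
    """TPM-normalised, filtered, top-2-removed matrix of the 500-gene run."""
    _, counts, lengths, _, truth = small_synth
    tpm = tpm_normalize(counts, lengths)
    expr = remove_top_expressed(filter_low_expression(tpm, 5.0), 2)
    return expr, truth
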
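"""Shared oracles and fixtures for the acceptance tests.

The oracles here are deliberately independent of the implementation paths
they check: the biweight midcorrelation is evaluated directly from its
printed formula, MI by explicit loops over the contingency table, and
point-in-polygon by winding numbers rather than ray casting.
"""

import numpy as np

import attractorscape as ats


def bicor_direct(x, y):
    def tilde(p):
        p = np.asarray(p, dtype=float)
        med = np.median(p)
        mad = np.median(np.abs(p - med))
        u = (p - med) / (9 * mad)
        w = (1 - u**2) ** 2 * ((1 - np.abs(u)) > 0)
        num = (p - med) * w
        return num / np.sqrt(np.sum(num**2))
    return float(np.sum(tilde(x) * tilde(y)))


def brute_force_mi(bx, by, k):
    n = len(bx)
    joint = np.zeros((k, k))
    for i in range(n):
        joint[bx[i], by[i]] += 1
    joint /= n
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    mi = 0.0
    for a in range(k):
        for b in range(k):
            if joint[a, b] > 0:
                mi += joint[a, b] * np.log(joint[a, b])
        if px[a] > 0:
            mi -= px[a] * np.log(px[a])
        if py[a] > 0:
            mi -= py[a] * np.log(py[a])
    return mi


def winding_number_inside(point, poly):
    x, y = point
    wn = 0
    for i in range(len(poly) - 1):
        x1, y1 = poly[i]
        x2, y2 = poly[i + 1]
        cross = (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1)
        if y1 <= y:
            if y2 > y and cross > 0:
                wn += 1
        elif y2 <= y and cross < 0:
            wn -= 1
    return wn != 0


def gaussian_landscape(sigma=0.1, grid_size=121, extent=0.6):
    g = np.linspace(-extent, extent, grid_size)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    z = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return ats.DensityLandscape(rv_grid=g, miv_grid=g, z=z,
                                peaks=[(0.0, 0.0, 1.0)], bandwidths=[],
                                n_superimposed=1)


def prepare_synth(n_genes, seed, **cfg_kwargs):
    """Generate, TPM-normalise, filter and de-spike one synthetic run."""
    cfg = ats.SyntheticConfig(n_genes=n_genes, seed=seed, **cfg_kwargs)
    counts, lengths, _, truth = ats.generate_timecourse(cfg)
    tpm = ats.tpm_normalize(counts, lengths)
    expr = ats.remove_top_expressed(ats.filter_low_expression(tpm, 5.0), 2)
    return expr, truth


def recovered_attractor_jaccard(n_genes, seed, element_size=100):
    """Run the landscape + element classification and score the recovered
    attractor set against the planted labels."""
    expr, truth = prepare_synth(n_genes, seed)
    ens = ats.sample_ensembles(expr, element_size, repeats=100, seed=seed,
                               scale="log")
    landscape = ats.spd_landscape(ens)
    boundary = ats.attractor_boundary(landscape)
    whole = ats.whole_transcriptome_trajectory(ens)
    part = ats.partition_elements(ats.rank_genes(expr, "fold_change"),
                                  element_size)
    trajs = ats.element_trajectories(part, expr, seed=seed, scale="log")
    res = ats.classify_elements(trajs, boundary, whole, partition=part,
                                expr=expr, peak=landscape.major_peak[:2],
                                seed=seed, scale="log")
    got = res.gene_sets["attractor"] | res.gene_sets["pseudo_attractor"]
    planted = set(truth.attractor_genes) & set(expr.gene_ids)
    return len(got & planted) / len(got | planted)
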
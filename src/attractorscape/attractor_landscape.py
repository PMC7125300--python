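"""Deviation-correlation attractor landscapes.

The state of the transcriptome at time t_i is summarised by its
deviation-from-temporal-average vector V(t_i), with
v_j(t_i) = x_j(t_i) - mean_t(x_j).  Two correlations between V(t_i) and the
initial V(t_0) trace a trajectory in a 2-D plane:

* R_v  — the cosine of the two deviation vectors (a Pearson-like linear
  index insensitive to amplitude);
* MI_v — histogram mutual information between the deviation vectors,
  permutation-bias corrected and normalised by the t_0 self-information.

Ensembles of n randomly chosen genes yield per-time clouds of (R_v, MI_v)
points; their spread shrinks as alpha/sqrt(n) + c (a law-of-large-numbers
check), and 2-D kernel densities of the clouds, superimposed over time,
form a landscape whose major peak marks the attractor.  The basin boundary
is the closed iso-contour at the mean z-level of the steepest-gradient
(inflection) points found scanning outward from the peak along the lattice
axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .corr_metrics import rank_bins, _mi_from_bins
from .io_normalize import ExpressionMatrix

__all__ = [
    "DeviationMatrix",
    "CorrelationTrajectory",
    "EnsembleDistribution",
    "DensityLandscape",
    "BasinBoundary",
    "deviation_matrix",
    "rv",
    "miv",
    "corrected_mi",
    "trajectory_for_genes",
    "sample_ensembles",
    "whole_transcriptome_trajectory",
    "lln_fit",
    "spd_landscape",
    "attractor_boundary",
    "point_in_basin",
]


@dataclass
class DeviationMatrix:
    """Row-centred genes × time matrix for one replicate."""

    values: pd.DataFrame  # index gene_ids, columns time_min
    replicate: object

    @property
    def time_points(self) -> list[float]:
        return list(self.values.columns)


@dataclass
class CorrelationTrajectory:
    """(R_v, MI_v) per time point for one gene set, replicate-averaged."""

    points: pd.DataFrame  # index time_min, columns ["rv", "miv"]
    subject: str = ""
    replicate_handling: str = "mean"

    @property
    def endpoint(self) -> tuple[float, float]:
        last = self.points.iloc[-1]
        return float(last["rv"]), float(last["miv"])


@dataclass
class EnsembleDistribution:
    """Per-time (R_v, MI_v) samples for `repeats` random gene sets of size n."""

    element_size: int
    repeats: int
    time_points: list
    rv_samples: np.ndarray   # (repeats, n_times)
    miv_samples: np.ndarray  # (repeats, n_times)

    def sds(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rv": self.rv_samples.std(axis=0, ddof=1),
            "miv": self.miv_samples.std(axis=0, ddof=1),
        }, index=self.time_points)


@dataclass
class BasinBoundary:
    """Closed iso-contour delimiting the attractor basin."""

    polyline: np.ndarray  # (m, 2) closed: first == last vertex
    level: float
    inflection_points: list = field(default_factory=list)


@dataclass
class DensityLandscape:
    """Superimposed per-time 2-D kernel densities on an (R_v, MI_v) lattice."""

    rv_grid: np.ndarray
    miv_grid: np.ndarray
    z: np.ndarray                 # shape (len(rv_grid), len(miv_grid))
    peaks: list                   # [(rv, miv, z), ...] sorted by z descending
    bandwidths: list              # per superimposed slice (h_rv, h_miv)
    n_superimposed: int
    skipped_times: list = field(default_factory=list)

    @property
    def major_peak(self) -> tuple[float, float, float]:
        if not self.peaks:
            raise ValueError("landscape has no peaks")
        return self.peaks[0]

    def total_mass(self) -> float:
        drv = self.rv_grid[1] - self.rv_grid[0]
        dmiv = self.miv_grid[1] - self.miv_grid[0]
        return float(self.z.sum() * drv * dmiv)


# ---------------------------------------------------------------------------
# deviation vectors and the two correlations

def deviation_matrix(expr: ExpressionMatrix, replicate,
                     scale: str = "tpm") -> DeviationMatrix:
    """Per-gene deviation from the temporal mean, for one replicate.

    ``scale="tpm"`` centres raw expression values; ``scale="log"`` centres
    ln(1 + x), which stops a handful of extreme high expressors from
    dominating the deviation vectors when marginals are heavy-tailed.
    """
    cols = expr.replicate_columns(replicate)
    if len(cols) < 2:
        raise ValueError("need at least 2 time points")
    sub = expr.values[cols].astype(float)
    sub.columns = expr.design.loc[cols, "time_min"].to_numpy()
    if scale == "log":
        sub = np.log1p(sub)
    elif scale != "tpm":
        raise ValueError("scale must be 'tpm' or 'log'")
    centred = sub.sub(sub.mean(axis=1), axis=0)
    return DeviationMatrix(values=centred, replicate=replicate)


def rv(v_ti, v_t0) -> float:
    """Cosine similarity of two deviation vectors."""
    a = np.asarray(v_ti, dtype=float)
    b = np.asarray(v_t0, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroDivisionError("zero-norm deviation vector")
    return float(np.dot(a, b) / (na * nb))


def corrected_mi(x, y, k: int = 10, n_permutations: int = 100,
                 rng=None) -> float:
    """Bias-corrected histogram MI of two vectors (nats)."""
    rng = np.random.default_rng(rng)
    bx = rank_bins(np.asarray(x, dtype=float), k)
    by = rank_bins(np.asarray(y, dtype=float), k)
    raw = _mi_from_bins(bx, by, k)
    bx_sorted = np.sort(bx)  # epsilon invariant to observation order
    by_sorted = np.sort(by)
    eps = min(_mi_from_bins(bx_sorted, rng.permutation(by_sorted), k)
              for _ in range(n_permutations))
    return max(raw - eps, 0.0)


def miv(v_ti, v_t0, k: int = 10, n_permutations: int = 100, rng=None,
        denom: float | None = None) -> float:
    """MI between deviation vectors, normalised by the t0 self-information.

    `denom` allows reuse of a precomputed corrected MI(V(t0), V(t0)).
    """
    rng = np.random.default_rng(rng)
    if denom is None:
        denom = corrected_mi(v_t0, v_t0, k=k, n_permutations=n_permutations,
                             rng=rng)
    if denom <= 0:
        raise ZeroDivisionError("MI(V(t0), V(t0)) is zero")
    return corrected_mi(v_ti, v_t0, k=k, n_permutations=n_permutations,
                        rng=rng) / denom


# ---------------------------------------------------------------------------
# trajectories

def _dev_arrays(expr: ExpressionMatrix, scale: str = "tpm") -> dict:
    """Per-replicate (deviation ndarray, time list); row order = expr genes."""
    out = {}
    for rep in expr.replicates:
        dm = deviation_matrix(expr, rep, scale=scale)
        out[rep] = (dm.values.to_numpy(), list(dm.values.columns))
    return out


def _traj_from_rows(dev_by_rep: dict, rows: np.ndarray, k: int,
                    n_permutations: int, rng) -> np.ndarray:
    """(n_times, 2) replicate-averaged trajectory for the given gene rows."""
    acc = None
    for rep, (dev, times) in dev_by_rep.items():
        sub = dev[rows]
        v0 = sub[:, 0]
        denom = corrected_mi(v0, v0, k=k, n_permutations=n_permutations, rng=rng)
        pts = np.empty((len(times), 2))
        pts[0] = (1.0, 1.0)  # self-correlation at t0 by construction
        for j in range(1, len(times)):
            vi = sub[:, j]
            pts[j, 0] = rv(vi, v0)
            pts[j, 1] = miv(vi, v0, k=k, n_permutations=n_permutations,
                            rng=rng, denom=denom)
        acc = pts if acc is None else acc + pts
    return acc / len(dev_by_rep)


def trajectory_for_genes(expr: ExpressionMatrix, genes, k: int = 10,
                         n_permutations: int = 100, seed=0,
                         subject: str = "", scale: str = "tpm") -> CorrelationTrajectory:
    """Replicate-averaged (R_v, MI_v) trajectory of a gene set vs t0."""
    dev_by_rep = _dev_arrays(expr, scale=scale)
    idx = pd.Index(expr.gene_ids)
    rows = idx.get_indexer(list(genes))
    if (rows < 0).any():
        raise KeyError("gene set contains genes absent from the matrix")
    rng = np.random.default_rng(seed)
    pts = _traj_from_rows(dev_by_rep, rows, k, n_permutations, rng)
    times = next(iter(dev_by_rep.values()))[1]
    return CorrelationTrajectory(
        points=pd.DataFrame(pts, index=times, columns=["rv", "miv"]),
        subject=subject)


def sample_ensembles(expr: ExpressionMatrix, n: int, repeats: int = 100,
                     seed=0, k: int = 10, n_permutations: int = 100,
                     scale: str = "tpm") -> EnsembleDistribution:
    """Distributions of (R_v, MI_v) for `repeats` random gene sets of size n.

    Genes are drawn without replacement; each draw's trajectory is
    replicate-averaged.
    """
    n_genes = len(expr.gene_ids)
    if n > n_genes:
        raise ValueError(f"element size {n} exceeds gene count {n_genes}")
    rng = np.random.default_rng(seed)
    dev_by_rep = _dev_arrays(expr, scale=scale)
    times = next(iter(dev_by_rep.values()))[1]
    rv_s = np.empty((repeats, len(times)))
    miv_s = np.empty((repeats, len(times)))
    for r in range(repeats):
        rows = rng.choice(n_genes, size=n, replace=False)
        pts = _traj_from_rows(dev_by_rep, rows, k, n_permutations, rng)
        rv_s[r] = pts[:, 0]
        miv_s[r] = pts[:, 1]
    return EnsembleDistribution(element_size=n, repeats=repeats,
                                time_points=times, rv_samples=rv_s,
                                miv_samples=miv_s)


def whole_transcriptome_trajectory(ensemble: EnsembleDistribution) -> CorrelationTrajectory:
    """Mean over the ensemble repeats: the whole-transcriptome trajectory."""
    pts = np.column_stack([ensemble.rv_samples.mean(axis=0),
                           ensemble.miv_samples.mean(axis=0)])
    return CorrelationTrajectory(
        points=pd.DataFrame(pts, index=ensemble.time_points,
                            columns=["rv", "miv"]),
        subject="whole_transcriptome")


# ---------------------------------------------------------------------------
# LLN check

def lln_fit(sds_by_n: dict) -> tuple[float, float, float]:
    """Least-squares fit of SD(n) = alpha / sqrt(n) + c.

    Returns (alpha, c, rmse).
    """
    if len(sds_by_n) < 3:
        raise ValueError("need at least 3 distinct element sizes")
    ns = np.array(sorted(sds_by_n), dtype=float)
    sds = np.array([sds_by_n[n] for n in sorted(sds_by_n)], dtype=float)
    design = np.column_stack([1.0 / np.sqrt(ns), np.ones_like(ns)])
    coef, *_ = np.linalg.lstsq(design, sds, rcond=None)
    resid = sds - design @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    return float(coef[0]), float(coef[1]), rmse


# ---------------------------------------------------------------------------
# landscape, boundary and basin membership

def spd_landscape(ensemble: EnsembleDistribution, grid_size: int = 100,
                  bandwidth_rule: str = "scott",
                  bandwidth_scale: float = 1.0,
                  mode: str = "sum") -> DensityLandscape:
    """Superimposed per-time 2-D kernel densities of the ensemble clouds.

    Each non-degenerate time slice gets a product-Gaussian KDE with a
    per-axis normal-reference (Scott) bandwidth h = sigma * m^(-1/6); the
    slice densities are summed on a shared lattice (`mode="mean"` averages
    instead).  Slices whose points are all identical (the t0 slice is a
    delta at (1, 1)) are skipped and reported.
    """
    if bandwidth_rule != "scott":
        raise ValueError("only the Scott normal-reference rule is implemented")
    pts_by_time, skipped = [], []
    for j, t in enumerate(ensemble.time_points):
        p = np.column_stack([ensemble.rv_samples[:, j],
                             ensemble.miv_samples[:, j]])
        if np.ptp(p[:, 0]) == 0 and np.ptp(p[:, 1]) == 0:
            skipped.append(t)
        else:
            pts_by_time.append(p)
    if len(pts_by_time) < 1:
        raise ValueError("degenerate ensemble: every time slice is a point mass")

    m = ensemble.repeats
    factor = m ** (-1.0 / 6.0) * bandwidth_scale  # Scott, d = 2
    bandwidths = []
    for p in pts_by_time:
        h = p.std(axis=0, ddof=1) * factor
        bandwidths.append(h)
    all_pts = np.vstack(pts_by_time)
    hmax = np.max(bandwidths, axis=0)
    lo = all_pts.min(axis=0) - 3.0 * hmax
    hi = all_pts.max(axis=0) + 3.0 * hmax
    rv_grid = np.linspace(lo[0], hi[0], grid_size)
    miv_grid = np.linspace(lo[1], hi[1], grid_size)
    cell = np.array([rv_grid[1] - rv_grid[0], miv_grid[1] - miv_grid[0]])

    z = np.zeros((grid_size, grid_size))
    for p, h in zip(pts_by_time, bandwidths):
        h = np.maximum(h, cell)  # floor: one lattice cell per axis
        ax = np.exp(-0.5 * ((rv_grid[:, None] - p[None, :, 0]) / h[0]) ** 2)
        ay = np.exp(-0.5 * ((miv_grid[:, None] - p[None, :, 1]) / h[1]) ** 2)
        z += (ax @ ay.T) / (m * 2.0 * np.pi * h[0] * h[1])
    if mode == "mean":
        z /= len(pts_by_time)
    elif mode != "sum":
        raise ValueError("mode must be 'sum' or 'mean'")

    # local maxima on the lattice (8-neighbourhood), minor bumps excluded
    footprint = np.ones((3, 3), dtype=bool)
    is_max = (z == ndimage.maximum_filter(z, footprint=footprint))
    is_max &= z > 0.01 * z.max()
    peaks = [(float(rv_grid[i]), float(miv_grid[j]), float(z[i, j]))
             for i, j in zip(*np.nonzero(is_max))]
    peaks.sort(key=lambda p: -p[2])
    return DensityLandscape(rv_grid=rv_grid, miv_grid=miv_grid, z=z,
                            peaks=peaks,
                            bandwidths=[tuple(map(float, h)) for h in bandwidths],
                            n_superimposed=len(pts_by_time),
                            skipped_times=skipped)


def _axis_inflections(z: np.ndarray, i0: int, j0: int):
    """Steepest-gradient points scanning the 4 axis directions from (i0, j0).

    Returns a list of ((i, j), z) at the max-|gradient| position per
    direction that has at least 2 cells of room.
    """
    out = []
    lines = [
        (z[i0, j0:], lambda s: (i0, j0 + s)),       # +miv
        (z[i0, j0::-1], lambda s: (i0, j0 - s)),    # -miv
        (z[i0:, j0], lambda s: (i0 + s, j0)),       # +rv
        (z[i0::-1, j0], lambda s: (i0 - s, j0)),    # -rv
    ]
    for profile, to_ij in lines:
        if profile.size < 3:
            continue
        grad = np.diff(profile)
        s = int(np.argmax(np.abs(grad)))
        # the steepest step straddles cells s and s+1: take its midpoint z
        zv = 0.5 * (profile[s] + profile[s + 1])
        out.append((to_ij(s), zv))
    return out


def attractor_boundary(landscape: DensityLandscape) -> BasinBoundary:
    """Closed iso-contour around the major peak at the inflection z-level.

    From the major peak the lattice is scanned along the four axis-aligned
    directions; the steepest-gradient (inflection) cell per direction is
    recorded, the boundary z-level is the mean of their z values, and the
    boundary is the closed contour at that level that encloses the peak.
    """
    z = landscape.z
    prv, pmiv, _ = landscape.major_peak
    i0 = int(np.argmin(np.abs(landscape.rv_grid - prv)))
    j0 = int(np.argmin(np.abs(landscape.miv_grid - pmiv)))
    inflections = _axis_inflections(z, i0, j0)
    if not inflections:
        raise ValueError("degenerate landscape: no room to scan from the peak")
    level = float(np.mean([zv for _, zv in inflections]))

    contours = measure.find_contours(z, level)
    drv = landscape.rv_grid[1] - landscape.rv_grid[0]
    dmiv = landscape.miv_grid[1] - landscape.miv_grid[0]
    peak_xy = np.array([prv, pmiv])
    for c in contours:
        closed = np.allclose(c[0], c[-1])
        if not closed:
            continue
        poly = np.column_stack([landscape.rv_grid[0] + c[:, 0] * drv,
                                landscape.miv_grid[0] + c[:, 1] * dmiv])
        if _ray_cast(peak_xy, poly):
            return BasinBoundary(polyline=poly, level=level,
                                 inflection_points=[
                                     (float(landscape.rv_grid[i]),
                                      float(landscape.miv_grid[j]), zv)
                                     for (i, j), zv in inflections])
    raise ValueError("no closed boundary contour encloses the major peak")


def _ray_cast(point: np.ndarray, poly: np.ndarray) -> bool:
    """Even-odd point-in-polygon test (horizontal ray towards +x)."""
    x, y = float(point[0]), float(point[1])
    inside = False
    n = len(poly) - 1 if np.allclose(poly[0], poly[-1]) else len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % len(poly)]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x_cross > x:
                inside = not inside
    return inside


def point_in_basin(point, boundary: BasinBoundary) -> bool:
    """Whether an (R_v, MI_v) point lies inside the basin boundary."""
    poly = boundary.polyline
    if not np.allclose(poly[0], poly[-1]):
        raise ValueError("boundary polyline is not closed")
    return _ray_cast(np.asarray(point, dtype=float), poly)
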
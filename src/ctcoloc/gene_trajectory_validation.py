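"""Developmental gene-expression validation of marker time periods.

If a marker genuinely drives cortical development in a given age window,
the genes coding for it should be preferentially expressed in cortex
during that window.  The test: fit a LOESS curve to the marker's (gene-set
averaged) postnatal expression over age, average the curve inside vs.
outside the marker's significant time period, and compare the inside mean
and the inside/outside ratio against the same statistics computed on many
same-sized gene sets drawn from a pool of genes not detected in brain.
Empirical p-values are positive-sided, (k+1)/(N+1); BH-FDR is applied
across all marker-by-statistic tests in one family.

LOESS here is locally quadratic with tricube weights (span 0.75 of the
subjects by default).  For fixed subject ages the smoother is linear in
the expression values, so it is exposed as a smoothing matrix, which makes
the null resampling a single matrix product.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spatial_nulls import fdr_adjust
from .synthetic_data import ExpressionDataset

__all__ = [
    "gene_set_trajectory",
    "loess_matrix",
    "loess_trajectory",
    "period_statistics",
    "trajectory_test",
]

MIN_SUBJECTS = 8


def gene_set_trajectory(data: ExpressionDataset,
                        genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Uniform average across the set's genes per subject: (ages, values)."""
    if not genes:
        raise ValueError("empty gene set")
    idx = data.gene_index(genes)  # raises naming the unknown gene
    return data.ages, data.expression[:, idx].mean(axis=1)


def loess_matrix(x: np.ndarray, grid: np.ndarray, span: float = 0.75,
                 degree: int = 2) -> np.ndarray:
    """Linear smoother H with curve = H @ y for LOESS at fixed abscissae.

    Tricube weights over the ``ceil(span * n)`` nearest points, local
    polynomial of ``degree``.  The grid must lie within the data range (no
    extrapolation) and at least :data:`MIN_SUBJECTS` points are required.
    """
    x = np.asarray(x, float)
    grid = np.asarray(grid, float)
    n = x.size
    if n < MIN_SUBJECTS:
        raise ValueError(f"need at least {MIN_SUBJECTS} subjects, got {n}")
    if grid.min() < x.min() or grid.max() > x.max():
        raise ValueError("evaluation grid outside the data range "
                         "(no extrapolation)")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    q = max(int(np.ceil(span * n)), degree + 2)
    H = np.zeros((grid.size, n))
    for gi, g in enumerate(grid):
        dist = np.abs(x - g)
        cut = np.sort(dist)[q - 1]
        if cut == 0:
            w = (dist == 0).astype(float)
        else:
            w = np.clip(1 - (dist / cut) ** 3, 0.0, None) ** 3
        use = w > 0
        D = np.vander(x[use] - g, degree + 1, increasing=True)
        Wd = w[use]
        A = D.T * Wd @ D
        # hat row: value at g is the local intercept
        hat = np.linalg.solve(A, D.T * Wd)[0]
        H[gi, use] = hat
    return H


def loess_trajectory(ages: np.ndarray, values: np.ndarray,
                     eval_grid: np.ndarray, span: float = 0.75,
                     degree: int = 2) -> np.ndarray:
    """LOESS curve of one series evaluated on the grid (deterministic)."""
    return loess_matrix(ages, eval_grid, span, degree) @ np.asarray(values,
                                                                    float)


def period_statistics(grid: np.ndarray, curve: np.ndarray,
                      period: tuple[float, float]
                      ) -> tuple[float, float, float]:
    """(mean inside period, mean outside, ratio) of the fitted curve."""
    grid = np.asarray(grid, float)
    inside = (grid >= period[0]) & (grid <= period[1])
    if not inside.any() or inside.all():
        raise ValueError(
            f"period {period} must split the grid into two non-empty parts")
    mean_in = float(curve[inside].mean())
    mean_out = float(curve[~inside].mean())
    if mean_out == 0:
        raise ValueError("mean outside the period is zero; ratio undefined")
    return mean_in, mean_out, mean_in / mean_out


def default_grid(ages: np.ndarray, step: float = 0.5) -> np.ndarray:
    """0.5-year evaluation grid inside the observed postnatal age range."""
    lo = np.ceil(ages.min() / step) * step
    hi = np.floor(ages.max() / step) * step
    return np.arange(lo, hi + 1e-9, step)


def trajectory_test(data: ExpressionDataset,
                    marker_sets: dict[str, tuple[list[str],
                                                 tuple[float, float]]],
                    n_null: int = 10_000, seed: int = 0,
                    span: float = 0.75, degree: int = 2,
                    grid_step: float = 0.5) -> pd.DataFrame:
    """Non-brain resampled test of period-specific expression per marker.

    ``marker_sets`` maps marker name to (gene list, significant period in
    years).  For every distinct set size, ``n_null`` same-sized gene sets
    are drawn (without replacement per draw) from the non-brain pool and
    pushed through the identical LOESS -> period-statistics pipeline; the
    same null draws serve every marker of that size, mirroring a constant
    null dataset.  Returns one row per marker with mean_in/mean_out/ratio,
    positive-sided empirical p for mean and ratio, and BH q-values
    computed across all tests at once.
    """
    if n_null < 1:
        raise ValueError("need at least one null draw")
    if np.any(data.ages <= 0):
        raise ValueError("expression data must be postnatal")
    rng = np.random.default_rng(seed)
    grid = default_grid(data.ages, grid_step)
    H = loess_matrix(data.ages, grid, span, degree)
    pool_idx = data.gene_index(data.nonbrain_pool)

    sizes = {len(genes) for genes, _ in marker_sets.values()}
    null_curves: dict[int, np.ndarray] = {}
    for s in sizes:
        if s > pool_idx.size:
            raise ValueError(
                f"gene-set size {s} exceeds non-brain pool "
                f"({pool_idx.size} genes)")
        draws = np.stack([rng.choice(pool_idx, size=s, replace=False)
                          for _ in range(n_null)])
        Y = data.expression[:, draws].mean(axis=2)     # (n_subj, n_null)
        null_curves[s] = (H @ Y).T                     # (n_null, n_grid)

    rows = []
    for marker, (genes, period) in marker_sets.items():
        ages, series = gene_set_trajectory(data, genes)
        curve = H @ series
        mean_in, mean_out, ratio = period_statistics(grid, curve, period)
        curves = null_curves[len(genes)]
        inside = (grid >= period[0]) & (grid <= period[1])
        n_in = curves[:, inside].mean(axis=1)
        n_out = curves[:, ~inside].mean(axis=1)
        n_ratio = n_in / n_out
        p_mean = (1 + int((n_in >= mean_in).sum())) / (1 + n_null)
        p_ratio = (1 + int((n_ratio >= ratio).sum())) / (1 + n_null)
        rows.append({"marker": marker, "n_genes": len(genes),
                     "period_start": period[0], "period_end": period[1],
                     "mean_in": mean_in, "mean_out": mean_out,
                     "ratio": ratio, "p_mean": p_mean, "p_ratio": p_ratio})
    out = pd.DataFrame(rows)
    qs = fdr_adjust(np.concatenate([out["p_mean"], out["p_ratio"]]))
    out["q_mean"] = qs[:len(out)]
    out["q_ratio"] = qs[len(out):]
    return out
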
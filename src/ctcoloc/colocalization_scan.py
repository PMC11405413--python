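"""Colocalization trajectories and explained-variance scans.

Cross-sectional colocalization is the spatial Spearman correlation between
a marker map and the modeled CT map at one age/percentile; scanning it over
the age grid yields lifespan colocalization trajectories.  The lifespan
change scans regress windowed relative CT change on marker maps — one
simple regression per (window, atlas) for the univariate scan, one OLS on
all predictors of a modality per window for the multivariate scan — and
compare each R² to null R² distributions from variogram-matched surrogate
predictors to obtain positive-sided empirical p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .ct_change_windows import CTChangeMap
from .parcel_core import AtlasSet, ParcelMap, check_aligned
from .spatial_nulls import NullEnsemble, empirical_p, fdr_adjust

__all__ = [
    "spearman_coloc",
    "coloc_trajectory",
    "univariate_scan",
    "multivariate_scan",
    "ols_r2",
]


def spearman_coloc(map_a: ParcelMap, map_b: ParcelMap) -> tuple[float, float]:
    """Spatial Spearman rho across parcels and its Fisher z transform."""
    check_aligned(map_a, map_b)
    if map_a.values.std() == 0 or map_b.values.std() == 0:
        raise ValueError("constant map has no rank correlation")
    rho = float(scipy.stats.spearmanr(map_a.values, map_b.values).statistic)
    z = float(np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15)))
    return rho, z


def coloc_trajectory(atlases: AtlasSet, trajectories,
                     sexes: tuple[str, ...] = ("average",)) -> pd.DataFrame:
    """Spearman colocalization of each atlas with CT over the full grid.

    Returns a long DataFrame (atlas, age, percentile, sex, rho, fisher_z)
    covering every age x percentile of the trajectory set.
    """
    check_aligned(atlases, trajectories)
    rows = []
    # rank the atlas maps once; CT ranks vary with the slice
    atlas_ranks = scipy.stats.rankdata(atlases.matrix(), axis=0)
    for sex in sexes:
        for pct in trajectories.percentiles:
            for age in trajectories.ages:
                ct = trajectories.slice_map(age, pct, sex).values
                ct_rank = scipy.stats.rankdata(ct)
                r = _pearson_vec(atlas_ranks, ct_rank)
                rows.append(pd.DataFrame({
                    "atlas": atlases.names, "age": age, "percentile": pct,
                    "sex": sex, "rho": r,
                    "fisher_z": np.arctanh(np.clip(r, -1 + 1e-15,
                                                   1 - 1e-15))}))
    return pd.concat(rows, ignore_index=True)


def _pearson_vec(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with y."""
    Xc = X - X.mean(0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(0) * (yc ** 2).sum())
    return (Xc.T @ yc) / denom


def ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """R² and adjusted R² of OLS of y on X (intercept always included)."""
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more parcels than predictors + 1")
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return float(r2), float(adj)


def _window_frame(changes: list[CTChangeMap]) -> pd.DataFrame:
    return pd.DataFrame({
        "window_start": [c.window[0] for c in changes],
        "window_end": [c.window[1] for c in changes],
        "window_center": [c.center for c in changes]})


def univariate_scan(atlas: ParcelMap, changes: list[CTChangeMap],
                    nulls: NullEnsemble) -> pd.DataFrame:
    """Simple regression of each window's change map on one atlas.

    R² (= squared Pearson correlation), Spearman rho for the association
    sign, and a positive-sided empirical p against R² of the surrogate
    predictors.  The same surrogate ensemble is reused for every window.
    """
    if nulls.source_name != atlas.name or \
            tuple(nulls.parcel_ids) != tuple(atlas.parcel_ids):
        raise ValueError("null ensemble does not match the atlas")
    for c in changes:
        check_aligned(atlas, c.map)
    Y = np.column_stack([c.values for c in changes])
    r = _pearson_vec(Y, atlas.values)
    r2 = r ** 2
    # null R2: correlation of every surrogate with every window map
    S = nulls.surrogates
    Sc = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    Yc = (Y - Y.mean(0)) / Y.std(0)
    null_r2 = ((Sc @ Yc) / Y.shape[0]) ** 2          # (n_nulls, n_windows)
    pvals = (1 + (null_r2 >= r2[None, :]).sum(0)) / (1 + nulls.n)
    rho = np.array([
        scipy.stats.spearmanr(atlas.values, c.values).statistic
        for c in changes])
    out = _window_frame(changes)
    out["predictor"] = atlas.name
    out["r2"] = r2
    out["rho"] = rho
    out["p"] = pvals
    out["n_nulls"] = nulls.n
    return out


def multivariate_scan(atlases: AtlasSet, changes: list[CTChangeMap],
                      nulls: dict[str, NullEnsemble],
                      n_null_iters: int | None = None,
                      label: str = "combined") -> pd.DataFrame:
    """OLS of each window's change map on all predictors jointly.

    Null distribution: in iteration t, every predictor is replaced by its
    t-th surrogate (drawn jointly, one fresh surrogate per atlas per
    iteration) and the regression is refit; empirical p is positive-sided
    on R².  Adjusted R² is reported as computed (it may be negative).
    """
    names = atlases.names
    missing = [n for n in names if n not in nulls]
    if missing:
        raise ValueError(f"no null ensemble for predictors {missing}")
    for c in changes:
        check_aligned(atlases, c.map)
    X = atlases.matrix()
    X = (X - X.mean(0)) / X.std(0)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more parcels than predictors + 1")
    navail = min(nulls[nm].n for nm in names)
    n_iter = navail if n_null_iters is None else n_null_iters
    if n_iter > navail:
        raise ValueError(f"requested {n_iter} null iterations but smallest "
                         f"ensemble has {navail}")

    Y = np.column_stack([c.values for c in changes])
    r2, adj = _multi_r2_all(X, Y)
    null_r2 = np.empty((n_iter, Y.shape[1]))
    for t in range(n_iter):
        Xt = np.column_stack([nulls[nm].surrogates[t] for nm in names])
        Xt = (Xt - Xt.mean(0)) / Xt.std(0)
        null_r2[t] = _multi_r2_all(Xt, Y)[0]
    pvals = (1 + (null_r2 >= r2[None, :]).sum(0)) / (1 + n_iter)

    out = _window_frame(changes)
    out["predictor"] = label
    out["r2"] = r2
    out["adj_r2"] = adj
    out["p"] = pvals
    out["n_nulls"] = n_iter
    return out


def _multi_r2_all(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray,
                                                         np.ndarray]:
    """R² / adjusted R² of OLS of every column of Y on the full X."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    resid = Y - Xd @ beta
    sst = ((Y - Y.mean(0)) ** 2).sum(0)
    r2 = 1.0 - (resid ** 2).sum(0) / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2, adj


def add_fdr(frames: list[pd.DataFrame],
            grouping: list | None = None) -> pd.DataFrame:
    """Concatenate scan frames and add BH q-values.

    ``grouping`` gives one family label per frame (e.g. the predictor's
    modality for univariate scans, a single label for combined scans);
    omitted, all tests form one family.
    """
    df = pd.concat(frames, ignore_index=True)
    if grouping is None:
        labels = np.zeros(len(df), dtype=int)
    else:
        labels = np.concatenate([
            np.repeat(g, len(f)) for g, f in zip(grouping, frames)])
    df["q"] = fdr_adjust(df["p"].to_numpy(), labels)
    return df
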
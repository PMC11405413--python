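"""Spatially autocorrelated null maps and empirical p-value machinery.

Parametric p-values are meaningless for across-parcel correlations: the
number of parcels is arbitrary and neighboring parcels are not independent.
All inference in this package therefore compares observed statistics to
null distributions built from surrogate maps that preserve the predictor
map's spatial autocorrelation, characterized by its variogram (semivariance
of value differences as a function of inter-parcel distance).

Surrogates are generated with a variogram-matching scheme: randomly permute
the map (destroying autocorrelation, preserving values), smooth the
permutation with distance-decaying kernels at a ladder of neighborhood
scales, and pick the scale and affine smoothed+noise mixture whose
variogram best matches the source map's; optionally the surrogate values
are then rank-mapped back onto the source value multiset, so each null map
is a spatially plausible rearrangement of the original values.

Empirical p-values use the valid finite-sample convention
``p = (1 + #{null >= observed}) / (1 + N)`` and are never zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from statsmodels.stats.multitest import multipletests

from .parcel_core import ParcelMap

__all__ = [
    "DistanceMatrix",
    "NullEnsemble",
    "pairwise_distances",
    "empirical_variogram",
    "smoothed_variogram",
    "variogram_fidelity",
    "generate_surrogates",
    "empirical_p",
    "fdr_adjust",
]


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric inter-parcel distance matrix with zero diagonal."""

    parcel_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        object.__setattr__(self, "d", d)
        n = len(self.parcel_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distances must be symmetric, nonnegative, "
                             "zero-diagonal")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)


def pairwise_distances(geometry) -> DistanceMatrix:
    """Euclidean centroid distances for a ParcelGeometry."""
    xyz = np.asarray(geometry.centroid_coords, float)
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(tuple(geometry.parcel_ids), d)


def _pair_bins(d: DistanceMatrix, n_bins: int):
    """Upper-triangle pair indices, sorted by distance, in equal-count bins."""
    iu, ju = np.triu_indices(d.n_parcels, k=1)
    dist = d.d[iu, ju]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > dist.size:
        raise ValueError(f"n_bins={n_bins} exceeds pair count {dist.size}")
    order = np.argsort(dist, kind="stable")
    bin_id = np.minimum((np.arange(dist.size) * n_bins) // dist.size,
                        n_bins - 1)
    bins = np.empty(dist.size, dtype=np.intp)
    bins[order] = bin_id
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    centers = np.bincount(bins, weights=dist, minlength=n_bins) / counts
    return iu, ju, bins, counts, centers


def empirical_variogram(pmap: ParcelMap, d: DistanceMatrix,
                        n_bins: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Binned semivariance gamma(h) = 0.5 * mean (x_u - x_v)^2 per bin.

    Distance bins contain (near-)equal numbers of parcel pairs; returns
    (bin centers, semivariance).
    """
    iu, ju, bins, counts, centers = _pair_bins(d, n_bins)
    sq = 0.5 * (pmap.values[iu] - pmap.values[ju]) ** 2
    gamma = np.bincount(bins, weights=sq, minlength=n_bins) / counts
    return centers, gamma


def _smooth_weights(d: DistanceMatrix, pv: float, nh: int):
    """Pair selection + Gaussian smoothing weights for variogram curves.

    Only pairs within the ``pv`` quantile of distances enter (spatial
    autocorrelation lives at short range; the long-range interhemispheric
    sill is uninformative); gamma is evaluated at ``nh`` points with a
    Gaussian kernel of bandwidth three grid spacings.
    """
    iu, ju = np.triu_indices(d.n_parcels, k=1)
    dist = d.d[iu, ju]
    cut = np.quantile(dist, pv)
    sel = dist <= cut
    iu, ju, dist = iu[sel], ju[sel], dist[sel]
    u = np.linspace(dist.min(), cut, nh)
    bw = 3.0 * (u[1] - u[0])
    W = np.exp(-0.5 * ((u[:, None] - dist[None, :]) / bw) ** 2)
    W /= W.sum(axis=1, keepdims=True)
    return iu, ju, u, W


def smoothed_variogram(values: np.ndarray, d: DistanceMatrix,
                       pv: float = 0.25, nh: int = 25
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-smoothed variogram curve over the short-distance range.

    Returns (evaluation distances, gamma).  ``values`` may be (n_parcels,)
    or (m, n_parcels) for m maps at once.
    """
    iu, ju, u, W = _smooth_weights(d, pv, nh)
    x = np.atleast_2d(np.asarray(values, float))
    sq = 0.5 * (x[:, iu] - x[:, ju]) ** 2
    gamma = sq @ W.T
    return u, (gamma[0] if np.asarray(values).ndim == 1 else gamma)


def variogram_fidelity(ens: "NullEnsemble", source: ParcelMap,
                       d: DistanceMatrix) -> np.ndarray:
    """Spearman correlation of each surrogate's smoothed variogram with
    the source map's, using the ensemble's own fitting parameters."""
    import scipy.stats
    pv = ens.params.get("pv", 0.25)
    nh = ens.params.get("n_bins", 25)
    _, g0 = smoothed_variogram(source.values, d, pv, nh)
    _, gs = smoothed_variogram(ens.surrogates, d, pv, nh)
    return np.array([scipy.stats.spearmanr(g0, g).statistic for g in gs])


@dataclasses.dataclass
class NullEnsemble:
    """N variogram-matched surrogate maps for one source map."""

    source_name: str
    parcel_ids: tuple[str, ...]
    surrogates: np.ndarray  # (n, n_parcels)
    seed: int
    params: dict

    @property
    def n(self) -> int:
        return self.surrogates.shape[0]

    def map(self, i: int) -> ParcelMap:
        return ParcelMap(self.parcel_ids, self.surrogates[i],
                         f"{self.source_name}_null{i}")


def _knn_ladder(n_parcels: int, frac_lo: float, frac_hi: float,
                n_scales: int) -> np.ndarray:
    ks = np.geomspace(max(3, int(frac_lo * n_parcels)),
                      max(4, int(frac_hi * n_parcels)), n_scales)
    return np.unique(np.round(ks).astype(int))


def generate_surrogates(pmap: ParcelMap, d: DistanceMatrix, n: int,
                        seed: int, *, n_bins: int = 25, pv: float = 0.25,
                        knn_fracs: tuple[float, float] = (0.05, 0.5),
                        n_scales: int = 8,
                        resample: bool = True) -> NullEnsemble:
    """Generate ``n`` surrogate maps matching the source map's variogram.

    Per surrogate: permute values, smooth with exponential-decay kernels
    truncated at each of a ladder of k-nearest-neighbor scales, select the
    scale and nonnegative affine combination (smoothed field + white noise)
    whose smoothed variogram (evaluated at ``n_bins`` points over pairs
    within the ``pv`` distance quantile) best fits the source variogram in
    least squares, and (by default) rank-remap values onto the source
    multiset.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need n >= 1 surrogates")
    x = np.asarray(pmap.values, float)
    if x.std() == 0:
        raise ValueError("cannot build surrogates for a constant map")
    if tuple(pmap.parcel_ids) != tuple(d.parcel_ids):
        raise ValueError("map and distance matrix parcel sets differ")
    npar = x.size
    rng = np.random.default_rng(seed)

    iu, ju, _, Wv = _smooth_weights(d, pv, n_bins)
    gamma0 = Wv @ (0.5 * (x[iu] - x[ju]) ** 2)

    # precompute row-normalized kernels for each neighborhood scale
    ks = _knn_ladder(npar, *knn_fracs, n_scales)
    order = np.argsort(d.d, axis=1)
    kernels = []
    for k in ks:
        nb = order[:, 1:k + 1]  # k nearest neighbors, self excluded
        dk = d.d[np.arange(npar)[:, None], nb]
        w = np.exp(-dk / dk[:, -1:])
        W = np.zeros((npar, npar))
        W[np.arange(npar)[:, None], nb] = w / w.sum(1, keepdims=True)
        kernels.append(W)

    perms = np.array([rng.permutation(npar) for _ in range(n)])
    xp = x[perms]                                    # (n, npar)
    eps = rng.standard_normal((n, npar))
    eps = (eps - eps.mean(1, keepdims=True)) / eps.std(1, keepdims=True)

    best_sse = np.full(n, np.inf)
    best = np.empty((n, npar))
    for W in kernels:
        sm = xp @ W.T
        sm = (sm - sm.mean(1, keepdims=True)) / sm.std(1, keepdims=True)
        # candidate variogram is alpha*gamma_sm + beta*gamma_eps; for
        # unit-variance white noise gamma_eps(h) ~= 1, so fit
        # gamma0 ~= alpha*gamma_sm + beta with alpha, beta >= 0
        dsq = 0.5 * (sm[:, iu] - sm[:, ju]) ** 2
        g_sm = dsq @ Wv.T
        # closed-form 2-parameter least squares with nonnegativity clipping
        gbar = g_sm.mean(1, keepdims=True)
        g0bar = gamma0.mean()
        sxx = ((g_sm - gbar) ** 2).sum(1)
        sxy = ((g_sm - gbar) * (gamma0 - g0bar)).sum(1)
        alpha = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-30), 0.0)
        alpha = np.clip(alpha, 0.0, None)
        beta = np.clip(g0bar - alpha * gbar[:, 0], 0.0, None)
        fit = alpha[:, None] * g_sm + beta[:, None]
        sse = ((fit - gamma0) ** 2).sum(1)
        better = sse < best_sse
        if np.any(better):
            cand = (np.sqrt(alpha)[:, None] * sm
                    + np.sqrt(beta)[:, None] * eps)
            best[better] = cand[better]
            best_sse[better] = sse[better]

    if resample:
        ranks = np.argsort(np.argsort(best, axis=1), axis=1)
        best = np.sort(x)[ranks]

    params = {"n_bins": n_bins, "pv": pv, "knn_fracs": knn_fracs,
              "n_scales": int(len(ks)), "resample": resample,
              "kernel": "exponential"}
    return NullEnsemble(pmap.name, tuple(pmap.parcel_ids), best,
                        int(seed), params)


def empirical_p(observed: float, nulls: np.ndarray,
                side: str = "greater") -> float:
    """One-sided empirical p = (1 + #{null at least as extreme}) / (1 + N).

    Ties count against the observation; the minimum attainable value is
    1/(N+1), never 0.
    """
    nulls = np.asarray(nulls, float).ravel()
    if nulls.size == 0:
        raise ValueError("need at least one null value")
    if side == "greater":
        k = int(np.sum(nulls >= observed))
    elif side == "less":
        k = int(np.sum(nulls <= observed))
    else:
        raise ValueError(f"unknown side {side!r}")
    return (1 + k) / (1 + nulls.size)


def fdr_adjust(pvalues, grouping=None) -> np.ndarray:
    """Benjamini-Hochberg q-values, adjusted independently within groups.

    ``grouping`` is an optional sequence of labels (same length as
    ``pvalues``); tests sharing a label form one FDR family.
    """
    p = np.asarray(pvalues, float).ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.empty_like(p)
    if grouping is None:
        grouping = np.zeros(p.size, dtype=int)
    grouping = np.asarray(grouping)
    if grouping.size != p.size:
        raise ValueError("grouping length must match p-values")
    for g in np.unique(grouping):
        sel = grouping == g
        q[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return q
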
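"""Dominance analysis and regional influence maps.

Total dominance decomposes a multivariate regression's R² into predictor-
wise contributions: for predictor x it is the average (over subset sizes,
then over subsets of that size not containing x) of the incremental R²
gained by adding x.  The per-predictor values are nonnegative for OLS on
non-degenerate designs and sum exactly to the full-model R², so they can
be read as the fraction of explained spatial variance carried by each
marker.  Enumeration is exact over all 2^p subsets (capped at p = 15).

Regional influence: for predictor x, the prediction-error difference
dPE = |residual of the model without x| - |residual of the full model|
per parcel; positive values mark parcels where x improves the fit.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools

import numpy as np
import pandas as pd
import scipy.stats

from .ct_change_windows import CTChangeMap
from .parcel_core import AtlasSet, ParcelMap, check_aligned
from .spatial_nulls import NullEnsemble, fdr_adjust

__all__ = [
    "DominanceResult",
    "total_dominance",
    "dominance_scan",
    "influence_map",
    "MAX_PREDICTORS",
]

MAX_PREDICTORS = 15


@dataclasses.dataclass
class DominanceResult:
    """Dominance decomposition for one change-map window."""

    window: tuple[float, float]
    full_model_r2: float
    full_model_adj_r2: float
    total_dominance: pd.Series      # per predictor, sums to full_model_r2
    spearman_rho: pd.Series         # association sign per predictor
    p_full: float | None = None
    q_full: float | None = None
    p: pd.Series | None = None      # per-predictor empirical p
    q: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"window_start": self.window[0],
                 "window_end": self.window[1], "term": "full_model",
                 "value": self.full_model_r2,
                 "adj_r2": self.full_model_adj_r2, "rho": np.nan,
                 "p": self.p_full, "q": self.q_full}]
        for name in self.total_dominance.index:
            rows.append({
                "window_start": self.window[0],
                "window_end": self.window[1], "term": name,
                "value": self.total_dominance[name], "adj_r2": np.nan,
                "rho": self.spearman_rho[name],
                "p": None if self.p is None else self.p[name],
                "q": None if self.q is None else self.q[name]})
        return pd.DataFrame(rows)


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    return (X - X.mean(0)) / sd


def _subset_r2_table(C: np.ndarray, c: np.ndarray) -> np.ndarray:
    """R² of OLS on every predictor subset, from correlations alone.

    ``C`` is the (p, p) predictor correlation matrix, ``c`` the (p, m)
    predictor-outcome correlations for m outcomes.  Returns (2^p, m) with
    subset S at index ``sum(1 << i for i in S)``; empty set has R² 0.
    For standardized data, R²(S) = c_Sᵀ C_SS⁻¹ c_S.
    """
    p = C.shape[0]
    m = c.shape[1]
    table = np.zeros((1 << p, m))
    for k in range(1, p + 1):
        subsets = list(itertools.combinations(range(p), k))
        idx = np.array(subsets)                       # (n_k, k)
        Cs = C[idx[:, :, None], idx[:, None, :]]      # (n_k, k, k)
        cs = c[idx]                                   # (n_k, k, m)
        sol = np.linalg.solve(Cs, cs)
        r2 = (cs * sol).sum(axis=1)                   # (n_k, m)
        masks = [sum(1 << i for i in s) for s in subsets]
        table[masks] = r2
    return table


@functools.lru_cache(maxsize=8)
def _dominance_weights(p: int):
    """Per predictor: subset indices without/with it and averaging weights.

    Weight of subset S (|S| = k, x not in S) is 1 / (p * C(p-1, k)): the
    incremental R² is first averaged within each subset size, then across
    the p sizes 0..p-1.
    """
    from math import comb
    out = []
    for x in range(p):
        others = [i for i in range(p) if i != x]
        idx0, idx1, w = [], [], []
        for k in range(p):
            for s in itertools.combinations(others, k):
                mask = sum(1 << i for i in s)
                idx0.append(mask)
                idx1.append(mask | (1 << x))
                w.append(1.0 / (p * comb(p - 1, k)))
        out.append((np.array(idx0), np.array(idx1), np.array(w)))
    return out


def _dominance_from_table(table: np.ndarray, p: int) -> np.ndarray:
    """(p, m) total dominance from the (2^p, m) subset R² table."""
    dom = np.empty((p, table.shape[1]))
    for x, (idx0, idx1, w) in enumerate(_dominance_weights(p)):
        dom[x] = w @ (table[idx1] - table[idx0])
    return dom


def _check_design(X: np.ndarray) -> None:
    n, p = X.shape
    if p > MAX_PREDICTORS:
        raise ValueError(
            f"{p} predictors exceed the exact-enumeration cap of "
            f"{MAX_PREDICTORS} (2^p subset models)")
    if n <= p + 1:
        raise ValueError("need more parcels than predictors + 1")
    if p > 1:
        C = np.corrcoef(X, rowvar=False)
        if np.linalg.cond(C) > 1e10:
            raise ValueError("rank-deficient predictor set")


def total_dominance(predictors: AtlasSet, outcome: CTChangeMap,
                    ) -> DominanceResult:
    """Exact total-dominance decomposition for one window."""
    check_aligned(predictors, outcome.map)
    X = _standardize(predictors.matrix())
    _check_design(X)
    n, p = X.shape
    y = outcome.values
    if y.std() == 0:
        raise ValueError("constant outcome map")
    C = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
    ycs = (y - y.mean()) / y.std()
    c = (X.T @ ycs / n)[:, None]
    table = _subset_r2_table(C, c)
    dom = _dominance_from_table(table, p)[:, 0]
    r2_full = float(table[-1, 0])
    adj = 1.0 - (1.0 - r2_full) * (n - 1) / (n - p - 1)
    rho = pd.Series(
        [scipy.stats.spearmanr(X[:, i], y).statistic for i in range(p)],
        index=predictors.names)
    return DominanceResult(outcome.window, r2_full, float(adj),
                           pd.Series(dom, index=predictors.names), rho)


def dominance_scan(predictors: AtlasSet, changes: list[CTChangeMap],
                   nulls: dict[str, NullEnsemble],
                   n_null_iters: int = 10_000,
                   fdr_family: str = "whole_analysis",
                   ) -> list[DominanceResult]:
    """Dominance decomposition per window with surrogate-based inference.

    Each null iteration replaces the whole predictor set by jointly drawn
    surrogates (one per atlas) and recomputes the full-model R² and every
    total dominance for every window.  Empirical p-values are positive-
    sided; BH-FDR is applied across the whole analysis — full-model plus
    predictor-wise tests of all windows in one family (e.g. 82 + 82 x 9).
    """
    names = predictors.names
    missing = [nm for nm in names if nm not in nulls]
    if missing:
        raise ValueError(f"no null ensemble for predictors {missing}")
    results = [total_dominance(predictors, ch) for ch in changes]

    navail = min(nulls[nm].n for nm in names)
    if n_null_iters > navail:
        raise ValueError(f"requested {n_null_iters} null iterations but "
                         f"smallest ensemble has {navail}")
    Y = np.column_stack([c.values for c in changes])
    Ys = _standardize(Y)
    n, p = predictors.n_parcels, len(names)
    nw = len(changes)
    obs_dom = np.column_stack([r.total_dominance.to_numpy()
                               for r in results])          # (p, nw)
    obs_full = np.array([r.full_model_r2 for r in results])
    ge_full = np.zeros(nw, dtype=int)
    ge_dom = np.zeros((p, nw), dtype=int)
    for t in range(n_null_iters):
        Xt = _standardize(np.column_stack(
            [nulls[nm].surrogates[t] for nm in names]))
        Ct = np.corrcoef(Xt, rowvar=False) if p > 1 else np.ones((1, 1))
        ct = Xt.T @ Ys / n
        table = _subset_r2_table(Ct, ct)
        ge_full += table[-1] >= obs_full
        ge_dom += _dominance_from_table(table, p) >= obs_dom
    p_full = (1 + ge_full) / (1 + n_null_iters)
    p_dom = (1 + ge_dom) / (1 + n_null_iters)

    allp = np.concatenate([p_full, p_dom.ravel()])
    allq = fdr_adjust(allp, np.repeat(fdr_family, allp.size))
    q_full, q_dom = allq[:nw], allq[nw:].reshape(p, nw)
    for w, r in enumerate(results):
        r.p_full = float(p_full[w])
        r.q_full = float(q_full[w])
        r.p = pd.Series(p_dom[:, w], index=names)
        r.q = pd.Series(q_dom[:, w], index=names)
    return results


def influence_map(predictors: AtlasSet, outcome: CTChangeMap,
                  target: str) -> ParcelMap:
    """dPE map: |reduced-model residual| - |full-model residual| per parcel.

    The reduced model omits ``target``; positive values mark parcels where
    the target predictor improves the fit of the change map.
    """
    if target not in predictors.names:
        raise ValueError(f"'{target}' not among predictors")
    if len(predictors) < 2:
        raise ValueError("influence map needs a reduced model "
                         "(at least two predictors)")
    check_aligned(predictors, outcome.map)
    X = _standardize(predictors.matrix())
    _check_design(X)
    y = outcome.values

    def resid(cols: np.ndarray) -> np.ndarray:
        Xd = np.column_stack([np.ones(len(y)), cols])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        return y - Xd @ beta

    keep = [i for i, nm in enumerate(predictors.names) if nm != target]
    dpe = np.abs(resid(X[:, keep])) - np.abs(resid(X))
    return ParcelMap(predictors.parcel_ids, dpe,
                     f"dPE_{target}", predictors.maps[0].hemisphere)
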
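"""Factor-analytic reduction of atlas libraries.

Collections of neurobiological marker maps are strongly intercorrelated;
to reduce multicollinearity in the downstream multivariate models each
modality's library is reduced by common factor analysis: minimum-residual
(minres/ULS) extraction on the atlas-by-atlas correlation matrix, a liberal
retention rule (every unrotated factor must explain at least a given
proportion — default 1% — of the set's total variable variance), oblique
promax rotation, and Thurstone regression factor scores, z-scored across
parcels, which become the factor-level marker maps (named ni1..n / ce1..n;
a single-map modality passes through unreduced, e.g. mr1).

The factor solution is validated against chance by refitting on libraries
whose parcel order has been permuted independently within each map and
comparing cumulative rotated explained variance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.optimize
from statsmodels.multivariate.factor_rotation import promax as _sm_promax

from .parcel_core import AtlasSet, ParcelMap

__all__ = [
    "FactorSolution",
    "FactorModelError",
    "fit_factor_model",
    "name_factors",
    "reduce_modality",
    "validate_against_permuted",
    "tucker_congruence",
]


class FactorModelError(ValueError):
    pass


@dataclasses.dataclass
class FactorSolution:
    """Fitted, rotated factor model of an atlas library.

    ``loadings`` is the promax pattern matrix (atlas x factor),
    ``structure`` the structure matrix (pattern @ Phi), ``scores`` the
    z-scored factor-score maps.  Variance proportions use the number of
    maps as denominator (proportion of total variable variance); rotated
    per-factor proportions are SS of structure loadings / n_maps and their
    cumulative sum can exceed the unrotated total because oblique factors
    overlap.
    """

    loadings: pd.DataFrame
    structure: pd.DataFrame
    factor_correlations: pd.DataFrame
    scores: AtlasSet
    variance_explained_unrotated: np.ndarray
    variance_explained_rotated: np.ndarray
    names: list[str]
    uniquenesses: np.ndarray
    unrotated_loadings: pd.DataFrame
    assignment: dict[str, list[str]]
    params: dict

    @property
    def n_factors(self) -> int:
        return len(self.names)

    @property
    def cumulative_rotated_variance(self) -> float:
        return float(self.variance_explained_rotated.sum())


def _correlation_matrix(atlases: AtlasSet) -> np.ndarray:
    X = atlases.matrix()
    if X.shape[0] <= X.shape[1]:
        raise FactorModelError("need more parcels than maps")
    R = np.corrcoef(X, rowvar=False)
    if np.linalg.cond(R) > 1e10:
        raise FactorModelError(
            "atlas correlation matrix is (near-)singular; remove duplicate "
            "or collinear maps")
    return R


def _minres(R: np.ndarray, k: int, tol: float = 1e-6,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-residual extraction of k factors from correlation matrix R.

    Optimizes uniquenesses so that the discarded eigenvalues of the
    reduced matrix R - diag(psi) are as small as possible (ULS); loadings
    come from the leading eigenpairs of the reduced matrix.
    """
    p = R.shape[0]
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    psi0 = np.clip(1.0 - smc, 0.01, 0.99)

    def loss_grad(psi):
        Rs = R - np.diag(psi)
        e, V = np.linalg.eigh(Rs)
        e, V = e[::-1], V[:, ::-1]
        resid = np.concatenate([np.minimum(e[:k], 0.0), e[k:]])
        residV = np.concatenate([V[:, :k][:, e[:k] < 0], V[:, k:]], axis=1)
        rvals = np.concatenate([e[:k][e[:k] < 0], e[k:]])
        f = float(np.sum(rvals ** 2))
        grad = -2.0 * (residV ** 2) @ rvals
        return f, grad

    res = scipy.optimize.minimize(
        loss_grad, psi0, jac=True, method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": tol})
    psi = res.x
    e, V = np.linalg.eigh(R - np.diag(psi))
    e, V = e[::-1][:k], V[:, ::-1][:, :k]
    lam = V * np.sqrt(np.clip(e, 0.0, None))
    return lam, psi


def _ledermann_bound(p: int) -> int:
    return int(np.floor((2 * p + 1 - np.sqrt(8 * p + 1)) / 2))


def fit_factor_model(atlases: AtlasSet, retention_threshold: float = 0.01,
                     promax_power: int = 4) -> FactorSolution:
    """Fit the minres + promax factor model with the retention rule.

    The number of factors is the largest k (up to the Ledermann bound) for
    which every unrotated factor's SS-loading proportion of total variable
    variance is at least ``retention_threshold``.  All maps must be
    z-scored.  Raises if zero factors survive the threshold.
    """
    if len(atlases) < 2:
        raise FactorModelError("need at least two maps for factor analysis")
    for m in atlases.maps:
        if not m.standardized:
            raise FactorModelError(
                f"map '{m.name}' is not z-scored; standardize first")
    p = len(atlases)
    R = _correlation_matrix(atlases)
    kmax = max(1, _ledermann_bound(p))

    best = None
    for k in range(1, kmax + 1):
        lam, psi = _minres(R, k)
        props = (lam ** 2).sum(axis=0) / p
        if np.min(props) >= retention_threshold:
            best = (k, lam, psi, props)
        else:
            break
    if best is None:
        raise FactorModelError(
            f"no unrotated factor reaches the retention threshold "
            f"{retention_threshold:.3g}; lower the threshold")
    k, lam, psi, props = best

    if k == 1:
        pattern, phi = lam.copy(), np.ones((1, 1))
    else:
        _, T = _sm_promax(lam, k=promax_power)
        pattern = lam @ np.linalg.inv(T.T)
        phi = T.T @ T
    structure = pattern @ phi

    # orient each factor so its top-loading atlas loads positively
    for j in range(k):
        top = np.argmax(np.abs(pattern[:, j]))
        if pattern[top, j] < 0:
            pattern[:, j] *= -1
            structure[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1

    rotated_var = (structure ** 2).sum(axis=0) / p

    # Thurstone regression factor scores, z-scored across parcels
    X = atlases.matrix()
    Z = (X - X.mean(0)) / X.std(0)
    W = np.linalg.solve(R, structure)
    raw = Z @ W
    sd = raw.std(0)
    if np.any(sd == 0):
        raise FactorModelError("degenerate factor scores (zero variance)")
    scores = (raw - raw.mean(0)) / sd

    names = [f"f{j + 1}" for j in range(k)]
    idx = pd.Index(atlases.names, name="atlas")
    cols = pd.Index(names, name="factor")
    score_maps = AtlasSet([
        ParcelMap(atlases.parcel_ids, scores[:, j], names[j],
                  atlases.maps[0].hemisphere, standardized=True)
        for j in range(k)])
    assignment = {n: [] for n in names}
    for i, atlas in enumerate(atlases.names):
        assignment[names[int(np.argmax(np.abs(pattern[i])))]].append(atlas)
    return FactorSolution(
        loadings=pd.DataFrame(pattern, idx, cols),
        structure=pd.DataFrame(structure, idx, cols),
        factor_correlations=pd.DataFrame(phi, cols, cols.copy()),
        scores=score_maps,
        variance_explained_unrotated=props,
        variance_explained_rotated=rotated_var,
        names=names,
        uniquenesses=psi,
        unrotated_loadings=pd.DataFrame(lam, idx, cols),
        assignment=assignment,
        params={"method": "minres", "rotation": "promax",
                "promax_power": promax_power,
                "retention_threshold": retention_threshold,
                "score_method": "thurstone-regression"},
    )


def name_factors(solution: FactorSolution,
                 modality_prefix: str) -> FactorSolution:
    """Rename factors to ``<prefix>1..n`` (in extraction order).

    The assignment report lists, per factor, the atlases whose maximal
    absolute pattern loading falls on it (ties to the lower factor index).
    """
    new = [f"{modality_prefix}{j + 1}" for j in range(solution.n_factors)]
    ren = dict(zip(solution.names, new))
    solution.loadings.columns = pd.Index(new, name="factor")
    solution.structure.columns = pd.Index(new, name="factor")
    solution.unrotated_loadings.columns = pd.Index(new, name="factor")
    solution.factor_correlations.index = pd.Index(new, name="factor")
    solution.factor_correlations.columns = pd.Index(new, name="factor")
    solution.scores = AtlasSet([m.with_values(m.values, name=ren[m.name])
                                for m in solution.scores.maps])
    solution.assignment = {ren[k]: v for k, v in solution.assignment.items()}
    solution.names = new
    return solution


def reduce_modality(atlases: AtlasSet, retention_threshold: float = 0.01,
                    prefix: str = "f",
                    ) -> tuple[AtlasSet, FactorSolution | None]:
    """Reduce one modality's library to factor-score maps.

    Single-map modalities pass through unreduced (z-scored, renamed
    ``<prefix>1``), mirroring the microstructural mr1 marker.
    """
    if len(atlases) == 1:
        m = atlases.maps[0]
        if not m.standardized:
            from .parcel_core import zscore_map
            m = zscore_map(m)
        return AtlasSet([m.with_values(m.values, name=f"{prefix}1")]), None
    sol = name_factors(fit_factor_model(atlases, retention_threshold), prefix)
    return sol.scores, sol


def validate_against_permuted(atlases: AtlasSet, n_permutations: int,
                              seed: int,
                              retention_threshold: float = 0.01) -> dict:
    """Permuted-map validation of the factor solution.

    Parcel order is permuted independently within each map (destroying
    shared spatial structure while keeping each map's values), the full
    retention + rotation pipeline is refit, and the observed cumulative
    rotated explained variance is compared against the null to give a
    one-sided empirical p = (1 + #{null >= observed}) / (1 + N).  Null
    libraries where no factor survives retention contribute zero variance.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    observed = fit_factor_model(
        atlases, retention_threshold).cumulative_rotated_variance
    rng = np.random.default_rng(seed)
    npar = atlases.n_parcels
    null = np.zeros(n_permutations)
    for b in range(n_permutations):
        maps = []
        for m in atlases.maps:
            perm = rng.permutation(npar)
            maps.append(ParcelMap(m.parcel_ids, m.values[perm], m.name,
                                  m.hemisphere, m.standardized))
        try:
            null[b] = fit_factor_model(
                AtlasSet(maps), retention_threshold
            ).cumulative_rotated_variance
        except FactorModelError:
            null[b] = 0.0
    p = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
    return {"observed_cumulative_variance": observed,
            "null_cumulative_variance": null, "p": p,
            "n_permutations": n_permutations, "seed": seed}


def tucker_congruence(a: np.ndarray, b: np.ndarray,
                      match: bool = True) -> np.ndarray:
    """Tucker congruence coefficients between loading-matrix columns.

    With ``match=True``, columns of ``b`` are greedily matched to columns
    of ``a`` by absolute congruence and the matched coefficients are
    returned (sign-free).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na = a / np.linalg.norm(a, axis=0)
    nb = b / np.linalg.norm(b, axis=0)
    C = np.abs(na.T @ nb)
    if not match:
        return C
    out = []
    used = set()
    for i in np.argsort(-C.max(axis=1)):
        j = max((j for j in range(C.shape[1]) if j not in used),
                key=lambda j: C[i, j])
        used.add(j)
        out.append(C[i, j])
    return np.array(out)
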
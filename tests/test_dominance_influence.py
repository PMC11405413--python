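"""Dominance decomposition, its oracle equivalence, and dPE influence."""

import itertools

import numpy as np
import pytest

from ctcoloc import (AtlasSet, ParcelMap, dominance_scan, influence_map,
                     total_dominance)
from ctcoloc.ct_change_windows import CTChangeMap


def orderings_average_oracle(X, y):
    """Independent formulation: average incremental R2 over all p!
    predictor orderings (brute force)."""
    n, p = X.shape

    def r2(cols):
        if not cols:
            return 0.0
        Xd = np.column_stack([np.ones(n), X[:, list(cols)]])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        return 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()

    dom = np.zeros(p)
    perms = list(itertools.permutations(range(p)))
    for perm in perms:
        chosen, prev = [], 0.0
        for x in perm:
            cur = r2(chosen + [x])
            dom[x] += cur - prev
            prev = cur
            chosen.append(x)
    return dom / len(perms)


def _design(n, p, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = X @ rng.standard_normal(p) + rng.standard_normal(n)
    ids = tuple(f"p{i}" for i in range(n))
    preds = AtlasSet([ParcelMap(ids, X[:, i], f"x{i}") for i in range(p)])
    return preds, CTChangeMap((0.0, 1.0), ParcelMap(ids, y, "y")), X, y


@pytest.mark.parametrize("p", [1, 2, 3, 5, 6])
def test_enumeration_equals_orderings_oracle(p):
    preds, outcome, X, y = _design(40, p, seed=p)
    res = total_dominance(preds, outcome)
    oracle = orderings_average_oracle((X - X.mean(0)) / X.std(0), y)
    assert np.allclose(res.total_dominance.to_numpy(), oracle, atol=1e-10)
    assert abs(res.total_dominance.sum() - res.full_model_r2) < 1e-10


def test_single_predictor_dominance_is_its_r2():
    preds, outcome, X, y = _design(40, 1, seed=0)
    res = total_dominance(preds, outcome)
    r = np.corrcoef(X[:, 0], y)[0, 1]
    assert res.total_dominance.iloc[0] == pytest.approx(r ** 2, abs=1e-12)


def test_orthogonal_predictors_dominance_is_marginal_r2():
    rng = np.random.default_rng(1)
    Q, _ = np.linalg.qr(rng.standard_normal((50, 2)))
    X = (Q - Q.mean(0)) / Q.std(0)  # exactly uncorrelated after centering?
    X = X - X.mean(0)
    # enforce exact orthogonality of centered columns
    X[:, 1] -= X[:, 0] * (X[:, 0] @ X[:, 1]) / (X[:, 0] @ X[:, 0])
    X /= X.std(0)
    y = 0.8 * X[:, 0] + 0.4 * X[:, 1] + rng.standard_normal(50)
    ids = tuple(f"p{i}" for i in range(50))
    preds = AtlasSet([ParcelMap(ids, X[:, i], f"x{i}") for i in range(2)])
    res = total_dominance(preds, CTChangeMap((0, 1), ParcelMap(ids, y, "y")))
    r1 = np.corrcoef(X[:, 0], y)[0, 1] ** 2
    r2 = np.corrcoef(X[:, 1], y)[0, 1] ** 2
    assert res.total_dominance.to_numpy() == pytest.approx([r1, r2],
                                                           abs=1e-10)
    assert res.full_model_r2 == pytest.approx(r1 + r2, abs=1e-10)


def test_dominance_relabeling_and_rescaling_invariance():
    preds, outcome, X, y = _design(40, 4, seed=7)
    base = total_dominance(preds, outcome).total_dominance
    ids = preds.parcel_ids
    shuffled = AtlasSet([preds.maps[i] for i in (2, 0, 3, 1)])
    re1 = total_dominance(shuffled, outcome).total_dominance
    assert np.allclose(re1.sort_index(), base.sort_index(), atol=1e-12)
    rescaled = AtlasSet([
        ParcelMap(ids, 3.0 * m.values - 5.0, m.name) for m in preds.maps])
    re2 = total_dominance(rescaled, outcome).total_dominance
    assert np.allclose(re2.to_numpy(), base.to_numpy(), atol=1e-12)


def test_predictor_cap_and_rank_deficiency_errors():
    rng = np.random.default_rng(2)
    ids = tuple(f"p{i}" for i in range(40))
    X = rng.standard_normal((40, 16))
    preds = AtlasSet([ParcelMap(ids, X[:, i], f"x{i}") for i in range(16)])
    outcome = CTChangeMap((0, 1), ParcelMap(ids, X[:, 0], "y"))
    with pytest.raises(ValueError, match="exceed"):
        total_dominance(preds, outcome)
    dup = AtlasSet([ParcelMap(ids, X[:, 0], "a"),
                    ParcelMap(ids, X[:, 0] * 2, "b")])
    with pytest.raises(ValueError, match="deficient"):
        total_dominance(dup, outcome)


def test_dominance_scan_family_size_and_sum_identity(atlases, change_maps,
                                                     small_nulls):
    results = dominance_scan(atlases, change_maps, small_nulls,
                             n_null_iters=100)
    for r in results:
        assert abs(r.total_dominance.sum() - r.full_model_r2) < 1e-10
        assert r.p is not None and (r.q >= r.p - 1e-12).all()
    # family: one full-model p plus one per predictor, per window
    n_p = sum(1 + len(r.p) for r in results)
    assert n_p == len(change_maps) * (1 + 9)


def test_dominance_scan_recovers_designed_mixture(atlases, change_maps,
                                                  small_nulls):
    """The two atlases mixed into the (10,15) change map occupy the top-2
    dominance ranks and reach the minimal empirical p."""
    target = [c for c in change_maps if c.window == (10.0, 15.0)]
    res = dominance_scan(atlases, target, small_nulls, n_null_iters=100)[0]
    top2 = set(res.total_dominance.sort_values(ascending=False).index[:2])
    assert top2 == {"atlas1", "atlas2"}
    assert res.p_full == pytest.approx(1 / 101)


def test_influence_map_formula_and_redundancy(atlases, change_maps):
    target = [c for c in change_maps if c.window == (10.0, 15.0)][0]
    dpe = influence_map(atlases, target, "atlas1")
    # direct recomputation of the formula
    X = atlases.zscored().matrix()
    y = target.values

    def absresid(M):
        Md = np.column_stack([np.ones(len(y)), M])
        beta, *_ = np.linalg.lstsq(Md, y, rcond=None)
        return np.abs(y - Md @ beta)

    expected = absresid(X[:, 1:]) - absresid(X)
    assert np.allclose(dpe.values, expected, atol=1e-10)
    assert dpe.values.mean() > 0  # atlas1 carries real signal

    # near-duplicate of the target predictor makes it redundant
    rng = np.random.default_rng(3)
    twin = atlases.maps[0].values + 1e-3 * rng.standard_normal(148)
    aug = AtlasSet(atlases.maps[:4]
                   + [ParcelMap(atlases.parcel_ids, twin, "twin")])
    dpe2 = influence_map(aug, target, "atlas1")
    assert np.abs(dpe2.values).max() < 0.1 * np.abs(dpe.values).max()


def test_influence_requires_a_reduced_model(atlases, change_maps):
    solo = atlases.subset(["atlas1"])
    with pytest.raises(ValueError):
        influence_map(solo, change_maps[0], "atlas1")
    with pytest.raises(ValueError, match="not among"):
        influence_map(atlases, change_maps[0], "nope")
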
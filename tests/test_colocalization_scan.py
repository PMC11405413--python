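"""Colocalization statistics and explained-variance scans."""

import numpy as np
import pytest

from ctcoloc import (ParcelMap, coloc_trajectory, multivariate_scan,
                     spearman_coloc, univariate_scan)
from ctcoloc.colocalization_scan import add_fdr, ols_r2
from ctcoloc.ct_change_windows import CTChangeMap


def _pm(vals, name="m"):
    return ParcelMap(tuple(f"p{i}" for i in range(len(vals))), vals, name)


def test_spearman_self_hand_case_and_rank_invariance():
    x = _pm([1.0, 2.0, 3.0], "x")
    assert spearman_coloc(x, x)[0] == pytest.approx(1.0)
    rho, z = spearman_coloc(x, _pm([3.0, 1.0, 2.0], "y"))
    assert rho == pytest.approx(-0.5)
    assert z == pytest.approx(np.arctanh(-0.5))
    mono = _pm(np.exp([1.0, 2.0, 3.0]), "e")
    assert spearman_coloc(x, mono)[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        spearman_coloc(x, _pm([2.0, 2.0, 2.0]))


def test_coloc_trajectory_covers_full_grid(atlases, trajectories):
    traj, _ = trajectories
    df = coloc_trajectory(atlases.subset(["atlas1"]), traj)
    assert len(df) == 171 * 7  # ages x percentiles for one atlas, one sex
    assert df.rho.abs().max() <= 1.0


def test_coloc_trajectory_perfect_alignment(trajectories):
    traj, _ = trajectories
    from ctcoloc.parcel_core import AtlasSet, zscore_map
    atlas = zscore_map(traj.slice_map(20.0, 50, "average"))
    atlas = atlas.with_values(atlas.values, name="ct_like")
    df = coloc_trajectory(AtlasSet([atlas]), traj)
    row = df[(df.age == 20.0) & (df.percentile == 50)]
    assert row.rho.iloc[0] == pytest.approx(1.0)


def test_univariate_r2_equals_squared_pearson(atlases, change_maps,
                                              small_nulls):
    a = atlases.maps[0]
    df = univariate_scan(a, change_maps, small_nulls[a.name])
    for _, row in df.iterrows():
        ch = [c for c in change_maps
              if c.window == (row.window_start, row.window_end)][0]
        r = np.corrcoef(a.values, ch.values)[0, 1]
        assert abs(row.r2 - r ** 2) < 1e-12


def test_univariate_perfect_predictor_minimal_p(atlases, change_maps,
                                                small_nulls):
    a = atlases.maps[0]
    perfect = CTChangeMap((10.0, 15.0), a.with_values(a.values, "dup"))
    df = univariate_scan(a, [perfect], small_nulls[a.name])
    assert df.r2.iloc[0] == pytest.approx(1.0)
    assert df.p.iloc[0] == pytest.approx(1 / 101)


def test_multivariate_exact_combination_and_invariances(atlases,
                                                        small_nulls):
    X = atlases.zscored().matrix()
    y = X @ np.linspace(1, 2, 9)
    ch = CTChangeMap((5.0, 10.0),
                     ParcelMap(atlases.parcel_ids, y, "mix"))
    df = multivariate_scan(atlases, [ch], small_nulls, 50)
    assert df.adj_r2.iloc[0] == pytest.approx(1.0)
    # predictor order invariance
    rev = atlases.subset(atlases.names[::-1])
    df2 = multivariate_scan(rev, [ch], small_nulls, 50)
    assert df2.r2.iloc[0] == pytest.approx(df.r2.iloc[0], abs=1e-10)


def test_multivariate_affine_predictor_rescaling_is_irrelevant(atlases,
                                                               change_maps):
    from ctcoloc.colocalization_scan import _multi_r2_all
    X = atlases.matrix()
    Y = np.column_stack([c.values for c in change_maps[:3]])
    r2a, _ = _multi_r2_all((X - X.mean(0)) / X.std(0), Y)
    scaled = X * np.linspace(0.2, 5, 9) + np.arange(9)
    r2b, _ = _multi_r2_all((scaled - scaled.mean(0)) / scaled.std(0), Y)
    assert np.allclose(r2a, r2b, atol=1e-10)


def test_noise_predictor_does_not_inflate_adjusted_r2():
    """Across 200 random draws, adding a pure-noise predictor leaves the
    mean adjusted R2 unchanged or lower."""
    rng = np.random.default_rng(0)
    diffs = []
    for _ in range(200):
        X = rng.standard_normal((60, 3))
        y = X[:, 0] + rng.standard_normal(60)
        _, adj_small = ols_r2(X, y)
        _, adj_big = ols_r2(np.column_stack([X, rng.standard_normal(60)]), y)
        diffs.append(adj_big - adj_small)
    assert np.mean(diffs) <= 0.005


def test_scan_model_counts_match_the_scheme(atlases, trajectories,
                                            small_nulls):
    """21 predictors x 81 windows univariate, 81 combined per modality."""
    from ctcoloc import build_windows
    assert len(build_windows(5, 90, 5, 1)) * 21 == 21 * 81


def test_add_fdr_groups_by_modality(atlases, change_maps, small_nulls):
    frames = [univariate_scan(m, change_maps[:2], small_nulls[m.name])
              for m in atlases.maps[:4]]
    df = add_fdr(frames, ["ni", "ni", "ce", "ce"])
    assert {"q"} <= set(df.columns)
    assert (df.q >= df.p - 1e-12).all()


def test_multivariate_requires_all_ensembles(atlases, change_maps,
                                             small_nulls):
    partial = {k: v for k, v in small_nulls.items() if k != "atlas3"}
    with pytest.raises(ValueError, match="atlas3"):
        multivariate_scan(atlases, change_maps[:1], partial, 10)
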
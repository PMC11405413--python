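"""Synthetic generators: determinism, designed correlations, ground truth."""

import numpy as np
import pytest

from ctcoloc import (GroundTruth, extract_change_series, make_atlas_library,
                     make_cohort, make_ct_trajectories,
                     make_expression_dataset, make_parcel_geometry,
                     sample_gp_map)
from ctcoloc.colocalization_scan import ols_r2
from ctcoloc.gene_trajectory_validation import (default_grid,
                                                loess_trajectory,
                                                period_statistics)


def test_geometry_counts_determinism_and_separation():
    g1 = make_parcel_geometry(74, seed=3)
    g2 = make_parcel_geometry(74, seed=3)
    assert g1.n_parcels == 148
    assert np.array_equal(g1.centroid_coords, g2.centroid_coords)
    left = g1.centroid_coords[np.array(g1.hemisphere) == "L", 0]
    right = g1.centroid_coords[np.array(g1.hemisphere) == "R", 0]
    assert left.max() < right.min()
    with pytest.raises(ValueError):
        make_parcel_geometry(2, seed=0)


def test_gp_map_determinism_and_autocorrelation_limits(geometry, distances):
    m1 = sample_gp_map(geometry, 25.0, seed=5)
    m2 = sample_gp_map(geometry, 25.0, seed=5)
    assert np.array_equal(m1.values, m2.values)
    with pytest.raises(ValueError):
        sample_gp_map(geometry, 0.0, seed=5)

    # long length scale: short-lag semivariance far below the sill
    from ctcoloc import empirical_variogram
    g1, gfar = [], []
    for s in range(20):
        m = sample_gp_map(geometry, 150.0, seed=3000 + s)
        _, gam = empirical_variogram(m, distances)
        g1.append(gam[0])
        gfar.append(gam[-5:].mean())
    assert np.mean(g1) < 0.3 * np.mean(gfar)

    # vanishing length scale: neighbor correlation ~ 0 over 100 seeds
    nn = np.argsort(distances.d, axis=1)[:, 1]
    rs = []
    for s in range(100):
        x = sample_gp_map(geometry, 1e-3, seed=s).values
        rs.append(np.corrcoef(x, x[nn])[0, 1])
    assert abs(np.mean(rs)) < 0.1


def test_atlas_library_cross_correlation_design(geometry):
    lib0 = make_atlas_library(geometry, 20, cross_correlation=0.0, seed=7)
    R = np.corrcoef(lib0.matrix(), rowvar=False)
    off = np.abs(R[np.triu_indices(20, 1)])
    assert off.mean() < 0.2

    lib9 = make_atlas_library(geometry, 20, cross_correlation=0.9, seed=8)
    ev = np.linalg.eigvalsh(np.corrcoef(lib9.matrix(), rowvar=False))
    assert ev[-1] / 20 > 0.6  # first PC explains > 60%

    assert len(make_atlas_library(geometry, 1, seed=9)) == 1
    with pytest.raises(ValueError):
        make_atlas_library(geometry, 0, seed=9)
    with pytest.raises(ValueError):
        make_atlas_library(geometry, 3, cross_correlation=-0.5, seed=9)


def test_trajectories_zero_mixture_gives_uniform_change(geometry, atlases):
    gt = GroundTruth(np.zeros(9), noise_sd=0.0, seed=3)
    traj, _ = make_ct_trajectories(geometry, atlases, gt)
    ch = extract_change_series(traj, [(10.0, 15.0)])[0]
    assert np.ptp(ch.values) < 1e-12
    assert np.all(traj.ct > 0)


def test_trajectories_single_atlas_perfect_correlation(geometry, atlases):
    w = np.zeros(9)
    w[3] = 1.0
    traj, _ = make_ct_trajectories(
        geometry, atlases, GroundTruth(w, noise_sd=0.0, seed=4))
    ch = extract_change_series(traj, [(10.0, 15.0)])[0]
    r = np.corrcoef(ch.values, atlases.maps[3].values)[0, 1]
    assert abs(r) > 1 - 1e-9


def test_construction_r2_recovered_by_regression(geometry, atlases,
                                                 truth_weights):
    """Regression of the realized change map on the true atlases recovers
    the construction R2 (tolerance 0.1; exact by design here)."""
    for seed in range(5):
        traj, realized = make_ct_trajectories(
            geometry, atlases,
            GroundTruth(truth_weights, construction_r2=0.6, seed=seed))
        ch = extract_change_series(traj, [(10.0, 15.0)])[0]
        r2, _ = ols_r2(atlases.zscored().matrix(), ch.values)
        assert abs(r2 - 0.6) < 0.1
        assert abs(realized.construction_r2 - 0.6) < 0.05


def test_trajectories_weight_mismatch_raises(geometry, atlases):
    with pytest.raises(ValueError, match="weights"):
        make_ct_trajectories(geometry, atlases,
                             GroundTruth(np.ones(3), noise_sd=0.1))


def test_ground_truth_requires_exactly_one_noise_parameter():
    with pytest.raises(ValueError):
        GroundTruth(np.ones(2), noise_sd=0.1, construction_r2=0.5)
    with pytest.raises(ValueError):
        GroundTruth(np.ones(2))
    with pytest.raises(ValueError):
        GroundTruth(np.zeros(2), construction_r2=0.5)


def test_expression_dataset_shape_and_null_construction():
    data = make_expression_dataset(n_subjects=33, seed=1)
    assert data.expression.shape[0] == 33
    assert len(data.nonbrain_pool) == 2154
    assert np.all(data.ages > 0)
    with pytest.raises(ValueError):
        make_expression_dataset(n_nonbrain_pool=0)

    # effect 0: signal genes indistinguishable from flat genes
    null = make_expression_dataset(effect_size=0.0, seed=2)
    sig = null.expression[:, :50].mean(0)
    flat = null.expression[:, 50:100].mean(0)
    import scipy.stats
    assert scipy.stats.ttest_ind(sig, flat).pvalue > 0.01


def test_expression_signal_genes_show_elevated_loess_ratio():
    """At effect 2 SD and n = 33 the LOESS within/outside ratio exceeds 1
    for at least 90% of individual signal genes."""
    data = make_expression_dataset(effect_size=2.0, seed=3)
    grid = default_grid(data.ages)
    n_ok = 0
    for k in range(50):
        curve = loess_trajectory(data.ages, data.expression[:, k], grid)
        _, _, ratio = period_statistics(grid, curve, data.peak_period)
        n_ok += ratio > 1
    assert n_ok >= 45


def test_cohort_structure_and_zero_noise_limit(geometry, trajectories):
    traj, _ = trajectories
    coh = make_cohort(geometry, traj, n_subjects=100, n_sites=20,
                      subject_sd=0, site_sd=0, noise_sd=0,
                      session_ages=(10.0, 15.0), seed=5)
    assert coh.n_subjects == 100
    counts = np.bincount([int(s[4:]) for s in coh.site])
    assert counts.max() - counts.min() <= 1
    # all subjects equal the population trajectory exactly
    pop10 = traj.slice_map(10.0, 50, "average").values
    assert np.allclose(coh.ct[:, 0, :], pop10[None, :])
    with pytest.raises(ValueError):
        make_cohort(geometry, traj, n_sites=0)
    with pytest.raises(ValueError):
        make_cohort(geometry, traj, session_ages=(10.0,))


def test_cohort_high_noise_attenuates_subject_r2(geometry, trajectories,
                                                 atlases):
    from ctcoloc import subject_change, subject_dominance
    traj, _ = trajectories
    A = atlases.zscored().matrix()
    means = []
    for noise in (0.0, 1.5):
        coh = make_cohort(geometry, traj, n_subjects=10, n_sites=2,
                          subject_sd=0, site_sd=0, noise_sd=noise,
                          session_ages=(10.0, 15.0), seed=6)
        res = subject_dominance(subject_change(coh, ("T0", "T1")), atlases)
        means.append(res.full_model_r2.mean())
    assert means[1] < means[0]
    assert means[1] < 0.15  # heavy noise: little spatial signal explained
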
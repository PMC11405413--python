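"""Subject-level transfer: change maps, dominance, group-mean null test."""

import numpy as np
import pytest

from ctcoloc import (cohort_average_change, group_mean_null_test,
                     make_cohort, subject_change, subject_dominance,
                     total_dominance)


@pytest.fixture(scope="module")
def clean_cohort(geometry, trajectories):
    traj, _ = trajectories
    return make_cohort(geometry, traj, n_subjects=15, n_sites=3,
                       subject_sd=0, site_sd=0, noise_sd=0,
                       session_ages=(10.0, 15.0), seed=11)


def test_zero_noise_subject_change_equals_population(clean_cohort,
                                                     trajectories):
    from ctcoloc import extract_change_series
    traj, _ = trajectories
    pop = extract_change_series(traj, [(10.0, 15.0)])[0]
    changes = subject_change(clean_cohort, ("T0", "T1"))
    assert len(changes) == 15
    for ch in changes.values():
        assert np.allclose(ch.values, pop.values, atol=1e-12)


def test_subject_missing_session_is_excluded(clean_cohort, caplog):
    import dataclasses
    ages = clean_cohort.ages.copy()
    ages[3, 1] = np.nan
    cohort = dataclasses.replace(clean_cohort, ages=ages)
    with caplog.at_level("INFO", logger="ctcoloc.cohort_subject_level"):
        changes = subject_change(cohort, ("T0", "T1"))
    assert len(changes) == 14
    assert cohort.subject_ids[3] not in changes
    assert "1 excluded" in caplog.text


def test_unknown_session_raises(clean_cohort):
    with pytest.raises(ValueError, match="unknown session"):
        subject_change(clean_cohort, ("T0", "T9"))


def test_cohort_average_ratio_nonlinearity(geometry, trajectories):
    """Change of the mean CT differs (slightly) from the mean of subject
    change maps once subjects have heterogeneous baselines."""
    traj, _ = trajectories
    cohort = make_cohort(geometry, traj, n_subjects=30, n_sites=3,
                         subject_sd=0.3, site_sd=0, noise_sd=0,
                         session_ages=(10.0, 15.0), seed=12)
    of_mean, mean_of = cohort_average_change(cohort, ("T0", "T1"))
    diff = np.abs(of_mean.values - mean_of.values)
    assert diff.max() > 0  # not identical ...
    assert np.corrcoef(of_mean.values, mean_of.values)[0, 1] > 0.98


def test_noiseless_cohort_recovers_population_dominance(clean_cohort,
                                                        atlases,
                                                        trajectories):
    from ctcoloc import extract_change_series
    traj, _ = trajectories
    pop = extract_change_series(traj, [(10.0, 15.0)])[0]
    pop_rank = tuple(total_dominance(atlases, pop)
                     .total_dominance.sort_values(ascending=False).index)
    res = subject_dominance(subject_change(clean_cohort, ("T0", "T1")),
                            atlases)
    assert len(res) == 15
    dom_cols = [f"dom_{n}" for n in atlases.names]
    for _, row in res.iterrows():
        rank = tuple(row[dom_cols].sort_values(ascending=False)
                     .index.str.replace("dom_", "", regex=False))
        assert rank == pop_rank


def test_group_mean_test_signal_cohort_minimal_p(clean_cohort, atlases,
                                                 small_nulls):
    changes = subject_change(clean_cohort, ("T0", "T1"))
    out = group_mean_null_test(changes, atlases, small_nulls, n_null=99)
    assert out["p_full"] == pytest.approx(1 / 100)
    assert out["mean_full_model_r2"] == pytest.approx(0.6, abs=0.05)
    top2 = set(out["mean_dominance"].sort_values(ascending=False).index[:2])
    assert top2 == {"atlas1", "atlas2"}


def test_group_mean_test_input_errors(clean_cohort, atlases, small_nulls):
    changes = subject_change(clean_cohort, ("T0", "T1"))
    with pytest.raises(ValueError):
        group_mean_null_test(changes, atlases, small_nulls, n_null=0)
    one = {k: changes[k] for k in list(changes)[:1]}
    with pytest.raises(ValueError, match="two subjects"):
        group_mean_null_test(one, atlases, small_nulls, n_null=10)
    with pytest.raises(ValueError, match="smallest ensemble"):
        group_mean_null_test(changes, atlases, small_nulls, n_null=5000)


def test_attenuation_monotone_in_measurement_noise(geometry, trajectories,
                                                   atlases):
    """Mean subject-level R2 decreases along a measurement-noise ladder."""
    traj, _ = trajectories
    means = []
    for noise in (0.0, 0.1, 0.4):
        r2s = []
        for rep in range(3):
            coh = make_cohort(geometry, traj, n_subjects=8, n_sites=2,
                              subject_sd=0, site_sd=0, noise_sd=noise,
                              session_ages=(10.0, 15.0), seed=40 + rep)
            res = subject_dominance(subject_change(coh, ("T0", "T1")),
                                    atlases)
            r2s.append(res.full_model_r2.mean())
        means.append(np.mean(r2s))
    assert means[0] > means[1] > means[2]
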
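"""Shared fixtures: one synthetic study world reused across the suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctcoloc import (GroundTruth, build_windows, extract_change_series,
                     generate_surrogates, make_atlas_library,
                     make_ct_trajectories, make_parcel_geometry,
                     pairwise_distances)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return make_parcel_geometry(74, seed=0)


@pytest.fixture(scope="session")
def distances(geometry):
    return pairwise_distances(geometry)


@pytest.fixture(scope="session")
def atlases(geometry):
    """Nine intercorrelated GP marker maps."""
    return make_atlas_library(geometry, 9, length_scale=25.0,
                              cross_correlation=0.3, seed=1)


@pytest.fixture(scope="session")
def truth_weights():
    w = np.zeros(9)
    w[0], w[1] = 0.5, 0.3
    return w


@pytest.fixture(scope="session")
def trajectories(geometry, atlases, truth_weights):
    """CT trajectories whose (10,15) change is 0.5*atlas1 + 0.3*atlas2
    plus GP noise at construction R2 = 0.6."""
    traj, realized = make_ct_trajectories(
        geometry, atlases, GroundTruth(truth_weights, construction_r2=0.6,
                                       seed=2), age_drift=0.05)
    return traj, realized


@pytest.fixture(scope="session")
def change_maps(trajectories):
    traj, _ = trajectories
    windows = build_windows(5, 30, 5, 5, extra_windows=[(5, 30)])
    return extract_change_series(traj, windows)


@pytest.fixture(scope="session")
def small_nulls(atlases, distances):
    """100-surrogate ensembles per atlas (test scale)."""
    return {m.name: generate_surrogates(m, distances, 100, seed=100 + i)
            for i, m in enumerate(atlases.maps)}
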
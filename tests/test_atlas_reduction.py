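"""Factor extraction, retention, rotation, naming and permuted validation."""

import subprocess

import numpy as np
import pytest

from ctcoloc import (AtlasSet, fit_factor_model, make_library_from_latents,
                     name_factors, reduce_modality, sample_gp_map,
                     tucker_congruence, validate_against_permuted)
from ctcoloc.atlas_reduction import FactorModelError


@pytest.fixture(scope="module")
def latent_library(geometry):
    """10 maps from 3 latent maps (loading 0.9), factor model exact in
    sample so the retention count is well defined."""
    return make_library_from_latents(geometry, 10, 3, 0.9, 25.0, seed=0,
                                     exact_structure=True)


def test_three_latents_retained_with_high_congruence(latent_library):
    lib, true_loadings = latent_library
    sol = fit_factor_model(lib, retention_threshold=0.01)
    assert sol.n_factors == 3
    cong = tucker_congruence(true_loadings, sol.loadings.to_numpy())
    assert cong.min() >= 0.9


def test_unrotated_proportions_nonincreasing_and_bounded(latent_library):
    lib, _ = latent_library
    sol = fit_factor_model(lib, 0.01)
    props = sol.variance_explained_unrotated
    assert np.all(np.diff(props) <= 1e-9)
    assert props.sum() <= 1.0 + 1e-9
    assert np.min(props) >= 0.01


def test_retained_count_monotone_in_threshold(latent_library):
    lib, _ = latent_library
    ks = [fit_factor_model(lib, th).n_factors
          for th in (0.005, 0.05, 0.20)]
    assert ks[0] >= ks[1] >= ks[2] >= 1


def test_model_reconstruction_identity(latent_library):
    """Pattern, factor correlations and uniquenesses reproduce the
    observed correlation matrix: P Phi P' + diag(psi) ~ R."""
    lib, _ = latent_library
    sol = fit_factor_model(lib, 0.01)
    R = np.corrcoef(lib.matrix(), rowvar=False)
    P = sol.loadings.to_numpy()
    Phi = sol.factor_correlations.to_numpy()
    model = P @ Phi @ P.T + np.diag(sol.uniquenesses)
    assert np.abs(model - R).max() < 0.01
    assert np.allclose(np.diag(Phi), 1.0)
    assert np.allclose(Phi, Phi.T)


def test_scores_are_zscored_and_sign_oriented(latent_library):
    lib, _ = latent_library
    sol = fit_factor_model(lib, 0.01)
    S = sol.scores.matrix()
    assert np.allclose(S.mean(0), 0, atol=1e-9)
    assert np.allclose(S.std(0), 1, atol=1e-9)
    for j, name in enumerate(sol.names):
        col = sol.loadings[name]
        assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0


def test_scores_invariant_to_map_order_up_to_sign(latent_library):
    lib, _ = latent_library
    sol1 = fit_factor_model(lib, 0.01)
    perm = [7, 2, 9, 0, 4, 1, 8, 3, 6, 5]
    lib2 = AtlasSet([lib.maps[i] for i in perm])
    sol2 = fit_factor_model(lib2, 0.01)
    S1, S2 = sol1.scores.matrix(), sol2.scores.matrix()
    C = np.abs(S1.T @ S2) / S1.shape[0]
    # each factor of one solution has a (anti)correlated twin in the other
    assert np.allclose(np.sort(C.max(axis=1)), 1.0, atol=1e-6)


def test_exactly_uncorrelated_maps_have_no_common_factors(geometry):
    lib, _ = make_library_from_latents(geometry, 8, 8, 1.0, None, seed=0,
                                       exact_structure=True)
    R = np.corrcoef(lib.matrix(), rowvar=False)
    assert np.abs(R - np.eye(8)).max() < 1e-12
    with pytest.raises(FactorModelError, match="threshold"):
        fit_factor_model(lib, 0.01)


def test_identical_maps_raise_conditioning_error(geometry):
    m = sample_gp_map(geometry, 25.0, seed=9, name="a")
    dup = AtlasSet([m, m.with_values(m.values, name="b")])
    with pytest.raises(FactorModelError, match="singular"):
        fit_factor_model(dup, 0.01)


def test_factor_naming_and_single_map_passthrough(latent_library, geometry):
    lib, _ = latent_library
    sol = name_factors(fit_factor_model(lib, 0.01), "ni")
    assert sol.names == ["ni1", "ni2", "ni3"]
    assert sorted(sum(sol.assignment.values(), [])) == sorted(lib.names)
    # ties in |loading| go to the lower-index factor (argmax convention)
    tied = np.array([[0.5, 0.5], [0.9, 0.1]])
    assert int(np.argmax(np.abs(tied[0]))) == 0

    single = AtlasSet([sample_gp_map(geometry, 25.0, seed=10, name="t1w")])
    scores, sol2 = reduce_modality(single, prefix="mr")
    assert sol2 is None and scores.names == ["mr1"]
    assert scores.maps[0].standardized


def test_minres_agrees_with_ml_factanal_oracle(latent_library, tmp_path):
    """Independent oracle: R's stats::factanal (maximum likelihood) on the
    same data recovers congruent unrotated loadings."""
    lib, _ = latent_library
    np.savetxt(tmp_path / "x.csv", lib.matrix(), delimiter=",")
    out = tmp_path / "l.csv"
    script = (f'x<-as.matrix(read.csv("{tmp_path}/x.csv",header=FALSE));'
              f'f<-factanal(x,factors=3,rotation="none");'
              f'write.csv(unclass(f$loadings),"{out}",row.names=FALSE)')
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                          text=True)
    assert proc.returncode == 0, proc.stderr
    ml = np.loadtxt(out, delimiter=",", skiprows=1)
    sol = fit_factor_model(lib, 0.01)
    cong = tucker_congruence(sol.unrotated_loadings.to_numpy(), ml)
    assert cong.min() >= 0.95


def test_permuted_validation_structured_library_minimal_p(latent_library):
    lib, _ = latent_library
    out = validate_against_permuted(lib, 99, seed=3)
    assert out["p"] == pytest.approx(1 / 100)
    with pytest.raises(ValueError):
        validate_against_permuted(lib, 0, seed=3)


def test_permuted_validation_null_library_p_uniform(geometry):
    """Libraries of independent white-noise maps: validation p is uniform
    (KS bound from the calibration design)."""
    import scipy.stats
    ps = []
    for run in range(60):
        maps = [sample_gp_map(geometry, 1e-3, seed=9000 + run * 10 + i,
                              name=f"m{i}") for i in range(6)]
        ps.append(validate_against_permuted(AtlasSet(maps), 24,
                                            seed=run)["p"])
    assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01
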
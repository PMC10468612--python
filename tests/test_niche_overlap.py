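import numpy as np
import pytest

import hybridzone as hz
from hybridzone.data_model_io import RasterStack
from hybridzone.niche_overlap import NicheGrid, occupancy_grid
from hybridzone.synthetic_data import LandscapeConfig, simulate_climate_landscape


def _stack(layers, names=None):
    arr = np.asarray(layers, dtype=float)
    names = names or [f"v{i}" for i in range(arr.shape[0])]
    nrows, ncols = arr.shape[1:]
    return RasterStack(names, arr, np.linspace(44, 42, nrows), np.linspace(30, 33, ncols))


def test_select_variables_drops_duplicated_layer():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((8, 9))
    stack = _stack([base, base.copy()], ["a", "b"])
    assert len(hz.select_variables(stack)) == 1


def test_select_variables_drops_one_of_a_correlated_pair():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((20, 20))
    b = a + 0.1 * rng.standard_normal((20, 20))  # r ~ 0.99
    c = rng.standard_normal((20, 20))
    kept = hz.select_variables(_stack([a, b, c], ["a", "b", "c"]))
    assert "c" in kept
    assert len(kept) == 2
    assert len({"a", "b"} & set(kept)) == 1


def test_select_variables_keeps_uncorrelated_set():
    rng = np.random.default_rng(3)
    layers = rng.standard_normal((4, 25, 25))
    stack = _stack(list(layers))
    assert hz.select_variables(stack) == stack.names


def test_pca_env_degenerate_and_isotropic_cases():
    rng = np.random.default_rng(4)
    a = rng.standard_normal((40, 40))
    env, scores = hz.pca_env(_stack([a, 2 * a + 3], ["a", "b"]))
    assert env.variance_explained[0] == pytest.approx(1.0, abs=1e-9)
    # isotropic cloud splits variance evenly
    iso = rng.standard_normal((2, 100, 100))
    env2, scores2 = hz.pca_env(_stack(list(iso)))
    assert env2.variance_explained[0] == pytest.approx(0.5, abs=0.05)
    # the background mean projects to the origin
    import pandas as pd

    mean_row = pd.DataFrame({n: [m] for n, m in zip(env2.variables, env2.mean)})
    np.testing.assert_allclose(env2.transform(mean_row), 0.0, atol=1e-9)


def test_pca_env_rejects_constant_variable():
    rng = np.random.default_rng(5)
    a = rng.standard_normal((10, 10))
    with pytest.raises(ValueError, match="constant"):
        hz.pca_env(_stack([a, np.zeros((10, 10))], ["a", "flat"]))


def _grids_from_points(pts_a, pts_b, bg, R=60):
    ga = occupancy_grid(pts_a, bg, "A", R=R)
    gb = occupancy_grid(pts_b, bg, "B", R=R)
    return ga, gb


def test_occupancy_grid_normalised_and_peaked():
    rng = np.random.default_rng(6)
    bg = rng.uniform(-3, 3, size=(4000, 2))
    occ = np.tile([[1.0, -1.0]], (30, 1)) + 0.01 * rng.standard_normal((30, 2))
    grid = occupancy_grid(occ, bg, "A", R=80)
    assert grid.z.sum() == pytest.approx(1.0, abs=1e-9)
    iy, ix = np.unravel_index(grid.z.argmax(), grid.z.shape)
    xg = np.linspace(grid.extent[0], grid.extent[1], 80)
    yg = np.linspace(grid.extent[2], grid.extent[3], 80)
    assert xg[ix] == pytest.approx(1.0, abs=0.2)
    assert yg[iy] == pytest.approx(-1.0, abs=0.2)


def test_identical_occurrences_give_identical_grids_and_d_one():
    rng = np.random.default_rng(7)
    bg = rng.uniform(-3, 3, size=(3000, 2))
    occ = rng.standard_normal((40, 2))
    ga, gb = _grids_from_points(occ, occ.copy(), bg)
    np.testing.assert_array_equal(ga.z, gb.z)
    assert hz.schoeners_d(ga, gb) == pytest.approx(1.0, abs=1e-12)


def test_schoeners_d_hand_examples_and_symmetry():
    extent = (0.0, 1.0, 0.0, 1.0)
    bg = np.ones((1, 3))
    z1 = NicheGrid("a", np.array([[0.5, 0.5, 0.0]]), bg, extent)
    z2 = NicheGrid("b", np.array([[0.0, 0.5, 0.5]]), bg, extent)
    z3 = NicheGrid("c", np.array([[0.0, 0.0, 1.0]]), bg, extent)
    assert hz.schoeners_d(z1, z2) == pytest.approx(0.5, abs=1e-12)
    assert hz.schoeners_d(z1, z1) == 1.0
    assert hz.schoeners_d(NicheGrid("d", np.array([[1.0, 0.0, 0.0]]), bg, extent),
                          z3) == 0.0
    assert hz.schoeners_d(z1, z2) == hz.schoeners_d(z2, z1)
    with pytest.raises(ValueError, match="aligned"):
        hz.schoeners_d(z1, NicheGrid("e", np.ones((2, 2)) / 4, np.ones((2, 2)),
                                     (0, 1, 0, 1)))


def test_schoeners_d_invariant_under_shared_cell_permutation():
    rng = np.random.default_rng(8)
    z1 = rng.uniform(size=(10, 10))
    z1 /= z1.sum()
    z2 = rng.uniform(size=(10, 10))
    z2 /= z2.sum()
    extent = (0.0, 1.0, 0.0, 1.0)
    bg = np.ones((10, 10))
    d0 = hz.schoeners_d(NicheGrid("a", z1, bg, extent), NicheGrid("b", z2, bg, extent))
    perm = rng.permutation(100)
    z1p = z1.ravel()[perm].reshape(10, 10)
    z2p = z2.ravel()[perm].reshape(10, 10)
    d1 = hz.schoeners_d(NicheGrid("a", z1p, bg, extent), NicheGrid("b", z2p, bg, extent))
    assert d0 == pytest.approx(d1, abs=1e-12)


def test_similarity_test_identical_species_at_floor_and_reproducible():
    rng = np.random.default_rng(9)
    bg = rng.uniform(-3, 3, size=(3000, 2))
    occ = 0.3 * rng.standard_normal((40, 2))
    ga, gb = _grids_from_points(occ, occ.copy(), bg)
    p1 = hz.similarity_test(ga, gb, n_reps=99, seed=5)
    p2 = hz.similarity_test(ga, gb, n_reps=99, seed=5)
    assert p1 == p2
    assert p1 <= 0.05  # observed D = 1 is (near) maximal


def test_similarity_test_null_calibration():
    """Unrelated compact niches at random positions: p-values spread over
    (0, 1] rather than piling up at the floor (the null itself relocates
    niches, so niches that ARE random relocations give dispersed p)."""
    rng = np.random.default_rng(10)
    bg = rng.uniform(-3, 3, size=(2000, 2))
    pvals = []
    for rep in range(10):
        ca, cb = rng.uniform(-2, 2, size=(2, 2))
        occ_a = ca + 0.5 * rng.standard_normal((30, 2))
        occ_b = cb + 0.5 * rng.standard_normal((30, 2))
        ga, gb = _grids_from_points(occ_a, occ_b, bg)
        pvals.append(hz.similarity_test(ga, gb, n_reps=99, seed=rep))
    pvals = np.array(pvals)
    assert pvals.max() - pvals.min() > 0.3
    assert 0.1 < pvals.mean() < 0.9
    assert (pvals <= 0.01).mean() <= 0.6


def test_project_shared_suitability_categories():
    cfg = LandscapeConfig(seed=13, niche_center_a=0.0, niche_center_b=0.0,
                          n_occurrences=60)
    stack, occ_a, occ_b = simulate_climate_landscape(cfg)
    env, bg = hz.pca_env(stack)
    sa = hz.env_scores_of_occurrences(stack, env, occ_a)
    sb = hz.env_scores_of_occurrences(stack, env, occ_b)
    ga = occupancy_grid(sa, bg, "A")
    gb = occupancy_grid(sb, bg, "B")
    cats = hz.project_shared_suitability(ga, gb, stack, env)
    assert set(np.unique(cats)) <= {-1, 0, 1, 2, 3}
    # same niche: overlap should dominate single-species cells
    n_both = (cats == 3).sum()
    n_single = ((cats == 1) | (cats == 2)).sum()
    assert n_both > n_single


def test_project_disjoint_niches_have_no_shared_cells():
    cfg = LandscapeConfig(seed=14, niche_center_a=-3.0, niche_center_b=3.0,
                          niche_sd=0.5, n_occurrences=60)
    stack, occ_a, occ_b = simulate_climate_landscape(cfg)
    env, bg = hz.pca_env(stack)
    ga = occupancy_grid(hz.env_scores_of_occurrences(stack, env, occ_a), bg, "A")
    gb = occupancy_grid(hz.env_scores_of_occurrences(stack, env, occ_b), bg, "B")
    cats = hz.project_shared_suitability(ga, gb, stack, env)
    assert (cats == 3).sum() == 0


def test_resolution_robustness_of_d():
    rng = np.random.default_rng(15)
    bg = rng.uniform(-3, 3, size=(4000, 2))
    occ_a = rng.standard_normal((60, 2))
    occ_b = rng.standard_normal((60, 2)) + 0.7
    d_100 = hz.schoeners_d(*_grids_from_points(occ_a, occ_b, bg, R=100))
    d_200 = hz.schoeners_d(*_grids_from_points(occ_a, occ_b, bg, R=200))
    assert abs(d_100 - d_200) < 0.02
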
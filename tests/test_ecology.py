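import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from rivertide import ecology as eco
from rivertide.core_io import AbundanceMatrix, ValidationError


def tmm_matrix(values):
    values = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        genome_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        state="tmm",
        norm_factors=np.ones(values.shape[1]),
        library_sizes=np.ones(values.shape[1]),
    )


def euclidean_dm(points):
    points = np.asarray(points, dtype=float)
    return eco.DistanceMatrix(
        [f"s{i}" for i in range(len(points))], squareform(pdist(points))
    )


# ---------------------------------------------------------------------------
# diversity


def test_shannon_uniform_closed_form():
    mat = tmm_matrix(np.ones((100, 1)))
    richness, h = eco.diversity(mat, "s0")
    assert richness == 100
    assert h == pytest.approx(math.log(100), abs=1e-12)


def test_shannon_degenerate_and_example():
    single = tmm_matrix(np.array([[5.0]]))
    assert eco.diversity(single, "s0") == (1, 0.0)
    mat = tmm_matrix(np.array([[0.5], [0.25], [0.25]]))
    _, h = eco.diversity(mat, "s0")
    assert h == pytest.approx(1.039721, abs=1e-6)
    with pytest.raises(ValidationError):
        eco.diversity(tmm_matrix(np.zeros((3, 1))), "s0")


# ---------------------------------------------------------------------------
# Bray-Curtis matrix


def test_bray_curtis_excludes_sparse_genomes():
    vals = np.zeros((2, 5))
    vals[0] = [1, 1, 1, 0, 0]  # present in exactly 3 samples: excluded
    vals[1] = [1, 2, 3, 4, 5]
    d = eco.bray_curtis_matrix(tmm_matrix(vals))
    # distances must come from genome 1 alone
    expected = abs(vals[1][:, None] - vals[1][None, :]) / (vals[1][:, None] + vals[1][None, :])
    np.testing.assert_allclose(d.values, expected, atol=1e-12)


def test_bray_curtis_matches_double_loop():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(1, 0.6, size=(12, 5))
    d = eco.bray_curtis_matrix(tmm_matrix(vals))
    for i in range(5):
        for j in range(5):
            expect = np.abs(vals[:, i] - vals[:, j]).sum() / (vals[:, i] + vals[:, j]).sum()
            assert d.values[i, j] == pytest.approx(expect, abs=1e-12)
    assert d.values.max() <= 1.0 and d.values.min() >= 0.0


def test_duplicate_samples_have_zero_distance():
    rng = np.random.default_rng(1)
    col = rng.lognormal(1, 0.5, size=10)
    vals = np.column_stack([col, col, rng.lognormal(1, 0.5, size=10),
                            rng.lognormal(1, 0.5, size=10), rng.lognormal(1, 0.5, size=10)])
    d = eco.bray_curtis_matrix(tmm_matrix(vals))
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# NMDS


def test_nmds_recovers_planted_plane():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(14, 2))
    d = euclidean_dm(pts)
    res = eco.nmds(d, seed=0, n_restarts=8)
    assert res.stress < 0.01
    _, corr = eco.procrustes_test(res.coords, pts, n_perm=49, seed=0)
    assert corr > 0.99


def test_nmds_invariant_to_distance_scaling():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(10, 2))
    d1 = euclidean_dm(pts)
    d5 = eco.DistanceMatrix(d1.sample_ids, 5.0 * d1.values)
    r1 = eco.nmds(d1, seed=3, n_restarts=5)
    r5 = eco.nmds(d5, seed=3, n_restarts=5)
    assert r1.stress == pytest.approx(r5.stress, abs=1e-6)
    _, corr = eco.procrustes_test(r1.coords, r5.coords, n_perm=49, seed=0)
    assert corr > 0.999999


def test_nmds_deterministic_under_seed():
    rng = np.random.default_rng(6)
    vals = rng.lognormal(0, 1, size=(20, 8))
    d = eco.bray_curtis_matrix(tmm_matrix(vals))
    a = eco.nmds(d, seed=11, n_restarts=5)
    b = eco.nmds(d, seed=11, n_restarts=5)
    np.testing.assert_array_equal(a.coords, b.coords)


# ---------------------------------------------------------------------------
# PERMANOVA


def test_permanova_exhaustive_small_n():
    """n=6, two groups of 3: permutation p equals exhaustive enumeration."""
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(6, 3))
    pts[:3] += 1.2
    d = euclidean_dm(pts)
    groups = np.array(["a"] * 3 + ["b"] * 3)
    d2 = d.values**2
    f_obs, _ = eco._permanova_f(d2, groups)
    # enumerate all 20 distinct labelings
    count = total = 0
    for combo in itertools.combinations(range(6), 3):
        lab = np.array(["b"] * 6, dtype=object)
        lab[list(combo)] = "a"
        f, _ = eco._permanova_f(d2, lab)
        total += 1
        count += f >= f_obs - 1e-12
    p_exact = count / total
    test = eco.permanova(d, groups, n_perm=9999, seed=0)
    assert test.p == pytest.approx(p_exact, abs=0.02)


def test_permanova_separated_clouds():
    rng = np.random.default_rng(8)
    pts = np.vstack([rng.normal(0, 0.1, size=(8, 2)), rng.normal(20, 0.1, size=(8, 2))])
    d = euclidean_dm(pts)
    groups = ["a"] * 8 + ["b"] * 8
    test = eco.permanova(d, groups, n_perm=999, seed=0)
    assert test.p == pytest.approx(1 / 1000)
    assert eco.permanova_r2(d, groups) > 0.9


def test_permanova_matches_skbio():
    """Cross-check the pseudo-F against the independent scikit-bio oracle."""
    from skbio.stats.distance import DistanceMatrix as SkbioDM
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(9)
    pts = rng.normal(size=(12, 4))
    pts[:6] += 0.8
    d = euclidean_dm(pts)
    groups = ["a"] * 6 + ["b"] * 6
    ours = eco.permanova(d, groups, n_perm=99, seed=0)
    theirs = skbio_permanova(SkbioDM(d.values, ids=d.sample_ids), groups, permutations=99)
    assert ours.value == pytest.approx(float(theirs["test statistic"]), rel=1e-10)


def test_permanova_sequential_time_term():
    rng = np.random.default_rng(10)
    t = np.tile(np.arange(8.0), 2)
    pts = np.column_stack([t * 0.5 + rng.normal(0, 0.3, 16), rng.normal(0, 0.3, 16)])
    pts[:8, 1] += 4.0
    d = euclidean_dm(pts)
    groups = ["a"] * 8 + ["b"] * 8
    r2_comp, r2_time = eco.permanova_sequential(d, groups, t)
    assert 0 < r2_comp < 1 and 0 < r2_time < 1
    assert r2_comp + r2_time <= 1.0 + 1e-9
    assert r2_time > 0.2  # time genuinely structures these data


def test_permanova_rejects_singleton_group():
    d = euclidean_dm(np.random.default_rng(0).normal(size=(5, 2)))
    with pytest.raises(ValidationError):
        eco.permanova(d, ["a", "b", "b", "b", "b"], n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# envfit


def _ordination(points):
    pts = np.asarray(points, dtype=float)
    return eco.OrdinationResult([f"s{i}" for i in range(len(pts))], pts, 0.0, 1, True)


def test_envfit_perfect_alignment():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(12, 2))
    ordi = _ordination(pts)
    variables = pd.DataFrame({"v": pts[:, 0]}, index=ordi.sample_ids)
    out = eco.envfit_vectors(ordi, variables, n_perm=99, seed=0)
    row = out.iloc[0]
    assert row["r2"] == pytest.approx(1.0, abs=1e-12)
    assert abs(row["dir1"]) == pytest.approx(1.0, abs=1e-9)
    assert abs(row["dir2"]) == pytest.approx(0.0, abs=1e-9)


def test_envfit_r2_matches_normal_equations():
    rng = np.random.default_rng(12)
    pts = rng.normal(size=(15, 2))
    y = rng.normal(size=15)
    ordi = _ordination(pts)
    out = eco.envfit_vectors(ordi, pd.DataFrame({"v": y}, index=ordi.sample_ids),
                             n_perm=9, seed=0)
    x = pts - pts.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.solve(x.T @ x, x.T @ yc)
    r2 = 1 - ((yc - x @ beta) ** 2).sum() / (yc**2).sum()
    assert out.iloc[0]["r2"] == pytest.approx(r2, abs=1e-10)


def test_envfit_skips_constant_variable():
    rng = np.random.default_rng(13)
    ordi = _ordination(rng.normal(size=(10, 2)))
    out = eco.envfit_vectors(ordi, pd.DataFrame({"c": np.ones(10)}, index=ordi.sample_ids),
                             n_perm=9, seed=0)
    assert bool(out.iloc[0]["skipped"])


# ---------------------------------------------------------------------------
# Procrustes


def test_procrustes_congruent_configurations():
    rng = np.random.default_rng(14)
    a = rng.normal(size=(10, 2))
    theta = 1.1
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    b = 3.7 * a @ rot + 2.0
    test, corr = eco.procrustes_test(a, b, n_perm=99, seed=0)
    assert test.value < 1e-10
    assert corr > 0.999999


def test_procrustes_identity_m2_plus_corr2():
    rng = np.random.default_rng(15)
    for _ in range(5):
        a, b = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        test, corr = eco.procrustes_test(a, b, n_perm=9, seed=0)
        assert test.value + corr**2 == pytest.approx(1.0, abs=1e-12)


def test_procrustes_m2_matches_scipy():
    from scipy.spatial import procrustes as scipy_procrustes

    rng = np.random.default_rng(16)
    a, b = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
    test, _ = eco.procrustes_test(a, b, n_perm=9, seed=0)
    _, _, m2 = scipy_procrustes(a, b)
    assert test.value == pytest.approx(m2, abs=1e-10)


# ---------------------------------------------------------------------------
# species accumulation, ANOSIM, PCA


def test_specaccum_saturated_community():
    present = np.ones((25, 6), dtype=bool)
    out = eco.species_accumulation(present, n_perm=20, seed=0)
    np.testing.assert_allclose(out["mean_richness"], 25.0)
    np.testing.assert_allclose(out["exact"], 25.0)


def test_specaccum_final_point_is_total_richness():
    rng = np.random.default_rng(17)
    present = rng.random((40, 8)) < 0.4
    present[:, 0] |= ~present.any(axis=1)  # every genome seen somewhere
    out = eco.species_accumulation(present, n_perm=30, seed=1)
    assert out["mean_richness"].iloc[-1] == pytest.approx(40.0)
    assert out["exact"].iloc[-1] == pytest.approx(40.0)


def test_specaccum_permutation_mean_matches_rarefaction():
    rng = np.random.default_rng(18)
    present = rng.random((60, 10)) < 0.3
    n_perm = 400
    out = eco.species_accumulation(present, n_perm=n_perm, seed=2)
    se = out["sd"] / math.sqrt(n_perm)
    assert (np.abs(out["mean_richness"] - out["exact"]) <= 2.5 * se + 0.3).all()


def test_anosim_separates_groups():
    rng = np.random.default_rng(19)
    pts = np.vstack([rng.normal(0, 0.2, size=(7, 2)), rng.normal(5, 0.2, size=(7, 2))])
    d = euclidean_dm(pts)
    res = eco.anosim(d, ["a"] * 7 + ["b"] * 7, n_perm=199, seed=0)
    assert res.value > 0.9
    # complementary relabelings reproduce the same partition, so the attainable
    # floor is slightly above 1/(n_perm+1)
    assert res.p <= 0.02


def test_pca_orients_by_variance():
    rng = np.random.default_rng(20)
    x = pd.DataFrame(
        {"big": rng.normal(0, 5, 30), "small": rng.normal(0, 1, 30)},
        index=[f"s{i}" for i in range(30)],
    )
    res = eco.pca(x)
    assert res.coords.shape == (30, 2)
    assert res.coords[:, 0].var() >= res.coords[:, 1].var()
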
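import numpy as np
import pytest
from scipy import stats

from erodescan import (
    dosage_matrix,
    dunn_posthoc,
    kruskal_wallis,
    pca,
    standardized_grm,
)

from conftest import make_matrix


def grm_double_loop(dosage):
    """Direct per-pair, per-site recomputation of the standardized GRM."""
    d = np.asarray(dosage, dtype=float)
    p = d.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    d, p = d[:, keep], p[keep]
    n, m = d.shape
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for s in range(m):
                zi = (d[i, s] - 2 * p[s]) / np.sqrt(2 * p[s] * (1 - p[s]))
                zj = (d[j, s] - 2 * p[s]) / np.sqrt(2 * p[s] * (1 - p[s]))
                acc += zi * zj
            g[i, j] = acc / m
    return g


class TestGrm:
    def test_identical_individuals_have_identical_rows(self):
        dosage = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 0, 1]])
        g = standardized_grm(dosage)
        np.testing.assert_allclose(g[0], g[1])

    def test_symmetric_with_unit_mean_diagonal_under_hwe(self, rng):
        p = rng.uniform(0.1, 0.9, size=4_000)
        dosage = rng.binomial(2, p, size=(30, 4_000))
        g = standardized_grm(dosage)
        np.testing.assert_allclose(g, g.T)
        assert np.mean(np.diag(g)) == pytest.approx(1.0, abs=0.05)

    def test_matches_double_loop_oracle_on_toy_matrix(self, rng):
        dosage = rng.integers(0, 3, size=(5, 8))
        np.testing.assert_allclose(standardized_grm(dosage),
                                   grm_double_loop(dosage), atol=1e-12)

    def test_monomorphic_sites_are_dropped(self):
        dosage = np.array([[0, 2, 0], [0, 0, 0], [0, 1, 0]])
        g = standardized_grm(dosage)  # only the middle site is informative
        assert g.shape == (3, 3)
        with pytest.raises(ValueError):
            standardized_grm(np.zeros((3, 2)))


class TestPca:
    def test_duplicated_individuals_get_identical_coordinates(self, rng):
        dosage = rng.integers(0, 3, size=(6, 50))
        dosage[1] = dosage[0]
        res = pca(standardized_grm(dosage), k=3)
        np.testing.assert_allclose(res.coordinates.iloc[0],
                                   res.coordinates.iloc[1], atol=1e-8)

    def test_eigenpairs_match_dense_solver_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=(10, 10))
            g = a @ a.T / 10
            res = pca(g, k=4)
            vals = np.sort(np.linalg.eigvalsh(g))[::-1]
            recon = (res.coordinates.to_numpy() ** 2).sum(axis=0)
            np.testing.assert_allclose(recon, vals[:4], rtol=1e-8)
            np.testing.assert_allclose(res.variance_fraction,
                                       vals[:4] / vals[vals > 1e-12].sum())

    def test_variance_fractions_sorted_and_normalized(self, rng):
        a = rng.normal(size=(8, 20))
        res = pca(a @ a.T, k=8)
        frac = res.variance_fraction
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() == pytest.approx(1.0)

    def test_planted_population_divergence_separates_on_axis_one(self):
        from erodescan import GenomeLayout
        from erodescan.simulate import PopulationSim, SimConfig, simulate_population
        hits = 0
        for seed in range(20):
            lay = GenomeLayout(scaffolds=(("s", 2_000_000),))
            cfg = SimConfig(layout=lay, populations=[
                PopulationSim("a", 8, theta_bg=0.1),
                PopulationSim("b", 8, theta_bg=0.1)],
                snp_spacing_bp=1_000, n_structure_sites=800,
                structure_fst=0.15, seed=seed)
            matrix, _, _, _ = simulate_population(cfg)
            res = pca(standardized_grm(dosage_matrix(matrix)), k=2,
                      samples=matrix.samples)
            pc1 = res.coordinates["PC1"].to_numpy()
            a, b = pc1[:8], pc1[8:]
            gap = abs(a.mean() - b.mean())
            spread = a.std() + b.std()
            if gap > spread:  # crude silhouette: between > within
                hits += 1
        assert hits >= 19


class TestKruskalWallis:
    def test_worked_example_two_groups(self):
        res = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert res.h_statistic == pytest.approx(3.857, abs=1e-3)
        assert res.df == 1

    def test_identical_values_give_h_zero_p_one(self):
        res = kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert res.h_statistic == 0.0 and res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0]), np.array([])])

    def test_null_rejection_rate_is_nominal(self, rng):
        n_rep, alpha = 2_000, 0.05
        rejections = 0
        for _ in range(n_rep):
            g = rng.normal(size=(3, 10))
            if kruskal_wallis(list(g)).p_value < alpha:
                rejections += 1
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07  # wider band than acceptance (fewer reps)


class TestDunn:
    def test_identical_groups_give_z_zero_p_one(self):
        df = dunn_posthoc([np.array([1.0, 2.0, 3.0]),
                           np.array([1.0, 2.0, 3.0])])
        assert df["z"].iloc[0] == pytest.approx(0.0)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_z_matches_direct_rank_formula(self, rng):
        for _ in range(20):
            sizes = rng.integers(3, 12, size=3)
            groups = [np.round(rng.normal(size=s), 1) for s in sizes]  # ties
            df = dunn_posthoc(groups, labels=["a", "b", "c"])
            pooled = np.concatenate(groups)
            ranks = stats.rankdata(pooled)
            n = pooled.size
            _, counts = np.unique(pooled, return_counts=True)
            tie = (counts ** 3 - counts).sum() / (12 * (n - 1))
            bounds = np.cumsum([0] + [len(g) for g in groups])
            means = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(3)]
            expected_ab = (means[0] - means[1]) / np.sqrt(
                (n * (n + 1) / 12 - tie) * (1 / sizes[0] + 1 / sizes[1]))
            got = df.set_index(["group1", "group2"]).loc[("a", "b"), "z"]
            assert got == pytest.approx(expected_ab, rel=1e-10)

    def test_adjusted_p_monotone_in_raw_p(self, rng):
        groups = [rng.normal(loc=i * 0.5, size=12) for i in range(4)]
        for method in ("holm", "bonferroni"):
            df = dunn_posthoc(groups, adjustment=method).sort_values("p")
            assert (df["p_adj"] >= df["p"] - 1e-15).all()
            assert np.all(np.diff(df["p_adj"]) >= -1e-12)

    def test_bonferroni_vs_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        groups = [rng.normal(loc=i, size=8) for i in range(3)]
        df = dunn_posthoc(groups, adjustment="holm")
        _, expected, _, _ = multipletests(df["p"], method="holm")
        np.testing.assert_allclose(df["p_adj"], expected)
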
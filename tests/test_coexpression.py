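"""Co-expression stack: adjacency/TOM closed forms, module detection on
block fixtures and planted data, eigengene and kME properties, and
module-trait statistics against an independent t-distribution route."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

import sncausal as sc
from sncausal import coexpression as cx


class TestSignedAdjacency:
    def test_closed_forms(self):
        # two perfectly correlated genes, two anti-correlated
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = np.vstack([x, x, -x])
        adj, kept = cx.signed_adjacency(expr, power=6)
        assert adj[0, 1] == pytest.approx(1.0)        # cor +1 -> a = 1
        assert adj[0, 2] == pytest.approx(0.0)        # cor -1 -> a = 0
        assert len(kept) == 3

    def test_zero_correlation_maps_to_half_power(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(2, 100000))
        adj, _ = cx.signed_adjacency(expr, power=6)
        assert adj[0, 1] == pytest.approx(0.5 ** 6, abs=0.002)

    def test_constant_gene_dropped_with_warning(self):
        expr = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [3.0, 1.0, 2.0]])
        with pytest.warns(UserWarning, match="constant"):
            adj, kept = cx.signed_adjacency(expr, power=2)
        assert list(kept) == [0, 2]


class TestTomSimilarity:
    def test_fully_connected_closed_form(self):
        a = np.ones((3, 3))
        tom = cx.tom_similarity(a)
        # (1 + 1) / (2 + 1 - 1) = 1 for every off-diagonal pair
        np.testing.assert_allclose(tom, 1.0)

    def test_empty_adjacency(self):
        tom = cx.tom_similarity(np.eye(4))
        off = tom[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(tom), 1.0)

    def test_symmetric_and_bounded_on_random_input(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.tom_similarity(a)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12

    def test_monotone_in_adjacency(self):
        """Raising one a_ij weakly raises TOM_ij on random 5-gene fixtures."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.uniform(0, 0.8, size=(5, 5))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            i, j = 1, 3
            t0 = cx.tom_similarity(a)[i, j]
            a2 = a.copy()
            a2[i, j] = a2[j, i] = a[i, j] + 0.1
            t1 = cx.tom_similarity(a2)[i, j]
            assert t1 >= t0 - 1e-12


class TestPowerSelection:
    def test_first_power_reaching_cut_wins(self):
        diag = pd.DataFrame({
            "power": [4, 6, 8], "signed_r2": [0.5, 0.85, 0.9],
            "slope": [-1, -1, -1], "mean_connectivity": [30, 10, 5],
        })
        assert cx.select_power(diag) == 6

    def test_fallback_to_best_fit(self):
        diag = pd.DataFrame({
            "power": [4, 8, 12], "signed_r2": [0.3, 0.5, 0.7],
            "slope": [-1, -1, -1], "mean_connectivity": [30, 10, 5],
        })
        assert cx.select_power(diag) == 12

    def test_near_empty_networks_excluded(self):
        # spuriously good fit at a power that destroys connectivity
        diag = pd.DataFrame({
            "power": [4, 8, 20], "signed_r2": [0.3, 0.5, 0.95],
            "slope": [-1, -1, -1], "mean_connectivity": [30, 10, 0.05],
        })
        assert cx.select_power(diag) == 8


class TestDetectModules:
    def test_two_block_fixture(self):
        n = 100
        tom = np.full((n, n), 0.05)
        tom[:50, :50] = 0.9
        tom[50:, 50:] = 0.9
        np.fill_diagonal(tom, 1.0)
        rng = np.random.default_rng(0)
        expr = np.zeros((n, 30))
        f1, f2 = rng.normal(size=(2, 30))
        expr[:50] = f1 + 0.1 * rng.normal(size=(50, 30))
        expr[50:] = f2 + 0.1 * rng.normal(size=(50, 30))
        # the blocks join at dissimilarity 0.95, so the cut must sit
        # between the within-block (0.1) and between-block heights
        labels, _ = cx.detect_modules(
            tom, expr, min_module_size=30, cut_height=0.9
        )
        assert labels.max() == 2
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[60]

    def test_degenerate_identical_tom_is_single_module(self):
        n = 40
        tom = np.full((n, n), 0.8)
        np.fill_diagonal(tom, 1.0)
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(n, 20))
        labels, _ = cx.detect_modules(tom, expr, min_module_size=30)
        assert set(labels) == {1}

    def test_too_few_genes_all_grey(self):
        with pytest.warns(UserWarning):
            labels, _ = cx.detect_modules(
                np.eye(5), np.random.default_rng(0).normal(size=(5, 10)),
                min_module_size=30,
            )
        assert (labels == 0).all()


class TestEigengene:
    def test_rank_one_module_recovers_member_profile(self):
        rng = np.random.default_rng(2)
        profile = rng.normal(size=50)
        expr = np.vstack([2 * profile, -3 * profile, 0.5 * profile])
        e = cx.module_eigengene(expr)
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(e, z)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_mean_member_kme_nonnegative(self):
        rng = np.random.default_rng(3)
        expr = rng.normal(size=(10, 40)) + rng.normal(size=40)
        e = cx.module_eigengene(expr)
        kmes = cx.kme(expr, e[None, :]).ravel()
        assert kmes.mean() >= 0

    def test_explains_at_least_any_single_member(self):
        """PC1 captures at least as much standardized variance as the best
        single member gene does."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            expr = rng.normal(size=(6, 50)) + 0.5 * rng.normal(size=50)
            z = (expr - expr.mean(1, keepdims=True)) / expr.std(1, keepdims=True)
            e = cx.module_eigengene(expr)

            def explained(v):
                c = np.array([np.corrcoef(v, g)[0, 1] ** 2 for g in z])
                return c.sum()

            assert explained(e) >= max(explained(g) for g in z) - 1e-9

    def test_rank_zero_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            e = cx.module_eigengene(np.ones((3, 10)))
        assert (e == 0).all()


class TestKme:
    def test_bounds_and_constant_gene_flagged_zero(self):
        rng = np.random.default_rng(5)
        expr = np.vstack([rng.normal(size=30), np.full(30, 2.0)])
        eig = rng.normal(size=(1, 30))
        k = cx.kme(expr, eig)
        assert np.abs(k).max() <= 1.0
        assert k[1, 0] == 0.0

    def test_independent_gene_has_small_kme(self):
        rng = np.random.default_rng(6)
        n = 2000
        factor = rng.normal(size=n)
        expr = np.vstack([factor + 0.1 * rng.normal(size=n),
                          rng.normal(size=n)])
        k = cx.kme(expr, factor[None, :])
        assert abs(k[0, 0]) > 0.9
        assert abs(k[1, 0]) < 0.1


class TestModuleTraitCorrelation:
    def test_closed_form_example(self):
        """n=20, r=0.5 -> t = 2.4495, two-sided p = 0.0248."""
        p = cx.student_correlation_p(0.5, 20)
        assert p == pytest.approx(0.0248, abs=2e-4)

    def test_extremes(self):
        assert cx.student_correlation_p(0.0, 30) == pytest.approx(1.0)
        assert cx.student_correlation_p(1.0, 30) == 0.0

    def test_matches_t_distribution_on_grid(self):
        """Incomplete-beta route equals the reference t CDF to 1e-10."""
        for n in (5, 10, 20, 50, 200):
            for r in (-0.9, -0.5, -0.1, 0.05, 0.3, 0.7, 0.99):
                t = r * np.sqrt((n - 2) / (1 - r * r))
                ref = 2 * sps.t.sf(abs(t), n - 2)
                assert cx.student_correlation_p(r, n) == pytest.approx(
                    ref, abs=1e-10
                )

    def test_constant_trait_flagged(self):
        rng = np.random.default_rng(8)
        eig = pd.DataFrame(rng.normal(size=(1, 10)), index=["ME1"])
        traits = pd.DataFrame({"flat": np.ones(10), "ok": rng.normal(size=10)})
        out = cx.module_trait_correlation(eig, traits)
        flat = out[out.trait == "flat"].iloc[0]
        assert flat.r == 0 and flat.p == 1 and flat.degenerate


class TestModuleDegEnrichment:
    def test_disjoint_module_p_is_one(self):
        labels = np.array([1, 1, 0, 0])
        genes = pd.Index(["a", "b", "c", "d"])
        out = sc.module_deg_enrichment(labels, genes, {"c"}, set(genes))
        assert out.p.iloc[0] == 1.0

    def test_nested_module_matches_closed_form(self):
        labels = np.array([1] * 3 + [0] * 7)
        genes = pd.Index([f"g{i}" for i in range(10)])
        degs = {"g0", "g1", "g2", "g3"}
        out = sc.module_deg_enrichment(labels, genes, degs, set(genes))
        # P(X >= 3), X ~ Hypergeom(10, 3, 4) = C(4,3)C(6,0)/C(10,3)
        assert out.p.iloc[0] == pytest.approx(4 / 120)

    def test_grey_module_excluded(self):
        labels = np.zeros(10, int)
        genes = pd.Index([f"g{i}" for i in range(10)])
        out = sc.module_deg_enrichment(labels, genes, {"g0"}, set(genes))
        assert out.empty


class TestPlantedRecovery:
    @pytest.fixture(scope="class")
    def planted(self):
        d = sc.SyntheticDesign(
            n_genes=400, cell_types={"A": 250}, n_modules=4, module_size=50,
            dag_genes=0, n_deg=0, n_cag_genes=0, rescue_frac=0, seed=11,
        )
        counts, meta, truth = sc.generate_dataset(d)
        norm = sc.log_normalize(counts)
        kept = sc.filter_genes_min_frac(counts)
        nf = norm.subset_genes(kept)
        est = sc.CoexpressionModules(random_state=0).fit(
            nf.values.T, feature_names=nf.genes
        )
        return est, truth, nf

    def test_adjusted_rand_index(self, planted):
        est, truth, nf = planted
        idx = truth.genes.get_indexer(nf.genes)
        ari = adjusted_rand_score(truth.module_labels[idx], est.labels_)
        assert ari >= 0.8

    def test_mean_member_kme(self, planted):
        est, _, _ = planted
        for m in np.unique(est.labels_):
            if m == 0:
                continue
            assert est.kme_.loc[est.labels_ == m, f"ME{m}"].mean() >= 0.6

    def test_sklearn_params_roundtrip(self, planted):
        est, _, _ = planted
        params = est.get_params()
        clone = sc.CoexpressionModules(**params)
        assert clone.get_params() == params
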
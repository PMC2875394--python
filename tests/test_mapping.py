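"""Trait mapping: admixture-mapping regression, kinship, mixed model, and
Bonferroni correction."""

import numpy as np
import pytest
from scipy import stats

from paddymix.admixture import AdmixtureFit
from paddymix.ancestry import LocalAncestry
from paddymix.mapping import (
    KinshipMatrix,
    PhenotypeTable,
    admixture_map,
    bonferroni,
    kinship_matrix,
    mixed_model_assoc,
    read_phenotype_tsv,
    reml_neg_loglik,
)
from paddymix.tree import allele_sharing_distance

from conftest import build_panel


def local_from_component(X, pop_names=("d0", "d1")):
    """LocalAncestry whose donor-1 component track is X (n x L)."""
    n, L = X.shape
    post = np.zeros((n, L, 2))
    post[:, :, 1] = X
    post[:, :, 0] = 1 - X
    fit = AdmixtureFit(
        K=2, Q=np.full((n, 2), 0.5), P=np.full((2, L), 0.5),
        loglik=0.0, n_iter=0, restart_index=0,
    )
    return LocalAncestry(posterior=post, switch_rate=1e-8, source_fit=fit)


def pheno_from_vector(ids, y, trait="t"):
    return PhenotypeTable(trait=trait, values=dict(zip(ids, map(float, y))))


class TestAdmixtureMap:
    def test_matches_scipy_linregress(self, rng):
        n, L = 40, 6
        X = rng.uniform(0, 1, (n, L))
        y = rng.standard_normal(n)
        panel = build_panel(rng.integers(0, 2, (n, L)).astype(np.int8))
        local = local_from_component(X)
        res = admixture_map(
            local, panel, pheno_from_vector(panel.accession_ids, y),
            panel.accession_ids, "d1", pop_names=["d0", "d1"],
        )
        for j in range(L):
            ref = stats.linregress(X[:, j], y)
            assert res.effect[j] == pytest.approx(ref.slope, abs=1e-10)
            assert res.p_value[j] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_component_is_na(self, rng):
        n = 20
        X = rng.uniform(0, 1, (n, 3))
        X[:, 1] = 0.4
        panel = build_panel(rng.integers(0, 2, (n, 3)).astype(np.int8))
        res = admixture_map(
            local_from_component(X), panel,
            pheno_from_vector(panel.accession_ids, rng.standard_normal(n)),
            panel.accession_ids, "d1", pop_names=["d0", "d1"],
        )
        assert np.isnan(res.p_value[1])
        assert not np.isnan(res.p_value[0])

    def test_null_trait_pvalues_uniform(self, rng):
        n, L = 60, 1000
        X = rng.uniform(0, 1, (n, L))
        y = rng.standard_normal(n)
        panel = build_panel(rng.integers(0, 2, (n, L)).astype(np.int8))
        res = admixture_map(
            local_from_component(X), panel,
            pheno_from_vector(panel.accession_ids, y),
            panel.accession_ids, "d1", pop_names=["d0", "d1"],
        )
        ks = stats.kstest(res.p_value, "uniform")
        assert ks.pvalue > 0.01

    def test_causal_in_donor_block_is_minimum(self, rng):
        # ancestry blocks around SNP 50 drive the trait: the minimum p-value
        # falls inside the block even though neighbors carry no direct effect
        n, L = 80, 101
        X = rng.uniform(0, 0.2, (n, L))
        block = slice(45, 56)
        carrier = rng.random(n) < 0.5
        X[carrier, block] = rng.uniform(0.7, 1.0, (carrier.sum(), 11))
        y = 2.0 * X[:, 50] + 0.3 * rng.standard_normal(n)
        panel = build_panel(rng.integers(0, 2, (n, L)).astype(np.int8))
        res = admixture_map(
            local_from_component(X), panel,
            pheno_from_vector(panel.accession_ids, y),
            panel.accession_ids, "d1", pop_names=["d0", "d1"],
        )
        assert 45 <= int(np.nanargmin(res.p_value)) <= 55

    def test_missing_phenotypes_dropped_and_min_subset(self, rng):
        panel = build_panel(rng.integers(0, 2, (5, 3)).astype(np.int8))
        X = rng.uniform(0, 1, (5, 3))
        pheno = pheno_from_vector(panel.accession_ids[:2], [1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            admixture_map(
                local_from_component(X), panel, pheno,
                panel.accession_ids, "d1", pop_names=["d0", "d1"],
            )


class TestKinship:
    def test_equals_one_minus_distance(self, rng):
        calls = rng.integers(0, 2, (12, 40)).astype(np.int8)
        calls[rng.random((12, 40)) < 0.1] = -1
        panel = build_panel(calls)
        kin = kinship_matrix(panel)
        D = allele_sharing_distance(panel)
        np.testing.assert_allclose(kin.k, 1.0 - D.d, atol=1e-15)
        np.testing.assert_allclose(np.diag(kin.k), 1.0)

    def test_identical_and_complementary(self):
        panel = build_panel([[0, 1, 0], [0, 1, 0], [1, 0, 1]])
        kin = kinship_matrix(panel)
        assert kin.k[0, 1] == 1.0
        assert kin.k[0, 2] == 0.0


class TestMixedModel:
    def test_identity_kinship_reproduces_ols(self, rng):
        n, L = 50, 30
        calls = rng.integers(0, 2, (n, L)).astype(np.int8)
        panel = build_panel(calls)
        y = rng.standard_normal(n)
        kin = KinshipMatrix(ids=panel.accession_ids, k=np.eye(n))
        res = mixed_model_assoc(
            panel, pheno_from_vector(panel.accession_ids, y), None, kin
        )
        for j in range(L):
            ref = stats.linregress(calls[:, j].astype(float), y)
            assert res.p_value[j] == pytest.approx(ref.pvalue, abs=1e-8)
            assert res.effect[j] == pytest.approx(ref.slope, abs=1e-8)

    def test_reml_matches_grid_search_oracle(self, rng):
        n = 80
        # structured kinship from two blocks
        groups = np.repeat([0, 1], n // 2)
        K = 0.5 * (groups[:, None] == groups[None, :]) + 0.5 * np.eye(n)
        w, U = np.linalg.eigh(K)
        u = U @ (np.sqrt(np.maximum(w, 0)) * rng.standard_normal(n))
        y = 1.0 + 2.0 * u + rng.standard_normal(n)
        X0 = np.ones((n, 1))
        yr, X0r = U.T @ y, U.T @ X0
        from paddymix.mapping import _reml_h

        h_hat = _reml_h(yr, X0r, np.maximum(w, 0))
        grid = np.linspace(0.0, 0.999, 2000)
        vals = [reml_neg_loglik(h, yr, X0r, np.maximum(w, 0)) for h in grid]
        h_grid = grid[int(np.argmin(vals))]
        assert h_hat == pytest.approx(h_grid, abs=1e-3)

    def test_polygenic_trait_inflation_controlled(self, rng):
        # trait driven by kinship structure only: genomic-control lambda of
        # null SNPs should be near 1 under the mixed model
        from paddymix.simulate import SimulationConfig, simulate_panel

        cfg = SimulationConfig(
            K=2, F_k=(0.4, 0.4), pop_names=("a", "b"),
            n_pure_per_pop=(60, 60), n_admixed=30,
            markers_per_chrom=(400,), spacing_bp=1000, seed=10,
        )
        panel, truth = simulate_panel(cfg)
        kin = kinship_matrix(panel)
        lambdas = []
        for rep in range(5):
            rng_rep = np.random.default_rng(rep)
            w, U = np.linalg.eigh(kin.k)
            u = U @ (np.sqrt(np.maximum(w, 0)) * rng_rep.standard_normal(panel.n_accessions))
            y = u + rng_rep.standard_normal(panel.n_accessions)
            res = mixed_model_assoc(
                panel, pheno_from_vector(panel.accession_ids, y),
                truth.Q_true, kin,
            )
            chi2 = stats.chi2.isf(res.p_value[~np.isnan(res.p_value)], df=1)
            lambdas.append(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
        assert 0.8 <= np.mean(lambdas) <= 1.2

    def test_q_column_dropped_against_intercept(self, rng):
        n, L = 40, 10
        panel = build_panel(rng.integers(0, 2, (n, L)).astype(np.int8))
        Q = rng.dirichlet(np.ones(3), size=n)
        kin = KinshipMatrix(ids=panel.accession_ids, k=np.eye(n))
        res = mixed_model_assoc(
            panel, pheno_from_vector(panel.accession_ids, rng.standard_normal(n)),
            Q, kin,
        )
        assert res.extras["n_fixed"] == 3  # intercept + 2 of 3 Q columns

    def test_non_psd_kinship_rejected(self, rng):
        n = 10
        panel = build_panel(rng.integers(0, 2, (n, 5)).astype(np.int8))
        bad = np.eye(n)
        bad[0, 0] = -1.0
        kin = KinshipMatrix(ids=panel.accession_ids, k=bad)
        with pytest.raises(ValueError, match="PSD"):
            mixed_model_assoc(
                panel, pheno_from_vector(panel.accession_ids, np.ones(n)),
                None, kin,
            )


class TestBonferroni:
    def test_threshold_values(self, rng):
        res = _result_with_pvals(np.array([0.04, 0.5]))
        res.p_value = np.array([0.04])
        res.marker_ids = ["m1"]
        out = bonferroni(res, 0.05)
        assert out.bonferroni_threshold == pytest.approx(0.05)
        res2 = _result_with_pvals(np.full(1311, 0.5))
        out2 = bonferroni(res2, 0.05)
        assert out2.bonferroni_threshold == pytest.approx(0.05 / 1311)
        assert out2.bonferroni_threshold == pytest.approx(3.814e-5, rel=1e-3)

    def test_all_p_one_no_flags(self):
        out = bonferroni(_result_with_pvals(np.ones(10)))
        assert out.significant.sum() == 0

    def test_na_pvalues_excluded_from_count(self):
        p = np.array([0.001, np.nan, 0.5, np.nan])
        out = bonferroni(_result_with_pvals(p), 0.05)
        assert out.bonferroni_threshold == pytest.approx(0.05 / 2)
        assert list(out.significant) == [True, False, False, False]


def _result_with_pvals(p):
    from paddymix.mapping import MappingResult

    L = len(p)
    return MappingResult(
        method="admixture_map",
        marker_ids=[f"m{j}" for j in range(L)],
        effect=np.zeros(L), se=np.ones(L), p_value=np.asarray(p, float),
        n_used=np.full(L, 10),
    )


def test_phenotype_tsv_round_trip(tmp_path):
    path = tmp_path / "pheno.tsv"
    path.write_text("accession\tamylose\nacc1\t21.5\nacc2\t14.0\n")
    tab = read_phenotype_tsv(path)
    assert tab.trait == "amylose"
    assert tab.values == {"acc1": 21.5, "acc2": 14.0}
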
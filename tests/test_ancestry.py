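"""Local-ancestry HMM: exact-posterior oracle, rate fitting, introgression
profiles, and segment calling."""

import itertools

import numpy as np
import pytest

from paddymix.admixture import AdmixtureFit
from paddymix.ancestry import (
    LocalAncestry,
    call_segments,
    fit_switch_rate,
    hmm_loglik,
    mean_introgression,
    posterior_ancestry,
    top_percentile_cutoff,
)
from paddymix.simulate import SimulationConfig, simulate_panel

from conftest import build_panel


def make_fit(Q, P):
    return AdmixtureFit(
        K=Q.shape[1], Q=np.asarray(Q, float), P=np.asarray(P, float),
        loglik=0.0, n_iter=0, restart_index=0,
    )


def brute_force_posterior(calls, pos, Q, P, r):
    """Path-enumeration oracle: exact posteriors and log-likelihood."""
    n, L = calls.shape
    K = Q.shape[1]
    stay = np.exp(-r * np.diff(pos).astype(float))
    post = np.zeros((n, L, K))
    total_ll = 0.0
    for i in range(n):
        tot = 0.0
        acc = np.zeros((L, K))
        for path in itertools.product(range(K), repeat=L):
            pr = Q[i, path[0]]
            for j in range(1, L):
                a = stay[j - 1]
                pr *= a * (path[j] == path[j - 1]) + (1 - a) * Q[i, path[j]]
            for j in range(L):
                g = calls[i, j]
                if g == 1:
                    pr *= P[path[j], j]
                elif g == 0:
                    pr *= 1 - P[path[j], j]
            tot += pr
            for j in range(L):
                acc[j, path[j]] += pr
        post[i] = acc / tot
        total_ll += np.log(tot)
    return post, total_ll


class TestPosterior:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 4))
        L = int(rng.integers(3, 8))
        n = 2
        P = rng.uniform(0.05, 0.95, (K, L))
        Q = rng.dirichlet(np.ones(K), size=n)
        pos = np.sort(rng.choice(np.arange(1, 10**6), size=L, replace=False))
        calls = rng.integers(0, 2, (n, L)).astype(np.int8)
        calls[0, min(1, L - 1)] = -1
        panel = build_panel(calls, chroms=[1] * L, positions=pos.tolist())
        r = float(rng.uniform(1e-7, 5e-6))
        la = posterior_ancestry(panel, make_fit(Q, P), r)
        ref_post, ref_ll = brute_force_posterior(calls, pos, Q, P, r)
        np.testing.assert_allclose(la.posterior, ref_post, atol=1e-10)
        assert la.loglik == pytest.approx(ref_ll, abs=1e-8)

    def test_uninformative_emissions_return_global_q(self, rng):
        K, L = 3, 10
        P = np.tile(rng.uniform(0.2, 0.8, L), (K, 1))  # identical across pops
        Q = rng.dirichlet(np.ones(K), size=4)
        calls = rng.integers(0, 2, (4, L)).astype(np.int8)
        panel = build_panel(calls)
        la = posterior_ancestry(panel, make_fit(Q, P), 1e-6)
        for i in range(4):
            np.testing.assert_allclose(
                la.posterior[i], np.tile(Q[i], (L, 1)), atol=1e-9
            )

    def test_large_rate_decouples_sites(self, rng):
        K, L = 2, 6
        P = rng.uniform(0.1, 0.9, (K, L))
        Q = rng.dirichlet(np.ones(K), size=3)
        calls = rng.integers(0, 2, (3, L)).astype(np.int8)
        panel = build_panel(calls, positions=[j * 10**6 for j in range(1, L + 1)])
        la = posterior_ancestry(panel, make_fit(Q, P), r=1.0)  # e^{-rd} ~ 0
        em = np.where(calls[:, :, None] == 1, P.T[None], 1 - P.T[None])
        expected = Q[:, None, :] * em
        expected /= expected.sum(axis=2, keepdims=True)
        np.testing.assert_allclose(la.posterior, expected, atol=1e-8)

    def test_posterior_normalized_and_chromosomes_independent(self, rng):
        calls = rng.integers(0, 2, (5, 12)).astype(np.int8)
        panel = build_panel(calls, chroms=[1] * 6 + [2] * 6)
        Q = rng.dirichlet(np.ones(3), size=5)
        P = rng.uniform(0.1, 0.9, (3, 12))
        la = posterior_ancestry(panel, make_fit(Q, P), 1e-5)
        np.testing.assert_allclose(la.posterior.sum(axis=2), 1.0, atol=1e-8)
        # chromosome 1 posteriors unchanged if chromosome 2 data changes
        calls2 = calls.copy()
        calls2[:, 6:] = rng.integers(0, 2, (5, 6))
        la2 = posterior_ancestry(
            build_panel(calls2, chroms=[1] * 6 + [2] * 6), make_fit(Q, P), 1e-5
        )
        np.testing.assert_allclose(
            la.posterior[:, :6], la2.posterior[:, :6], atol=1e-12
        )

    def test_bad_rate(self):
        panel = build_panel([[0, 1]])
        fit = make_fit(np.array([[1.0]]), np.full((1, 2), 0.5))
        with pytest.raises(ValueError):
            posterior_ancestry(panel, fit, float("nan"))


class TestSwitchRate:
    def test_single_element_grid(self, rng):
        calls = rng.integers(0, 2, (3, 5)).astype(np.int8)
        panel = build_panel(calls)
        fit = make_fit(rng.dirichlet(np.ones(2), 3), rng.uniform(0.2, 0.8, (2, 5)))
        assert fit_switch_rate(panel, fit, [2e-6]) == 2e-6

    def test_argmax_contract_and_recovery(self):
        # admixed mosaic panel simulated at rho: the selected grid rate is
        # within one log-step of rho
        rho = 1e-7
        cfg = SimulationConfig(
            K=2, F_k=(0.45, 0.45), pop_names=("a", "b"),
            n_pure_per_pop=(20, 20), n_admixed=60,
            markers_per_chrom=(300,), spacing_bp=260_000,
            switch_rate=rho, seed=8,
        )
        panel, truth = simulate_panel(cfg)
        fit = make_fit(truth.Q_true, truth.ancestral_freqs)
        grid = [rho / 10, rho / 3, rho, rho * 3, rho * 10]
        best = fit_switch_rate(panel, fit, grid)
        lls = [hmm_loglik(panel, fit, r) for r in grid]
        assert lls[grid.index(best)] == max(lls)
        assert best in (rho / 3, rho, rho * 3)

    def test_empty_or_bad_grid(self, rng):
        panel = build_panel([[0, 1]])
        fit = make_fit(np.array([[1.0]]), np.full((1, 2), 0.5))
        with pytest.raises(ValueError):
            fit_switch_rate(panel, fit, [])
        with pytest.raises(ValueError):
            fit_switch_rate(panel, fit, [0.0])


def one_hot_local(ancestry, K, pop_names=None):
    """LocalAncestry built from a hard per-SNP ancestry matrix."""
    n, L = ancestry.shape
    post = np.zeros((n, L, K))
    for k in range(K):
        post[:, :, k] = ancestry == k
    fit = AdmixtureFit(
        K=K, Q=np.full((n, K), 1.0 / K), P=np.full((K, L), 0.5),
        loglik=0.0, n_iter=0, restart_index=0,
    )
    return LocalAncestry(posterior=post, switch_rate=1e-8, source_fit=fit)


class TestProfile:
    def test_zero_profile(self):
        anc = np.zeros((4, 10), dtype=int)  # everyone pure cluster0
        local = one_hot_local(anc, K=2)
        prof = mean_introgression(
            local, ["rec"] * 4, "rec", "donor1",
            pop_names=["donor0", "donor1"],
        )
        assert prof.values.max() == 0.0
        assert prof.threshold_95 == 0.0

    def test_nearest_rank_top5_cutoff(self):
        # 95 values at 0.01 and 5 at 0.50: the top-5% cutoff is 0.50
        values = np.array([0.01] * 95 + [0.50] * 5)
        assert top_percentile_cutoff(values, 0.05) == pytest.approx(0.50)
        # and the plain 95th-smallest value would have been 0.01
        assert np.sort(values)[94] == pytest.approx(0.01)

    def test_planted_block_peaks_above_threshold(self):
        K, n, L = 2, 20, 300
        anc = np.zeros((n, L), dtype=int)
        anc[:10, 25:35] = 1  # half the recipients share a 10-SNP donor block
        local = one_hot_local(anc, K)
        prof = mean_introgression(
            local, ["rec"] * n, "rec", "d1", pop_names=["d0", "d1"]
        )
        assert prof.values[25:35].min() > prof.threshold_95
        assert prof.values[:25].max() <= prof.threshold_95

    def test_input_validation(self):
        local = one_hot_local(np.zeros((2, 4), dtype=int), K=2)
        with pytest.raises(ValueError, match="differ"):
            mean_introgression(local, ["a", "a"], "a", "a", pop_names=["a", "b"])
        with pytest.raises(ValueError, match="no accessions"):
            mean_introgression(local, ["a", "a"], "zzz", "b", pop_names=["a", "b"])


class TestSegments:
    def make_local(self, donor_post):
        """One accession, one chromosome, arbitrary donor posterior track."""
        L = len(donor_post)
        post = np.zeros((1, L, 2))
        post[0, :, 1] = donor_post
        post[0, :, 0] = 1 - np.asarray(donor_post)
        fit = AdmixtureFit(
            K=2, Q=np.full((1, 2), 0.5), P=np.full((2, L), 0.5),
            loglik=0.0, n_iter=0, restart_index=0,
        )
        return LocalAncestry(posterior=post, switch_rate=1e-8, source_fit=fit)

    def call(self, donor_post, **kw):
        L = len(donor_post)
        panel = build_panel(
            np.zeros((1, L), dtype=np.int8),
            positions=[(j + 1) * 1000 for j in range(L)],
        )
        local = self.make_local(donor_post)
        return call_segments(
            local, panel, "acc1", "d1", pop_names=["d0", "d1"], **kw
        )

    def test_four_snp_run_not_called(self):
        assert self.call([0.9, 0.9, 0.9, 0.9, 0.1, 0.1]) == []

    def test_five_snp_run_called(self):
        calls = self.call([0.9] * 5 + [0.1])
        assert len(calls) == 1
        assert calls[0].n_snps == 5
        assert (calls[0].start_bp, calls[0].end_bp) == (1000, 5000)
        assert calls[0].mean_posterior == pytest.approx(0.9)

    def test_split_run_only_long_half_called(self):
        track = [0.9] * 5 + [0.2] + [0.9] * 3
        calls = self.call(track)
        assert len(calls) == 1
        assert calls[0].n_snps == 5

    def test_runs_do_not_cross_chromosomes(self):
        L = 10
        panel = build_panel(
            np.zeros((1, L), dtype=np.int8),
            chroms=[1] * 5 + [2] * 5,
            positions=[(j % 5 + 1) * 1000 for j in range(L)],
        )
        local = self.make_local([0.9] * 10)
        calls = call_segments(local, panel, "acc1", "d1", pop_names=["d0", "d1"])
        assert [c.chrom for c in calls] == [1, 2]
        assert all(c.n_snps == 5 for c in calls)

    def test_threshold_is_strict(self):
        assert self.call([0.5] * 6) == []  # > post_min, not >=
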
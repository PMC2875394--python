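"""Synthetic-panel generator: Balding-Nichols frequencies, mosaics,
introgression planting, and phenotype simulation."""

import numpy as np
import pytest

from paddymix.fst import fst_overall, fst_per_snp
from paddymix.simulate import (
    IntrogressionEvent,
    SimulationConfig,
    draw_subpop_freqs,
    simulate_panel,
    simulate_phenotype,
)


class TestFreqs:
    def test_zero_divergence_limit_exact(self):
        P = draw_subpop_freqs(3, 50, (0.2, 0.8), (0.0, 0.0, 0.0), seed=1)
        np.testing.assert_allclose(P[0], P[1])
        np.testing.assert_allclose(P[0], P[2])

    def test_deterministic_given_seed(self):
        a = draw_subpop_freqs(2, 100, (0.1, 0.9), (0.3, 0.3), seed=7)
        b = draw_subpop_freqs(2, 100, (0.1, 0.9), (0.3, 0.3), seed=7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_divergence(self):
        with pytest.raises(ValueError):
            draw_subpop_freqs(2, 10, (0.1, 0.9), (0.3, 1.0), seed=0)
        with pytest.raises(ValueError):
            draw_subpop_freqs(2, 10, (0.1, 0.9), (-0.1, 0.3), seed=0)

    def test_weir_estimate_matches_divergence(self):
        # K=2 at F=0.3, 100 haploids per pop over 5000 loci
        cfg = SimulationConfig(
            K=2, F_k=(0.3, 0.3), pop_names=("a", "b"),
            n_pure_per_pop=(100, 100), n_admixed=0,
            markers_per_chrom=(5000,), spacing_bp=1000, seed=2,
        )
        panel, truth = simulate_panel(cfg)
        res = fst_per_snp(panel, truth.labels_true, ["a", "b"])
        assert fst_overall(res) == pytest.approx(0.3, abs=0.03)


class TestPanel:
    def test_pure_panel_one_hot(self):
        cfg = SimulationConfig(
            K=2, F_k=(0.3, 0.3), pop_names=("a", "b"),
            n_pure_per_pop=(5, 5), n_admixed=0,
            markers_per_chrom=(50,), spacing_bp=1000, seed=0,
        )
        panel, truth = simulate_panel(cfg)
        assert (truth.Q_true.max(axis=1) == 1.0).all()
        assert (truth.local_ancestry_true[:5] == 0).all()
        assert (truth.local_ancestry_true[5:] == 1).all()

    def test_full_carrier_fraction_forces_assignment(self):
        ev = IntrogressionEvent(
            donor=1, recipient=0, chrom=1,
            start_bp=10_000, end_bp=20_000, carrier_fraction=1.0,
        )
        cfg = SimulationConfig(
            K=2, F_k=(0.3, 0.3), pop_names=("a", "b"),
            n_pure_per_pop=(20, 5), n_admixed=0,
            markers_per_chrom=(50,), spacing_bp=1000, seed=1,
            introgression_events=(ev,),
        )
        panel, truth = simulate_panel(cfg)
        assert len(truth.introgression_carriers[0]) == 20
        block = (panel.positions >= 10_000) & (panel.positions <= 20_000)
        for acc in truth.introgression_carriers[0]:
            i = panel.accession_index(acc)
            assert (truth.local_ancestry_true[i, block] == 1).all()

    def test_q_rows_sum_to_one_and_ancestry_range(self):
        cfg = SimulationConfig(seed=3, n_admixed=40)
        panel, truth = simulate_panel(cfg)
        np.testing.assert_allclose(truth.Q_true.sum(axis=1), 1.0, atol=1e-12)
        assert truth.local_ancestry_true.min() >= 0
        assert truth.local_ancestry_true.max() < cfg.K

    def test_realized_freqs_match_ancestral(self):
        cfg = SimulationConfig(
            K=2, F_k=(0.3, 0.3), pop_names=("a", "b"),
            n_pure_per_pop=(500, 500), n_admixed=0,
            markers_per_chrom=(200,), spacing_bp=1000, seed=4,
        )
        panel, truth = simulate_panel(cfg)
        emp = panel.calls[:500].mean(axis=0)
        # binomial error at n=500 is ~0.022; allow 4 sigma
        assert np.abs(emp - truth.ancestral_freqs[0]).max() < 0.09

    def test_mosaic_switch_count_consistent_with_rate(self):
        rho = 5e-7
        cfg = SimulationConfig(
            K=2, F_k=(0.3, 0.3), pop_names=("a", "b"),
            n_pure_per_pop=(0, 0), n_admixed=200,
            markers_per_chrom=(200,), spacing_bp=260_000,
            switch_rate=rho, admix_alpha=1.0, seed=5,
        )
        panel, truth = simulate_panel(cfg)
        A = truth.local_ancestry_true
        switches = (A[:, 1:] != A[:, :-1]).sum()
        # expected redraws = n * (L-1) * (1 - e^{-rho d}); a redraw changes
        # the state with prob sum_k q_k (1-q_k) <= 1
        redraw_p = 1 - np.exp(-rho * 260_000)
        upper = 200 * 199 * redraw_p
        assert 0.2 * upper < switches < 1.05 * upper

    def test_determinism_and_empty_error(self):
        cfg = SimulationConfig(seed=6)
        p1, t1 = simulate_panel(cfg)
        p2, t2 = simulate_panel(cfg)
        np.testing.assert_array_equal(p1.calls, p2.calls)
        np.testing.assert_array_equal(t1.Q_true, t2.Q_true)
        with pytest.raises(ValueError):
            simulate_panel(
                SimulationConfig(
                    K=2, F_k=(0.3, 0.3), pop_names=("a", "b"),
                    n_pure_per_pop=(0, 0), n_admixed=0,
                    markers_per_chrom=(10,), seed=0,
                )
            )

    def test_event_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                introgression_events=(
                    IntrogressionEvent(0, 0, 1, 1, 2, 0.5),  # donor == recipient
                ),
            )
        with pytest.raises(ValueError):
            SimulationConfig(
                introgression_events=(
                    IntrogressionEvent(0, 1, 99, 1, 2, 0.5),  # chrom outside layout
                ),
            )


@pytest.fixture(scope="module")
def small_panel():
    cfg = SimulationConfig(
        K=2, F_k=(0.4, 0.4), pop_names=("a", "b"),
        n_pure_per_pop=(250, 250), n_admixed=0,
        markers_per_chrom=(100,), spacing_bp=1000, seed=7,
    )
    return simulate_panel(cfg)


class TestPhenotype:
    def test_h2_zero_is_pure_noise(self, small_panel):
        panel, truth = small_panel
        causal = [(0, 2.0)]
        cors = []
        for rep in range(10):
            pheno = simulate_phenotype(truth, panel, causal, h2=0.0, seed=rep)
            y = np.array([pheno.values[a] for a in panel.accession_ids])
            g = panel.calls[:, 0].astype(float)
            cors.append(np.corrcoef(y, g)[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_variance_fraction_near_h2(self, small_panel):
        panel, truth = small_panel
        causal = [(0, 1.0)]
        g = panel.calls[:, 0].astype(float)
        vg = np.var(g)
        fracs = []
        for rep in range(20):
            pheno = simulate_phenotype(truth, panel, causal, h2=0.5, seed=100 + rep)
            y = np.array([pheno.values[a] for a in panel.accession_ids])
            fracs.append(vg / np.var(y))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.1)

    def test_deterministic(self, small_panel):
        panel, truth = small_panel
        a = simulate_phenotype(truth, panel, [(3, 1.0)], h2=0.4, seed=9)
        b = simulate_phenotype(truth, panel, [(3, 1.0)], h2=0.4, seed=9)
        assert a.values == b.values

    def test_h2_one_without_variance_errors(self, small_panel):
        panel, truth = small_panel
        mono = [(j, 1.0) for j in range(1)]
        # build a causal set with zero variance: weight 0
        with pytest.raises(ValueError):
            simulate_phenotype(truth, panel, [(0, 0.0)], h2=1.0, seed=0)

    def test_missing_causal_calls_imputed(self, small_panel):
        panel, truth = small_panel
        calls = panel.calls.copy()
        calls[0, 5] = -1
        from conftest import build_panel

        panel2 = build_panel(calls)
        pheno = simulate_phenotype(truth, panel2, [(5, 1.0)], h2=1.0, seed=0)
        y0 = pheno.values[panel2.accession_ids[0]]
        assert y0 == pytest.approx(float(panel2.allele_freq()[5]))
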
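"""Simulate a diverse inbred panel and infer its population structure.

Generates a 395-accession panel from five diverged subpopulations plus 90
admixed lines (~1,300 SNPs over 12 chromosomes), fits the admixture model by
multi-restart EM, and classifies accessions with the 80% ancestry rule.
"""

import numpy as np

import paddymix as pm
from paddymix.simulate import SimulationConfig, simulate_panel

cfg = SimulationConfig(seed=42)
panel, truth = simulate_panel(cfg)
panel = pm.apply_qc(panel)  # MAF > 1%, missingness <= 20%
print(f"panel: {panel.n_accessions} accessions x {panel.n_markers} SNPs after QC")

fit = pm.fit_admixture(panel, K=5, n_restarts=3, seed=1)
fit = pm.apply_permutation(fit, pm.align_components(fit, truth.Q_true))
labels = pm.classify_accessions(fit, 0.80, panel=panel,
                                cluster_names=list(cfg.pop_names))

n_adm = labels.count(pm.ADMIXED)
print(f"log-likelihood {fit.loglik:.1f} after {fit.n_iter} EM iterations")
print(f"{n_adm} accessions admixed at the 80% rule")
mae = np.abs(fit.Q - truth.Q_true).mean()
print(f"mean |Q_hat - Q_true| = {mae:.4f}  (ancestry recovered to ~1%)")
print("\nfirst three accessions (ancestry proportions per subpopulation):")
for i in range(3):
    row = " ".join(f"{q:.2f}" for q in fit.Q[i])
    print(f"  {panel.accession_ids[i]:22s} [{row}] -> {labels[i]}")
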
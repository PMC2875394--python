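"""Maximum-likelihood admixture model fitting by EM.

The model: accession i draws the allele at SNP l from ancestral cluster k
with probability q_ik (its global ancestry proportion), and that cluster
contributes the alternate allele with probability p_kl. The log-likelihood
over non-missing haploid calls g_il is

    sum_il  g_il log(sum_k q_ik p_kl) + (1 - g_il) log(sum_k q_ik (1 - p_kl)).

Fitting is EM with closed-form updates from the per-call cluster
responsibilities, restarted from several random initializations; the restart
with the best final likelihood wins. This deterministically (given a seed)
recovers the same point estimates of Q and P that Bayesian clustering with
the admixture model targets; accessions are then classified to their top
cluster unless its share falls below a threshold (80% by default), in which
case they are called admixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .panel import ADMIXED, MISSING, GenotypePanel

logger = logging.getLogger(__name__)

#: Allele frequencies are kept in [EPS, 1-EPS] so fixed sites cannot
#: produce log(0) for a discordant call.
EPS = 1e-6


@dataclass
class AdmixtureFit:
    """Point estimates of global ancestry (Q) and cluster frequencies (P)."""

    K: int
    Q: np.ndarray          # n x K, rows on the simplex
    P: np.ndarray          # K x L, entries in [EPS, 1-EPS]
    loglik: float
    n_iter: int
    restart_index: int
    loglik_trace: list[float] | None = None


def admixture_loglik(
    panel: GenotypePanel, Q: np.ndarray, P: np.ndarray
) -> float:
    """Model log-likelihood of the panel under (Q, P)."""
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    n, L = panel.calls.shape
    if Q.shape[0] != n or P.shape[1] != L or Q.shape[1] != P.shape[0]:
        raise ValueError(
            f"dimension mismatch: calls {n}x{L}, Q {Q.shape}, P {P.shape}"
        )
    Pc = np.clip(P, EPS, 1 - EPS)
    if not np.array_equal(Pc, P):
        logger.debug("P clipped to [%g, %g] for likelihood evaluation", EPS, 1 - EPS)
    m1 = Q @ Pc          # P(call = 1)
    m0 = Q @ (1 - Pc)    # P(call = 0)
    obs = panel.calls != MISSING
    g1 = obs & (panel.calls == 1)
    g0 = obs & (panel.calls == 0)
    return float(np.log(m1[g1]).sum() + np.log(m0[g0]).sum())


def fit_admixture(
    panel: GenotypePanel,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
    keep_trace: bool = False,
) -> AdmixtureFit:
    """Multi-restart EM fit; returns the restart with the best likelihood.

    Each restart initializes Q rows from a flat Dirichlet and P from the
    observed per-SNP frequencies perturbed per cluster, then iterates EM
    until the log-likelihood improves by less than `tol` or `max_iter` is
    reached. EM never decreases the likelihood, which is asserted.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > panel.n_accessions:
        raise ValueError(
            f"K={K} exceeds the number of accessions ({panel.n_accessions})"
        )
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    n, L = panel.calls.shape
    obs = panel.calls != MISSING
    G1 = (obs & (panel.calls == 1)).astype(float)
    G0 = (obs & (panel.calls == 0)).astype(float)
    n_obs_per_acc = obs.sum(axis=1).astype(float)
    base_freq = np.clip(panel.allele_freq(), EPS, 1 - EPS)
    base_freq = np.where(np.isnan(base_freq), 0.5, base_freq)

    best: AdmixtureFit | None = None
    for restart in range(n_restarts):
        if K == 1:
            Q = np.ones((n, 1))
            P = base_freq[None, :].copy()
            ll = admixture_loglik(panel, Q, P)
            fit = AdmixtureFit(
                K=1, Q=Q, P=P, loglik=ll, n_iter=1, restart_index=restart,
                loglik_trace=[ll] if keep_trace else None,
            )
        else:
            Q = rng.dirichlet(np.ones(K), size=n)
            noise = rng.uniform(-0.1, 0.1, size=(K, L))
            P = np.clip(base_freq[None, :] + noise, EPS, 1 - EPS)
            fit = _em_run(
                G1, G0, n_obs_per_acc, Q, P, tol, max_iter, restart,
                keep_trace=keep_trace,
            )
        logger.debug(
            "restart %d: loglik %.4f after %d iterations",
            restart, fit.loglik, fit.n_iter,
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def _em_run(
    G1: np.ndarray,
    G0: np.ndarray,
    n_obs_per_acc: np.ndarray,
    Q: np.ndarray,
    P: np.ndarray,
    tol: float,
    max_iter: int,
    restart: int,
    keep_trace: bool = False,
) -> AdmixtureFit:
    """One EM run. Responsibilities are marginalized analytically so each
    iteration is four (n x L) @ (L x K)-shaped matmuls."""
    prev_ll = -np.inf
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        m1 = Q @ P
        m0 = Q @ (1 - P)
        ll = float(
            (G1 * _safe_log(m1)).sum() + (G0 * _safe_log(m0)).sum()
        )
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood in EM")
        # EM guarantee: the likelihood never decreases.
        assert ll >= prev_ll - 1e-8, (
            f"EM decreased the log-likelihood: {prev_ll} -> {ll}"
        )
        if keep_trace:
            trace.append(ll)
        if ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll

        A = np.divide(G1, m1, out=np.zeros_like(G1), where=m1 > 0)
        B = np.divide(G0, m0, out=np.zeros_like(G0), where=m0 > 0)
        # sum_l r_ilk (cluster responsibility summed over SNPs)
        R_q = Q * (A @ P.T + B @ (1 - P).T)
        Q = R_q / np.maximum(n_obs_per_acc, 1.0)[:, None]
        Q = np.maximum(Q, 0)
        Q /= Q.sum(axis=1, keepdims=True)
        num = P * (Q.T @ A)          # sum_i r_ilk g_il
        den = num + (1 - P) * (Q.T @ B)
        P = np.divide(num, den, out=np.full_like(P, 0.5), where=den > 0)
        P = np.clip(P, EPS, 1 - EPS)
    return AdmixtureFit(
        K=Q.shape[1], Q=Q, P=P, loglik=prev_ll, n_iter=n_iter,
        restart_index=restart, loglik_trace=trace if keep_trace else None,
    )


def _safe_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(x, 1e-300))


def classify_accessions(
    fit: AdmixtureFit,
    threshold: float = 0.80,
    panel: GenotypePanel | None = None,
    cluster_names: list[str] | None = None,
) -> list[str]:
    """Assign each accession to its majority cluster, or call it admixed.

    An accession whose maximum ancestry share is below `threshold` (strictly
    less than; the boundary value itself is assigned) is labeled ADMIXED.
    When a panel is given, labels are written onto its accession records.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    names = cluster_names or [f"cluster{k}" for k in range(fit.K)]
    if len(names) != fit.K:
        raise ValueError("cluster_names must have length K")
    top = fit.Q.argmax(axis=1)
    top_val = fit.Q.max(axis=1)
    labels = [
        names[k] if v >= threshold else ADMIXED
        for k, v in zip(top, top_val)
    ]
    if panel is not None:
        if panel.n_accessions != len(labels):
            raise ValueError("panel size does not match fit")
        for acc, lab in zip(panel.accessions, labels):
            acc.assigned_subpop = lab
    return labels


def align_components(
    fit: AdmixtureFit, reference_Q: np.ndarray
) -> np.ndarray:
    """Resolve label switching against a reference ancestry matrix.

    Returns the permutation `perm` (cluster j of the fit corresponds to
    reference column perm[j]... inverted for application, see
    `apply_permutation`) maximizing the summed column-wise correlation
    between Q and the reference, via optimal assignment. Constant columns
    correlate with nothing and are matched last with a warning.
    """
    reference_Q = np.asarray(reference_Q, dtype=float)
    if reference_Q.shape != fit.Q.shape:
        raise ValueError(
            f"reference Q shape {reference_Q.shape} != fit Q shape {fit.Q.shape}"
        )
    K = fit.K
    score = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            score[a, b] = _corr(fit.Q[:, a], reference_Q[:, b])
    rows, cols = linear_sum_assignment(-score)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows  # new column b comes from fitted column perm[b]
    return perm


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        logger.warning("constant ancestry column during alignment")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def apply_permutation(fit: AdmixtureFit, perm: np.ndarray) -> AdmixtureFit:
    """Reorder Q columns and P rows so cluster labels follow `perm`."""
    perm = np.asarray(perm, dtype=int)
    return AdmixtureFit(
        K=fit.K,
        Q=fit.Q[:, perm],
        P=fit.P[perm, :],
        loglik=fit.loglik,
        n_iter=fit.n_iter,
        restart_index=fit.restart_index,
        loglik_trace=fit.loglik_trace,
    )
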
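"""Site-by-site local ancestry along chromosomes, and introgression calls.

Conditional on a fitted admixture model (global proportions q_i and cluster
allele frequencies p_kl), the ancestral origin of each SNP in accession i is
modeled as a hidden Markov chain along each chromosome (the linkage model):

* hidden state at SNP l = ancestral cluster of origin, in 0..K-1;
* initial distribution q_i (the accession's global ancestry);
* between adjacent SNPs at physical distance d bp, the chain stays put with
  probability e^{-r d} and otherwise re-draws its state from q_i, where r is
  the per-bp ancestry switch rate;
* emission: cluster k emits the observed haploid call g with probability
  p_kl^g (1 - p_kl)^{1-g}; a missing call emits 1 under every state.

Forward–backward with per-site scaling gives exact per-SNP posteriors over
ancestral origin. Introgression is then a component of ancestry that
disagrees with the accession's subpopulation assignment: subpopulation-level
profiles average the donor component over all member accessions, and
per-accession segments are maximal runs of >= 5 consecutive SNPs whose donor
posterior exceeds a threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .admixture import EPS, AdmixtureFit
from .panel import MISSING, GenotypePanel, chrom_spans

logger = logging.getLogger(__name__)


@dataclass
class LocalAncestry:
    """Per-accession, per-SNP posterior over the K ancestral origins."""

    posterior: np.ndarray       # n x L x K, sums to 1 over K
    switch_rate: float
    source_fit: AdmixtureFit
    loglik: float = math.nan    # total HMM log-likelihood over accessions


@dataclass
class IntrogressionProfile:
    """Mean donor-ancestry per SNP across one recipient subpopulation."""

    recipient_pop: str
    donor_pop: str
    values: np.ndarray          # per-SNP means, in [0, 1]
    threshold_95: float         # top-5% cutoff of the per-SNP means


@dataclass
class IntrogressionCall:
    """A contiguous run of SNPs with donor ancestry in one accession."""

    accession_id: str
    donor_pop: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    mean_posterior: float


def posterior_ancestry(
    panel: GenotypePanel, fit: AdmixtureFit, r: float
) -> LocalAncestry:
    """Exact HMM posteriors by scaled forward–backward, all accessions.

    The recursion is vectorized over accessions: the mixture-kernel
    transition (stay w.p. a = e^{-r d}, else re-draw from q_i) lets each
    forward update be a * alpha + (1 - a) * q_i without forming K x K
    matrices. Scaling factors give the exact per-accession log-likelihood.
    """
    if not np.isfinite(r) or r < 0:
        raise ValueError(f"switch rate must be finite and >= 0, got {r}")
    n, L = panel.calls.shape
    K = fit.K
    if fit.Q.shape[0] != n or fit.P.shape[1] != L:
        raise ValueError("fit dimensions do not match the panel")
    P = np.clip(fit.P, EPS, 1 - EPS)
    Q = np.clip(fit.Q, 1e-12, None)
    Q = Q / Q.sum(axis=1, keepdims=True)
    calls = panel.calls
    pos = panel.positions
    spans = chrom_spans(panel.chroms)

    post = np.empty((n, L, K))
    total_ll = 0.0
    for _, start, stop in spans:
        Lc = stop - start
        # emission[i, l, k]
        em = np.ones((n, Lc, K))
        seg = calls[:, start:stop]
        for k in range(K):
            pk = P[k, start:stop]
            em[:, :, k] = np.where(
                seg == 1, pk[None, :], np.where(seg == 0, 1 - pk[None, :], 1.0)
            )
        stay = np.exp(-r * np.diff(pos[start:stop]).astype(float))

        alpha = np.empty((Lc, n, K))
        scale = np.empty((Lc, n))
        a0 = Q * em[:, 0, :]
        scale[0] = a0.sum(axis=1)
        alpha[0] = a0 / scale[0][:, None]
        for j in range(1, Lc):
            a = stay[j - 1]
            pred = a * alpha[j - 1] + (1 - a) * Q
            unnorm = pred * em[:, j, :]
            scale[j] = unnorm.sum(axis=1)
            alpha[j] = unnorm / scale[j][:, None]

        beta = np.empty((Lc, n, K))
        beta[Lc - 1] = 1.0
        for j in range(Lc - 2, -1, -1):
            a = stay[j]
            nxt = em[:, j + 1, :] * beta[j + 1]
            mix = (Q * nxt).sum(axis=1)
            beta[j] = (a * nxt + (1 - a) * mix[:, None]) / scale[j + 1][:, None]

        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        post[:, start:stop, :] = np.moveaxis(gamma, 0, 1)
        total_ll += float(np.log(scale).sum())
    return LocalAncestry(
        posterior=post, switch_rate=r, source_fit=fit, loglik=total_ll
    )


def refine_local_ancestry(
    panel: GenotypePanel,
    fit: AdmixtureFit,
    tau: float = 0.2,
    n_burn: int = 6,
    r_burn: float = 1e-6,
    n_cool: int = 8,
    rate_grid: tuple[float, ...] = (1e-7, 2e-7, 3e-7, 5e-7),
) -> LocalAncestry:
    """Self-consistent linkage-model fit of local ancestry.

    The one-shot HMM conditions on the global admixture fit, which is blind
    to short introgressed blocks: a mostly-pure carrier's global q rounds its
    minor ancestry to ~0, and the recipient cluster's frequency estimates
    absorb the carriers' block genotypes, suppressing the very contrast the
    HMM needs. This routine re-estimates the cluster allele frequencies from
    the local-ancestry posteriors themselves (each SNP's genotype counts
    toward the cluster its posterior assigns it to), holding the ancestry
    prior fixed at the global Q mixed with uniform weight `tau` so every
    ancestry stays reachable for every accession.

    Two phases mirror the two-phase burn-in of Bayesian linkage-model fits:
    a permissive phase at switch rate `r_burn` lets candidate blocks seed the
    frequency updates, then the chain is cooled to the rate in `rate_grid`
    that maximizes the total HMM likelihood under the refined frequencies and
    iterated to convergence. Returns the posteriors at the cooled rate.
    """
    if not (0 <= tau < 1):
        raise ValueError("tau must be in [0, 1)")
    if n_burn < 1 or n_cool < 1:
        raise ValueError("n_burn and n_cool must be >= 1")
    if len(rate_grid) == 0:
        raise ValueError("empty rate grid")
    K = fit.K
    Q_prior = (1 - tau) * fit.Q + tau / K
    P = np.clip(fit.P, EPS, 1 - EPS)
    obs = panel.calls != MISSING
    g1 = (panel.calls == 1).astype(float)

    def fb(P: np.ndarray, r: float) -> LocalAncestry:
        work = AdmixtureFit(K=K, Q=Q_prior, P=P, loglik=np.nan, n_iter=0,
                            restart_index=fit.restart_index)
        return posterior_ancestry(panel, work, r)

    local = fb(P, r_burn)
    r_cold = rate_grid[0]
    for it in range(n_burn + n_cool):
        num = np.einsum("il,ilk->kl", g1 * obs, local.posterior)
        den = (local.posterior * obs[:, :, None]).sum(axis=0).T
        P = np.clip(
            np.divide(num, np.maximum(den, 1e-9)), EPS, 1 - EPS
        )
        if it == n_burn:
            lls = [fb(P, r).loglik for r in rate_grid]
            r_cold = float(rate_grid[int(np.argmax(lls))])
            logger.info("linkage-model cooled to switch rate %.3g", r_cold)
        local = fb(P, r_burn if it < n_burn else r_cold)
        logger.debug("linkage-model iteration %d: loglik %.2f", it + 1, local.loglik)
    return local


def _floor_rows(Q: np.ndarray, floor: float) -> np.ndarray:
    K = Q.shape[1]
    out = (1 - K * floor) * Q + floor
    return out / out.sum(axis=1, keepdims=True)


def hmm_loglik(panel: GenotypePanel, fit: AdmixtureFit, r: float) -> float:
    """Total forward log-likelihood over accessions at switch rate r."""
    return posterior_ancestry(panel, fit, r).loglik


def fit_switch_rate(
    panel: GenotypePanel, fit: AdmixtureFit, grid: list[float]
) -> float:
    """Grid maximum-likelihood estimate of the per-bp switch rate."""
    if len(grid) == 0:
        raise ValueError("empty switch-rate grid")
    for r in grid:
        if not (r > 0 and np.isfinite(r)):
            raise ValueError(f"grid rates must be positive and finite, got {r}")
    lls = [hmm_loglik(panel, fit, r) for r in grid]
    best = int(np.argmax(lls))
    logger.info(
        "switch-rate grid: best r=%.3g (loglik %.2f)", grid[best], lls[best]
    )
    return float(grid[best])


def mean_introgression(
    local: LocalAncestry,
    labels: list[str],
    recipient: str,
    donor: str,
    pop_names: list[str] | None = None,
) -> IntrogressionProfile:
    """Per-SNP mean donor component over the recipient subpopulation.

    The threshold is the top-5% cutoff of the per-SNP means: with nearest
    ranks, the smallest value among the ceil(0.05 L) largest means. Profile
    peaks above it mark loci where introgression exceeds background.
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    n, L, K = local.posterior.shape
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} accessions")
    names = pop_names or [f"cluster{k}" for k in range(K)]
    try:
        donor_idx = names.index(donor)
    except ValueError:
        raise ValueError(f"unknown donor population {donor!r}") from None
    rows = [i for i, lab in enumerate(labels) if lab == recipient]
    if not rows:
        raise ValueError(f"no accessions labeled {recipient!r}")
    values = local.posterior[rows, :, donor_idx].mean(axis=0)
    return IntrogressionProfile(
        recipient_pop=recipient,
        donor_pop=donor,
        values=values,
        threshold_95=top_percentile_cutoff(values, 0.05),
    )


def top_percentile_cutoff(values: np.ndarray, top_frac: float = 0.05) -> float:
    """Nearest-rank cutoff of the top `top_frac` of values: the smallest of
    the ceil(top_frac * n) largest values."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty value array")
    k = max(1, math.ceil(top_frac * n))
    return float(v[n - k])


def call_segments(
    local: LocalAncestry,
    panel: GenotypePanel,
    accession: str,
    donor: str,
    min_snps: int = 5,
    post_min: float = 0.5,
    pop_names: list[str] | None = None,
) -> list[IntrogressionCall]:
    """Introgressed segments: maximal runs of consecutive SNPs (within a
    chromosome) with donor posterior > `post_min`, kept when the run spans
    at least `min_snps` SNPs."""
    n, L, K = local.posterior.shape
    names = pop_names or [f"cluster{k}" for k in range(K)]
    try:
        donor_idx = names.index(donor)
    except ValueError:
        raise ValueError(f"unknown donor population {donor!r}") from None
    i = panel.accession_index(accession)
    donor_post = local.posterior[i, :, donor_idx]
    above = donor_post > post_min
    pos = panel.positions
    calls: list[IntrogressionCall] = []
    for chrom, start, stop in chrom_spans(panel.chroms):
        j = start
        while j < stop:
            if not above[j]:
                j += 1
                continue
            run_start = j
            while j < stop and above[j]:
                j += 1
            if j - run_start >= min_snps:
                calls.append(
                    IntrogressionCall(
                        accession_id=accession,
                        donor_pop=donor,
                        chrom=chrom,
                        start_bp=int(pos[run_start]),
                        end_bp=int(pos[j - 1]),
                        n_snps=j - run_start,
                        mean_posterior=float(donor_post[run_start:j].mean()),
                    )
                )
    return calls


def call_segments_all(
    local: LocalAncestry,
    panel: GenotypePanel,
    labels: list[str],
    pop_names: list[str],
    min_snps: int = 5,
    post_min: float = 0.5,
) -> list[IntrogressionCall]:
    """Segments for every accession and every donor differing from its
    assigned subpopulation (admixed accessions scan all donors)."""
    out: list[IntrogressionCall] = []
    for i, acc in enumerate(panel.accession_ids):
        for donor in pop_names:
            if donor == labels[i]:
                continue
            out.extend(
                call_segments(
                    local, panel, acc, donor,
                    min_snps=min_snps, post_min=post_min, pop_names=pop_names,
                )
            )
    return out
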
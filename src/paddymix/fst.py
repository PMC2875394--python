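"""Unbiased F_ST estimation between subpopulation groups.

Implements the Weir mean-square estimator for haploid samples, which corrects
for unequal sample sizes across groups. For each SNP with m groups of sizes
n_i and alt-allele frequencies p_i (computed over non-missing calls):

    pbar = sum(n_i p_i) / sum(n_i)
    MSG  = sum(n_i p_i (1 - p_i)) / sum(n_i - 1)        (within groups)
    MSP  = sum(n_i (p_i - pbar)^2) / (m - 1)            (between groups)
    n_c  = (sum(n_i) - sum(n_i^2)/sum(n_i)) / (m - 1)
    Fhat = (MSP - MSG) / (MSP + (n_c - 1) MSG)

Negative estimates, which have no biological meaning, are set to 0. The
genome-wide (and windowed) estimate is the ratio-of-sums
sum(MSP - MSG) / sum(MSP + (n_c - 1) MSG), again clamped at 0; the mean of
per-SNP values is also reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    """Per-SNP, genome-wide, and optionally windowed F_ST estimates.

    `per_snp` holds the clamped per-SNP estimates (NaN where fewer than two
    groups had >= 2 non-missing calls); `components` the (MSP, MSG, n_c)
    triples feeding the ratio-of-sums aggregate.
    """

    groups: tuple[str, ...]
    per_snp: np.ndarray
    msp: np.ndarray
    msg: np.ndarray
    n_c: np.ndarray
    n_na: int = 0
    windows: list[tuple[int, int, int, float, int]] = field(default_factory=list)

    @property
    def overall(self) -> float:
        return fst_overall(self)

    @property
    def mean_per_snp(self) -> float:
        """Mean of per-SNP estimates over non-NA SNPs (alternative aggregate)."""
        ok = ~np.isnan(self.per_snp)
        if not ok.any():
            raise ValueError("no SNP has a defined F_ST estimate")
        return float(self.per_snp[ok].mean())


def fst_per_snp(
    panel: GenotypePanel,
    labels: dict[str, str] | list[str],
    groups: list[str],
) -> FstResult:
    """Per-SNP unbiased F_ST across the given groups.

    `labels` maps accession id to group label (or lists labels in accession
    order); accessions outside `groups` are ignored. A SNP needs at least two
    groups with >= 2 non-missing calls; otherwise its estimate is NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    label_list = _as_label_list(panel, labels)
    members = [
        np.array([lab == g for lab in label_list]) for g in groups
    ]
    for g, mask in zip(groups, members):
        if not mask.any():
            raise ValueError(f"group {g!r} has no accessions")

    obs = panel.calls != MISSING
    alt = (panel.calls == 1)
    L = panel.n_markers
    m_groups = len(groups)

    n_i = np.empty((m_groups, L))
    p_i = np.empty((m_groups, L))
    for gi, mask in enumerate(members):
        n = obs[mask].sum(axis=0)
        a = alt[mask].sum(axis=0)
        n_i[gi] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[gi] = np.where(n > 0, a / np.maximum(n, 1), np.nan)

    eligible = n_i >= 2
    m_eff = eligible.sum(axis=0)
    defined = m_eff >= 2

    # Work only with eligible groups per SNP.
    n_e = np.where(eligible, n_i, 0.0)
    p_e = np.where(eligible, p_i, 0.0)
    n_tot = n_e.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n_e * p_e).sum(axis=0) / n_tot
        msg = (n_e * p_e * (1 - p_e)).sum(axis=0) / np.where(
            eligible, n_e - 1, 0.0
        ).sum(axis=0)
        msp = (n_e * (p_e - pbar) ** 2 * eligible).sum(axis=0) / (m_eff - 1)
        n_c = (n_tot - (n_e**2).sum(axis=0) / n_tot) / (m_eff - 1)
        denom = msp + (n_c - 1) * msg
        raw = np.where(denom > 0, (msp - msg) / np.where(denom != 0, denom, 1.0), np.nan)

    per_snp = np.where(defined, np.maximum(raw, 0.0), np.nan)
    msp = np.where(defined, msp, np.nan)
    msg = np.where(defined, msg, np.nan)
    n_c = np.where(defined, n_c, np.nan)
    n_na = int((~defined).sum())
    if n_na:
        logger.warning("F_ST undefined at %d of %d SNPs", n_na, L)
    return FstResult(
        groups=tuple(groups), per_snp=per_snp, msp=msp, msg=msg, n_c=n_c, n_na=n_na
    )


def _as_label_list(panel: GenotypePanel, labels) -> list[str]:
    if isinstance(labels, dict):
        return [labels.get(a, "") for a in panel.accession_ids]
    labels = list(labels)
    if len(labels) != panel.n_accessions:
        raise ValueError(
            f"{len(labels)} labels for {panel.n_accessions} accessions"
        )
    return [str(x) for x in labels]


def _ratio_of_sums(msp: np.ndarray, msg: np.ndarray, n_c: np.ndarray) -> float:
    ok = ~np.isnan(msp)
    if not ok.any():
        raise ValueError("no SNP has a defined F_ST estimate")
    num = (msp[ok] - msg[ok]).sum()
    den = (msp[ok] + (n_c[ok] - 1) * msg[ok]).sum()
    if den <= 0:
        return 0.0
    return float(max(num / den, 0.0))


def fst_overall(result: FstResult) -> float:
    """Genome-wide ratio-of-sums estimate, clamped at 0."""
    return _ratio_of_sums(result.msp, result.msg, result.n_c)


def fst_windows(
    result: FstResult, panel: GenotypePanel, window_bp: int = 100_000
) -> FstResult:
    """Tile each chromosome into half-open windows and aggregate within them.

    Windows are [k*window_bp, (k+1)*window_bp) from 0 up to the last marker;
    each window's estimate is the ratio-of-sums over the SNPs inside. Empty
    windows are reported with NaN and n_snps = 0.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    if len(result.per_snp) != panel.n_markers:
        raise ValueError("result and panel have different SNP counts")
    chroms = panel.chroms
    pos = panel.positions
    windows: list[tuple[int, int, int, float, int]] = []
    for chrom in sorted(set(chroms.tolist())):
        on = chroms == chrom
        chrom_end = int(pos[on].max())
        n_win = chrom_end // window_bp + 1
        for w in range(n_win):
            lo, hi = w * window_bp, (w + 1) * window_bp
            inside = on & (pos >= lo) & (pos < hi)
            n_snps = int((inside & ~np.isnan(result.per_snp)).sum())
            if n_snps == 0:
                windows.append((chrom, lo, hi, np.nan, 0))
                continue
            fhat = _ratio_of_sums(
                np.where(inside, result.msp, np.nan),
                result.msg,
                result.n_c,
            )
            windows.append((chrom, lo, hi, fhat, n_snps))
    return FstResult(
        groups=result.groups,
        per_snp=result.per_snp,
        msp=result.msp,
        msg=result.msg,
        n_c=result.n_c,
        n_na=result.n_na,
        windows=windows,
    )


def pairwise_fst_table(
    panel: GenotypePanel,
    labels: dict[str, str] | list[str],
    groups: list[str],
) -> dict[tuple[str, str], float]:
    """Genome-wide F_ST for every unordered pair of groups."""
    out: dict[tuple[str, str], float] = {}
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            res = fst_per_snp(panel, labels, [groups[a], groups[b]])
            out[(groups[a], groups[b])] = fst_overall(res)
    return out
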
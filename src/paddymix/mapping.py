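"""Trait mapping: admixture mapping and mixed-model association.

Two complementary strategies for localizing trait loci in a structured
inbred panel:

* **Admixture mapping** — within the admixed accessions, regress the trait
  on the posterior donor-ancestry component at each SNP (ordinary least
  squares, t-test on the slope). Ancestry blocks span many SNPs, so the
  signal extends around a causal locus even when no genotyped SNP tags it.
* **Mixed-model association** — over the full panel, test each SNP in
  y = mu + SNP b + Q g + u + e with a polygenic random effect
  u ~ N(0, sg^2 KIN), where KIN is the allele-sharing kinship. The variance
  ratio is estimated once by REML on the null (no-SNP) model through a
  single eigendecomposition of KIN, then reused for every SNP's generalized
  least squares (the population-parameters-previously-determined
  approximation); one Q column is dropped against the intercept.

Both report per-SNP effect, standard error and two-sided p-value, plus the
Bonferroni threshold alpha / (number of tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .ancestry import LocalAncestry
from .panel import MISSING, GenotypePanel
from .tree import allele_sharing_distance

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeTable:
    """Trait means per accession (averages over replicate measurements)."""

    trait: str
    values: dict[str, float]
    units: str = ""

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite phenotype for accession {bad[0]!r}")

    def vector_for(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """(values, availability mask) aligned to `ids`."""
        y = np.full(len(ids), np.nan)
        for i, a in enumerate(ids):
            if a in self.values:
                y[i] = self.values[a]
        return y, ~np.isnan(y)


@dataclass
class KinshipMatrix:
    """Allele-sharing similarity, 1 - allele-sharing distance."""

    ids: list[str]
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if not np.allclose(self.k, self.k.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")


@dataclass
class MappingResult:
    method: str
    marker_ids: list[str]
    effect: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    n_used: np.ndarray
    bonferroni_threshold: float = np.nan
    significant: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_tests(self) -> int:
        return int((~np.isnan(self.p_value)).sum())


def read_phenotype_tsv(path, trait: str | None = None) -> PhenotypeTable:
    """Two-column TSV (accession id, value), optional header."""
    values: dict[str, float] = {}
    name = trait or "trait"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and not _is_float(parts[1]):
                name = trait or parts[1]
                continue
            values[parts[0]] = float(parts[1])
    return PhenotypeTable(trait=name, values=values)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# admixture mapping


def admixture_map(
    local: LocalAncestry,
    panel: GenotypePanel,
    phenotype: PhenotypeTable,
    subset: list[str],
    donor: str,
    pop_names: list[str] | None = None,
) -> MappingResult:
    """Regress the trait on the donor-ancestry component, SNP by SNP.

    `subset` is normally the admixed class. SNPs where the donor component
    does not vary across the subset get NA. Accessions without a phenotype
    are dropped (logged).
    """
    n, L, K = local.posterior.shape
    names = pop_names or [f"cluster{k}" for k in range(K)]
    donor_idx = names.index(donor)
    rows = [panel.accession_index(a) for a in subset]
    y_all, have = phenotype.vector_for([panel.accession_ids[r] for r in rows])
    n_missing = int((~have).sum())
    if n_missing:
        logger.info("admixture mapping: dropping %d accessions without phenotype", n_missing)
    rows = [r for r, h in zip(rows, have) if h]
    y = y_all[have]
    if len(rows) < 3:
        raise ValueError("need >= 3 phenotyped accessions in the subset")
    X = local.posterior[rows, :, donor_idx]   # n_sub x L
    effect, se, pval = _ols_scan(X, y)
    if np.isnan(pval).all():
        raise ValueError("donor ancestry component is constant at every SNP")
    return MappingResult(
        method="admixture_map",
        marker_ids=list(panel.marker_ids),
        effect=effect,
        se=se,
        p_value=pval,
        n_used=np.full(L, len(rows)),
        extras={"donor": donor, "subset_size": len(rows)},
    )


def _ols_scan(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simple OLS of y on each column of X (with intercept)."""
    n, L = X.shape
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    varies = sxx > 1e-24
    sxy = xc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(varies, sxy / np.where(varies, sxx, 1.0), np.nan)
        resid_ss = (yc**2).sum() - beta**2 * sxx
        df = n - 2
        sigma2 = resid_ss / df
        se = np.sqrt(np.maximum(sigma2, 0) / np.where(varies, sxx, 1.0))
        t = beta / se
    pval = np.where(varies, 2 * stats.t.sf(np.abs(t), df), np.nan)
    se = np.where(varies, se, np.nan)
    return beta, se, pval


# ---------------------------------------------------------------------------
# kinship and mixed model


def kinship_matrix(panel: GenotypePanel) -> KinshipMatrix:
    """Genetic relatedness as allele-sharing similarity (1 - distance)."""
    D = allele_sharing_distance(panel)
    return KinshipMatrix(ids=D.ids, k=1.0 - D.d)


def mixed_model_assoc(
    panel: GenotypePanel,
    phenotype: PhenotypeTable,
    Q: np.ndarray | None,
    kin: KinshipMatrix,
) -> MappingResult:
    """Per-SNP mixed-model association with a polygenic random effect.

    The null model y = mu + Q g + u + e is fit by REML over the heritability
    ratio h = sg^2/(sg^2+se^2) using the eigendecomposition of the kinship;
    each SNP is then tested by generalized least squares in the rotated
    coordinates with a Wald t-test on its effect.
    """
    ids = panel.accession_ids
    if kin.ids != ids:
        raise ValueError("kinship ids do not match the panel")
    y_all, have = phenotype.vector_for(ids)
    idx = np.flatnonzero(have)
    y = y_all[idx]
    n = len(idx)

    X0_cols = [np.ones(n)]
    if Q is not None:
        Qm = np.asarray(Q, dtype=float)
        if Qm.shape[0] != len(ids):
            raise ValueError("Q rows do not match the panel")
        # drop one column: rows sum to 1, collinear with the intercept
        X0_cols.extend(Qm[idx, :-1].T)
    X0 = np.column_stack(X0_cols)
    X0 = _drop_collinear(X0)
    p0 = X0.shape[1]
    if n < p0 + 3:
        raise ValueError("too few phenotyped accessions for the fixed effects")

    Kmat = kin.k[np.ix_(idx, idx)]
    w, U = np.linalg.eigh((Kmat + Kmat.T) / 2)
    if w.min() < -1e-8:
        raise ValueError(f"kinship is not PSD (min eigenvalue {w.min():.3g})")
    w = np.clip(w, 0.0, None)

    yr = U.T @ y
    X0r = U.T @ X0
    h_hat = _reml_h(yr, X0r, w)
    logger.info("REML heritability ratio on the null model: h=%.4f", h_hat)
    v = h_hat * w + (1 - h_hat)      # rotated residual variances (up to scale)
    sw = 1.0 / np.sqrt(v)

    calls = panel.calls[idx, :].astype(float)
    miss = panel.calls[idx, :] == MISSING
    if miss.any():
        freqs = np.where(
            miss, np.nan, calls
        )
        colmean = np.nanmean(np.where(miss, np.nan, calls), axis=0)
        colmean = np.where(np.isnan(colmean), 0.0, colmean)
        calls = np.where(miss, colmean[None, :], calls)

    Xr = U.T @ calls                  # rotated SNP columns
    yw = yr * sw
    X0w = X0r * sw[:, None]
    Xw = Xr * sw[:, None]

    # Residualize y and each SNP on the null fixed effects (FWL theorem),
    # then the SNP effect is a simple weighted regression per SNP.
    Q0, _ = np.linalg.qr(X0w)
    y_res = yw - Q0 @ (Q0.T @ yw)
    X_res = Xw - Q0 @ (Q0.T @ Xw)
    df = n - p0 - 1
    sxx = (X_res**2).sum(axis=0)
    varies = sxx > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(varies, (X_res.T @ y_res) / np.where(varies, sxx, 1.0), np.nan)
        rss = (y_res**2).sum() - beta**2 * sxx
        sigma2 = rss / df
        se = np.sqrt(np.maximum(sigma2, 0) / np.where(varies, sxx, 1.0))
        t = beta / se
    pval = np.where(varies, 2 * stats.t.sf(np.abs(t), df), np.nan)
    se = np.where(varies, se, np.nan)
    n_dropped = int((~varies).sum())
    if n_dropped:
        logger.warning("%d SNPs collinear with the null design; reported NA", n_dropped)
    return MappingResult(
        method="mixed_model",
        marker_ids=list(panel.marker_ids),
        effect=beta,
        se=se,
        p_value=pval,
        n_used=np.full(panel.n_markers, n),
        extras={"h_reml": h_hat, "n_fixed": p0},
    )


def _drop_collinear(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Keep a maximal independent subset of columns (QR with pivoting)."""
    keep: list[int] = []
    basis: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        for b in basis:
            v = v - b * (b @ X[:, j])
        norm = np.linalg.norm(v)
        if norm > tol * max(1.0, np.linalg.norm(X[:, j])):
            basis.append(v / norm)
            keep.append(j)
        else:
            logger.warning("dropping collinear fixed-effect column %d", j)
    return X[:, keep]


def reml_neg_loglik(h: float, yr: np.ndarray, X0r: np.ndarray, w: np.ndarray) -> float:
    """Negative restricted log-likelihood at heritability ratio h, in the
    eigenbasis of the kinship (profile over the scale parameter)."""
    n, p = X0r.shape
    v = h * w + (1 - h)
    if (v <= 0).any():
        return np.inf
    sw = 1.0 / np.sqrt(v)
    Xw = X0r * sw[:, None]
    yw = yr * sw
    XtX = Xw.T @ Xw
    try:
        beta = np.linalg.solve(XtX, Xw.T @ yw)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        return np.inf
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.log(v).sum()
        + logdet_XtX
        + (n - p)
    )
    return -ll


def _reml_h(yr: np.ndarray, X0r: np.ndarray, w: np.ndarray) -> float:
    """Maximize the restricted likelihood over h in [0, 1)."""
    obj = lambda h: reml_neg_loglik(h, yr, X0r, w)
    # coarse grid to bracket the optimum, then bounded refinement
    grid = np.linspace(0.0, 0.999, 40)
    vals = [obj(h) for h in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


# ---------------------------------------------------------------------------
# multiple testing


def bonferroni(result: MappingResult, alpha: float = 0.05) -> MappingResult:
    """Attach the Bonferroni threshold alpha / n_tests and significance flags."""
    n_tests = result.n_tests
    if n_tests == 0:
        raise ValueError("no non-NA p-values")
    thr = alpha / n_tests
    result.bonferroni_threshold = thr
    with np.errstate(invalid="ignore"):
        result.significant = np.where(
            np.isnan(result.p_value), False, result.p_value <= thr
        )
    return result
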
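"""Synthetic genotype panels with known population structure.

The generator emulates the data structure of a diverse inbred rice panel
genotyped on a sparse genome-wide SNP array:

* K diverged subpopulations whose allele frequencies follow the
  Balding–Nichols model around a shared ancestral frequency, with
  per-subpopulation divergence parameters F_k;
* mostly-pure accessions plus a minority of admixed ones whose genomes are
  Markov ancestry mosaics along each chromosome;
* shared introgression blocks: the same donor-ancestry interval carried by
  many accessions of a recipient subpopulation, as produced by artificial
  selection on an introgressed allele;
* quantitative traits controlled by one or a few causal SNPs whose allele
  frequencies differ between subpopulations.

Every draw goes through a single numpy Generator, so a config plus seed is
fully reproducible. The generator returns both the observable panel and a
`SyntheticTruth` with the latent quantities (ancestry proportions, local
ancestry, ancestral frequencies, carriers) that downstream tests score
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import ADMIXED, AccessionRecord, GenotypePanel, SNPMarker

#: Default subpopulation names, mirroring the five major rice groups.
DEFAULT_POPS = (
    "indica",
    "aus",
    "tropical_japonica",
    "temperate_japonica",
    "group_v",
)

#: Default Balding–Nichols divergence per subpopulation. Chosen so pairwise
#: F_ST (≈ (F_i + F_j)/2 between two subpopulations) spans roughly 0.23–0.53,
#: the range observed between the five rice groups: the closest pair
#: (indica–aus) sits near 0.23 and the most diverged pairs near 0.5.
DEFAULT_F = (0.20, 0.26, 0.40, 0.60, 0.45)

#: Pure accessions per subpopulation (sums to 305; with 90 admixed the panel
#: matches the 395-accession study design, including the small group_v).
DEFAULT_N_PURE = (77, 57, 97, 60, 14)


@dataclass(frozen=True)
class IntrogressionEvent:
    """A shared donor block: `carrier_fraction` of the recipient
    subpopulation carries donor ancestry over [start_bp, end_bp]."""

    donor: int
    recipient: int
    chrom: int
    start_bp: int
    end_bp: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in [0, 1]")
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel generator.

    `markers_per_chrom` and `spacing_bp` lay markers at a regular physical
    spacing on each chromosome (12 chromosomes of ~109 markers at 260 kb by
    default, ≈1,300 SNPs genome-wide). `switch_rate` is the expected number
    of ancestry switches per bp in admixed mosaics.
    """

    K: int = 5
    F_k: tuple[float, ...] = DEFAULT_F
    pop_names: tuple[str, ...] = DEFAULT_POPS
    n_pure_per_pop: tuple[int, ...] = DEFAULT_N_PURE
    n_admixed: int = 90
    markers_per_chrom: tuple[int, ...] = (109,) * 12
    spacing_bp: int = 260_000
    base_freq_range: tuple[float, float] = (0.1, 0.9)
    switch_rate: float = 1e-8
    admix_alpha: float = 0.5
    introgression_events: tuple[IntrogressionEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.F_k) != self.K or len(self.n_pure_per_pop) != self.K:
            raise ValueError("F_k and n_pure_per_pop must have length K")
        if len(self.pop_names) != self.K:
            raise ValueError("pop_names must have length K")
        for F in self.F_k:
            if not (0 <= F < 1):
                raise ValueError(f"F_k values must be in [0, 1), got {F}")
        if self.n_admixed < 0 or any(n < 0 for n in self.n_pure_per_pop):
            raise ValueError("accession counts must be >= 0")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")
        n_chrom = len(self.markers_per_chrom)
        for ev in self.introgression_events:
            if not (1 <= ev.chrom <= n_chrom):
                raise ValueError(f"event chrom {ev.chrom} outside layout")
            chrom_len = self.markers_per_chrom[ev.chrom - 1] * self.spacing_bp
            if ev.end_bp > chrom_len:
                raise ValueError(
                    f"event interval end {ev.end_bp} beyond chromosome "
                    f"{ev.chrom} length {chrom_len}"
                )
            if not (0 <= ev.donor < self.K and 0 <= ev.recipient < self.K):
                raise ValueError("event donor/recipient outside 0..K-1")
            if ev.donor == ev.recipient:
                raise ValueError("event donor equals recipient")

    @property
    def L(self) -> int:
        return int(sum(self.markers_per_chrom))

    @property
    def n_accessions(self) -> int:
        return int(sum(self.n_pure_per_pop)) + self.n_admixed


@dataclass
class SyntheticTruth:
    """Latent ground truth behind a simulated panel."""

    pop_names: tuple[str, ...]
    Q_true: np.ndarray                    # n x K, rows sum to 1
    local_ancestry_true: np.ndarray       # n x L, entries in 0..K-1
    ancestral_freqs: np.ndarray           # K x L
    labels_true: list[str]                # pop name or ADMIXED
    causal_loci: list[tuple[int, float]] = field(default_factory=list)
    introgression_carriers: dict[int, list[str]] = field(default_factory=dict)


def draw_subpop_freqs(
    K: int,
    L: int,
    base_freq_range: tuple[float, float] = (0.1, 0.9),
    F_k: tuple[float, ...] | np.ndarray = (0.2,),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Balding–Nichols subpopulation allele frequencies.

    Per locus l an ancestral frequency p_l is drawn uniform on
    `base_freq_range`; each subpopulation's frequency is then an independent
    Beta(p_l (1-F_k)/F_k, (1-p_l)(1-F_k)/F_k) draw. F_k = 0 is the
    no-divergence limit p_kl = p_l.
    """
    if K < 1 or L < 1:
        raise ValueError("K and L must be >= 1")
    F = np.asarray(F_k, dtype=float)
    if F.shape != (K,):
        raise ValueError(f"F_k must have length K={K}")
    if ((F < 0) | (F >= 1)).any():
        raise ValueError("F_k values must be in [0, 1)")
    rng = _as_rng(seed)
    lo, hi = base_freq_range
    if not (0 < lo <= hi < 1):
        raise ValueError("base_freq_range must satisfy 0 < lo <= hi < 1")
    p_anc = rng.uniform(lo, hi, size=L)
    P = np.empty((K, L))
    for k in range(K):
        if F[k] == 0:
            P[k] = p_anc
        else:
            ratio = (1 - F[k]) / F[k]
            P[k] = rng.beta(p_anc * ratio, (1 - p_anc) * ratio)
    return P


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypePanel, SyntheticTruth]:
    """Draw a genotype panel and its ground truth from `config`."""
    if config.n_accessions == 0:
        raise ValueError("config defines zero accessions")
    rng = np.random.default_rng(config.seed)
    K, L = config.K, config.L

    markers = _layout_markers(config)
    P = draw_subpop_freqs(
        K, L, config.base_freq_range, config.F_k, seed=rng
    )

    # --- global ancestry -------------------------------------------------
    n = config.n_accessions
    Q = np.zeros((n, K))
    labels: list[str] = []
    acc_ids: list[str] = []
    pop_of_pure: list[int] = []
    i = 0
    for k, n_k in enumerate(config.n_pure_per_pop):
        for j in range(n_k):
            Q[i, k] = 1.0
            labels.append(config.pop_names[k])
            acc_ids.append(f"{config.pop_names[k]}_{j + 1}")
            pop_of_pure.append(k)
            i += 1
    for j in range(config.n_admixed):
        # Two- or (rarely) three-way admixture between random subpopulations.
        n_src = 2 if K == 2 or rng.random() < 0.8 else 3
        n_src = min(n_src, K)
        srcs = rng.choice(K, size=n_src, replace=False)
        w = rng.dirichlet(np.full(n_src, config.admix_alpha))
        Q[i, srcs] = w
        labels.append(ADMIXED)
        acc_ids.append(f"adm_{j + 1}")
        i += 1

    # --- local ancestry mosaics ------------------------------------------
    pos = np.array([m.pos_bp for m in markers])
    chroms = np.array([m.chrom for m in markers])
    A = np.empty((n, L), dtype=np.int64)
    n_pure = sum(config.n_pure_per_pop)
    for idx in range(n_pure):
        A[idx] = pop_of_pure[idx]
    for idx in range(n_pure, n):
        A[idx] = _ancestry_mosaic(
            Q[idx], chroms, pos, config.switch_rate, rng
        )

    # --- shared introgression blocks -------------------------------------
    # Every carrier gets donor ancestry over the same interval (a shared
    # selected segment); genotypes inside the block are then drawn from the
    # donor's allele frequencies like any other donor-ancestry region.
    carriers_by_event: dict[int, list[str]] = {}
    for ev_idx, ev in enumerate(config.introgression_events):
        recip_rows = [
            r for r in range(n_pure) if pop_of_pure[r] == ev.recipient
        ]
        n_carry = int(round(ev.carrier_fraction * len(recip_rows)))
        chosen = sorted(
            rng.choice(len(recip_rows), size=n_carry, replace=False).tolist()
        )
        rows = [recip_rows[c] for c in chosen]
        in_block = (
            (chroms == ev.chrom) & (pos >= ev.start_bp) & (pos <= ev.end_bp)
        )
        for r in rows:
            A[r, in_block] = ev.donor
        carriers_by_event[ev_idx] = [acc_ids[r] for r in rows]

    # --- genotype calls ---------------------------------------------------
    p_site = P[A, np.arange(L)[None, :]]
    calls = (rng.random((n, L)) < p_site).astype(np.int8)

    panel = GenotypePanel(
        markers=markers,
        accessions=[AccessionRecord(id=a) for a in acc_ids],
        calls=calls,
    )
    truth = SyntheticTruth(
        pop_names=config.pop_names,
        Q_true=Q,
        local_ancestry_true=A,
        ancestral_freqs=P,
        labels_true=labels,
        introgression_carriers=carriers_by_event,
    )
    return panel, truth


def _layout_markers(config: SimulationConfig) -> list[SNPMarker]:
    markers = []
    for c, n_m in enumerate(config.markers_per_chrom, start=1):
        for j in range(n_m):
            markers.append(
                SNPMarker(
                    id=f"c{c}m{j + 1}",
                    chrom=c,
                    pos_bp=(j + 1) * config.spacing_bp,
                )
            )
    return markers


def _ancestry_mosaic(
    q: np.ndarray,
    chroms: np.ndarray,
    pos: np.ndarray,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Markov mosaic: stay with prob e^{-r d} between adjacent markers, else
    redraw the ancestry from q; chromosomes restart independently."""
    L = len(pos)
    out = np.empty(L, dtype=np.int64)
    K = len(q)
    state = -1
    for j in range(L):
        if j == 0 or chroms[j] != chroms[j - 1]:
            state = int(rng.choice(K, p=q))
        else:
            d = pos[j] - pos[j - 1]
            if rng.random() >= np.exp(-switch_rate * d):
                state = int(rng.choice(K, p=q))
        out[j] = state
    return out


def simulate_phenotype(
    truth: SyntheticTruth,
    panel: GenotypePanel,
    causal: list[tuple[int, float]],
    h2: float,
    seed: int | np.random.Generator = 0,
):
    """Quantitative trait from additive causal SNPs plus Gaussian noise.

    y_i = sum_c effect_c * g_ic + e_i, with the noise variance set to
    Vg (1 - h2) / h2 so the genetic fraction of the total variance is h2 in
    expectation (Vg = variance of the genetic values across the panel).
    Missing causal calls contribute the panel allele frequency. h2 = 0 gives
    pure unit-variance noise, independent of genotype.
    """
    from .mapping import PhenotypeTable

    if not (0 <= h2 <= 1):
        raise ValueError("h2 must be in [0, 1]")
    rng = _as_rng(seed)
    n = panel.n_accessions
    freqs = panel.allele_freq()
    g_val = np.zeros(n)
    for marker_idx, effect in causal:
        if not (0 <= marker_idx < panel.n_markers):
            raise ValueError(f"causal marker index {marker_idx} out of range")
        col = panel.calls[:, marker_idx].astype(float)
        col[panel.calls[:, marker_idx] == -1] = freqs[marker_idx]
        g_val += effect * col
    truth.causal_loci = list(causal)
    if h2 == 0:
        y = rng.standard_normal(n)
    else:
        vg = float(np.var(g_val))
        if vg == 0:
            raise ValueError(
                "h2 > 0 requested but the causal loci carry no genetic variance"
            )
        sigma_e = 0.0 if h2 == 1 else np.sqrt(vg * (1 - h2) / h2)
        y = g_val + sigma_e * rng.standard_normal(n)
    return PhenotypeTable(
        trait="synthetic_trait",
        values=dict(zip(panel.accession_ids, y.tolist())),
        units="arbitrary",
    )


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
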
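"""Core genotype-panel container for inbred SNP data.

Accessions are inbred lines, so every call is haploid-coded: 0 (reference
allele), 1 (alternate allele), or -1 (missing). The panel bundles the call
matrix with its marker map (chromosome, bp position, alleles) and accession
metadata, and is the substrate of every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

#: Sentinel subpopulation labels used on accession records.
UNASSIGNED = "UNASSIGNED"
ADMIXED = "ADMIXED"


class PanelValidationError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass(frozen=True)
class SNPMarker:
    """A biallelic SNP with 1-based physical coordinates."""

    id: str
    chrom: int
    pos_bp: int
    allele_ref: str = "A"
    allele_alt: str = "G"

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise PanelValidationError(
                f"marker {self.id}: pos_bp must be >= 1, got {self.pos_bp}"
            )
        if self.chrom < 1:
            raise PanelValidationError(
                f"marker {self.id}: chrom must be a positive integer"
            )
        if self.allele_ref == self.allele_alt:
            raise PanelValidationError(
                f"marker {self.id}: ref and alt alleles are identical"
            )


@dataclass
class AccessionRecord:
    """One inbred accession; `assigned_subpop` is set by classification."""

    id: str
    name: str = ""
    assigned_subpop: str = UNASSIGNED


@dataclass
class GenotypePanel:
    """Accessions x markers haploid call matrix with metadata.

    `calls` is an int8 matrix with entries in {0, 1, MISSING}; rows follow
    `accessions`, columns follow `markers`. Markers must be sorted by
    (chrom, pos_bp) with strictly increasing positions within a chromosome.
    """

    markers: list[SNPMarker]
    accessions: list[AccessionRecord]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        n, L = self.calls.shape
        if n != len(self.accessions) or L != len(self.markers):
            raise PanelValidationError(
                f"call matrix is {n}x{L} but panel has "
                f"{len(self.accessions)} accessions and {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelValidationError(
                f"call[{i},{j}] = {self.calls[i, j]} outside {{0, 1, {MISSING}}}"
            )
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise PanelValidationError(f"duplicate marker id {dup!r}")
        acc_ids = [a.id for a in self.accessions]
        if len(set(acc_ids)) != len(acc_ids):
            raise PanelValidationError("duplicate accession ids")
        prev: tuple[int, int] | None = None
        for m in self.markers:
            key = (m.chrom, m.pos_bp)
            if prev is not None and key <= prev:
                raise PanelValidationError(
                    f"markers not sorted by (chrom, pos_bp) at {m.id!r}"
                )
            prev = key

    # -- convenience views -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def accession_ids(self) -> list[str]:
        return [a.id for a in self.accessions]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def chroms(self) -> np.ndarray:
        return np.array([m.chrom for m in self.markers], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos_bp for m in self.markers], dtype=np.int64)

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls (NaN if none)."""
        obs = self.observed()
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, alt / np.maximum(n_obs, 1), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (~self.observed()).mean(axis=0)

    def subset_markers(self, index: np.ndarray) -> "GenotypePanel":
        """New panel restricted to the marker columns in `index` (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            markers=[self.markers[int(j)] for j in index],
            accessions=[replace_record(a) for a in self.accessions],
            calls=self.calls[:, index].copy(),
        )

    def subset_accessions(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            markers=list(self.markers),
            accessions=[replace_record(self.accessions[int(i)]) for i in index],
            calls=self.calls[index, :].copy(),
        )

    def accession_index(self, acc_id: str) -> int:
        try:
            return self.accession_ids.index(acc_id)
        except ValueError:
            raise KeyError(f"accession {acc_id!r} not in panel") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.markers == other.markers
            and [(a.id, a.name, a.assigned_subpop) for a in self.accessions]
            == [(a.id, a.name, a.assigned_subpop) for a in other.accessions]
            and np.array_equal(self.calls, other.calls)
        )


def replace_record(a: AccessionRecord) -> AccessionRecord:
    return AccessionRecord(id=a.id, name=a.name, assigned_subpop=a.assigned_subpop)


def chrom_spans(chroms: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (chrom, start, stop) column spans of a sorted chrom vector."""
    spans = []
    start = 0
    for j in range(1, len(chroms) + 1):
        if j == len(chroms) or chroms[j] != chroms[start]:
            spans.append((int(chroms[start]), start, j))
            start = j
    return spans
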
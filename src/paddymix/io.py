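"""Reading, writing, and QC of genotype panels.

Three interchange formats are supported:

* ``tsv_matrix`` — header row of marker ids, first column the accession id,
  cells ``0``/``1``/``NA``; a sidecar map file (``<path>.map``) holds marker
  id, chromosome, bp position, ref and alt alleles.
* ``vcf`` — VCF v4.2; haploid-coded calls are represented as homozygous
  diploid genotypes (0 -> 0/0, 1 -> 1/1, missing -> ./.). Heterozygous input
  genotypes are resolved by the het policy below.
* ``structure`` — plain-text STRUCTURE input, two integer rows per
  individual, missing coded as -9.

Heterozygous diploid input: inbred accessions should be homozygous, so a het
call is either set to missing (``het_as_missing``, the default) or collapsed
to the panel's majority allele at that SNP (``het_as_major``).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Literal

import numpy as np

from .panel import (
    MISSING,
    AccessionRecord,
    GenotypePanel,
    PanelValidationError,
    SNPMarker,
)

logger = logging.getLogger(__name__)

Format = Literal["tsv_matrix", "vcf", "structure"]
HetPolicy = Literal["het_as_missing", "het_as_major"]

_FORMATS = ("tsv_matrix", "vcf", "structure")


class PanelParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def map_path_for(path: str | Path) -> Path:
    """Sidecar marker-map path for a TSV matrix file."""
    return Path(str(path) + ".map")


# ---------------------------------------------------------------------------
# reading


def read_panel(
    path: str | Path,
    format: Format = "tsv_matrix",
    het_policy: HetPolicy = "het_as_missing",
) -> GenotypePanel:
    """Read and validate a genotype panel.

    Markers are sorted by (chrom, pos_bp) on load. For VCF input only
    biallelic SNP records are kept; others are skipped with a warning.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv_matrix":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path, het_policy)
    return _read_structure(path, het_policy)


def _build_sorted(markers, accessions, calls, source: Path) -> GenotypePanel:
    order = sorted(
        range(len(markers)), key=lambda j: (markers[j].chrom, markers[j].pos_bp)
    )
    try:
        return GenotypePanel(
            markers=[markers[j] for j in order],
            accessions=accessions,
            calls=calls[:, order],
        )
    except PanelValidationError as exc:
        raise PanelParseError(f"{source}: {exc}") from exc


def _read_tsv(path: Path) -> GenotypePanel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise PanelParseError(f"{path}:1: empty header")
        marker_ids = header.split("\t")[1:]
        acc_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(marker_ids) + 1:
                raise PanelParseError(
                    f"{path}:{lineno}: expected {len(marker_ids) + 1} columns, "
                    f"got {len(parts)}"
                )
            acc_ids.append(parts[0])
            row = []
            for col, cell in enumerate(parts[1:], start=2):
                if cell == "NA":
                    row.append(MISSING)
                elif cell in ("0", "1"):
                    row.append(int(cell))
                else:
                    raise PanelParseError(
                        f"{path}:{lineno}: bad call {cell!r} in column {col}"
                    )
            rows.append(row)
    markers = _read_map(map_path_for(path), marker_ids)
    accessions = [AccessionRecord(id=a) for a in acc_ids]
    calls = np.array(rows, dtype=np.int8).reshape(len(acc_ids), len(marker_ids))
    return _build_sorted(markers, accessions, calls, path)


def _read_map(path: Path, marker_ids: list[str]) -> list[SNPMarker]:
    if not path.exists():
        # Positions default to marker order on one pseudo-chromosome.
        return [
            SNPMarker(id=m, chrom=1, pos_bp=j + 1)
            for j, m in enumerate(marker_ids)
        ]
    by_id: dict[str, SNPMarker] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PanelParseError(f"{path}:{lineno}: expected >=3 columns")
            mid = parts[0]
            if mid in by_id:
                raise PanelParseError(f"{path}:{lineno}: duplicate marker id {mid!r}")
            ref = parts[3] if len(parts) > 3 else "A"
            alt = parts[4] if len(parts) > 4 else "G"
            try:
                by_id[mid] = SNPMarker(
                    id=mid, chrom=int(parts[1]), pos_bp=int(parts[2]),
                    allele_ref=ref, allele_alt=alt,
                )
            except (ValueError, PanelValidationError) as exc:
                raise PanelParseError(f"{path}:{lineno}: {exc}") from exc
    missing = [m for m in marker_ids if m not in by_id]
    if missing:
        raise PanelParseError(f"{path}: no map entry for marker {missing[0]!r}")
    return [by_id[m] for m in marker_ids]


def _read_vcf(path: Path, het_policy: HetPolicy) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    acc_ids = list(vcf.samples)
    markers: list[SNPMarker] = []
    columns: list[np.ndarray] = []
    het_cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            warnings.warn(
                f"skipping non-biallelic-SNP record {rec.CHROM}:{rec.POS}",
                stacklevel=2,
            )
            continue
        chrom = _chrom_to_int(rec.CHROM)
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        markers.append(
            SNPMarker(id=mid, chrom=chrom, pos_bp=rec.POS,
                      allele_ref=rec.REF, allele_alt=rec.ALT[0])
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.full(len(acc_ids), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 3] = 1
        columns.append(col)
        het_cols.append(gt == 1)
    if not markers:
        raise PanelParseError(f"{path}: no biallelic SNP records")
    calls = np.stack(columns, axis=1)
    het = np.stack(het_cols, axis=1)
    calls = _resolve_hets(calls, het, het_policy)
    return _build_sorted(
        markers, [AccessionRecord(id=a) for a in acc_ids], calls, path
    )


def _resolve_hets(
    calls: np.ndarray, het: np.ndarray, het_policy: HetPolicy
) -> np.ndarray:
    if not het.any():
        return calls
    if het_policy == "het_as_missing":
        calls[het] = MISSING
        return calls
    if het_policy != "het_as_major":
        raise ValueError(f"unknown het policy {het_policy!r}")
    # Majority allele per SNP among unambiguous calls; ties go to ref.
    obs = (calls != MISSING) & ~het
    n1 = np.where(obs, calls == 1, False).sum(axis=0)
    n0 = np.where(obs, calls == 0, False).sum(axis=0)
    major = (n1 > n0).astype(np.int8)
    calls[het] = np.broadcast_to(major, calls.shape)[het]
    return calls


def _chrom_to_int(chrom: str) -> int:
    c = chrom.lower().removeprefix("chr")
    try:
        return int(c)
    except ValueError:
        raise PanelParseError(f"non-integer chromosome label {chrom!r}") from None


def _read_structure(path: Path, het_policy: HetPolicy) -> GenotypePanel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 2 != 0:
        raise PanelParseError(f"{path}: odd number of genotype rows")
    acc_ids: list[str] = []
    rows_a: list[list[int]] = []
    rows_b: list[list[int]] = []
    for pair_idx in range(0, len(lines), 2):
        a = lines[pair_idx].split()
        b = lines[pair_idx + 1].split()
        if a[0] != b[0]:
            raise PanelParseError(
                f"{path}: row pair {pair_idx // 2 + 1} has mismatched ids "
                f"{a[0]!r} vs {b[0]!r}"
            )
        if len(a) != len(b):
            raise PanelParseError(
                f"{path}: row pair for {a[0]!r} has unequal lengths"
            )
        acc_ids.append(a[0])
        rows_a.append([int(x) for x in a[1:]])
        rows_b.append([int(x) for x in b[1:]])
    alleles_a = np.array(rows_a, dtype=np.int16)
    alleles_b = np.array(rows_b, dtype=np.int16)
    missing = (alleles_a == -9) | (alleles_b == -9)
    het = (alleles_a != alleles_b) & ~missing
    calls = np.where(missing, MISSING, alleles_a).astype(np.int8)
    calls = _resolve_hets(calls, het, het_policy)
    marker_ids = [f"snp{j + 1}" for j in range(calls.shape[1])]
    markers = _read_map(map_path_for(path), marker_ids)
    return _build_sorted(
        markers, [AccessionRecord(id=a) for a in acc_ids], calls, path
    )


# ---------------------------------------------------------------------------
# writing


def write_panel(panel: GenotypePanel, path: str | Path, format: Format = "tsv_matrix") -> None:
    """Write a panel; the TSV dialect also writes its ``<path>.map`` sidecar."""
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "tsv_matrix":
        _write_tsv(panel, path)
    elif format == "vcf":
        _write_vcf(panel, path)
    else:
        _write_structure(panel, path)


def _write_tsv(panel: GenotypePanel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\t" + "\t".join(panel.marker_ids) + "\n")
        for i, acc in enumerate(panel.accessions):
            cells = [
                "NA" if c == MISSING else str(int(c)) for c in panel.calls[i]
            ]
            fh.write(acc.id + "\t" + "\t".join(cells) + "\n")
    with open(map_path_for(path), "w") as fh:
        for m in panel.markers:
            fh.write(
                f"{m.id}\t{m.chrom}\t{m.pos_bp}\t{m.allele_ref}\t{m.allele_alt}\n"
            )


_GT = {0: "0/0", 1: "1/1", MISSING: "./."}


def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=paddymix\n')
        for chrom in sorted({m.chrom for m in panel.markers}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.accession_ids)
            + "\n"
        )
        for j, m in enumerate(panel.markers):
            gts = "\t".join(_GT[int(c)] for c in panel.calls[:, j])
            fh.write(
                f"{m.chrom}\t{m.pos_bp}\t{m.id}\t{m.allele_ref}\t{m.allele_alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _write_structure(panel: GenotypePanel, path: Path) -> None:
    with open(path, "w") as fh:
        for i, acc in enumerate(panel.accessions):
            row = " ".join(
                "-9" if c == MISSING else str(int(c)) for c in panel.calls[i]
            )
            # Inbred: both allele rows identical.
            fh.write(f"{acc.id} {row}\n")
            fh.write(f"{acc.id} {row}\n")


# ---------------------------------------------------------------------------
# QC


def apply_qc(
    panel: GenotypePanel, maf_min: float = 0.01, max_missing: float = 0.2
) -> GenotypePanel:
    """Filter SNPs by minor allele frequency and missingness.

    Keeps SNPs whose MAF (over non-missing calls) is strictly greater than
    `maf_min` and whose missing fraction is at most `max_missing`. The
    accession set is unchanged and the input panel is not modified.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if not (0 <= max_missing <= 1):
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    maf = panel.minor_allele_freq()
    with np.errstate(invalid="ignore"):
        keep = (maf > maf_min) & (panel.missing_fraction() <= max_missing)
    keep &= ~np.isnan(maf)
    if not keep.any():
        raise ValueError("empty panel after QC: no SNP passed the filters")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("QC removed %d of %d SNPs", n_dropped, panel.n_markers)
    return panel.subset_markers(keep)
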
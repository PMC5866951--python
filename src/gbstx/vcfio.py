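"""VCF ingestion: from a pileup-caller VCF to genotype and allele-count matrices.

The pipeline starts where the upstream aligner/caller stops: a VCF of
candidate variants on transcriptome contigs.  This module extracts, per
sample, the bi-allelic genotype (count of alternate alleles), the read
depth, and — when the caller emitted allelic depths (``AD``) — the
(ref, alt) read counts, as rectangular matrices keyed by ``chrom:pos``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from cyvcf2 import VCF

from .matrices import MISSING, AlleleCountMatrix, GenotypeMatrix, MatrixError

log = logging.getLogger(__name__)


class VcfError(ValueError):
    """Raised for unusable VCF input."""


@dataclass
class VariantRecord:
    """One variant site with per-sample genotype/depth/allele-count data.

    ``genotypes[i]`` is an unphased allele-index pair ``(a, b)`` or ``None``
    for missing (half-missing calls collapse to missing).  ``allele_counts[i]``
    is ``(ref reads, alt reads)`` or ``None`` when the caller gave no ``AD``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    genotypes: list[tuple[int, int] | None]
    depths: list[int]
    allele_counts: list[tuple[int, int] | None]

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class ReadStats:
    """Per-stage counters for one VCF read pass."""

    total: int = 0
    kept: int = 0
    dropped_indel: int = 0
    dropped_multiallelic: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "kept": self.kept,
            "dropped_indel": self.dropped_indel,
            "dropped_multiallelic": self.dropped_multiallelic,
        }


def read_vcf(
    path: str | Path,
    drop_indels: bool = True,
    biallelic_only: bool = True,
    stats: ReadStats | None = None,
) -> Iterator[VariantRecord]:
    """Yield :class:`VariantRecord` for each retained data line of a VCF.

    Indels and multi-allelic sites are dropped at read time when the
    corresponding flags are set; drop counters accumulate in ``stats`` and
    are logged once the file is exhausted.  A VCF without genotype columns
    is rejected ("sites-only VCF").
    """
    path = str(path)
    if stats is None:
        stats = ReadStats()
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise VcfError(f"{path}: malformed VCF header ({exc})") from exc
    if len(vcf.samples) == 0:
        raise VcfError(f"{path}: sites-only VCF (no genotype columns)")

    lineno = 0  # data lines, 1-based
    try:
        for variant in vcf:
            lineno += 1
            stats.total += 1
            if drop_indels and (variant.is_indel or not variant.is_snp):
                stats.dropped_indel += 1
                continue
            if biallelic_only and len(variant.ALT) != 1:
                stats.dropped_multiallelic += 1
                continue
            stats.kept += 1
            yield _to_record(variant)
    except VcfError:
        raise
    except Exception as exc:
        raise VcfError(f"{path}: malformed record at data line {lineno + 1} ({exc})") from exc
    finally:
        log.info(
            "read_vcf %s: %d records, %d kept, %d indels dropped, %d multi-allelic dropped",
            path, stats.total, stats.kept, stats.dropped_indel, stats.dropped_multiallelic,
        )


def _to_record(variant) -> VariantRecord:
    n = len(variant.genotypes)
    genotypes: list[tuple[int, int] | None] = []
    for gt in variant.genotypes:
        a, b = gt[0], gt[1] if len(gt) > 2 else -1
        if a < 0 or b < 0:  # half-missing treated as missing
            genotypes.append(None)
        else:
            genotypes.append((a, b))  # phase discarded

    depths = [int(d) if d >= 0 else 0 for d in (variant.gt_depths if variant.gt_depths is not None else [-1] * n)]

    counts: list[tuple[int, int] | None] = [None] * n
    ad = variant.format("AD")
    if ad is not None:
        ad = np.asarray(ad)
        for i in range(n):
            r, a = int(ad[i, 0]), int(ad[i, 1]) if ad.shape[1] > 1 else 0
            if r < 0 or a < 0:
                counts[i] = None
            else:
                counts[i] = (r, a)

    return VariantRecord(
        chrom=variant.CHROM,
        pos=int(variant.POS),
        ref=variant.REF,
        alts=list(variant.ALT),
        genotypes=genotypes,
        depths=depths,
        allele_counts=counts,
    )


def build_matrices(
    records: Iterable[VariantRecord],
    samples: list[str],
) -> tuple[GenotypeMatrix, AlleleCountMatrix]:
    """Assemble the genotype and allele-count matrices from a record stream.

    Matrices share locus order (file order) and sample order.  Genotype
    entries are the count of alternate alleles; allele-count entries are
    missing where the record carries no per-sample ``AD`` or the genotype
    is missing.
    """
    loci: list[str] = []
    gt_rows: list[np.ndarray] = []
    ref_rows: list[np.ndarray] = []
    alt_rows: list[np.ndarray] = []
    seen: set[str] = set()
    n = len(samples)

    for rec in records:
        if len(rec.genotypes) != n:
            raise MatrixError(
                f"{rec.locus}: record has {len(rec.genotypes)} samples, expected {n}"
            )
        if rec.locus in seen:
            raise MatrixError(f"duplicate locus {rec.locus}")
        seen.add(rec.locus)
        loci.append(rec.locus)

        gt = np.full(n, MISSING, dtype=np.int16)
        ref = np.full(n, MISSING, dtype=np.int32)
        alt = np.full(n, MISSING, dtype=np.int32)
        for j, pair in enumerate(rec.genotypes):
            if pair is None:
                continue
            gt[j] = sum(1 for a in pair if a > 0)
            ac = rec.allele_counts[j]
            if ac is not None:
                ref[j], alt[j] = ac
        gt_rows.append(gt)
        ref_rows.append(ref)
        alt_rows.append(alt)

    shape = (len(loci), n)
    gm = GenotypeMatrix(loci, samples, np.vstack(gt_rows) if gt_rows else np.empty(shape, np.int16))
    cm = AlleleCountMatrix(
        loci, samples,
        np.vstack(ref_rows) if ref_rows else np.empty(shape, np.int32),
        np.vstack(alt_rows) if alt_rows else np.empty(shape, np.int32),
    )
    return gm, cm


def matrices_from_vcf(
    path: str | Path,
    drop_indels: bool = True,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, AlleleCountMatrix, ReadStats]:
    """Convenience wrapper: read a VCF and build both matrices in one pass."""
    stats = ReadStats()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    vcf.close()
    records = read_vcf(path, drop_indels=drop_indels, biallelic_only=biallelic_only, stats=stats)
    gm, cm = build_matrices(records, samples)
    return gm, cm, stats
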
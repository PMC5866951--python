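"""Generic SNP filter chain and population-aware filtering.

The chain applied to every species' genotype matrix, in this fixed order:

1. low-support masking (per-entry depth and alternate-read support),
2. sparse-sample removal,
3. locus missingness,
4. minor-allele-frequency (MAF),

with an alternative grouped mode that retains a locus when the MAF and
missingness criteria hold in at least one population even if they fail on
the pooled panel — the behaviour standard VCF tooling lacks for
structured panels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import ClassVar

import numpy as np

from .matrices import MISSING, AlleleCountMatrix, GenotypeMatrix, MatrixError, SampleMap

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """All thresholds of the filter chain.

    min_depth
        Reads required to keep any genotype entry (default 5).
    min_alt_reads
        Alternate-read support required before a SNP/alt call is accepted
        (default 4).  Entry-level for alt-carrying genotypes; in site-level
        (discovery) mode the threshold applies to the locus column sum.
    maf_threshold
        Minimum minor-allele frequency for a locus, inclusive (default 0.02;
        grouped per-population filtering conventionally uses 0.05).
    max_missing
        Maximum tolerated missing fraction per locus; strictly greater is
        removed (default 0.5).
    het_excess_threshold
        Heterozygosity proportion above which a locus is treated as a
        homoeolog misalignment artefact (default 0.4).
    dosage_tolerance
        Half-width of the allele-frequency bins for tetraploid dosage
        calling (default 0.05).
    """

    min_depth: int = 5
    min_alt_reads: int = 4
    maf_threshold: float = 0.02
    max_missing: float = 0.5
    het_excess_threshold: float = 0.4
    dosage_tolerance: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "max_missing", "het_excess_threshold", "dosage_tolerance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("min_depth", "min_alt_reads"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name}={v} must be a non-negative integer")

    #: per-population MAF default when filtering within groups
    POPULATION_MAF: ClassVar[float] = 0.05


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class FilterReport:
    """Chained per-stage counts plus per-sample removals with reasons."""

    stages: list[FilterStage] = field(default_factory=list)
    removed_samples: list[dict] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_removed: int) -> FilterStage:
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError(
                f"stage {name!r}: n_in={n_in} does not chain from previous "
                f"n_out={self.stages[-1].n_out}"
            )
        if n_removed > n_in:
            raise ValueError(f"stage {name!r}: removed {n_removed} > in {n_in}")
        stage = FilterStage(name, n_in, n_removed)
        self.stages.append(stage)
        log.info("filter stage %s: %d in, %d removed, %d out", name, n_in, n_removed, stage.n_out)
        return stage

    def to_json(self) -> str:
        payload = {
            "stages": [
                {**asdict(s), "n_out": s.n_out} for s in self.stages
            ],
            "removed_samples": self.removed_samples,
            "details": self.details,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# entry-level masking


def mask_low_support(
    genotypes: GenotypeMatrix,
    counts: AlleleCountMatrix,
    config: FilterConfig | None = None,
) -> GenotypeMatrix:
    """Blank genotype entries lacking read support.

    An entry becomes missing when its depth is below ``min_depth``, or when
    it carries an alternate allele (call 1 or 2) on fewer than
    ``min_alt_reads`` alternate reads.  Homozygous-reference entries only
    need the depth condition.
    """
    config = config or FilterConfig()
    if genotypes.loci != counts.loci or genotypes.samples != counts.samples:
        raise MatrixError("genotype and count matrices do not share axes")
    depth = counts.depth()
    data = genotypes.data.copy()
    low_depth = depth < config.min_depth
    weak_alt = (data > 0) & (counts.alt < config.min_alt_reads)
    data[low_depth | weak_alt] = MISSING
    return GenotypeMatrix(list(genotypes.loci), list(genotypes.samples), data)


def site_alt_support(counts: AlleleCountMatrix, min_alt_reads: int = 4) -> np.ndarray:
    """Discovery-mode site filter: boolean per locus, True when the column
    accumulates at least ``min_alt_reads`` alternate reads across samples —
    the support needed before the site is declared a SNP at all."""
    alt = np.where(counts.alt == MISSING, 0, counts.alt)
    return alt.sum(axis=1) >= min_alt_reads


# ---------------------------------------------------------------------------
# per-locus statistics


def maf(column: np.ndarray) -> float:
    """Minor-allele frequency of one locus from diploid calls.

    ``f = alt alleles / (2 x non-missing calls)``; returns ``min(f, 1-f)``.
    Missing calls are excluded from numerator and denominator.
    """
    column = np.asarray(column)
    ok = column != MISSING
    n = int(ok.sum())
    if n == 0:
        raise MatrixError("no data: all calls missing at locus")
    f = float(column[ok].sum()) / (2.0 * n)
    return min(f, 1.0 - f)


def _maf_vector(data: np.ndarray) -> np.ndarray:
    """Vectorised MAF per locus; NaN for all-missing loci."""
    ok = data != MISSING
    n = ok.sum(axis=1)
    alt = np.where(ok, data, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, alt / (2.0 * n), np.nan)
    return np.minimum(f, 1.0 - f)


def _missing_fraction(data: np.ndarray) -> np.ndarray:
    return (data == MISSING).mean(axis=1)


# ---------------------------------------------------------------------------
# locus filters


def filter_loci(
    genotypes: GenotypeMatrix,
    config: FilterConfig | None = None,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with excess missing data, then loci below the MAF cut.

    Missingness strictly above ``max_missing`` removes the locus;
    ``maf >= maf_threshold`` retains it (inclusive).  All-missing loci are
    removed at the missingness stage regardless of the threshold (their MAF
    is undefined).  Stage order is fixed so reports are reproducible.
    """
    config = config or FilterConfig()
    if report is None:
        report = FilterReport()
    if genotypes.n_loci == 0 or genotypes.n_samples == 0:
        raise MatrixError("empty genotype matrix")

    miss = _missing_fraction(genotypes.data)
    keep_miss = (miss <= config.max_missing) & (miss < 1.0)
    report.add_stage("locus_missingness", genotypes.n_loci, int((~keep_miss).sum()))
    m1 = genotypes.subset_loci(keep_miss)

    mafs = _maf_vector(m1.data)
    keep_maf = mafs >= config.maf_threshold
    report.add_stage("maf", m1.n_loci, int((~keep_maf).sum()))
    m2 = m1.subset_loci(keep_maf)
    return m2, report


def population_filter(
    genotypes: GenotypeMatrix,
    popmap: SampleMap,
    config: FilterConfig | None = None,
) -> tuple[list[str], FilterReport]:
    """Grouped filtering: retain a locus when the MAF criterion (with the
    missingness cap assessed in the same group) is satisfied in at least one
    population, even if the pooled panel fails it.

    Returns the retained locus list (input order) and a report whose
    ``details['per_locus_populations']`` names, per retained locus, the
    populations that satisfied the criterion.
    """
    config = config or FilterConfig(maf_threshold=FilterConfig.POPULATION_MAF)
    popmap.check_covers(genotypes.samples, "population")
    report = FilterReport()

    pops = popmap.populations()
    cols_by_pop = {
        p: [j for j, s in enumerate(genotypes.samples) if popmap.population[s] == p]
        for p in pops
    }
    satisfied: dict[str, list[str]] = {}
    keep = np.zeros(genotypes.n_loci, dtype=bool)
    for p in pops:
        sub = genotypes.data[:, cols_by_pop[p]]
        miss = _missing_fraction(sub)
        mafs = _maf_vector(sub)
        ok = (miss <= config.max_missing) & (mafs >= config.maf_threshold)  # NaN MAF compares False
        keep |= ok
        for i in np.flatnonzero(ok):
            satisfied.setdefault(genotypes.loci[i], []).append(p)

    report.add_stage("population_maf", genotypes.n_loci, int((~keep).sum()))
    report.details["per_locus_populations"] = satisfied
    retained = [l for l, k in zip(genotypes.loci, keep) if k]
    return retained, report


def consolidate_lists(
    list_a: dict[str, tuple[str, str]],
    list_b: dict[str, tuple[str, str]],
) -> tuple[dict[str, tuple[str, str]], int]:
    """Merge two per-group SNP lists (locus -> (ref, alt)).

    Loci present in both groups with different alternate alleles are
    tri-allelic across groups and are dropped (count returned).  A shared
    locus with conflicting *reference* alleles indicates upstream
    inconsistency and raises.
    """
    merged: dict[str, tuple[str, str]] = dict(list_a)
    n_triallelic = 0
    for locus, (ref, alt) in list_b.items():
        if locus not in merged:
            merged[locus] = (ref, alt)
            continue
        ref_a, alt_a = merged[locus]
        if ref_a != ref:
            raise MatrixError(f"{locus}: reference mismatch between lists ({ref_a} vs {ref})")
        if alt_a != alt:
            del merged[locus]
            n_triallelic += 1
    log.info("consolidate_lists: %d loci merged, %d tri-allelic removed", len(merged), n_triallelic)
    return merged, n_triallelic


def drop_sparse_samples(
    genotypes: GenotypeMatrix,
    max_sample_missing: float = 0.8,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove samples whose missing fraction exceeds the threshold."""
    if not 0.0 <= max_sample_missing <= 1.0:
        raise ValueError("max_sample_missing outside [0, 1]")
    miss = (genotypes.data == MISSING).mean(axis=0)
    removed = [s for s, m in zip(genotypes.samples, miss) if m > max_sample_missing]
    if len(removed) == genotypes.n_samples:
        raise MatrixError("all samples removed by missingness threshold")
    if report is not None:
        for s, m in zip(genotypes.samples, miss):
            if m > max_sample_missing:
                report.removed_samples.append(
                    {"sample": s, "reason": f"missing fraction {m:.3f} > {max_sample_missing}"}
                )
    kept = [s for s in genotypes.samples if s not in set(removed)]
    return genotypes.subset_samples(kept), removed
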
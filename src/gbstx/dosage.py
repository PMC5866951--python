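"""Tetraploid allele-dosage genotyping by allele-frequency binning.

Standard pileup callers assume uniform ploidy and cannot genotype a
segmental allotetraploid, where some chromosomes pair tetrasomically
(autopolyploid-style, dosage classes 0-4) and others disomically
(allopolyploid-style, behaving as diploid with classes {0, 2, 4}).  Here
the per-entry alternate-read fraction is binned around the five expected
dosage frequencies 0, 1/4, 1/2, 3/4, 1 with a +/-5% tolerance; fractions
falling in the gaps between bins are treated as missing.  Loci are then
kept when at least three distinct dosage classes segregate, and classified
as tetrasomic (all five classes observed) or disomic (exactly {0, 2, 4}).

A related artefact check for allotetraploids genotyped as diploids
(homoeolog misalignment): loci heterozygous in more than a threshold
proportion of samples are flagged as collapsed homoeologous sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import FilterConfig
from .matrices import (
    MISSING,
    AlleleCountMatrix,
    DosageMatrix,
    GenotypeMatrix,
    MatrixError,
)

PLOIDY = 4
_BIN_CENTERS = np.arange(PLOIDY + 1) / PLOIDY  # 0, .25, .5, .75, 1
# absolute guard so a frequency exactly on a bin edge (e.g. 0.80 for the
# 75-85% bin) is not lost to one-ulp rounding of the edge comparison
_EDGE_EPS = 1e-9


@dataclass
class InheritanceCall:
    locus: str
    mode: str  # "tetrasomic" | "disomic" | "ambiguous"
    observed_classes: tuple[int, ...]


def bin_dosage(alt_freq: float, tolerance: float = 0.05) -> int:
    """Dosage (0-4) whose expected frequency lies within ``tolerance`` of
    the observed alternate-allele fraction, or missing for gap frequencies.

    Bin edges are inclusive; with any tolerance below 0.125 the bins are
    disjoint so at most one dosage can match.
    """
    if np.isnan(alt_freq):
        return MISSING
    if not 0.0 <= alt_freq <= 1.0:
        raise ValueError(f"allele fraction {alt_freq} outside [0, 1]")
    d = int(round(alt_freq * PLOIDY))
    if abs(alt_freq - _BIN_CENTERS[d]) <= tolerance + _EDGE_EPS:
        return d
    return MISSING


def call_dosage_matrix(
    counts: AlleleCountMatrix,
    config: FilterConfig | None = None,
) -> DosageMatrix:
    """Elementwise frequency binning of an allele-count matrix.

    Entries below ``min_depth`` (including zero-depth and missing entries)
    become missing before binning.
    """
    config = config or FilterConfig()
    depth = counts.depth()
    freq = counts.alt_fraction()
    freq[depth < config.min_depth] = np.nan

    nearest = np.where(np.isnan(freq), 0, np.round(freq * PLOIDY)).astype(int)
    in_bin = np.abs(freq - _BIN_CENTERS[nearest]) <= config.dosage_tolerance + _EDGE_EPS
    data = np.where(np.isnan(freq) | ~in_bin, MISSING, nearest).astype(np.int16)
    return DosageMatrix(list(counts.loci), list(counts.samples), data)


def retain_polymorphic(column: np.ndarray, min_classes: int = 3) -> bool:
    """True when the locus shows at least ``min_classes`` distinct
    non-missing dosage classes across samples."""
    column = np.asarray(column)
    return len(set(column[column != MISSING].tolist())) >= min_classes


def classify_inheritance(column: np.ndarray, locus: str = "") -> InheritanceCall:
    """Inheritance mode of one locus from its observed dosage classes.

    All five classes -> tetrasomic; exactly {0, 2, 4} -> disomic; anything
    else -> ambiguous (the conservative default for partial class sets).
    """
    column = np.asarray(column)
    observed = tuple(sorted(set(column[column != MISSING].tolist())))
    if len(observed) == PLOIDY + 1:
        mode = "tetrasomic"
    elif observed == (0, 2, 4):
        mode = "disomic"
    else:
        mode = "ambiguous"
    return InheritanceCall(locus=locus, mode=mode, observed_classes=observed)


def inheritance_table(dosages: DosageMatrix, min_classes: int = 3) -> pd.DataFrame:
    """Per-locus polymorphism retention and inheritance classification,
    with a panel-level tetrasomic:disomic summary in ``df.attrs``."""
    records = []
    for i, locus in enumerate(dosages.loci):
        col = dosages.data[i]
        poly = retain_polymorphic(col, min_classes)
        call = classify_inheritance(col, locus) if poly else InheritanceCall(locus, "ambiguous", ())
        records.append(
            {"locus": locus, "polymorphic": poly, "mode": call.mode,
             "n_classes": len(call.observed_classes)}
        )
    df = pd.DataFrame.from_records(records)
    n_tetra = int((df["mode"] == "tetrasomic").sum())
    n_di = int((df["mode"] == "disomic").sum())
    df.attrs["n_tetrasomic"] = n_tetra
    df.attrs["n_disomic"] = n_di
    df.attrs["tetrasomic_fraction"] = n_tetra / (n_tetra + n_di) if n_tetra + n_di else np.nan
    return df


def het_excess_filter(column: np.ndarray, threshold: float = 0.4) -> bool:
    """True (remove) when the heterozygote proportion among non-missing
    diploid-coded calls exceeds ``threshold`` — the signature of reads from
    two homoeologous sub-genome copies collapsing onto one locus."""
    column = np.asarray(column)
    obs = column[column != MISSING]
    if obs.size == 0:
        raise MatrixError("all calls missing at locus")
    return float((obs == 1).mean()) > threshold


def apply_het_excess_filter(
    genotypes: GenotypeMatrix,
    threshold: float = 0.4,
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop misalignment-flagged loci; loci with no data are also dropped.
    Applied locus-by-locus (not gene-by-gene): homoeolog similarity varies
    within a gene, so well-aligning SNPs in the same contig survive."""
    removed: list[str] = []
    keep = np.ones(genotypes.n_loci, dtype=bool)
    for i, locus in enumerate(genotypes.loci):
        col = genotypes.data[i]
        if (col == MISSING).all() or het_excess_filter(col, threshold):
            keep[i] = False
            removed.append(locus)
    return genotypes.subset_loci(keep), removed
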
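"""Validation analytics: Nei's distance, neighbour-joining, ASE sampling.

Genotype quality is validated indirectly: replicated samples of known
varieties should cluster by variety on a neighbour-joining dendrogram of
Nei's (1972) standard genetic distance, computed here from per-sample
allele-frequency profiles (call / ploidy) with pairwise deletion of
missing loci.

The allele-specific-expression (ASE) model quantifies the main hazard of
genotyping from mRNA: if one allele of a heterozygote is expressed at
fraction ``p``, the chance of observing both alleles among ``n``
independent reads is ``1 - p^n - (1-p)^n``, so shallow sampling of skewed
transcripts miscalls heterozygotes as homozygotes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj as _skbio_nj

from .matrices import MISSING, MatrixError

log = logging.getLogger(__name__)


def allele_freq_profile(calls: np.ndarray, ploidy: int = 2) -> np.ndarray:
    """Per-locus alternate-allele frequency of one sample: call / ploidy,
    NaN where the call is missing."""
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    calls = np.asarray(calls, dtype=float)
    out = calls / ploidy
    out[calls == MISSING] = np.nan
    return out


def nei_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Nei's standard genetic distance between two frequency profiles.

    ``D = -ln( Jxy / sqrt(Jx * Jy) )`` with, over loci where both profiles
    are non-missing and summing over the two alleles per locus:
    ``Jxy = mean(x*y + (1-x)(1-y))``, ``Jx = mean(x^2 + (1-x)^2)``,
    ``Jy`` likewise.  Zero normalized identity gives +infinity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if not ok.any():
        raise MatrixError("no shared non-missing loci between profiles")
    xs, ys = x[ok], y[ok]
    jxy = float(np.mean(xs * ys + (1 - xs) * (1 - ys)))
    jx = float(np.mean(xs**2 + (1 - xs) ** 2))
    jy = float(np.mean(ys**2 + (1 - ys) ** 2))
    if jxy == 0.0:
        log.warning("nei_distance: zero identity, returning +inf")
        return math.inf
    return -math.log(jxy / math.sqrt(jx * jy))


def distance_matrix(matrix, ploidy: int = 2, popmap=None) -> pd.DataFrame:
    """Pairwise Nei distances between samples of a genotype/dosage matrix,
    or between populations (on population mean allele frequencies) when a
    ``popmap`` with population labels is given."""
    profiles = {}
    freqs = allele_freq_profile_matrix(matrix, ploidy)
    if popmap is None:
        names = matrix.samples
        for j, s in enumerate(names):
            profiles[s] = freqs[:, j]
    else:
        popmap.check_covers(matrix.samples, "population")
        names = popmap.populations()
        for p in names:
            cols = [j for j, s in enumerate(matrix.samples) if popmap.population[s] == p]
            with np.errstate(invalid="ignore"):
                profiles[p] = np.nanmean(freqs[:, cols], axis=1)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(profiles[names[i]], profiles[names[j]])
    return pd.DataFrame(d, index=names, columns=names)


def allele_freq_profile_matrix(matrix, ploidy: int = 2) -> np.ndarray:
    """Loci x samples matrix of alternate-allele frequencies (NaN missing)."""
    return allele_freq_profile(matrix.data, ploidy)


def nj_tree(d: pd.DataFrame):
    """Saitou-Nei neighbour joining on a square distance DataFrame.

    Returns an unrooted ``skbio.TreeNode``; negative branch-length
    estimates are clamped to zero.  Non-finite distances must be resolved
    by the caller (cap them or drop the offending pairs) first.
    """
    if d.shape[0] < 3:
        raise ValueError("neighbour joining needs at least 3 samples")
    values = d.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(
            "distance matrix contains non-finite entries; cap infinite "
            "distances or drop the offending sample pairs before NJ"
        )
    dm = SkbioDistanceMatrix(values, ids=[str(i) for i in d.index])
    return _skbio_nj(dm, neg_as_zero=True)


def to_newick(tree) -> str:
    return str(tree).strip()


def ase_detection_prob(major_fraction: float, depth: int) -> float:
    """Probability of sampling at least one read of each allele.

    Under independent read draws with major-allele fraction ``p`` the
    probability that ``n`` reads contain both alleles is
    ``1 - p^n - (1-p)^n``, clamped to [0, 1].  This is the chance a
    heterozygote with expression imbalance ``p : 1-p`` is even observable
    as heterozygous at depth ``n``.
    """
    if not 0.0 <= major_fraction <= 1.0:
        raise ValueError("major_fraction outside [0, 1]")
    if depth < 0 or int(depth) != depth:
        raise ValueError("depth must be a non-negative integer")
    p = major_fraction
    val = 1.0 - p**depth - (1.0 - p) ** depth
    return min(1.0, max(0.0, val))


def ase_table(
    major_fractions=(0.5, 0.6, 0.7, 0.8, 0.9),
    depths=(5, 10, 15, 20, 30, 50),
) -> pd.DataFrame:
    """Detection-probability table over expression ratios x read depths."""
    data = {
        n: [ase_detection_prob(p, n) for p in major_fractions] for n in depths
    }
    df = pd.DataFrame(data, index=[f"{int(p*100)}:{int(round((1-p)*100))}" for p in major_fractions])
    df.index.name = "expression_ratio"
    df.columns.name = "reads"
    return df


def missingness_vs_reads(genotypes, read_counts: dict[str, int]) -> pd.DataFrame:
    """Per-sample missing-call fraction against total sequencing yield.

    Returns a table (sample, reads, missing_fraction) sorted by read
    count — the diagnostic for how much library yield drives genotype
    completeness.
    """
    unmatched = [s for s in genotypes.samples if s not in read_counts]
    if unmatched:
        raise MatrixError(f"samples without read counts: {unmatched[:5]}")
    miss = (genotypes.data == MISSING).mean(axis=0)
    df = pd.DataFrame(
        {
            "sample": genotypes.samples,
            "reads": [read_counts[s] for s in genotypes.samples],
            "missing_fraction": miss,
        }
    )
    return df.sort_values("reads", ignore_index=True)
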
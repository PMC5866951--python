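"""Synthetic genotype panels with the statistical structure of
transcriptome-based genotyping studies.

Every generator is fully determined by its seed and parameter record and
emits the ground truth alongside the observation matrices, so each
pipeline stage can be tested against known answers:

* inbred diploid panels — single-seed-descent lines with residual
  heterozygosity (~4% per line at F7/F8), several seedlings per line;
* F1 pseudo-testcross families — loci segregating 1:1 (het x hom) or
  1:2:1 (het x het);
* segmental allotetraploid panels — a stated mixture of tetrasomic
  (dosage classes 0-4) and disomic ({0, 2, 4}) loci;
* homoeolog-misalignment artefacts — loci rewritten heterozygous in
  nearly all samples;
* read sampling — per-entry Poisson depth (with an optional log-normal
  per-locus expression weight) and binomial allele draws, optionally
  skewed by an allele-specific-expression ratio.  No per-read error by
  default; the filters under test target depth and misalignment, not
  base-call noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import (
    MISSING,
    AlleleCountMatrix,
    DosageMatrix,
    GenotypeMatrix,
    SampleMap,
)


@dataclass
class SyntheticTruth:
    """Ground truth and full parameter record of one simulated panel."""

    seed: int
    params: dict
    truth: np.ndarray  # true genotype (0-2) or dosage (0-4) matrix
    inheritance_mode: list[str] | None = None  # per locus, tetraploid panels
    misaligned: np.ndarray | None = None  # per-locus bool flags
    read_budget: np.ndarray | None = None  # total reads per sample


@dataclass
class InbredPanel:
    truth: SyntheticTruth
    genotypes: GenotypeMatrix  # observed seedling calls
    counts: AlleleCountMatrix
    linemap: SampleMap


@dataclass
class F1Family:
    truth: SyntheticTruth
    genotypes: GenotypeMatrix  # progeny calls
    parents: dict[str, tuple[int, int]]  # locus -> (parent1, parent2)


@dataclass
class TetraploidPanel:
    truth: SyntheticTruth
    counts: AlleleCountMatrix


def _loci(n: int) -> list[str]:
    return [f"ctg{i // 10 + 1}:{(i % 10 + 1) * 100}" for i in range(n)]


def sample_reads(
    truth: np.ndarray,
    ploidy: int,
    mean_depth: float,
    rng: np.random.Generator,
    depth_model: str = "poisson",
    locus_weight_sigma: float = 0.0,
    ase_major: float | None = None,
    error_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ref, alt) read counts for a truth matrix.

    Depth per entry is Poisson around ``mean_depth`` (or exactly
    ``mean_depth`` with ``depth_model='fixed'``), optionally modulated by a
    log-normal per-locus expression weight of the given sigma (mean 1).
    Alt reads are binomial with success probability truth/ploidy; for
    balanced heterozygotes an ASE major-allele fraction can skew the draw
    (major allele assigned to ref).  ``error_rate`` flips individual reads.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    n_loci, n_samples = truth.shape
    lam = np.full((n_loci, n_samples), float(mean_depth))
    if locus_weight_sigma > 0:
        w = rng.lognormal(mean=-locus_weight_sigma**2 / 2, sigma=locus_weight_sigma, size=n_loci)
        lam *= w[:, None]
    if depth_model == "poisson":
        depth = rng.poisson(lam)
    elif depth_model == "fixed":
        depth = np.round(lam).astype(int)
    else:
        raise ValueError(f"unknown depth model {depth_model!r}")

    frac = truth / float(ploidy)
    if ase_major is not None:
        balanced = np.isclose(frac, 0.5)
        frac = np.where(balanced, 1.0 - ase_major, frac)  # major allele -> ref
    alt = rng.binomial(depth, frac)
    ref = depth - alt
    if error_rate > 0:
        flipped_to_alt = rng.binomial(ref, error_rate)
        flipped_to_ref = rng.binomial(alt, error_rate)
        ref = ref - flipped_to_alt + flipped_to_ref
        alt = alt - flipped_to_ref + flipped_to_alt
    return ref.astype(np.int32), alt.astype(np.int32)


def call_genotypes_from_counts(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Naive diploid pileup-style caller for simulated reads: zero depth ->
    missing, only ref reads -> 0, only alt -> 2, both -> 1."""
    depth = ref + alt
    out = np.full(ref.shape, MISSING, dtype=np.int16)
    out[(depth > 0) & (alt == 0)] = 0
    out[(depth > 0) & (ref == 0)] = 2
    out[(ref > 0) & (alt > 0)] = 1
    return out


def simulate_inbred_panel(
    n_lines: int = 38,
    seedlings_per_line: int = 5,
    n_loci: int = 2000,
    residual_het: float = 0.0435,
    within_line_discordance: float = 0.0,
    mean_depth: float = 10.0,
    locus_weight_sigma: float = 1.0,
    alt_freq_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> InbredPanel:
    """Inbred diploid panel: lines from single-seed descent with residual
    heterozygosity, replicated seedlings, and read-sampled observations.

    Each line is heterozygous at a locus with probability ``residual_het``
    and otherwise homozygous for the alternate allele with the locus's
    population frequency.  Seedlings copy their line's genotype except for
    injected within-line discordance (a seedling flipped to the opposing
    homozygote — the signal the opposing-homs retention class detects).
    """
    if not 0.0 <= residual_het <= 1.0:
        raise ValueError("residual_het outside [0, 1]")
    rng = np.random.default_rng(seed)
    loci = _loci(n_loci)
    p = rng.uniform(*alt_freq_range, size=n_loci)

    het = rng.random((n_loci, n_lines)) < residual_het
    hom_alt = rng.random((n_loci, n_lines)) < p[:, None]
    line_truth = np.where(het, 1, np.where(hom_alt, 2, 0)).astype(np.int16)

    samples = [f"L{k+1:03d}_s{r+1}" for k in range(n_lines) for r in range(seedlings_per_line)]
    linemap = SampleMap(line={s: s.split("_")[0] for s in samples})

    seedling_truth = np.repeat(line_truth, seedlings_per_line, axis=1)
    if within_line_discordance > 0:
        disc = rng.random(seedling_truth.shape) < within_line_discordance
        flipped = np.where(seedling_truth == 0, 2, np.where(seedling_truth == 2, 0, 0))
        seedling_truth = np.where(disc, flipped, seedling_truth)

    ref, alt = sample_reads(
        seedling_truth, 2, mean_depth, rng, locus_weight_sigma=locus_weight_sigma
    )
    observed = call_genotypes_from_counts(ref, alt)

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_lines": n_lines, "seedlings_per_line": seedlings_per_line,
            "n_loci": n_loci, "residual_het": residual_het,
            "within_line_discordance": within_line_discordance,
            "mean_depth": mean_depth, "locus_weight_sigma": locus_weight_sigma,
            "alt_freq_range": list(alt_freq_range),
        },
        truth=seedling_truth,
        read_budget=(ref + alt).sum(axis=0),
    )
    return InbredPanel(
        truth=truth,
        genotypes=GenotypeMatrix(loci, samples, observed),
        counts=AlleleCountMatrix(loci, samples, ref, alt),
        linemap=linemap,
    )


def simulate_f1_cross(
    n_progeny: int = 95,
    n_loci_11: int = 500,
    n_loci_121: int = 500,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> F1Family:
    """F1 pseudo-testcross family: the first ``n_loci_11`` loci segregate
    1:1 (parent1 het x parent2 hom-ref), the rest 1:2:1 (het x het).
    Progeny genotypes are exact Mendelian draws; an optional missing rate
    masks calls at random."""
    rng = np.random.default_rng(seed)
    n_loci = n_loci_11 + n_loci_121
    loci = _loci(n_loci)
    samples = [f"F1_{i+1:03d}" for i in range(n_progeny)]

    geno = np.empty((n_loci, n_progeny), dtype=np.int16)
    # 1:1 — gametes: het parent passes alt with p=1/2, hom-ref parent passes ref
    geno[:n_loci_11] = rng.binomial(1, 0.5, size=(n_loci_11, n_progeny))
    # 1:2:1 — both parents pass alt with p=1/2
    geno[n_loci_11:] = rng.binomial(1, 0.5, size=(n_loci_121, n_progeny)) + rng.binomial(
        1, 0.5, size=(n_loci_121, n_progeny)
    )
    truth_geno = geno.copy()
    if missing_rate > 0:
        geno = geno.copy()
        geno[rng.random(geno.shape) < missing_rate] = MISSING

    parents = {
        loci[i]: (1, 0) if i < n_loci_11 else (1, 1) for i in range(n_loci)
    }
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_progeny": n_progeny, "n_loci_11": n_loci_11,
            "n_loci_121": n_loci_121, "missing_rate": missing_rate,
        },
        truth=truth_geno,
        inheritance_mode=["1:1"] * n_loci_11 + ["1:2:1"] * n_loci_121,
    )
    return F1Family(truth=truth, genotypes=GenotypeMatrix(loci, samples, geno), parents=parents)


def simulate_tetraploid_panel(
    n_samples: int = 285,
    n_loci: int = 1000,
    prop_tetrasomic: float = 0.8,
    mean_depth: float = 250.0,
    alt_freq_range: tuple[float, float] = (0.4, 0.6),
    seed: int = 0,
) -> TetraploidPanel:
    """Segmental allotetraploid panel with a stated tetrasomic:disomic
    locus mixture (default 4:1) and binomial read sampling.

    Tetrasomic loci draw dosages Binomial(4, p) per sample (random
    chromosome pairing among four homologues); disomic loci draw a diploid
    genotype Binomial(2, p) and double it, so only {0, 2, 4} occur.  Locus
    alternate-allele frequencies are intermediate (default U(0.4, 0.6)),
    emulating loci whose five dosage classes are actually resolvable in a
    panel — the regime the frequency-binning caller is designed for.
    """
    if not 0.0 <= prop_tetrasomic <= 1.0:
        raise ValueError("prop_tetrasomic outside [0, 1]")
    rng = np.random.default_rng(seed)
    loci = _loci(n_loci)
    samples = [f"T{i+1:03d}" for i in range(n_samples)]
    p = rng.uniform(*alt_freq_range, size=n_loci)
    is_tetra = rng.random(n_loci) < prop_tetrasomic

    dosage = np.empty((n_loci, n_samples), dtype=np.int16)
    tetra_rows = np.flatnonzero(is_tetra)
    di_rows = np.flatnonzero(~is_tetra)
    dosage[tetra_rows] = rng.binomial(4, p[tetra_rows][:, None], size=(len(tetra_rows), n_samples))
    dosage[di_rows] = 2 * rng.binomial(2, p[di_rows][:, None], size=(len(di_rows), n_samples))

    ref, alt = sample_reads(dosage, 4, mean_depth, rng)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_samples": n_samples, "n_loci": n_loci,
            "prop_tetrasomic": prop_tetrasomic, "mean_depth": mean_depth,
            "alt_freq_range": list(alt_freq_range),
        },
        truth=dosage,
        inheritance_mode=["tetrasomic" if t else "disomic" for t in is_tetra],
        read_budget=(ref + alt).sum(axis=0),
    )
    return TetraploidPanel(truth=truth, counts=AlleleCountMatrix(loci, samples, ref, alt))


def inject_misalignment(
    matrix,
    prop_loci: float = 0.05,
    het_rate: float = 0.99,
    seed: int = 0,
):
    """Overwrite a random locus subset with homoeolog-collapse artefacts.

    Each sample at a flagged locus becomes heterozygous with probability
    ``het_rate``: genotype matrices get call 1; allele-count matrices get a
    balanced (depth/2, depth/2) split at the entry's existing depth.
    Returns (modified matrix, per-locus boolean flags).
    """
    if not (0.0 <= prop_loci <= 1.0 and 0.0 <= het_rate <= 1.0):
        raise ValueError("prop_loci and het_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_loci = matrix.n_loci
    flags = np.zeros(n_loci, dtype=bool)
    n_pick = int(round(prop_loci * n_loci))
    flags[rng.choice(n_loci, size=n_pick, replace=False)] = True

    if isinstance(matrix, GenotypeMatrix):
        data = matrix.data.copy()
        for i in np.flatnonzero(flags):
            make_het = rng.random(matrix.n_samples) < het_rate
            row = data[i]
            row[make_het & (row != MISSING)] = 1
            data[i] = row
        return GenotypeMatrix(list(matrix.loci), list(matrix.samples), data), flags

    if isinstance(matrix, AlleleCountMatrix):
        ref = matrix.ref.copy()
        alt = matrix.alt.copy()
        for i in np.flatnonzero(flags):
            make_het = rng.random(matrix.n_samples) < het_rate
            present = matrix.ref[i] != MISSING
            sel = make_het & present
            depth = (matrix.ref[i] + matrix.alt[i])[sel]
            ref[i, sel] = depth // 2
            alt[i, sel] = depth - depth // 2
        return AlleleCountMatrix(list(matrix.loci), list(matrix.samples), ref, alt), flags

    raise TypeError(f"cannot inject misalignment into {type(matrix).__name__}")
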
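"""In-memory genotype containers for transcriptome-based SNP genotyping.

Three rectangular loci x samples matrices carry the pipeline state:

* :class:`GenotypeMatrix` — diploid calls coded as the count of alternate
  alleles, ``{0, 1, 2}``, with ``-1`` for missing.
* :class:`AlleleCountMatrix` — per-entry ``(ref reads, alt reads)`` pairs,
  the raw material for allele-frequency dosage calling and depth masking.
* :class:`DosageMatrix` — tetraploid calls ``{0..4}`` (copies of the
  alternate allele), ``-1`` for missing.

All three share a plain-text TSV dialect: one header row whose first field
is ``chrom:pos`` followed by sample names, one row per locus keyed by
``chrom:pos``, missing encoded as ``NA``.  Allele-count cells are written
``ref,alt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing call in integer-coded matrices.
MISSING: int = -1

_MISSING_TOKEN = "NA"


class MatrixError(ValueError):
    """Raised for malformed or inconsistent matrix data."""


def _check_axes(loci: Sequence[str], samples: Sequence[str]) -> None:
    if len(set(loci)) != len(loci):
        dupes = pd.Index(loci)[pd.Index(loci).duplicated()].unique().tolist()
        raise MatrixError(f"duplicate locus identifiers: {dupes[:5]}")
    if len(set(samples)) != len(samples):
        raise MatrixError("duplicate sample identifiers")


@dataclass
class _IntMatrix:
    """Shared behaviour of the integer-coded (genotype/dosage) matrices."""

    loci: list[str]
    samples: list[str]
    data: np.ndarray  # shape (n_loci, n_samples), int, MISSING for missing

    _max_value: int = field(default=2, init=False, repr=False)

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        self.samples = list(self.samples)
        self.data = np.asarray(self.data, dtype=np.int16)
        _check_axes(self.loci, self.samples)
        if self.data.shape != (len(self.loci), len(self.samples)):
            raise MatrixError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        valid = (self.data == MISSING) | (
            (self.data >= 0) & (self.data <= self._max_value)
        )
        if not valid.all():
            bad = np.unique(self.data[~valid])
            raise MatrixError(f"invalid calls {bad.tolist()}; allowed 0..{self._max_value} or {MISSING}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missing_mask(self) -> np.ndarray:
        return self.data == MISSING

    def subset_loci(self, keep: Iterable[str] | np.ndarray):
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array([i for i, l in enumerate(self.loci) if l in wanted], dtype=int)
        return type(self)(
            [self.loci[i] for i in idx], list(self.samples), self.data[idx]
        )

    def subset_samples(self, keep: Iterable[str]):
        wanted = set(keep)
        idx = [i for i, s in enumerate(self.samples) if s in wanted]
        return type(self)(
            list(self.loci), [self.samples[i] for i in idx], self.data[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data.astype(float), index=self.loci, columns=self.samples)
        return df.mask(df == MISSING)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, type(self)):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and np.array_equal(self.data, other.data)
        )


class GenotypeMatrix(_IntMatrix):
    """Bi-allelic diploid calls: 0 hom-ref, 1 het, 2 hom-alt, -1 missing."""

    _max_value = 2


class DosageMatrix(_IntMatrix):
    """Tetraploid alternate-allele dosage calls 0..4, -1 missing."""

    _max_value = 4


@dataclass
class AlleleCountMatrix:
    """Per-entry (ref reads, alt reads); both -1 where counts are missing."""

    loci: list[str]
    samples: list[str]
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        self.samples = list(self.samples)
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        _check_axes(self.loci, self.samples)
        shape = (len(self.loci), len(self.samples))
        if self.ref.shape != shape or self.alt.shape != shape:
            raise MatrixError("count array shape does not match axes")
        if ((self.ref == MISSING) != (self.alt == MISSING)).any():
            raise MatrixError("ref/alt missingness must coincide")
        if ((self.ref < MISSING) | (self.alt < MISSING)).any():
            raise MatrixError("negative read counts")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missing_mask(self) -> np.ndarray:
        return self.ref == MISSING

    def depth(self) -> np.ndarray:
        """Total reads per entry; 0 where counts are missing."""
        d = self.ref + self.alt
        d[self.missing_mask()] = 0
        return d

    def alt_fraction(self) -> np.ndarray:
        """Alternate-read fraction per entry; NaN where depth is 0 or missing."""
        d = self.depth().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(d > 0, self.alt / d, np.nan)
        f[self.missing_mask()] = np.nan
        return f

    def subset_loci(self, keep: Iterable[str] | np.ndarray) -> "AlleleCountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array([i for i, l in enumerate(self.loci) if l in wanted], dtype=int)
        return AlleleCountMatrix(
            [self.loci[i] for i in idx], list(self.samples), self.ref[idx], self.alt[idx]
        )

    def subset_samples(self, keep: Iterable[str]) -> "AlleleCountMatrix":
        wanted = set(keep)
        idx = [i for i, s in enumerate(self.samples) if s in wanted]
        return AlleleCountMatrix(
            list(self.loci), [self.samples[i] for i in idx],
            self.ref[:, idx], self.alt[:, idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
        )


@dataclass
class SampleMap:
    """Sample -> population and/or inbred-line labels.

    Populations drive grouped MAF filtering; lines drive per-line consensus
    genotyping of replicated seedlings.
    """

    population: dict[str, str] = field(default_factory=dict)
    line: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping, what in ((self.population, "population"), (self.line, "line")):
            for sample, label in mapping.items():
                if not str(label).strip():
                    raise MatrixError(f"empty {what} label for sample {sample!r}")

    def check_covers(self, samples: Iterable[str], which: str = "population") -> None:
        mapping = self.population if which == "population" else self.line
        missing = [s for s in samples if s not in mapping]
        if missing:
            raise MatrixError(f"samples not mapped to a {which}: {missing[:5]}")

    def populations(self) -> list[str]:
        return sorted(set(self.population.values()))

    def lines(self) -> list[str]:
        return sorted(set(self.line.values()))


def read_sample_map(path: str | Path) -> SampleMap:
    """Read a sample map TSV with columns ``sample`` plus ``population``
    and/or ``line``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise MatrixError(f"{path}: sample map needs a 'sample' column")
    pop = {}
    line = {}
    if "population" in df.columns:
        pop = dict(zip(df["sample"], df["population"]))
    if "line" in df.columns:
        line = dict(zip(df["sample"], df["line"]))
    if not pop and not line:
        raise MatrixError(f"{path}: need a 'population' or 'line' column")
    return SampleMap(population=pop, line=line)


# ---------------------------------------------------------------------------
# TSV round trip


def write_matrix(matrix, path: str | Path) -> None:
    """Write a matrix in the shared TSV dialect (``NA`` = missing)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom:pos\t" + "\t".join(matrix.samples) + "\n")
        if isinstance(matrix, AlleleCountMatrix):
            miss = matrix.missing_mask()
            for i, locus in enumerate(matrix.loci):
                cells = [
                    _MISSING_TOKEN if miss[i, j] else f"{matrix.ref[i, j]},{matrix.alt[i, j]}"
                    for j in range(matrix.n_samples)
                ]
                fh.write(locus + "\t" + "\t".join(cells) + "\n")
        else:
            for i, locus in enumerate(matrix.loci):
                cells = [
                    _MISSING_TOKEN if v == MISSING else str(int(v))
                    for v in matrix.data[i]
                ]
                fh.write(locus + "\t" + "\t".join(cells) + "\n")


def read_matrix(path: str | Path, kind: str = "auto"):
    """Read a TSV matrix; ``kind`` in {'auto','genotype','dosage','counts'}.

    Auto-detection: any cell containing a comma means allele counts; an
    integer cell above 2 means dosage; otherwise genotype.  A dosage matrix
    whose values never exceed 2 is indistinguishable from a genotype matrix,
    so pass ``kind='dosage'`` explicitly when it matters.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2:
            raise MatrixError(f"{path}: header has no sample columns")
        samples = cols[1:]
        loci: list[str] = []
        rows: list[list[str]] = []
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise MatrixError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            loci.append(parts[0])
            rows.append(parts[1:])

    is_counts = kind == "counts"
    if kind == "auto":
        is_counts = any("," in c for row in rows for c in row)

    if is_counts:
        shape = (len(loci), len(samples))
        ref = np.full(shape, MISSING, dtype=np.int32)
        alt = np.full(shape, MISSING, dtype=np.int32)
        for i, row in enumerate(rows):
            for j, cell in enumerate(row):
                if cell == _MISSING_TOKEN:
                    continue
                try:
                    r, a = cell.split(",")
                    ref[i, j] = int(r)
                    alt[i, j] = int(a)
                except ValueError as exc:
                    raise MatrixError(
                        f"{path}: bad count cell {cell!r} at locus {loci[i]}"
                    ) from exc
        return AlleleCountMatrix(loci, samples, ref, alt)

    data = np.full((len(loci), len(samples)), MISSING, dtype=np.int16)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell == _MISSING_TOKEN:
                continue
            try:
                data[i, j] = int(cell)
            except ValueError as exc:
                raise MatrixError(
                    f"{path}: unknown token {cell!r} at locus {loci[i]}"
                ) from exc
    if kind == "dosage" or (kind == "auto" and data.max(initial=0) > 2):
        return DosageMatrix(loci, samples, data)
    return GenotypeMatrix(loci, samples, data)
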